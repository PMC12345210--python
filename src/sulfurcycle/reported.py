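"""Published maximal-rate measurements used as fixture inputs.

The maximal transformation rates of the Bohai Sea surface-sediment
incubations are wet-lab measurements; they enter this package only as
inputs. Two printings exist that disagree in the last digit: the figure
caption (taken as canonical here) and the running text. The text also
reports a directly measured biological sulfite oxidation rate (12.8) that
is not the total-minus-chemical difference (13.10 − 1.34 = 11.76); both
sulfite addends are therefore exposed and selected by the flux-network
convention.

:func:`fixture_rate_estimates` turns a chosen printing into rate
estimates by engineering noiseless three-replicate time courses whose
first sampling interval embeds each rate, and running the first-interval
estimator on them — so every downstream number is produced by the same
code path that handles measured data.
"""

from __future__ import annotations

from .fluxes import RateEstimate, TimeCoursePanel, estimate_max_rate
from .synthetic import incubation_fixture

#: Figure-caption printing (canonical): role -> (value, sem), µmol/h/g.
FIG5_CAPTION_RATES = {
    "sulfide_total_consumption": (140.58, 11.59),
    "sulfide_chemical_consumption": (76.52, 10.86),
    "zvs_production": (155.07, 3.06),
    "thiosulfate_production": (10.21, 1.08),
    "sulfite_net_production": (25.22, 2.69),
    "sulfite_total_consumption": (13.10, 1.05),
    "sulfite_chemical_oxidation": (1.34, 0.15),
    "sulfate_production": (19.97, 1.67),
}

#: Running-text printing, including the directly reported biological
#: sulfite oxidation rate used by the text convention.
RESULTS_TEXT_RATES = {
    "sulfide_total_consumption": (140.3, 11.6),
    "sulfide_chemical_consumption": (76.4, 10.8),
    "zvs_production": (154.8, 3.1),
    "thiosulfate_production": (10.2, 1.1),
    "sulfite_net_production": (25.2, 2.7),
    "sulfite_biological_oxidation": (12.8, 1.0),
}

#: Series geometry per role: (species, direction, group, component).
_ROLE_SERIES = {
    "sulfide_total_consumption": ("sulfide", "consumption", "experimental", "total"),
    "sulfide_chemical_consumption": ("sulfide", "consumption", "control", "chemical"),
    "zvs_production": ("zerovalent_sulfur", "production", "experimental", "total"),
    "thiosulfate_production": ("thiosulfate", "production", "experimental", "total"),
    "sulfite_net_production": ("sulfite", "production", "experimental", "total"),
    "sulfite_total_consumption": ("sulfite", "consumption", "experimental", "total"),
    "sulfite_chemical_oxidation": ("sulfite", "consumption", "control", "chemical"),
    "sulfite_biological_oxidation": ("sulfite", "consumption", "experimental", "biological"),
    "sulfate_production": ("sulfate", "production", "experimental", "total"),
}


def fixture_panel(role: str, value: float) -> TimeCoursePanel:
    """Noiseless panel whose first-interval scaled slope equals `value`."""
    species, direction, group, _ = _ROLE_SERIES[role]
    return incubation_fixture(
        incubation_id=f"fixture_{role}",
        species=species,
        direction=direction,
        group=group,
        rate_umol_h_g=value,
    )


def fixture_rate_estimates(source: str = "fig5") -> dict[str, RateEstimate]:
    """Role-named rate estimates recovered from engineered time courses.

    `source` is "fig5" (caption printing) or "text" (running-text
    printing). The estimates are computed by the first-interval estimator
    on the engineered panels, not assigned.
    """
    table = {"fig5": FIG5_CAPTION_RATES, "text": RESULTS_TEXT_RATES}[source]
    out: dict[str, RateEstimate] = {}
    for role, (value, _sem) in table.items():
        species, direction, group, component = _ROLE_SERIES[role]
        panel = fixture_panel(role, value)
        out[role] = estimate_max_rate(
            panel, species, direction, method="first_interval",
            group=group, component=component,
        )
    return out
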