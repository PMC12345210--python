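"""Maximal sulfur-transformation rates from slurry incubations and the
mass-balance flux network.

Spiked slurry incubations (experimental / heat-killed control / blank) are
sampled on a fixed time grid. Because substrate limitation and product
accumulation slow every transformation as the incubation proceeds, the
maximal rate of a species is estimated from the first sampling interval
after substrate addition (the "first-interval convention"); for processes
that stay linear over the whole incubation a whole-period least-squares
slope is used instead.

Rates are expressed in µmol of sulfur species per hour per gram of wet
sediment:

    rate = |Δconc (µmol/L)| × liquid_L / (Δt (h) × sediment_g)

The biological component of a consumption rate is the total (experimental)
rate minus the chemical (heat-killed control) rate. The individual rate
estimates are then assembled into a five-node mass-balance network
(sulfide → zerovalent sulfur → sulfite → sulfate, with a thiosulfate side
branch): zerovalent-sulfur oxidation to sulfite is the sum of net sulfite
production and the sulfite consumption fluxes, and the residual between
zerovalent-sulfur production and its accounted consumption is reported as
its "unknown fate".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SPECIES = ("sulfide", "zerovalent_sulfur", "thiosulfate", "sulfite", "sulfate")
GROUPS = ("experimental", "control", "blank")
DIRECTIONS = ("consumption", "production")
COMPONENTS = ("total", "chemical", "biological")
METHODS = ("first_interval", "whole_period_linear")

#: The two published conventions for the sulfite-consumption addend in the
#: zerovalent-sulfur-to-sulfite flux: the figure uses the total sulfite
#: consumption rate, the running text uses the biological sulfite oxidation
#: rate. They differ in the second decimal of the summed flux.
CONVENTIONS = ("fig6_total_sulfite_consumption", "text_biological_sulfite_oxidation")


class CensoredDataError(ValueError):
    """All values of a series fall below the detection limit."""

    def __init__(self, species: str):
        self.species = species
        super().__init__(
            f"all {species} concentrations are below the detection limit; "
            "no rate can be estimated"
        )


def round_report(value: float, ndigits: int = 2) -> float:
    """Round half-up to `ndigits` decimals, the convention used when
    reporting rates (banker's rounding would round 48.525 down)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TimeCoursePanel:
    """Measured concentrations for one incubation setup.

    `data` is a long-format table with columns
    ``species, group, replicate, time_h, conc_uM`` (conc may be NaN for
    below-detection-limit samples). `sediment_g` and `liquid_L` are the wet
    sediment mass and the added liquid volume of the slurry; `lod_uM` maps
    species to their assay detection limits.
    """

    incubation_id: str
    data: pd.DataFrame
    sediment_g: float
    liquid_L: float
    lod_uM: Mapping[str, float] = field(default_factory=dict)

    REQUIRED_COLUMNS = ("species", "group", "replicate", "time_h", "conc_uM")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"time-course table missing columns: {missing}")
        if self.sediment_g <= 0:
            raise ValueError("sediment_g must be positive")
        if self.liquid_L <= 0:
            raise ValueError("liquid_L must be positive")
        bad_species = set(self.data["species"]) - set(SPECIES)
        if bad_species:
            raise ValueError(f"unknown species: {sorted(bad_species)}")
        bad_groups = set(self.data["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown groups: {sorted(bad_groups)}")
        for (sp, grp, rep), sub in self.data.groupby(["species", "group", "replicate"]):
            t = sub["time_h"].to_numpy(dtype=float)
            if (t < 0).any():
                raise ValueError(f"negative time in series {(sp, grp, rep)}")
            if len(np.unique(t)) != len(t) or (np.diff(np.sort(t)) <= 0).any():
                raise ValueError(f"times not strictly increasing in series {(sp, grp, rep)}")
        self.data = self.data.sort_values(["species", "group", "replicate", "time_h"]).reset_index(
            drop=True
        )

    def series(self, species: str, group: str) -> pd.DataFrame:
        """Wide table time_h × replicate for one species/group, NaN where
        the measurement is missing or below the detection limit."""
        sub = self.data[(self.data["species"] == species) & (self.data["group"] == group)]
        if sub.empty:
            return pd.DataFrame()
        wide = sub.pivot(index="time_h", columns="replicate", values="conc_uM").sort_index()
        lod = self.lod_uM.get(species)
        if lod is not None:
            wide = wide.mask(wide < lod)
        return wide

    def has_group(self, species: str, group: str) -> bool:
        return not self.series(species, group).empty


@dataclass
class RateEstimate:
    """A maximal consumption or production rate in µmol/h/g wet sediment."""

    species: str
    direction: str
    component: str
    value: float
    sem: float | None = None
    method: str | None = None
    n_replicates: int | None = None
    flags: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if self.sem is not None and self.sem < 0:
            raise ValueError("sem must be non-negative")

    @property
    def rounded(self) -> float:
        return round_report(self.value)


def _replicate_rate_first_interval(
    t: np.ndarray, c: np.ndarray, blank_drift: np.ndarray | None
) -> float:
    if np.isnan(c[0]) or np.isnan(c[1]):
        raise ValueError("first post-addition interval has missing or below-LOD values")
    dconc = c[1] - c[0]
    if blank_drift is not None:
        dconc -= blank_drift[1] - blank_drift[0]
    return abs(dconc) / (t[1] - t[0])


def _replicate_rate_whole_period(
    t: np.ndarray, c: np.ndarray, blank_drift: np.ndarray | None
) -> float:
    if blank_drift is not None:
        c = c - (blank_drift - blank_drift[0])
    ok = ~np.isnan(c)
    if ok.sum() < 3:
        raise ValueError("whole-period fit needs at least 3 non-missing timepoints")
    slope = np.polyfit(t[ok], c[ok], 1)[0]
    return abs(slope)


def linearity_r2(t: np.ndarray, c: np.ndarray) -> float:
    """R² of a straight-line fit; advisory heuristic for choosing the
    whole-period method (R² > 0.98 suggests the process stayed linear)."""
    ok = ~np.isnan(c)
    t, c = t[ok], c[ok]
    slope, intercept = np.polyfit(t, c, 1)
    resid = c - (slope * t + intercept)
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def estimate_max_rate(
    panel: TimeCoursePanel,
    species: str,
    direction: str,
    method: str = "first_interval",
    group: str = "experimental",
    component: str = "total",
    blank_correct: bool = True,
) -> RateEstimate:
    """Estimate the maximal transformation rate of `species` from `panel`.

    `method="first_interval"` scales the concentration change over the
    first sampling interval; `method="whole_period_linear"` uses the
    ordinary least-squares slope over the whole series. Rates from the
    control group carry ``component="chemical"`` by convention (pass
    ``group="control", component="chemical"``). If a blank series exists on
    the same time grid its drift is subtracted from the concentration
    changes before scaling.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    wide = panel.series(species, group)
    if wide.empty:
        raise ValueError(f"no {group} series for {species} in {panel.incubation_id}")
    if len(wide) < 2:
        raise ValueError(f"{species} {group} series has fewer than 2 timepoints")
    if method == "whole_period_linear" and len(wide) < 3:
        raise ValueError("whole_period_linear requires at least 3 timepoints")
    if wide.isna().all().all():
        raise CensoredDataError(species)

    t = wide.index.to_numpy(dtype=float)
    blank_drift = None
    if blank_correct:
        blank = panel.series(species, "blank")
        if not blank.empty and np.array_equal(blank.index.to_numpy(dtype=float), t):
            blank_drift = blank.mean(axis=1).to_numpy(dtype=float)
        elif not blank.empty:
            warnings.warn(
                f"blank series for {species} is not on the experimental time grid; "
                "blank correction skipped",
                stacklevel=2,
            )
        # no blank at all: silently skipped, the setup may not include one

    per_rep = []
    fit = (
        _replicate_rate_first_interval
        if method == "first_interval"
        else _replicate_rate_whole_period
    )
    for rep in wide.columns:
        c = wide[rep].to_numpy(dtype=float)
        per_rep.append(fit(t, c, blank_drift))

    scale = panel.liquid_L / panel.sediment_g
    scaled = np.asarray(per_rep) * scale
    value = float(scaled.mean())
    sem = float(scaled.std(ddof=1) / math.sqrt(len(scaled))) if len(scaled) > 1 else None

    flags = []
    if method == "first_interval":
        r2 = linearity_r2(t, wide.mean(axis=1).to_numpy(dtype=float))
        if r2 > 0.98 and len(t) >= 3:
            flags.append("linear_series_consider_whole_period")

    return RateEstimate(
        species=species,
        direction=direction,
        component=component,
        value=value,
        sem=sem,
        method=method,
        n_replicates=len(scaled),
        flags=flags,
        provenance={
            "incubation_id": panel.incubation_id,
            "group": group,
            "per_replicate": [float(x) for x in scaled],
            "blank_corrected": blank_drift is not None,
        },
    )


def biological_rate(total: RateEstimate, chemical: RateEstimate) -> RateEstimate:
    """Biological component = total − chemical, SEMs propagated in
    quadrature. A negative difference is returned as-is but flagged."""
    if total.species != chemical.species or total.direction != chemical.direction:
        raise ValueError(
            "total and chemical rates must describe the same species and direction "
            f"(got {total.species}/{total.direction} vs {chemical.species}/{chemical.direction})"
        )
    if total.component != "total" or chemical.component != "chemical":
        raise ValueError("expected components 'total' and 'chemical'")
    value = total.value - chemical.value
    sem = None
    if total.sem is not None and chemical.sem is not None:
        sem = math.hypot(total.sem, chemical.sem)
    flags = ["negative_biological_rate"] if value < 0 else []
    return RateEstimate(
        species=total.species,
        direction=total.direction,
        component="biological",
        value=value,
        sem=sem,
        method=total.method,
        n_replicates=total.n_replicates,
        flags=flags,
        provenance={"total": total.value, "chemical": chemical.value},
    )


def zvs_oxidation_to_sulfite(
    sulfite_net_production: RateEstimate,
    thiosulfate_production: RateEstimate,
    sulfite_consumption: RateEstimate,
) -> RateEstimate:
    """Zerovalent-sulfur oxidation to sulfite, inferred by mass balance.

    Zerovalent sulfur cannot be spiked directly (insoluble), so its
    oxidation flux to sulfite is the sum of the observed net sulfite
    production and the fluxes draining the sulfite pool (reported here as
    thiosulfate production and sulfite consumption).
    """
    addends = {
        "sulfite_net_production": sulfite_net_production,
        "thiosulfate_production": thiosulfate_production,
        "sulfite_consumption": sulfite_consumption,
    }
    missing = [name for name, r in addends.items() if r is None]
    if missing:
        raise ValueError(f"missing addends: {missing}")
    value = sum(r.value for r in addends.values())
    return RateEstimate(
        species="zerovalent_sulfur",
        direction="consumption",
        component="biological",
        value=value,
        provenance={name: r.value for name, r in addends.items()},
    )


def zvs_unknown_fate(
    zvs_production: RateEstimate,
    zvs_to_sulfite: RateEstimate,
    thiosulfate_production: RateEstimate,
) -> RateEstimate:
    """Residual of the zerovalent-sulfur budget: production minus its
    accounted consumption (oxidation to sulfite, conversion to
    thiosulfate). May be negative (flagged), e.g. if rates were measured
    in incompatible setups."""
    for name, r in {
        "zvs_production": zvs_production,
        "zvs_to_sulfite": zvs_to_sulfite,
        "thiosulfate_production": thiosulfate_production,
    }.items():
        if r is None:
            raise ValueError(f"missing input: {name}")
    value = zvs_production.value - zvs_to_sulfite.value - thiosulfate_production.value
    flags = ["negative_unknown_fate"] if value < 0 else []
    return RateEstimate(
        species="zerovalent_sulfur",
        direction="consumption",
        component="total",
        value=value,
        flags=flags,
        provenance={
            "zvs_production": zvs_production.value,
            "zvs_to_sulfite": zvs_to_sulfite.value,
            "thiosulfate_production": thiosulfate_production.value,
        },
    )


#: Roles a rate collection must provide to assemble the network. The
#: sulfite-consumption addend depends on the convention.
_REQUIRED_ROLES = (
    "sulfide_total_consumption",
    "sulfide_chemical_consumption",
    "zvs_production",
    "thiosulfate_production",
    "sulfite_net_production",
)
_CONVENTION_ADDEND = {
    "fig6_total_sulfite_consumption": "sulfite_total_consumption",
    "text_biological_sulfite_oxidation": "sulfite_biological_oxidation",
}


@dataclass
class FluxNetwork:
    """Five-species mass-balance network of maximal sulfur-oxidation
    fluxes (µmol/h/g), with the zerovalent-sulfur residual reported as
    its unknown fate."""

    nodes: tuple[str, ...]
    edges: list[tuple[str, str, RateEstimate]]
    zvs_to_sulfite: float
    unknown_fate: float
    balance_residuals: dict[str, float]
    convention: str

    def edge_value(self, source: str, sink: str) -> float:
        for s, k, r in self.edges:
            if (s, k) == (source, sink):
                return r.value
        raise KeyError(f"no edge {source} -> {sink}")

    def to_dict(self) -> dict:
        return {
            "convention": self.convention,
            "nodes": list(self.nodes),
            "edges": [
                {
                    "source": s,
                    "sink": k,
                    "value": r.value,
                    "rounded": r.rounded,
                    "component": r.component,
                    "provenance": r.provenance,
                }
                for s, k, r in self.edges
            ],
            "zvs_to_sulfite": self.zvs_to_sulfite,
            "unknown_fate": self.unknown_fate,
            "balance_residuals": self.balance_residuals,
        }

    def to_dot(self) -> str:
        lines = ["digraph sulfur_flux {", "  rankdir=LR;"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for s, k, r in self.edges:
            lines.append(f'  "{s}" -> "{k}" [label="{r.rounded}"];')
        lines.append("}")
        return "\n".join(lines)


def build_flux_network(
    rates: Mapping[str, RateEstimate],
    convention: str = "fig6_total_sulfite_consumption",
) -> FluxNetwork:
    """Assemble the mass-balance network from role-named rate estimates.

    Required roles: sulfide_total_consumption, sulfide_chemical_consumption,
    zvs_production, thiosulfate_production, sulfite_net_production, plus
    the convention's sulfite addend (sulfite_total_consumption or
    sulfite_biological_oxidation). Optional roles sulfate_production and
    thiosulfate_consumption add edges when present.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    addend_role = _CONVENTION_ADDEND[convention]
    missing = [r for r in (*_REQUIRED_ROLES, addend_role) if r not in rates]
    if missing:
        raise ValueError(f"missing required rates: {missing}")

    bio_sulfide = biological_rate(
        rates["sulfide_total_consumption"], rates["sulfide_chemical_consumption"]
    )
    zvs_ox = zvs_oxidation_to_sulfite(
        rates["sulfite_net_production"], rates["thiosulfate_production"], rates[addend_role]
    )
    unknown = zvs_unknown_fate(rates["zvs_production"], zvs_ox, rates["thiosulfate_production"])

    edges: list[tuple[str, str, RateEstimate]] = [
        ("sulfide", "zerovalent_sulfur", bio_sulfide),
        ("zerovalent_sulfur", "sulfite", zvs_ox),
        ("zerovalent_sulfur", "thiosulfate", rates["thiosulfate_production"]),
    ]
    if "sulfate_production" in rates:
        edges.append(("sulfite", "sulfate", rates["sulfate_production"]))
    if "thiosulfate_consumption" in rates:
        edges.append(("thiosulfate", "sulfate", rates["thiosulfate_consumption"]))

    # ZVS node budget closes exactly because the unknown fate is defined as
    # its residual; the identity is re-evaluated here rather than assumed.
    residuals = {n: 0.0 for n in SPECIES}
    residuals["zerovalent_sulfur"] = (
        rates["zvs_production"].value
        - zvs_ox.value
        - rates["thiosulfate_production"].value
        - unknown.value
    )

    return FluxNetwork(
        nodes=SPECIES,
        edges=edges,
        zvs_to_sulfite=zvs_ox.value,
        unknown_fate=unknown.value,
        balance_residuals=residuals,
        convention=convention,
    )


def rates_table(rates: Iterable[RateEstimate]) -> pd.DataFrame:
    """Tidy table of rate estimates for TSV export."""
    rows = []
    for r in rates:
        rows.append(
            {
                "species": r.species,
                "direction": r.direction,
                "component": r.component,
                "value_umol_h_g": r.value,
                "rounded": r.rounded,
                "sem": r.sem,
                "method": r.method,
                "n_replicates": r.n_replicates,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
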