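"""Controlled gene-family vocabulary, capability rules, and autotrophy
pathway definitions.

The capability rules and the carbon-fixation pathway gene lists ship as
editable YAML so curators can swap in their own marker sets; the defaults
below are loaded from ``data/`` at import time of the calling functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

#: Gene families the capability rules understand. Subtype columns (SQR
#: type I–VI, PDO type I–III, sHdr subunit) are carried through but the
#: rules only read family labels, except for sHdr where synteny of subunit
#: subtypes is required.
FAMILY_VOCABULARY = frozenset(
    {
        "sqr",
        "fccB",
        "fccA",
        "pdo",
        "rdsrA",
        "rdsrB",
        "dsrA_reductive",
        "dsrB_reductive",
        "dsrC",
        "dsrEFH",
        "tusA",
        "shdr_subunit",
        "sor",
        "soxA",
        "soxB",
        "soxC",
        "soxD",
        "soxX",
        "soxY",
        "soxZ",
        "tsdA",
        "doxD",
        "sat_oxidative",
        "aprA_oxidative",
        "aprB_oxidative",
        "sorA",
        "suox",
        "phsA",
    }
)

#: Case-insensitive synonyms -> canonical family labels.
FAMILY_SYNONYMS = {
    "fcsd": "fccB",
    "fcsd_catalytic_subunit": "fccB",
    "sat": "sat_oxidative",
    "apra": "aprA_oxidative",
    "aprb": "aprB_oxidative",
    "shdr": "shdr_subunit",
    "soux": "suox",
}

#: Substrate capability rules: each substrate is oxidizable iff at least
#: one alternative fires. An alternative either requires a set of gene
#: families, or (for sHdr) a syntenic subunit cluster detected from gene
#: order. SoxC is deliberately not required for the thiosulfate Sox call
#: (reported separately) and SoxD is never required.
DEFAULT_CAPABILITY_RULES = {
    "sulfide": (
        {"name": "SQR", "requires": ("sqr",)},
        {"name": "FCSD", "requires": ("fccB",)},
    ),
    "zerovalent_sulfur": (
        {"name": "PDO", "requires": ("pdo",)},
        {"name": "rDsr", "requires": ("rdsrA", "rdsrB")},
        {"name": "sHdr", "requires_cluster": "shdr"},
        {"name": "SOR", "requires": ("sor",)},
    ),
    "thiosulfate": (
        {"name": "Sox", "requires": ("soxA", "soxB", "soxX", "soxY", "soxZ")},
        {"name": "TsdA", "requires": ("tsdA",)},
        {"name": "DoxD", "requires": ("doxD",)},
    ),
    "sulfite": (
        {
            "name": "Sat-AprAB",
            "requires": ("sat_oxidative", "aprA_oxidative", "aprB_oxidative"),
        },
        {"name": "SorA", "requires": ("sorA",)},
        {"name": "SUOX", "requires": ("suox",)},
    ),
}


@dataclass(frozen=True)
class PathwayDefinition:
    """A carbon-fixation pathway as a marker/accessory gene split."""

    name: str
    marker_genes: frozenset[str]
    accessory_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.marker_genes & self.accessory_genes:
            raise ValueError(f"{self.name}: marker and accessory sets overlap")
        if not self.all_genes:
            raise ValueError(f"{self.name}: pathway has no genes")

    @property
    def all_genes(self) -> frozenset[str]:
        return self.marker_genes | self.accessory_genes


def load_capability_rules(path: str | Path | None = None) -> dict:
    """Load substrate rules from YAML, or return the built-in defaults."""
    if path is None:
        return DEFAULT_CAPABILITY_RULES
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        substrate: tuple(
            {
                "name": alt["name"],
                **(
                    {"requires_cluster": alt["requires_cluster"]}
                    if "requires_cluster" in alt
                    else {"requires": tuple(alt["requires"])}
                ),
            }
            for alt in alternatives
        )
        for substrate, alternatives in raw.items()
    }


def load_autotrophy_pathways(path: str | Path | None = None) -> list[PathwayDefinition]:
    """Load carbon-fixation pathway definitions from YAML.

    Defaults ship with the package; they are reconstructions from standard
    carbon-fixation biochemistry and are meant to be replaced with
    project-specific curated lists.
    """
    if path is None:
        ref = resources.files("sulfurcycle").joinpath("data/autotrophy_pathways.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return [
        PathwayDefinition(
            name=name,
            marker_genes=frozenset(spec.get("markers", [])),
            accessory_genes=frozenset(spec.get("accessory", [])),
        )
        for name, spec in raw.items()
    ]
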