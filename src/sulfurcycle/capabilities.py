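"""Rule-based sulfur-oxidation capability calling for genomes.

Each genome (typically a metagenome-assembled genome, MAG) is represented
by a table of positional gene-family annotations. Capability per sulfur
substrate is decided by boolean rules over gene-family presence:

* sulfide — SQR or FCSD (FccB catalytic subunit suffices);
* zerovalent sulfur — PDO, complete rDsrAB, a syntenic sHdr cluster, or SOR;
* thiosulfate — the SoxABXYZ complex (SoxC optional, SoxD never required),
  TsdA, or DoxD;
* sulfite — the complete oxidative Sat-AprAB route (all three genes), SorA,
  or SUOX.

The sHdr complex is only called from gene order: a run of consecutive
genes on one scaffold whose subunit labels follow the canonical cluster
order HdrC1-HdrB1-HdrA-HYP-HdrC2-HdrB2 (or its exact reversal, as a
minus-strand operon appears reversed in coordinate order), at least five
subunits long. Informational flags record functional context (Sox lacking
SoxD, SoxB-only genomes carrying TsdA, rDsr with DsrC, DsrEFH with TusA,
putative sulfur reducers carrying reductive DsrAB plus PhsA).

Autotrophy is confirmed per carbon-fixation pathway by a completeness
rule — at least 70% of the pathway's genes present, or all marker genes
present plus more than 50% of the accessory genes — and a genome with at
least one confirmed pathway is labelled an autotroph.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pathways import (
    DEFAULT_CAPABILITY_RULES,
    FAMILY_SYNONYMS,
    FAMILY_VOCABULARY,
    PathwayDefinition,
    load_autotrophy_pathways,
)

SHDR_ORDER = ("HdrC1", "HdrB1", "HdrA", "HYP", "HdrC2", "HdrB2")
SUBSTRATES = ("sulfide", "zerovalent_sulfur", "thiosulfate", "sulfite")


def normalize_family(label: str) -> str:
    """Map a family label to the controlled vocabulary, case-insensitively
    and through the synonym table. Unknown labels are returned unchanged
    (callers count and warn)."""
    key = label.strip().lower()
    if key in FAMILY_SYNONYMS:
        return FAMILY_SYNONYMS[key]
    for fam in FAMILY_VOCABULARY:
        if fam.lower() == key:
            return fam
    return label.strip()


@dataclass
class GeneHit:
    genome_id: str
    scaffold_id: str
    family: str
    subtype: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        self.family = normalize_family(self.family)
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"gene hit with start > end on {self.scaffold_id}")
        if self.family == "shdr_subunit" and self.subtype is None:
            raise ValueError("shdr_subunit hits require a subunit subtype")


@dataclass
class GenomeRecord:
    genome_id: str
    taxonomy: str = ""
    completeness: float | None = None
    contamination: float | None = None
    hits: list[GeneHit] = field(default_factory=list)

    def families_present(self) -> set[str]:
        return {h.family for h in self.hits}


@dataclass
class ShdrCluster:
    scaffold_id: str
    subunits: tuple[str, ...]
    orientation: str  # "forward" | "reverse"
    start: int | None = None
    end: int | None = None

    def __len__(self) -> int:
        return len(self.subunits)


@dataclass
class CapabilityProfile:
    genome_id: str
    substrates: dict[str, bool]
    pathways: dict[str, list[str]]
    flags: dict[str, bool]
    trophic: str | None = None
    shdr_clusters: list[ShdrCluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sub in SUBSTRATES:
            if self.substrates.get(sub, False) != bool(self.pathways.get(sub)):
                raise ValueError(
                    f"{self.genome_id}: substrate flag for {sub} inconsistent with "
                    "its supporting-pathway list"
                )

    @property
    def any_capability(self) -> bool:
        return any(self.substrates.values())


def qc_filter_genomes(records: Iterable[GenomeRecord]) -> list[GenomeRecord]:
    """Keep genomes with completeness over 50% and contamination below
    10% (strict inequalities)."""
    records = list(records)
    missing = [
        r.genome_id for r in records if r.completeness is None or r.contamination is None
    ]
    if missing:
        raise ValueError(f"genomes missing QC fields: {missing}")
    return [r for r in records if r.completeness > 50 and r.contamination < 10]


def _match_run(
    labels: Sequence[str | None],
    start: int,
    canonical: Sequence[str],
    max_gap: int,
) -> tuple[int, int]:
    """Longest run of subunit labels starting at `start` that follows
    `canonical` order consecutively, tolerating up to `max_gap`
    non-subunit genes between matched subunits. Returns (n_subunits,
    index past the last matched gene); (0, start) if none."""
    first = labels[start]
    if first is None:
        return 0, start
    best = (0, start)
    for offset, name in enumerate(canonical):
        if name != first:
            continue
        count, pos, last_end = 1, offset + 1, start + 1
        i = start + 1
        gap = 0
        while i < len(labels) and pos < len(canonical):
            if labels[i] is None:
                gap += 1
                if gap > max_gap:
                    break
                i += 1
                continue
            if labels[i] == canonical[pos]:
                count += 1
                pos += 1
                i += 1
                last_end = i
                gap = 0
            else:
                break
        if count > best[0]:
            best = (count, last_end)
    return best


def detect_shdr_clusters(
    hits: Iterable[GeneHit],
    min_len: int = 5,
    max_gap: int = 0,
) -> list[ShdrCluster]:
    """Scan scaffolds for syntenic sHdr clusters.

    Genes are ordered by start coordinate per scaffold; maximal runs of
    consecutive sHdr subunits matching the canonical order (or its exact
    reversal) are reported when at least `min_len` subunits long. Runs are
    taken greedily, leftmost-first, non-overlapping; `max_gap` permits
    that many intervening non-sHdr genes inside a run (0 by default:
    strictly consecutive).
    """
    clusters: list[ShdrCluster] = []
    by_scaffold: dict[str, list[GeneHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold_id, []).append(h)
    for scaffold_id in sorted(by_scaffold):
        genes = sorted(
            by_scaffold[scaffold_id],
            key=lambda h: (h.start if h.start is not None else 0, h.end or 0),
        )
        labels: list[str | None] = [
            g.subtype if g.family == "shdr_subunit" else None for g in genes
        ]
        i = 0
        while i < len(genes):
            fwd = _match_run(labels, i, SHDR_ORDER, max_gap)
            rev = _match_run(labels, i, SHDR_ORDER[::-1], max_gap)
            count, stop, orientation = max(
                (fwd[0], fwd[1], "forward"), (rev[0], rev[1], "reverse"),
                key=lambda x: x[0],
            )
            if count >= min_len:
                members = [g for g in genes[i:stop] if g.family == "shdr_subunit"]
                clusters.append(
                    ShdrCluster(
                        scaffold_id=scaffold_id,
                        subunits=tuple(g.subtype for g in members),  # type: ignore[arg-type]
                        orientation=orientation,
                        start=members[0].start,
                        end=members[-1].end,
                    )
                )
                i = stop
            else:
                i += 1
    return clusters


def evaluate_capability_rules(
    present: set[str],
    has_shdr_cluster: bool,
    rules: Mapping[str, Sequence[Mapping]] | None = None,
) -> tuple[dict[str, bool], dict[str, list[str]]]:
    """Evaluate the substrate rules over a gene-family presence set.

    Shared by the caller and by the community simulator's ground truth so
    that planted capability profiles and called profiles are decided by
    one definition.
    """
    rules = rules if rules is not None else DEFAULT_CAPABILITY_RULES
    substrates: dict[str, bool] = {}
    pathways: dict[str, list[str]] = {}
    for substrate, alternatives in rules.items():
        supporting = []
        for alt in alternatives:
            if alt.get("requires_cluster") == "shdr":
                if has_shdr_cluster:
                    supporting.append(alt["name"])
            elif all(g in present for g in alt["requires"]):
                supporting.append(alt["name"])
        pathways[substrate] = supporting
        substrates[substrate] = bool(supporting)
    return substrates, pathways


_SOX_CORE = ("soxA", "soxB", "soxX", "soxY", "soxZ")


def _context_flags(present: set[str]) -> dict[str, bool]:
    sox_complete = all(g in present for g in _SOX_CORE)
    return {
        "sox_lacks_soxD": sox_complete and "soxD" not in present,
        "soxB_only_with_tsdA": (
            "soxB" in present
            and "tsdA" in present
            and not any(g in present for g in ("soxA", "soxC", "soxX", "soxY", "soxZ"))
        ),
        "rdsr_with_dsrC": {"rdsrA", "rdsrB", "dsrC"} <= present,
        "dsrEFH_with_tusA": {"dsrEFH", "tusA"} <= present,
        "putative_sulfur_reducer": {"dsrA_reductive", "dsrB_reductive", "phsA"} <= present,
    }


def _autotrophy_gene_names() -> frozenset[str]:
    global _AUTOTROPHY_GENES
    if _AUTOTROPHY_GENES is None:
        _AUTOTROPHY_GENES = frozenset(
            g for p in load_autotrophy_pathways() for g in p.all_genes
        )
    return _AUTOTROPHY_GENES


_AUTOTROPHY_GENES: frozenset[str] | None = None


def call_sulfur_capabilities(
    record: GenomeRecord,
    rules: Mapping[str, Sequence[Mapping]] | None = None,
    shdr_min_len: int = 5,
    shdr_max_gap: int = 0,
) -> CapabilityProfile:
    """Call the per-substrate sulfur-oxidation capabilities of one genome."""
    known = FAMILY_VOCABULARY | _autotrophy_gene_names()
    unknown = Counter(h.family for h in record.hits if h.family not in known)
    if unknown:
        warnings.warn(
            f"{record.genome_id}: {sum(unknown.values())} hits with unknown "
            f"family labels ignored by the rules: {dict(unknown)}",
            stacklevel=2,
        )
    present = record.families_present() & FAMILY_VOCABULARY
    clusters = detect_shdr_clusters(
        record.hits, min_len=shdr_min_len, max_gap=shdr_max_gap
    )
    substrates, pathways = evaluate_capability_rules(present, bool(clusters), rules)
    return CapabilityProfile(
        genome_id=record.genome_id,
        substrates=substrates,
        pathways=pathways,
        flags=_context_flags(present),
        shdr_clusters=clusters,
    )


def confirm_pathway(pathway: PathwayDefinition, present: set[str]) -> dict:
    """Apply the pathway completeness rule to one genome's gene set.

    Confirmed iff ≥70% of all pathway genes are present, or every marker
    gene is present and more than 50% of the accessory genes are. A
    pathway defined without accessory genes is confirmed by its markers
    alone.
    """
    all_genes = pathway.all_genes
    present_genes = all_genes & present
    frac = len(present_genes) / len(all_genes)
    markers_ok = pathway.marker_genes <= present
    if pathway.accessory_genes:
        accessory_frac = len(pathway.accessory_genes & present) / len(pathway.accessory_genes)
        marker_branch = markers_ok and accessory_frac > 0.50
    else:
        accessory_frac = None
        marker_branch = markers_ok
    return {
        "confirmed": frac >= 0.70 or marker_branch,
        "present_fraction": frac,
        "markers_present": markers_ok,
        "accessory_fraction": accessory_frac,
    }


def call_autotrophy(
    record: GenomeRecord,
    pathways: Sequence[PathwayDefinition] | None = None,
) -> tuple[str, dict[str, dict]]:
    """Label a genome autotroph iff at least one carbon-fixation pathway
    is confirmed; otherwise heterotroph_or_mixotroph."""
    if pathways is None:
        pathways = load_autotrophy_pathways()
    present = record.families_present()
    verdicts = {p.name: confirm_pathway(p, present) for p in pathways}
    trophic = (
        "autotroph"
        if any(v["confirmed"] for v in verdicts.values())
        else "heterotroph_or_mixotroph"
    )
    return trophic, verdicts


def parse_rank(lineage: str, rank: str) -> str:
    """Extract one rank from a GTDB-style lineage (d__;p__;c__;...)."""
    prefix = {"domain": "d__", "phylum": "p__", "class": "c__", "order": "o__",
              "family": "f__", "genus": "g__", "species": "s__"}[rank]
    for part in lineage.split(";"):
        part = part.strip()
        if part.startswith(prefix):
            return part[len(prefix):] or "Unclassified"
    return "Unclassified"


def summarize_capabilities(
    profiles: Sequence[CapabilityProfile],
    abundances: Mapping[str, float] | None = None,
    taxonomy: Mapping[str, str] | None = None,
    rank: str = "phylum",
) -> tuple[pd.DataFrame, dict]:
    """Per-taxon and community-level capable-genome fractions.

    For each taxon at `rank` and each substrate: the fraction of genomes
    capable by count and, when abundances are given, weighted by relative
    abundance. The community summary reports overall fractions, including
    the fraction of genomes with at least one sulfur-oxidation gene route
    and the fraction with the complete Sat-AprAB sulfite pathway.
    """
    profiles = list(profiles)
    if abundances is not None:
        dropped = [p.genome_id for p in profiles if p.genome_id not in abundances]
        if dropped:
            warnings.warn(
                f"{len(dropped)} genomes missing abundance excluded from "
                "abundance-weighted summaries",
                stacklevel=2,
            )

    rows = []
    for p in profiles:
        taxon = (
            parse_rank(taxonomy.get(p.genome_id, ""), rank) if taxonomy else "all"
        )
        row = {"genome_id": p.genome_id, "taxon": taxon, "any": p.any_capability}
        for sub in SUBSTRATES:
            row[sub] = p.substrates.get(sub, False)
        row["sat_aprab_complete"] = "Sat-AprAB" in p.pathways.get("sulfite", [])
        row["abundance"] = abundances.get(p.genome_id) if abundances else None
        rows.append(row)
    df = pd.DataFrame(rows)

    capability_cols = ["any", *SUBSTRATES, "sat_aprab_complete"]
    per_taxon = (
        df.groupby("taxon")
        .agg(
            n_genomes=("genome_id", "size"),
            **{f"{c}_count_ratio": (c, "mean") for c in capability_cols},
        )
        .reset_index()
    )
    if abundances is not None:
        wdf = df.dropna(subset=["abundance"])
        weighted = []
        for taxon, sub in wdf.groupby("taxon"):
            total = sub["abundance"].sum()
            weighted.append(
                {
                    "taxon": taxon,
                    **{
                        f"{c}_abundance_ratio": (
                            sub.loc[sub[c], "abundance"].sum() / total if total > 0 else 0.0
                        )
                        for c in capability_cols
                    },
                }
            )
        per_taxon = per_taxon.merge(pd.DataFrame(weighted), on="taxon", how="left")

    n = len(df)
    community = {
        "n_genomes": n,
        "n_capable": int(df["any"].sum()),
        "pct_capable": 100.0 * df["any"].mean() if n else 0.0,
        "n_sat_aprab_complete": int(df["sat_aprab_complete"].sum()),
        "pct_sat_aprab_complete": 100.0 * df["sat_aprab_complete"].mean() if n else 0.0,
        **{f"pct_{sub}": 100.0 * df[sub].mean() if n else 0.0 for sub in SUBSTRATES},
    }
    if abundances is not None:
        wdf = df.dropna(subset=["abundance"])
        total = wdf["abundance"].sum()
        if total > 0:
            community["pct_capable_abundance"] = (
                100.0 * wdf.loc[wdf["any"], "abundance"].sum() / total
            )
    return per_taxon, community


def profiles_table(profiles: Sequence[CapabilityProfile]) -> pd.DataFrame:
    """Tidy per-genome capability table for TSV export."""
    rows = []
    for p in profiles:
        row = {"genome_id": p.genome_id, "trophic": p.trophic}
        for sub in SUBSTRATES:
            row[sub] = p.substrates.get(sub, False)
            row[f"{sub}_pathways"] = ";".join(p.pathways.get(sub, []))
        for flag, val in p.flags.items():
            row[flag] = val
        row["n_shdr_clusters"] = len(p.shdr_clusters)
        rows.append(row)
    return pd.DataFrame(rows)
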