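"""Seeded generators for every input the pipeline consumes, with recorded
ground truth.

Two generators cover the two halves of the analysis:

* :func:`simulate_incubation` emulates a spiked slurry incubation (by
  default 1 mM sulfide into a 1:100 slurry of 1 g sediment, sampled every
  10 min, three replicates, with a heat-killed control and a sediment-free
  blank). Substrate decays at the chemical-plus-biological rate with a
  monotonically non-increasing per-interval rate — the premise under which
  the first-interval convention estimates the maximum — and products
  accrue by fixed split fractions. Gaussian measurement noise and
  detection-limit censoring are applied last. The truth record carries
  both the instantaneous initial rates and the average rate over the first
  sampling interval; the latter is the estimand of the first-interval
  convention under continuously declining kinetics.

* :func:`simulate_community` emulates a MAG catalog: genomes with sampled
  sulfur-gene complements (complete Sox/rDsrAB/Sat-AprAB complexes planted
  jointly so realistic co-occurrence exists), valid and decoy sHdr gene
  runs, planted autotrophy pathways, lognormal genome abundances turned
  into scaffold coverage tables by the read-count arithmetic of the
  abundance module, MAG depth fractions with an explicit unmapped row, and
  paired control/experimental transcript depths with planted fold changes.
  Capabilities are evaluated from the planted gene presence with the same
  boolean rules the caller uses and stored as ground truth.

Identical seeds give byte-identical outputs; each sub-generator draws
from its own named stream so adding draws to one stage never shifts
another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .capabilities import (
    SHDR_ORDER,
    GeneHit,
    GenomeRecord,
    evaluate_capability_rules,
)
from .fluxes import TimeCoursePanel
from .pathways import PathwayDefinition, load_autotrophy_pathways
from .capabilities import confirm_pathway


class SimulationError(ValueError):
    """Raised when simulation parameters are physically infeasible."""


def stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent pseudorandom stream derived from one seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# incubation time courses


@dataclass
class IncubationSimParams:
    """Parameters of a simulated spiked slurry incubation.

    Defaults mirror the sulfide experiment: 1 mM spike into 1 g sediment
    diluted 100-fold (99 mL buffer), sampled every 10 min for an hour,
    three replicates, measurement noise of 5% of the initial
    concentration. Rates are in µmol/h/g wet sediment.
    """

    species: str = "sulfide"
    initial_conc_uM: float = 1000.0
    sediment_g: float = 1.0
    liquid_L: float = 0.099
    chemical_rate: float = 76.52
    biological_rate: float = 64.06
    decay: str = "first_order"  # or "saturating"
    km_uM: float = 100.0
    product_split: Mapping[str, float] = field(
        default_factory=lambda: {
            "zerovalent_sulfur": 0.80,
            "thiosulfate": 0.06,
            "sulfite": 0.14,
        }
    )
    noise_sd_uM: float = 50.0
    lod_uM: float = 0.5
    timepoints: Sequence[float] = tuple(np.round(np.arange(0, 7) / 6.0, 6))
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.chemical_rate < 0 or self.biological_rate < 0:
            raise ValueError("rates must be non-negative")
        split_sum = sum(self.product_split.values())
        if not np.isclose(split_sum, 1.0):
            raise ValueError(f"product split fractions must sum to 1 (got {split_sum})")
        if self.decay not in ("first_order", "saturating"):
            raise ValueError(f"unknown decay form {self.decay!r}")
        t = np.asarray(self.timepoints, dtype=float)
        if len(t) < 2 or (np.diff(t) <= 0).any() or t[0] != 0:
            raise ValueError("timepoints must start at 0 and strictly increase")

    @property
    def scale(self) -> float:
        """µM/h → µmol/h/g conversion factor."""
        return self.liquid_L / self.sediment_g

    @property
    def total_rate(self) -> float:
        return self.chemical_rate + self.biological_rate


def _substrate_curve(params: IncubationSimParams, rate_umol_h_g: float) -> np.ndarray:
    """Noiseless substrate concentration at the sampling times given an
    initial transformation rate, under the chosen decay form."""
    t = np.asarray(params.timepoints, dtype=float)
    c0 = params.initial_conc_uM
    if rate_umol_h_g == 0:
        return np.full_like(t, c0)
    if params.decay == "first_order":
        k = rate_umol_h_g / (c0 * params.scale)  # 1/h
        return c0 * np.exp(-k * t)
    # saturating: dC/dt = -vmax * C / (C + Km), initial rate matched
    km = params.km_uM
    vmax = rate_umol_h_g / params.scale * (c0 + km) / c0  # µM/h
    conc = np.empty_like(t)
    conc[0] = c = c0
    substeps = 200
    for i in range(1, len(t)):
        dt = (t[i] - t[i - 1]) / substeps
        for _ in range(substeps):
            dc = vmax * c / (c + km) * dt
            if dc > c:
                raise SimulationError(
                    "consumption exceeds available substrate within one step; "
                    "reduce rates or refine the time grid"
                )
            c -= dc
        conc[i] = c
    return conc


def simulate_incubation(
    params: IncubationSimParams, seed: int = 0
) -> tuple[TimeCoursePanel, dict]:
    """Simulate one incubation; returns the measured panel and the truth.

    The experimental group consumes substrate at the chemical+biological
    rate, the heat-killed control at the chemical rate only, and the blank
    (no sediment) is flat. Products accrue in proportion to consumed
    substrate by the split fractions.
    """
    rng = stream(seed, f"incubation:{params.species}")
    t = np.asarray(params.timepoints, dtype=float)
    curves: dict[tuple[str, str], np.ndarray] = {}

    for group, rate in (
        ("experimental", params.total_rate),
        ("control", params.chemical_rate),
    ):
        substrate = _substrate_curve(params, rate)
        consumed = params.initial_conc_uM - substrate
        curves[(params.species, group)] = substrate
        for product, frac in params.product_split.items():
            curves[(product, group)] = frac * consumed
    curves[(params.species, "blank")] = np.full_like(t, params.initial_conc_uM)
    for product in params.product_split:
        curves[(product, "blank")] = np.zeros_like(t)

    rows = []
    for (species, group), clean in sorted(curves.items()):
        for rep in range(1, params.n_replicates + 1):
            noisy = clean + rng.normal(0.0, params.noise_sd_uM, size=len(t))
            noisy = np.clip(noisy, 0.0, None)
            for ti, ci in zip(t, noisy):
                rows.append(
                    {
                        "species": species,
                        "group": group,
                        "replicate": rep,
                        "time_h": ti,
                        "conc_uM": ci,
                    }
                )
    panel = TimeCoursePanel(
        incubation_id=f"sim_{params.species}_seed{seed}",
        data=pd.DataFrame(rows),
        sediment_g=params.sediment_g,
        liquid_L=params.liquid_L,
        lod_uM={sp: params.lod_uM for sp in {s for s, _ in curves}},
    )

    dt1 = t[1] - t[0]
    truth: dict = {
        "instantaneous": {
            "total_consumption": params.total_rate,
            "chemical_consumption": params.chemical_rate,
            "biological_consumption": params.biological_rate,
        },
        "first_interval": {},
        "product_split": dict(params.product_split),
    }
    for group, label in (("experimental", "total"), ("control", "chemical")):
        clean = curves[(params.species, group)]
        truth["first_interval"][f"{label}_consumption"] = (
            (clean[0] - clean[1]) / dt1 * params.scale
        )
        for product, frac in params.product_split.items():
            key = f"{product}_production_{label}"
            truth["first_interval"][key] = (
                frac * (clean[0] - clean[1]) / dt1 * params.scale
            )
    truth["first_interval"]["biological_consumption"] = (
        truth["first_interval"]["total_consumption"]
        - truth["first_interval"]["chemical_consumption"]
    )
    return panel, truth


def incubation_fixture(
    incubation_id: str,
    species: str,
    direction: str,
    rate_umol_h_g: float,
    group: str = "experimental",
    sediment_g: float = 1.0,
    liquid_L: float = 0.099,
    dt_h: float = 1.0 / 6.0,
    n_timepoints: int = 4,
    n_replicates: int = 3,
    initial_conc_uM: float = 1000.0,
) -> TimeCoursePanel:
    """Noiseless time course whose first sampling interval embeds a given
    scaled rate.

    The concentration change over the first interval equals
    ``rate × dt × sediment / liquid`` and later intervals shrink (60%,
    30%, ... of the first), so the per-interval rate declines and the
    first-interval convention recovers exactly the embedded value. Used to
    carry externally measured rates through the estimator code path.
    """
    dconc = rate_umol_h_g * dt_h * sediment_g / liquid_L
    sign = -1.0 if direction == "consumption" else 1.0
    c0 = initial_conc_uM if direction == "consumption" else 0.0
    if direction == "consumption" and dconc * 2 > c0:
        c0 = dconc * 2.5
    conc = [c0]
    factor = 1.0
    for _ in range(n_timepoints - 1):
        conc.append(conc[-1] + sign * dconc * factor)
        factor *= 0.6
    rows = [
        {
            "species": species,
            "group": group,
            "replicate": rep,
            "time_h": i * dt_h,
            "conc_uM": c,
        }
        for rep in range(1, n_replicates + 1)
        for i, c in enumerate(conc)
    ]
    return TimeCoursePanel(
        incubation_id=incubation_id,
        data=pd.DataFrame(rows),
        sediment_g=sediment_g,
        liquid_L=liquid_L,
    )


# ---------------------------------------------------------------------------
# synthetic MAG community

DEFAULT_PHYLA = {
    "Proteobacteria": 0.26,
    "Desulfobacterota": 0.11,
    "Gemmatimonadota": 0.08,
    "Myxococcota": 0.07,
    "Chloroflexota": 0.06,
    "Planctomycetota": 0.06,
    "Acidobacteriota": 0.06,
    "Nitrospirota": 0.05,
    "Bacteroidota": 0.05,
    "Verrucomicrobiota": 0.04,
    "Actinomycetota": 0.04,
    "Other": 0.12,
}

#: Whole complexes planted jointly so complete Sox / rDsrAB / Sat-AprAB
#: genomes occur at realistic frequency; SoxD is never planted (absent
#: from all samples in the system this emulates).
DEFAULT_COMPLEX_PREVALENCE = {
    "sox": (("soxA", "soxB", "soxX", "soxY", "soxZ"), 0.09),
    "rdsr": (("rdsrA", "rdsrB"), 0.06),
    "sat_aprab": (("sat_oxidative", "aprA_oxidative", "aprB_oxidative"), 0.11),
}

#: Independent per-family prevalences, loosely mirroring a coastal-sediment
#: MAG catalog in which most genomes carry at least one sulfur-oxidation
#: gene and PDO is the commonest zerovalent-sulfur gene.
DEFAULT_FAMILY_PREVALENCE = {
    "sqr": 0.27,
    "fccB": 0.13,
    "fccA": 0.08,
    "pdo": 0.33,
    "sor": 0.01,
    "soxB": 0.04,  # lone SoxB, on top of complete complexes
    "soxC": 0.05,
    "tsdA": 0.10,
    "doxD": 0.05,
    "sat_oxidative": 0.12,  # lone Sat without AprAB
    "sorA": 0.04,
    "suox": 0.02,
    "dsrA_reductive": 0.0,  # planted jointly below
    "dsrB_reductive": 0.0,
    "dsrC": 0.10,
    "dsrEFH": 0.05,
    "tusA": 0.20,
    "phsA": 0.07,
}

SQR_SUBTYPES = ("type I", "type II", "type III", "type IV", "type VI")
SQR_SUBTYPE_WEIGHTS = (0.115, 0.147, 0.703, 0.003, 0.032)
PDO_SUBTYPES = ("type I", "type II", "type III")
PDO_SUBTYPE_WEIGHTS = (0.357, 0.377, 0.266)


@dataclass
class CommunitySimParams:
    """Parameters of a simulated MAG catalog with planted ground truth."""

    n_genomes: int = 200
    phylum_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PHYLA))
    family_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_PREVALENCE)
    )
    complex_prevalence: Mapping[str, tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPLEX_PREVALENCE)
    )
    reductive_dsr_prevalence: float = 0.08
    shdr_valid_rate: float = 0.08
    shdr_decoy_rate: float = 0.10
    autotroph_fraction: float = 0.15
    pathway_dropout: float = 0.10
    qc_fail_fraction: float = 0.10
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    scaffold_mean_count: float = 4.0
    scaffold_length_mu: float = 10.0  # log-bp; exp(10) ≈ 22 kb
    scaffold_length_sigma: float = 0.6
    n_samples: int = 3
    sample_total_reads: int = 1_000_000
    unmapped_fraction: float = 0.30
    transcript_fold_changes: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("pdo", "Planctomycetota"): 76.0}
    )
    transcript_noise_sigma: float = 0.15
    transcript_total_reads: int = 1_000_000_000

    def __post_init__(self) -> None:
        for name, p in self.family_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {name} outside [0, 1]")
        if not 0 <= self.autotroph_fraction <= 1:
            raise ValueError("autotroph_fraction outside [0, 1]")
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")


@dataclass
class SimulatedCommunity:
    """Bundle of generated tables plus the ground truth per genome."""

    records: list[GenomeRecord]
    hits: pd.DataFrame
    coverage: pd.DataFrame
    mag_depth: pd.DataFrame
    transcripts: pd.DataFrame
    transcript_totals: dict[str, float]
    sample_metadata: pd.DataFrame
    truth: dict


def _is_valid_shdr_order(subtypes: Sequence[str], min_len: int = 5) -> bool:
    """Window predicate used to reject decoy runs that would be real
    clusters: some window of >= min_len consecutive subunits follows the
    canonical order forward or reversed."""
    for canonical in (SHDR_ORDER, SHDR_ORDER[::-1]):
        joined = "|".join(canonical)
        for i in range(len(subtypes)):
            for j in range(i + min_len, len(subtypes) + 1):
                if "|".join(subtypes[i:j]) in joined:
                    return True
    return False


def _plant_shdr_run(rng: np.random.Generator, valid: bool) -> list[str]:
    if valid:
        length = int(rng.integers(5, 7))
        offset = int(rng.integers(0, 7 - length))
        run = list(SHDR_ORDER[offset : offset + length])
        if rng.random() < 0.5:
            run.reverse()
        return run
    run = list(SHDR_ORDER)
    while True:
        rng.shuffle(run)
        if not _is_valid_shdr_order(run):
            return run


def simulate_community(
    params: CommunitySimParams, seed: int = 0
) -> SimulatedCommunity:
    """Generate a synthetic MAG catalog and every table downstream stages
    read, together with the planted truth."""
    rng_tax = stream(seed, "taxonomy")
    rng_gene = stream(seed, "genes")
    rng_qc = stream(seed, "qc")
    rng_ab = stream(seed, "abundance")
    rng_tx = stream(seed, "transcripts")

    phyla = list(params.phylum_weights)
    weights = np.asarray(list(params.phylum_weights.values()), dtype=float)
    weights = weights / weights.sum()
    pathways = load_autotrophy_pathways()

    records: list[GenomeRecord] = []
    hit_rows: list[dict] = []
    truth_genomes: dict[str, dict] = {}

    for g in range(params.n_genomes):
        genome_id = f"MAG{g:05d}"
        phylum = phyla[rng_tax.choice(len(phyla), p=weights)]
        taxonomy = f"d__Bacteria;p__{phylum}"

        fails_qc = rng_qc.random() < params.qc_fail_fraction
        if fails_qc:
            # fail on completeness or contamination, half and half
            if rng_qc.random() < 0.5:
                completeness = float(rng_qc.uniform(20, 50))
                contamination = float(rng_qc.uniform(0, 9))
            else:
                completeness = float(rng_qc.uniform(55, 100))
                contamination = float(rng_qc.uniform(10, 25))
        else:
            completeness = float(rng_qc.uniform(55, 100))
            contamination = float(rng_qc.uniform(0, 9))

        first_hit_idx = len(hit_rows)
        planted: set[str] = set()
        for families, p in params.complex_prevalence.values():
            if rng_gene.random() < p:
                planted.update(families)
        if rng_gene.random() < params.reductive_dsr_prevalence:
            planted.update(("dsrA_reductive", "dsrB_reductive"))
        for family, p in params.family_prevalence.items():
            if p > 0 and rng_gene.random() < p:
                planted.add(family)

        has_valid_shdr = rng_gene.random() < params.shdr_valid_rate
        has_decoy_shdr = rng_gene.random() < params.shdr_decoy_rate

        is_autotroph_planted = rng_gene.random() < params.autotroph_fraction
        autotroph_genes: set[str] = set()
        if is_autotroph_planted:
            pw: PathwayDefinition = pathways[int(rng_gene.integers(len(pathways)))]
            autotroph_genes = {
                gene
                for gene in pw.all_genes
                if gene in pw.marker_genes or rng_gene.random() >= params.pathway_dropout
            }

        # lay the genes out on scaffolds; sulfur genes land at random
        # cursor positions, sHdr runs are appended contiguously
        n_scaffolds = 1 + int(rng_gene.poisson(params.scaffold_mean_count))
        scaffold_ids = [f"{genome_id}_sc{i}" for i in range(n_scaffolds)]
        cursors = {sc: int(rng_gene.integers(1, 5000)) for sc in scaffold_ids}

        def place(sc: str, family: str, subtype: str | None) -> None:
            start = cursors[sc]
            length = int(rng_gene.integers(600, 2400))
            cursors[sc] = start + length + int(rng_gene.integers(50, 500))
            hit_rows.append(
                {
                    "genome_id": genome_id,
                    "scaffold_id": sc,
                    "family": family,
                    "subtype": subtype,
                    "start": start,
                    "end": start + length - 1,
                    "strand": "+" if rng_gene.random() < 0.5 else "-",
                }
            )

        for family in sorted(planted):
            sc = scaffold_ids[int(rng_gene.integers(n_scaffolds))]
            subtype = None
            if family == "sqr":
                subtype = SQR_SUBTYPES[rng_gene.choice(len(SQR_SUBTYPES), p=SQR_SUBTYPE_WEIGHTS)]
            elif family == "pdo":
                subtype = PDO_SUBTYPES[rng_gene.choice(len(PDO_SUBTYPES), p=PDO_SUBTYPE_WEIGHTS)]
            place(sc, family, subtype)
        for gene in sorted(autotroph_genes):
            place(scaffold_ids[int(rng_gene.integers(n_scaffolds))], gene, None)

        strand = "+" if rng_gene.random() < 0.5 else "-"
        if has_valid_shdr:
            sc = scaffold_ids[int(rng_gene.integers(n_scaffolds))]
            for sub in _plant_shdr_run(rng_gene, valid=True):
                place(sc, "shdr_subunit", sub)
        if has_decoy_shdr:
            sc = scaffold_ids[int(rng_gene.integers(n_scaffolds))]
            for sub in _plant_shdr_run(rng_gene, valid=False):
                place(sc, "shdr_subunit", sub)

        substrates, pathways_fired = evaluate_capability_rules(planted, has_valid_shdr)
        trophic_truth = "heterotroph_or_mixotroph"
        if is_autotroph_planted and any(
            confirm_pathway(pw, autotroph_genes)["confirmed"] for pw in pathways
        ):
            trophic_truth = "autotroph"

        genome_hits = [
            GeneHit(
                genome_id=r["genome_id"],
                scaffold_id=r["scaffold_id"],
                family=r["family"],
                subtype=r["subtype"],
                start=r["start"],
                end=r["end"],
                strand=r["strand"],
            )
            for r in hit_rows[first_hit_idx:]
        ]
        records.append(
            GenomeRecord(
                genome_id=genome_id,
                taxonomy=taxonomy,
                completeness=completeness,
                contamination=contamination,
                hits=genome_hits,
            )
        )
        truth_genomes[genome_id] = {
            "phylum": phylum,
            "passes_qc": completeness > 50 and contamination < 10,
            "planted_families": sorted(planted),
            "has_valid_shdr": has_valid_shdr,
            "has_decoy_shdr": has_decoy_shdr,
            "substrates": substrates,
            "pathways": pathways_fired,
            "trophic": trophic_truth,
            "autotroph_planted": is_autotroph_planted,
        }

    hits_df = pd.DataFrame(hit_rows)

    # scaffold coverage consistent with the reads/(length x total) x 1e6 formula
    genome_abundance = rng_ab.lognormal(
        params.abundance_mu, params.abundance_sigma, size=params.n_genomes
    )
    sample_ids = [f"S{i}" for i in range(1, params.n_samples + 1)]
    sample_depths = [2.0, 26.0, 38.0][: params.n_samples] or [2.0]
    cov_rows = []
    scaffold_lengths: dict[str, int] = {}
    for rec, ab in zip(records, genome_abundance):
        scaffolds = sorted({h.scaffold_id for h in rec.hits}) or [f"{rec.genome_id}_sc0"]
        for sc in scaffolds:
            length = max(
                2000,
                int(rng_ab.lognormal(params.scaffold_length_mu, params.scaffold_length_sigma)),
            )
            scaffold_lengths[sc] = length
            for sample in sample_ids:
                sample_factor = rng_ab.lognormal(0.0, 0.3)
                abundance = ab * sample_factor
                mapped = int(round(abundance * length * params.sample_total_reads / 1e6))
                mapped = min(mapped, params.sample_total_reads)
                cov_rows.append(
                    {
                        "scaffold_id": sc,
                        "sample_id": sample,
                        "mapped_reads": mapped,
                        "length_bp": length,
                        "sample_total_reads": params.sample_total_reads,
                    }
                )
    coverage_df = pd.DataFrame(cov_rows)

    mag_rows = []
    for sample in sample_ids:
        fractions = genome_abundance * rng_ab.lognormal(0.0, 0.2, size=params.n_genomes)
        fractions = fractions / fractions.sum() * (1.0 - params.unmapped_fraction)
        for rec, frac in zip(records, fractions):
            mag_rows.append(
                {"mag_id": rec.genome_id, "sample_id": sample, "raw_fraction": float(frac)}
            )
        mag_rows.append(
            {"mag_id": "unmapped", "sample_id": sample, "raw_fraction": params.unmapped_fraction}
        )
    mag_depth_df = pd.DataFrame(mag_rows)

    tx_rows = []
    for rec in records:
        phylum = truth_genomes[rec.genome_id]["phylum"]
        for family in sorted({h.family for h in rec.hits} - {"shdr_subunit"}):
            base = rng_tx.lognormal(3.0, 1.0)
            fold = params.transcript_fold_changes.get((family, phylum), 1.0)
            noise = rng_tx.lognormal(0.0, params.transcript_noise_sigma, size=2)
            gene_id = f"{rec.genome_id}|{family}"
            tx_rows.append(
                {
                    "gene_id": gene_id,
                    "condition": "control",
                    "depth": base * noise[0],
                    "taxon": phylum,
                    "family": family,
                }
            )
            tx_rows.append(
                {
                    "gene_id": gene_id,
                    "condition": "experimental",
                    "depth": base * fold * noise[1],
                    "taxon": phylum,
                    "family": family,
                }
            )
    transcripts_df = pd.DataFrame(tx_rows)
    transcript_totals = {
        "control": float(params.transcript_total_reads),
        "experimental": float(params.transcript_total_reads),
    }

    sample_metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "station": ["SIM"] * len(sample_ids),
            "depth_cm": sample_depths[: len(sample_ids)]
            + [38.0] * (len(sample_ids) - len(sample_depths)),
        }
    )

    truth = {
        "genomes": truth_genomes,
        "genome_abundance": {
            rec.genome_id: float(ab) for rec, ab in zip(records, genome_abundance)
        },
        "scaffold_lengths": scaffold_lengths,
        "transcript_fold_changes": {
            f"{fam}|{phy}": fold
            for (fam, phy), fold in params.transcript_fold_changes.items()
        },
    }
    return SimulatedCommunity(
        records=records,
        hits=hits_df,
        coverage=coverage_df,
        mag_depth=mag_depth_df,
        transcripts=transcripts_df,
        transcript_totals=transcript_totals,
        sample_metadata=sample_metadata,
        truth=truth,
    )
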