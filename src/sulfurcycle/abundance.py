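"""Relative-abundance normalizations for scaffolds, genes, and MAGs, and
depth-layer assignment of sediment samples.

Scaffold relative abundance is mapped reads normalized by scaffold length
and library size, scaled by 10^6 for readability:

    abundance = mapped_reads / (length_bp × sample_total_reads) × 10^6

A functional gene's abundance is the sum over the scaffolds carrying it.
MAG relative abundances arrive as per-sample mapped fractions including an
explicit unmapped row; the unmapped fraction is removed and the remaining
fractions renormalized to sum to one per sample.

Samples are assigned to sediment layers by core depth: surface 0–2 cm,
middle 8–30 cm, bottom below (deeper than) 30 cm. The scheme has a gap at
2–8 cm; such samples are flagged unassigned rather than forced into a
layer.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

LAYERS = ("surface", "middle", "bottom", "unassigned")
ANNOTATED_SCAFFOLD_MIN_BP = 2000


def scaffold_relative_abundance(
    coverage: pd.DataFrame,
    enforce_min_length: bool = True,
) -> pd.DataFrame:
    """Per-scaffold, per-sample relative abundance.

    `coverage` columns: scaffold_id, sample_id, mapped_reads, length_bp,
    sample_total_reads. Only scaffolds of at least 2,000 bp are annotated
    upstream, so shorter scaffolds are rejected unless
    `enforce_min_length=False`.
    """
    df = coverage.copy()
    if (df["length_bp"] <= 0).any():
        raise ValueError("scaffold length must be positive")
    if (df["sample_total_reads"] <= 0).any():
        raise ValueError("sample total reads must be positive")
    if (df["mapped_reads"] > df["sample_total_reads"]).any():
        raise ValueError("mapped_reads exceeds sample_total_reads")
    if enforce_min_length and (df["length_bp"] < ANNOTATED_SCAFFOLD_MIN_BP).any():
        short = df.loc[df["length_bp"] < ANNOTATED_SCAFFOLD_MIN_BP, "scaffold_id"]
        raise ValueError(
            f"{short.nunique()} scaffolds shorter than {ANNOTATED_SCAFFOLD_MIN_BP} bp; "
            "pass enforce_min_length=False to keep them"
        )
    df["abundance"] = (
        df["mapped_reads"] / (df["length_bp"] * df["sample_total_reads"]) * 1e6
    )
    return df[["scaffold_id", "sample_id", "abundance"]]


def gene_relative_abundance(
    gene_map: pd.DataFrame,
    scaffold_abundance: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene abundance as the sum over its carrying scaffolds.

    `gene_map` columns: gene_id, scaffold_id (one row per carrying
    scaffold); genes mapping to no scaffold in the abundance table are
    reported missing with a warning.
    """
    merged = gene_map.merge(scaffold_abundance, on="scaffold_id", how="left")
    orphan = merged.loc[merged["abundance"].isna(), "gene_id"].unique()
    if len(orphan):
        warnings.warn(
            f"{len(orphan)} genes map to scaffolds absent from the coverage "
            f"table and are reported as missing: {sorted(orphan)[:5]}...",
            stacklevel=2,
        )
        merged = merged.dropna(subset=["abundance"])
    return (
        merged.groupby(["gene_id", "sample_id"], as_index=False)["abundance"].sum()
    )


def renormalize_mag_abundance(depth_table: pd.DataFrame) -> pd.DataFrame:
    """Drop the unmapped fraction and renormalize MAG fractions to one.

    `depth_table` columns: mag_id, sample_id, raw_fraction, with one
    ``mag_id == "unmapped"`` row per sample.
    """
    if (depth_table["raw_fraction"] < 0).any():
        raise ValueError("raw fractions must be non-negative")
    out = []
    for sample, sub in depth_table.groupby("sample_id"):
        if "unmapped" not in set(sub["mag_id"]):
            raise ValueError(f"sample {sample} lacks an 'unmapped' row")
        mags = sub[sub["mag_id"] != "unmapped"].copy()
        mapped_sum = mags["raw_fraction"].sum()
        if mapped_sum <= 0:
            raise ValueError(f"sample {sample}: mapped fraction sums to zero")
        mags["rel_abundance"] = mags["raw_fraction"] / mapped_sum
        out.append(mags[["mag_id", "sample_id", "rel_abundance"]])
    return pd.concat(out, ignore_index=True)


def assign_layer(depth_cm: float) -> str:
    """Map a core depth to a sediment layer (surface 0–2, middle 8–30,
    bottom >30 cm; the 2–8 cm gap is unassigned)."""
    if depth_cm < 0:
        raise ValueError("depth must be non-negative")
    if depth_cm <= 2:
        return "surface"
    if 8 <= depth_cm <= 30:
        return "middle"
    if depth_cm > 30:
        return "bottom"
    warnings.warn(
        f"depth {depth_cm} cm falls in the 2–8 cm gap of the layer scheme; "
        "left unassigned",
        stacklevel=2,
    )
    return "unassigned"


def assign_layers(metadata: pd.DataFrame) -> pd.DataFrame:
    """Vectorized layer assignment for a sample metadata table with a
    depth_cm column."""
    out = metadata.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["layer"] = [assign_layer(d) for d in out["depth_cm"]]
    n_gap = int((out["layer"] == "unassigned").sum())
    if n_gap:
        warnings.warn(f"{n_gap} samples fall in the 2–8 cm gap and are unassigned",
                      stacklevel=2)
    return out


def aggregate_by_layer(
    gene_abundance: pd.DataFrame,
    layers: pd.DataFrame,
    gene_groups: pd.DataFrame,
) -> pd.DataFrame:
    """Sum gene abundances per substrate-pathway group per layer.

    `gene_abundance` columns: gene_id, sample_id, abundance;
    `layers` columns: sample_id, layer; `gene_groups` columns: gene_id,
    group (e.g. the substrate a gene family oxidizes).
    """
    merged = gene_abundance.merge(layers[["sample_id", "layer"]], on="sample_id").merge(
        gene_groups, on="gene_id"
    )
    unassigned = merged["layer"] == "unassigned"
    merged = merged[~unassigned]
    result = (
        merged.groupby(["layer", "group"], as_index=False)["abundance"]
        .sum()
        .sort_values(["layer", "group"])
        .reset_index(drop=True)
    )
    return result
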