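"""Metatranscriptome depth normalization and descriptive log2 fold
changes between sulfide-amended and unamended control incubations.

Per-gene mapped depth is normalized by the condition's total cleaned read
count and scaled by 10^9 for readability. Expression change is the
descriptive contrast

    log2FC = log2(experimental) − log2(control)

which is undefined at zero abundance; a configurable pseudocount policy
handles zeros (default: the smallest nonzero normalized abundance across
both conditions). Community-level contrasts aggregate by summing
normalized abundances within a group per condition before taking the log
ratio (ratio of sums), so a group's fold change is that of its pooled
transcript mass.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

PSEUDOCOUNT_POLICIES = ("auto", "fixed", "skip_zeros")


def normalize_depth(depth, total_cleaned_reads):
    """Normalized transcript abundance: depth / total × 10^9."""
    depth = np.asarray(depth, dtype=float)
    total = np.asarray(total_cleaned_reads, dtype=float)
    if (total <= 0).any():
        raise ValueError("total cleaned reads must be positive")
    if (depth < 0).any():
        raise ValueError("depth must be non-negative")
    out = depth / total * 1e9
    return float(out) if out.ndim == 0 else out


def resolve_pseudocount(
    experimental: np.ndarray,
    control: np.ndarray,
    policy: str = "auto",
    fixed_value: float = 1.0,
) -> float:
    """Pseudocount ε used in log2(exp + ε) − log2(ctrl + ε)."""
    if policy == "fixed":
        return fixed_value
    if policy == "skip_zeros":
        return 0.0
    if policy != "auto":
        raise ValueError(f"unknown pseudocount policy {policy!r}")
    pooled = np.concatenate([np.atleast_1d(experimental), np.atleast_1d(control)])
    nonzero = pooled[pooled > 0]
    return float(nonzero.min()) if len(nonzero) else 1.0


def log2fc(experimental, control, pseudocount: float = 0.0):
    """log2 fold change of experimental over control abundance.

    With ``pseudocount=0`` and both abundances positive this is the exact
    log ratio; with a zero on either side and no pseudocount the result is
    NaN (undefined, flagged by callers).
    """
    e = np.asarray(experimental, dtype=float)
    c = np.asarray(control, dtype=float)
    if (e < 0).any() or (c < 0).any():
        raise ValueError("abundances must be non-negative")
    e = e + pseudocount
    c = c + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((e > 0) & (c > 0), np.log2(np.where(e > 0, e, 1))
                       - np.log2(np.where(c > 0, c, 1)), np.nan)
    return float(out) if out.ndim == 0 else out


def normalize_table(
    depths: pd.DataFrame,
    totals: dict[str, float],
) -> pd.DataFrame:
    """Add a normalized-abundance column to a long depth table.

    `depths` columns: gene_id, condition, depth, plus optional taxon and
    family; `totals` maps condition → total cleaned reads.
    """
    missing = set(depths["condition"]) - set(totals)
    if missing:
        raise ValueError(f"conditions without totals: {sorted(missing)}")
    out = depths.copy()
    out["abundance"] = [
        normalize_depth(d, totals[c]) for d, c in zip(out["depth"], out["condition"])
    ]
    return out


def per_gene_log2fc(
    normalized: pd.DataFrame,
    pseudocount_policy: str = "auto",
    fixed_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2FC between experimental and control conditions."""
    wide = normalized.pivot_table(
        index="gene_id", columns="condition", values="abundance", aggfunc="sum"
    ).fillna(0.0)
    for cond in ("experimental", "control"):
        if cond not in wide.columns:
            wide[cond] = 0.0
    eps = resolve_pseudocount(
        wide["experimental"].to_numpy(), wide["control"].to_numpy(),
        pseudocount_policy, fixed_pseudocount,
    )
    fc = log2fc(wide["experimental"].to_numpy(), wide["control"].to_numpy(), eps)
    out = wide.reset_index()
    out["log2fc"] = fc
    out["undefined"] = np.isnan(fc)
    out.attrs["pseudocount"] = eps
    return out


def aggregate_expression(
    normalized: pd.DataFrame,
    by: list[str],
    pseudocount_policy: str = "auto",
    fixed_pseudocount: float = 1.0,
    mean_of_logs: bool = False,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Grouped abundances and log2FCs (ratio of sums by default).

    `by` lists grouping columns present in the table (e.g. ["family"],
    ["family", "taxon"]). `mean_of_logs=True` averages per-gene log2FCs
    within the group instead of taking the log ratio of summed
    abundances. `top_n` keeps the groups with the highest pooled
    abundance and adds their rank.
    """
    missing = [c for c in by if c not in normalized.columns]
    if missing:
        raise ValueError(f"grouping columns absent: {missing}")
    grouped = normalized.pivot_table(
        index=by, columns="condition", values="abundance", aggfunc="sum"
    ).fillna(0.0)
    for cond in ("experimental", "control"):
        if cond not in grouped.columns:
            grouped[cond] = 0.0
    grouped = grouped.reset_index()
    eps = resolve_pseudocount(
        grouped["experimental"].to_numpy(), grouped["control"].to_numpy(),
        pseudocount_policy, fixed_pseudocount,
    )
    if mean_of_logs:
        gene_fc = per_gene_log2fc(normalized, pseudocount_policy, fixed_pseudocount)
        gene_meta = normalized[["gene_id", *by]].drop_duplicates()
        merged = gene_fc.merge(gene_meta, on="gene_id")
        fc = merged.groupby(by)["log2fc"].mean().reset_index(name="log2fc")
        grouped = grouped.merge(fc, on=by, how="left")
    else:
        grouped["log2fc"] = log2fc(
            grouped["experimental"].to_numpy(), grouped["control"].to_numpy(), eps
        )
    grouped["undefined"] = grouped["log2fc"].isna()
    grouped["pooled_abundance"] = grouped["experimental"] + grouped["control"]
    grouped = grouped.sort_values("pooled_abundance", ascending=False).reset_index(drop=True)
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    if top_n is not None:
        grouped = grouped.head(top_n).reset_index(drop=True)
    grouped.attrs["pseudocount"] = eps
    return grouped
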