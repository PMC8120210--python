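"""Derived maturation metrics and group-level aggregation.

Covers the simple derived quantities (estimated cardiomyocyte volume,
EHT muscular mass), the adult-gene-set maturation score computed on an
already-normalized expression matrix, and mean +/- SEM aggregation over
the S0-S3 conditioning groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "estimate_cm_volume",
    "muscular_mass",
    "maturation_score",
    "group_aggregate",
]


def estimate_cm_volume(mean_length_um: float, mean_cross_section_um2: float) -> float:
    """Estimated cardiomyocyte volume (um^3): mean length x mean cross-section."""
    if not (mean_length_um > 0 and mean_cross_section_um2 > 0):
        raise ValueError("length and cross-section must be positive")
    return float(mean_length_um) * float(mean_cross_section_um2)


def muscular_mass(tissue_length_mm: float, actinin_cross_section_mm2: float) -> float:
    """EHT muscular mass (mm^3): tissue length x actinin+ cross-section."""
    if not (tissue_length_mm > 0 and actinin_cross_section_mm2 > 0):
        raise ValueError("length and cross-section must be positive")
    return float(tissue_length_mm) * float(actinin_cross_section_mm2)


def maturation_score(
    expr: pd.DataFrame,
    gene_set,
    group_a,
    group_b,
    *,
    mean: str = "arithmetic",
    pseudocount: float = 0.0,
) -> dict:
    """Adult-gene-set expression fold of group_a over group_b.

    ``expr`` is genes x samples (non-negative, already normalized).  The
    score is the ratio of the set-average per-gene group means:
    mean_genes(mean_a) / mean_genes(mean_b) for ``mean="arithmetic"``
    (the default), or the geometric analogue.  Per-gene folds are also
    returned; a zero denominator is handled by ``pseudocount`` with a
    warning.
    """
    gene_set = list(gene_set)
    group_a, group_b = list(group_a), list(group_b)
    if not gene_set:
        raise ValueError("empty gene set")
    if not group_a or not group_b:
        raise ValueError("both sample groups must be non-empty")
    missing = [g for g in gene_set if g not in expr.index]
    if missing:
        raise ValueError(f"gene-set members absent from the matrix: {missing}")
    sub = expr.loc[gene_set]
    if (sub.to_numpy() < 0).any():
        raise ValueError("expression matrix must be non-negative")
    mean_a = sub[group_a].mean(axis=1)
    mean_b = sub[group_b].mean(axis=1)
    if (mean_b == 0).any() or (mean_a == 0).any():
        if pseudocount <= 0:
            pseudocount = 0.5
        warnings.warn(
            f"zero group-mean abundance; applying pseudocount {pseudocount}",
            stacklevel=2,
        )
        mean_a = mean_a + pseudocount
        mean_b = mean_b + pseudocount
    per_gene = mean_a / mean_b
    if mean == "geometric":
        fold = float(np.exp(np.log(per_gene).mean()))
    else:
        fold = float(mean_a.mean() / mean_b.mean())
    return dict(fold=fold, per_gene_folds=per_gene)


def group_aggregate(
    metrics: pd.DataFrame,
    group_col: str = "group",
    *,
    reference: str = "S0",
    groups=None,
) -> pd.DataFrame:
    """Mean, SD, SEM and n per metric per group, plus fold vs reference.

    ``metrics`` holds one row per sample with a group label column and
    numeric metric columns.  SEM = SD/sqrt(n); a single-sample group gets
    NaN SEM (flagged by ``n == 1``).  Unknown labels (when ``groups`` is
    given) raise.
    """
    if metrics.empty:
        raise ValueError("empty metrics table")
    if groups is not None:
        unknown = set(metrics[group_col]) - set(groups)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
    value_cols = [c for c in metrics.columns if c != group_col]
    rows = []
    ref_means = {}
    for grp, sub in metrics.groupby(group_col, sort=True):
        for col in value_cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            n = vals.size
            if n == 0:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else np.nan
            rows.append(
                dict(
                    group=grp,
                    metric=col,
                    mean=mean,
                    sd=sd,
                    sem=sd / np.sqrt(n) if n > 1 else np.nan,
                    n=n,
                )
            )
            if grp == reference:
                ref_means[col] = mean
    out = pd.DataFrame(rows)
    out["fold_vs_" + reference] = [
        r["mean"] / ref_means[r["metric"]]
        if r["metric"] in ref_means and ref_means[r["metric"]] != 0
        else np.nan
        for r in rows
    ]
    return out
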