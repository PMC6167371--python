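"""Negative-binomial differential expression between subtypes.

A DESeq-style gene-level test: counts are normalized by median-of-ratios
size factors; per-gene dispersion is estimated by method of moments on
the normalized counts (floored at 1e-8); a Wald statistic is formed on
the log2 difference of group means with a plug-in NB variance and
referred to a t distribution with nA + nB - 2 degrees of freedom. The
reported fold change is Subtype B over Subtype A with a pseudocount of
0.5 on each group mean.

The study's gene filter is applied verbatim: adjusted p < 0.05 (strict),
|log2 fold change| >= 1 and base mean >= 100 (both inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["nb_test", "bh_adjust", "filter_degs", "DEG_ALPHA", "DEG_LFC", "DEG_BASE_MEAN"]

DEG_ALPHA = 0.05
DEG_LFC = 1.0
DEG_BASE_MEAN = 100.0
_DISPERSION_FLOOR = 1e-8


def nb_test(counts_a, counts_b, size_factors: pd.Series) -> pd.DataFrame:
    """Per-gene NB Wald test of group B vs group A.

    Parameters
    ----------
    counts_a, counts_b : DataFrame
        Raw counts, genes x samples, same gene index.
    size_factors : Series
        Size factors covering the samples of both groups.

    Returns
    -------
    DataFrame with columns ``baseMean``, ``log2FoldChange`` (B vs A),
    ``pvalue``.
    """
    a = pd.DataFrame(counts_a)
    b = pd.DataFrame(counts_b)
    if not a.index.equals(b.index):
        raise ValueError("gene indices of the two groups differ")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    for name, grp in (("A", a), ("B", b)):
        if (grp.sum(axis=0) <= 0).any():
            raise ValueError(f"group {name} contains a sample with zero library")
    sf = pd.Series(size_factors)
    sfa = sf.reindex(a.columns)
    sfb = sf.reindex(b.columns)
    if sfa.isna().any() or sfb.isna().any():
        raise ValueError("size factors missing for some samples")

    qa = a.div(sfa, axis=1).to_numpy(dtype=float)
    qb = b.div(sfb, axis=1).to_numpy(dtype=float)
    na, nb = qa.shape[1], qb.shape[1]
    ma = qa.mean(axis=1)
    mb = qb.mean(axis=1)
    base_mean = np.hstack([qa, qb]).mean(axis=1)

    # Method-of-moments dispersion on normalized counts, pooled over
    # groups: Var(q) ~= mu * mean(1/sf) + disp * mu^2.
    inv_a = float((1.0 / sfa).mean())
    inv_b = float((1.0 / sfb).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        da = (qa.var(axis=1, ddof=1) - ma * inv_a) / np.square(ma)
        db = (qb.var(axis=1, ddof=1) - mb * inv_b) / np.square(mb)
    da = np.where(np.isfinite(da), da, 0.0)
    db = np.where(np.isfinite(db), db, 0.0)
    disp = np.maximum(((na - 1) * da + (nb - 1) * db) / (na + nb - 2), _DISPERSION_FLOOR)

    lfc = np.log2(mb + 0.5) - np.log2(ma + 0.5)

    # Plug-in NB variance of each group mean, delta method to log2 scale.
    var_ma = (ma * inv_a / na + disp * np.square(ma)) / na
    var_mb = (mb * inv_b / nb + disp * np.square(mb)) / nb
    ln2sq = np.log(2.0) ** 2
    var_lfc = (var_ma / np.square(ma + 0.5) + var_mb / np.square(mb + 0.5)) / ln2sq
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / np.sqrt(var_lfc)
    pvalue = np.where(
        var_lfc > 0,
        2.0 * stats.t.sf(np.abs(wald), df=na + nb - 2),
        np.where(lfc == 0.0, 1.0, 0.0),
    )
    return pd.DataFrame(
        {"baseMean": base_mean, "log2FoldChange": lfc, "pvalue": pvalue},
        index=a.index,
    )


def bh_adjust(pvals) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvals, pd.Series):
        return pd.Series(adjusted, index=pvals.index, name="padj")
    return adjusted


def filter_degs(
    table: pd.DataFrame,
    alpha: float = DEG_ALPHA,
    lfc_min: float = DEG_LFC,
    base_mean_min: float = DEG_BASE_MEAN,
) -> pd.DataFrame:
    """Apply the three-part DEG filter and annotate direction.

    Adds ``padj`` (if absent), ``pass`` and ``direction`` columns;
    direction is ``B-UP`` for positive fold changes passing the filter,
    ``A-UP`` for negative, ``none`` otherwise. Boundary semantics:
    adjusted p strictly below ``alpha``; |log2FC| and baseMean inclusive.
    """
    out = table.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["pvalue"])
    passing = (
        (out["padj"] < alpha)
        & (out["log2FoldChange"].abs() >= lfc_min)
        & (out["baseMean"] >= base_mean_min)
    )
    out["pass"] = passing
    out["direction"] = np.where(
        passing, np.where(out["log2FoldChange"] > 0, "B-UP", "A-UP"), "none"
    )
    return out


def deg_gene_lists(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(A-UP, B-UP) gene id lists from a filtered DEG table."""
    if "direction" not in table.columns:
        table = filter_degs(table)
    a_up = list(table.index[table["direction"] == "A-UP"])
    b_up = list(table.index[table["direction"] == "B-UP"])
    return a_up, b_up
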