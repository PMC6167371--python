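"""Per-sample tumor micro-environment scores.

Stromal and immune scores are single-sample rank-weighted running-sum
enrichment scores (ssGSEA-style) of stromal and immune signature gene
sets; their sum is the combined (ESTIMATE-style) score, from which tumor
purity is inferred through the published cosine transform

    purity = cos(0.6049872018 + 0.0001467884 * combined_score)

clipped to [0, 1]. The cytolytic (CYT) score is the geometric mean of
GZMA and PRF1 expression on the linear FPKM scale.

The enrichment statistic walks the sample's genes in decreasing rank
order; in-set steps add the gene's rank weight ``rank**alpha``
(normalized over the set), out-of-set steps subtract ``1/(N - m)``
uniformly, and the score is the sum of the running-sum deviations over
all steps. Random gene sets therefore have a positive expected score
(rank weights front-load the in-set mass), matching the score scale the
purity transform's coefficients assume.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import ExpressionMatrix, _as_frame

__all__ = [
    "ssgsea_score",
    "estimate_purity",
    "cyt_score",
    "score_panel",
    "PURITY_INTERCEPT",
    "PURITY_SLOPE",
]

PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884


def _single_sample_score(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment score of one sample.

    ``values`` are the expression values (any monotone scale), ``in_set``
    a boolean membership mask aligned with them.
    """
    n = values.size
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("signature has no genes in the matrix")
    if m == n:
        # No out-of-set mass: the walk is degenerate; defined as 0.
        return 0.0
    ranks = rankdata(values)  # ascending, average ties
    order = np.argsort(-ranks, kind="stable")  # decreasing rank walk
    mask = in_set[order]
    weights = ranks[order] ** alpha
    inc = np.where(mask, weights, 0.0)
    inc_total = inc.sum()
    dec = np.where(mask, 0.0, 1.0 / (n - m))
    running = np.cumsum(inc / inc_total - dec)
    return float(running.sum())


def ssgsea_score(
    expression,
    signature,
    alpha: float = 0.25,
) -> pd.Series:
    """Per-sample enrichment score of one gene set.

    Parameters
    ----------
    expression : DataFrame or ExpressionMatrix
        Genes x samples; ranks are taken per sample (ties averaged).
        Conventionally log2 FPKM, but any per-sample monotone transform
        gives identical scores.
    signature : iterable of str
        Gene ids; ids absent from the matrix are dropped with a warning.
    alpha : float
        Rank-weighting exponent for in-set steps.
    """
    frame = _as_frame(expression)
    sig = list(dict.fromkeys(signature))
    present = [g for g in sig if g in frame.index]
    if len(present) < len(sig):
        warnings.warn(
            f"{len(sig) - len(present)} signature genes absent from matrix; dropped",
            stacklevel=2,
        )
    if not present:
        raise ValueError("signature is empty after filtering to matrix genes")
    in_set = frame.index.isin(present)
    vals = frame.to_numpy(dtype=float)
    scores = [
        _single_sample_score(vals[:, j], in_set, alpha) for j in range(vals.shape[1])
    ]
    return pd.Series(scores, index=frame.columns, name="ssgsea")


def estimate_purity(score) -> np.ndarray | float | pd.Series:
    """Tumor purity from the combined stromal+immune score via the
    published cosine transform, clipped to [0, 1]."""
    arg = PURITY_INTERCEPT + PURITY_SLOPE * np.asarray(score, dtype=float)
    purity = np.clip(np.cos(arg), 0.0, 1.0)
    if isinstance(score, pd.Series):
        return pd.Series(purity, index=score.index, name="purity")
    if np.isscalar(score):
        return float(purity)
    return purity


def cyt_score(
    fpkm,
    cyt_genes: tuple[str, str] = ("GZMA", "PRF1"),
    offset: float = 0.01,
) -> pd.Series:
    """Cytolytic activity: geometric mean of GZMA and PRF1 FPKM."""
    frame = _as_frame(fpkm)
    missing = [g for g in cyt_genes if g not in frame.index]
    if missing:
        raise ValueError(f"cytolytic gene(s) missing from matrix: {missing}")
    vals = frame.loc[list(cyt_genes)].to_numpy(dtype=float) + offset
    score = np.exp(np.log(vals).mean(axis=0))
    return pd.Series(score, index=frame.columns, name="cyt")


def score_panel(
    fpkm: ExpressionMatrix,
    stromal_signature,
    immune_signature,
    cyt_genes: tuple[str, str] = ("GZMA", "PRF1"),
    alpha: float = 0.25,
    cyt_offset: float = 0.01,
    log_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """All micro-environment factors per sample.

    Returns a DataFrame with columns ``stromal``, ``immune``,
    ``estimate`` (= stromal + immune exactly), ``purity`` and ``cyt``.
    Enrichment ranks are taken on log2(FPKM + pseudocount).
    """
    frame = _as_frame(fpkm)
    logged = np.log2(frame + log_pseudocount)
    stromal = ssgsea_score(logged, stromal_signature, alpha=alpha)
    immune = ssgsea_score(logged, immune_signature, alpha=alpha)
    combined = stromal + immune
    panel = pd.DataFrame(
        {
            "stromal": stromal,
            "immune": immune,
            "estimate": combined,
            "purity": estimate_purity(combined),
            "cyt": cyt_score(frame, cyt_genes=cyt_genes, offset=cyt_offset),
        }
    )
    panel.index.name = "sample"
    return panel
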