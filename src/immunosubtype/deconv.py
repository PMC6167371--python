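"""Immune cell-type abundance from bulk expression.

A reference-based linear mixing estimate in the TIMER style: marker
genes whose expression is positively driven by tumor content are first
discarded (Spearman correlation with tumor purity above a threshold,
default 0 i.e. only non-positively correlated markers are kept), and
each sample's expression on the retained genes is regressed on the six
immune reference profiles by non-negative least squares after per-gene
scaling. Coefficients are reported raw and simplex-normalized
(proportions among the immune compartment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import spearmanr

from .preprocess import _as_frame

__all__ = ["select_informative_genes", "fit_fractions", "CellFractions"]

_MIN_GENES_PER_TYPE = 5


@dataclass
class CellFractions:
    """Per-sample immune cell-type abundances.

    ``raw`` holds the NNLS coefficients; ``simplex`` rescales each
    sample's coefficients to sum to 1 (proportions among immune cells;
    zero rows stay zero).
    """

    raw: pd.DataFrame
    simplex: pd.DataFrame

    @property
    def cell_types(self) -> pd.Index:
        return self.raw.columns


def select_informative_genes(
    expression,
    purity: pd.Series,
    marker_sets: dict[str, list[str]],
    rho_max: float = 0.0,
) -> dict[str, list[str]]:
    """Purity-filtered marker genes per cell type.

    Markers whose Spearman correlation with purity across samples
    exceeds ``rho_max`` are removed (they track the malignant
    compartment, not infiltration). If fewer than 5 genes survive for a
    type, the threshold is relaxed in steps of 0.1 with a warning; a
    type that cannot reach 5 genes even at rho_max = 1 is an error.
    """
    frame = _as_frame(expression)
    purity = pd.Series(purity).reindex(frame.columns)
    if purity.isna().any():
        raise ValueError("purity missing for some samples")
    selected: dict[str, list[str]] = {}
    for cell_type, markers in marker_sets.items():
        present = [g for g in dict.fromkeys(markers) if g in frame.index]
        if len(present) < _MIN_GENES_PER_TYPE:
            raise ValueError(
                f"cell type {cell_type!r} has {len(present)} markers in the matrix; "
                f"need at least {_MIN_GENES_PER_TYPE}"
            )
        rho = np.array(
            [spearmanr(frame.loc[g], purity).statistic for g in present]
        )
        rho = np.where(np.isfinite(rho), rho, 0.0)
        threshold = rho_max
        keep = [g for g, r in zip(present, rho) if r <= threshold]
        while len(keep) < _MIN_GENES_PER_TYPE and threshold < 1.0:
            threshold = min(threshold + 0.1, 1.0)
            keep = [g for g, r in zip(present, rho) if r <= threshold]
            warnings.warn(
                f"relaxed purity-correlation threshold to {threshold:.1f} "
                f"for {cell_type!r}",
                stacklevel=2,
            )
        if len(keep) < _MIN_GENES_PER_TYPE:
            raise ValueError(
                f"cell type {cell_type!r} retains {len(keep)} genes even at "
                "threshold 1.0"
            )
        selected[cell_type] = keep
    return selected


def fit_fractions(expression, reference_profiles: pd.DataFrame) -> CellFractions:
    """Non-negative least squares fit of each sample on the reference.

    ``expression`` is genes x samples (linear scale, e.g. FPKM) on the
    selected informative genes; ``reference_profiles`` is genes x cell
    types on the same linear scale. Genes are matched by id and scaled by
    the standard deviation of the reference values across types (genes
    flat across the reference carry no information and are weighted by
    1), then each sample vector is decomposed by NNLS.
    """
    frame = _as_frame(expression)
    ref = reference_profiles.reindex(frame.index)
    if ref.isna().any().any():
        missing = list(frame.index[ref.isna().any(axis=1)][:5])
        raise ValueError(f"reference profiles missing for genes {missing}...")
    R = ref.to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        corr = np.corrcoef(R.T)
        pairs = [
            (ref.columns[i], ref.columns[j])
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if corr[i, j] > 0.9999
        ]
        raise ValueError(f"reference is rank deficient; collinear types: {pairs}")
    scale = R.std(axis=1, ddof=0)
    scale[scale == 0] = 1.0
    Rs = R / scale[:, None]
    X = frame.to_numpy(dtype=float) / scale[:, None]
    coefs = np.empty((frame.shape[1], R.shape[1]))
    for j in range(frame.shape[1]):
        coefs[j], _ = nnls(Rs, X[:, j])
    raw = pd.DataFrame(coefs, index=frame.columns, columns=ref.columns)
    totals = raw.sum(axis=1)
    simplex = raw.div(totals.where(totals > 0, 1.0), axis=0)
    return CellFractions(raw=raw, simplex=simplex)
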