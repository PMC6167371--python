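"""Count normalization and transformation.

The analysis chain uses two parallel normalizations of the raw count
matrix: a variance-stabilizing-style transform of size-factor-normalized
counts (used for variable-gene selection and PCA) and FPKM followed by
log2 median-centering (used for scoring, z-scores and heatmaps).

The variance-stabilizing transform here is ``log2(count / size_factor + 1)``,
a shifted-log approximation of the parametric DESeq-style VST: downstream
use is only variance ranking and PCA geometry, which the shifted log
preserves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "size_factors",
    "vst",
    "counts_to_fpkm",
    "log2_median_center",
    "select_variable_genes",
]

#: Recognised unit tags for :class:`ExpressionMatrix`.
UNITS = ("counts", "fpkm", "log2fpkm_centered", "vst")


@dataclass
class ExpressionMatrix:
    """A gene x sample expression grid with a unit tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes in rows, samples in columns. Gene and sample ids must be
        unique and no value may be missing.
    unit : str
        One of ``counts``, ``fpkm``, ``log2fpkm_centered``, ``vst``.
        The ``counts`` unit additionally requires non-negative integers.
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not self.data.index.is_unique:
            raise ValueError("gene ids are not unique")
        if not self.data.columns.is_unique:
            raise ValueError("sample ids are not unique")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.unit == "counts":
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.data.shape
        return f"ExpressionMatrix({g} genes x {s} samples, unit={self.unit!r})"


def _as_frame(matrix, unit: str | None = None) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        if unit is not None and matrix.unit != unit:
            raise ValueError(f"expected unit {unit!r}, got {matrix.unit!r}")
        return matrix.data
    return matrix


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample the factor is the median, over genes whose count is
    positive in every sample, of the ratio of the sample's count to the
    gene's geometric mean across samples.

    Raises
    ------
    ValueError
        If no gene has a positive count in every sample, or fewer than
        two samples are supplied.
    """
    frame = _as_frame(counts)
    if frame.shape[1] < 2:
        raise ValueError("size factors require at least two samples")
    vals = frame.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    expressed = (vals > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene has a nonzero count in every sample; "
            "median-of-ratios size factors are undefined"
        )
    logc = np.log(vals[expressed])
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.median(np.exp(logc - log_geomean), axis=0)
    return pd.Series(factors, index=frame.columns, name="size_factor")


def vst(counts, factors: pd.Series | None = None) -> ExpressionMatrix:
    """Shifted-log variance-stabilizing transform of normalized counts.

    ``value = log2(count / size_factor + 1)``.
    """
    frame = _as_frame(counts)
    if (frame.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if factors is None:
        factors = size_factors(frame)
    factors = pd.Series(factors, index=frame.columns).astype(float)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    transformed = np.log2(frame.div(factors, axis=1) + 1.0)
    return ExpressionMatrix(transformed, unit="vst")


def counts_to_fpkm(counts, gene_lengths_bp: pd.Series) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    ``fpkm = count * 1e9 / (library_size * length_bp)`` where the library
    size is the per-sample column sum of raw counts.
    """
    frame = _as_frame(counts)
    lengths = pd.Series(gene_lengths_bp).reindex(frame.index).astype(float)
    if lengths.isna().any():
        missing = list(frame.index[lengths.isna()][:5])
        raise ValueError(f"gene lengths missing for {missing}...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib_size = frame.sum(axis=0)
    if (lib_size <= 0).any():
        bad = list(lib_size.index[lib_size <= 0])
        raise ValueError(f"zero library size in samples {bad}")
    fpkm = frame.div(lib_size, axis=1).div(lengths, axis=0) * 1e9
    return ExpressionMatrix(fpkm, unit="fpkm")


def log2_median_center(fpkm, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Per-gene log2 transform followed by median centering across samples."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    frame = _as_frame(fpkm)
    logged = np.log2(frame + pseudocount)
    centered = logged.sub(logged.median(axis=1), axis=0)
    return ExpressionMatrix(centered, unit="log2fpkm_centered")


def select_variable_genes(matrix, n: int) -> list[str]:
    """Ids of the ``n`` genes with the largest across-sample variance.

    Ties are broken by lexicographic gene id so the selection is
    deterministic. Variance uses the unbiased (n-1) denominator.
    """
    frame = _as_frame(matrix)
    if n > frame.shape[0]:
        raise ValueError(f"requested {n} genes but matrix has {frame.shape[0]}")
    variances = frame.var(axis=1, ddof=1)
    order = sorted(frame.index, key=lambda g: (-variances[g], g))
    return order[:n]
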