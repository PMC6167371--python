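"""Signature z-scores of tumors against matched noncancer controls.

Per gene, a tumor's z-score is its FPKM minus the mean FPKM of the
noncancer controls, divided by the control standard deviation (n-1
denominator), computed on the linear FPKM scale exactly as the defining
equation states (an optional log2 mode exists but is off by default).
Signature-level scores are the unweighted mean z over the signature's
genes; genes with zero control variance are excluded and recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import _as_frame

__all__ = ["zscore", "average_signature_z", "checkpoint_panel", "ZScoreResult"]

#: Immune checkpoint panel as commonly listed. Some published gene
#: lists print "Tim-2" where Tim-3 (HAVCR2) is almost certainly meant;
#: the label is configurable rather than silently corrected.
_CHECKPOINT_BASE = ("PD-1", "PD-L1", "PD-L2", "CTLA4", "B7-1", "B7-2", "Galectin-9")


def checkpoint_panel(tim_label: str = "Tim-3") -> list[str]:
    """The 8-gene immune checkpoint panel, with a configurable Tim label."""
    return [*_CHECKPOINT_BASE[:6], tim_label, _CHECKPOINT_BASE[6]]


@dataclass
class ZScoreResult:
    """Per-gene x per-tumor z values and the genes excluded for zero
    control variance."""

    z: pd.DataFrame
    excluded_genes: list[str] = field(default_factory=list)


def zscore(tumor_fpkm, normal_fpkm, log2: bool = False, pseudocount: float = 1.0) -> ZScoreResult:
    """Z-scores of tumor expression against the control distribution.

    ``z_gs = (x_gs - mean_g(controls)) / sd_g(controls)`` with the
    unbiased control standard deviation. Requires at least two control
    samples. Genes whose control SD is zero are dropped with a warning.
    """
    tumors = _as_frame(tumor_fpkm)
    normals = _as_frame(normal_fpkm)
    if normals.shape[1] < 2:
        raise ValueError("need at least 2 noncancer control samples")
    normals = normals.reindex(tumors.index)
    if normals.isna().any().any():
        raise ValueError("control matrix lacks some tumor-matrix genes")
    if log2:
        tumors = np.log2(tumors + pseudocount)
        normals = np.log2(normals + pseudocount)
    mu = normals.mean(axis=1)
    sd = normals.std(axis=1, ddof=1)
    degenerate = sd == 0
    excluded = list(tumors.index[degenerate])
    if excluded:
        warnings.warn(
            f"{len(excluded)} genes with zero control SD excluded from z-scores",
            stacklevel=2,
        )
    z = tumors.loc[~degenerate].sub(mu[~degenerate], axis=0).div(sd[~degenerate], axis=0)
    return ZScoreResult(z=z, excluded_genes=excluded)


def average_signature_z(z, signature) -> pd.Series:
    """Unweighted mean z over a signature's genes, per sample."""
    frame = z.z if isinstance(z, ZScoreResult) else _as_frame(z)
    genes = [g for g in dict.fromkeys(signature) if g in frame.index]
    if not genes:
        raise ValueError("no signature gene has a valid z-score")
    return frame.loc[genes].mean(axis=0)
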