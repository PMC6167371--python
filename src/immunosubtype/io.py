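"""Plain-text readers and writers: TSV matrices, GMT gene sets, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .preprocess import ExpressionMatrix

__all__ = [
    "read_counts_tsv",
    "read_gene_lengths_tsv",
    "read_annotation_tsv",
    "read_gmt",
    "write_gmt",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


def read_counts_tsv(path: str | Path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(frame, unit="counts")


def read_gene_lengths_tsv(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0].rename("length_bp")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Gene sets from a GMT file (set name, description, genes...)."""
    return {name: list(genes) for name, genes in _gseapy_read_gmt(str(path)).items()}


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Matrix TSV plus a sidecar JSON recording the unit tag."""
    path = Path(path)
    matrix.data.to_csv(path, sep="\t", index_label="gene")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"unit": matrix.unit}, sort_keys=True))


def read_matrix_tsv(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    unit = "counts"
    if sidecar.exists():
        unit = json.loads(sidecar.read_text())["unit"]
    return ExpressionMatrix(frame, unit=unit)
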