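"""The end-to-end immune subtyping model.

:class:`ImmuneSubtypeModel` is built from a raw count matrix, gene
lengths, a sample annotation table and a bundle of gene signatures; its
:meth:`~ImmuneSubtypeModel.fit` runs the whole analysis chain —
normalization, micro-environment scoring, PCA + k-means subtyping,
negative-binomial differential expression with over-representation
analysis, immune deconvolution, signature z-scores and survival — and
returns an :class:`ImmuneSubtypeResults` holding every table, with a
``summary()`` and a ``save()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deconv as deconv_mod
from . import dge as dge_mod
from . import enrich as enrich_mod
from . import microenv, preprocess, signatures as sig_mod, subtype as subtype_mod
from .deconv import CellFractions
from .preprocess import ExpressionMatrix
from .report import SurvivalResult, km_logrank, subtype_fraction_table
from .subtype import ClusterResult, SubtypeCall

__all__ = ["ImmuneSubtypeModel", "ImmuneSubtypeResults"]

#: Signature-bundle keys with a fixed meaning in the pipeline.
STROMAL_KEY = "STROMAL_SIGNATURE"
IMMUNE_KEY = "IMMUNE_SIGNATURE"
TIMER_PREFIX = "TIMER_"
ZSCORE_PANELS = (
    "MACROPHAGE_M1",
    "MACROPHAGE_M2",
    "B_REG",
    "ACTIVATED_STROMA",
    "NORMAL_STROMA",
    "IMMUNE_CHECKPOINT",
)


class ImmuneSubtypeModel:
    """Immune subtyping of a tumor/normal bulk RNA-seq cohort.

    Parameters
    ----------
    counts : ExpressionMatrix or DataFrame
        Raw counts, genes x samples.
    gene_lengths : Series
        Transcript lengths in bp, indexed by gene id.
    samples : DataFrame
        Indexed by sample id with a ``tissue`` column ('tumor'/'normal');
        optional ``time``/``event`` columns enable survival analysis.
    gene_signatures : dict
        Name -> gene list. Must contain the stromal and immune scoring
        sets (``STROMAL_SIGNATURE``/``IMMUNE_SIGNATURE``); ``TIMER_*``
        sets feed deconvolution and any of the z-score panel names are
        scored against normals.
    reference_profiles : DataFrame, optional
        Genes x immune-cell-type linear-scale means for deconvolution;
        deconvolution is skipped when absent.
    """

    def __init__(
        self,
        counts,
        gene_lengths: pd.Series,
        samples: pd.DataFrame,
        gene_signatures: dict[str, list[str]],
        reference_profiles: pd.DataFrame | None = None,
        n_top_genes: int = 1000,
        ssgsea_alpha: float = 0.25,
        cyt_genes: tuple[str, str] = ("GZMA", "PRF1"),
        cyt_offset: float = 0.01,
        deg_alpha: float = dge_mod.DEG_ALPHA,
        deg_lfc: float = dge_mod.DEG_LFC,
        deg_base_mean: float = dge_mod.DEG_BASE_MEAN,
        cohort_name: str = "cohort",
    ) -> None:
        self.counts = (
            counts if isinstance(counts, ExpressionMatrix)
            else ExpressionMatrix(pd.DataFrame(counts), unit="counts")
        )
        self.gene_lengths = pd.Series(gene_lengths)
        self.samples = pd.DataFrame(samples)
        if "tissue" not in self.samples.columns:
            raise ValueError("sample table needs a 'tissue' column")
        missing = self.counts.samples.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"annotation missing for samples {list(missing)[:5]}")
        self.samples = self.samples.loc[self.counts.samples]
        self.gene_signatures = dict(gene_signatures)
        for key in (STROMAL_KEY, IMMUNE_KEY):
            if key not in self.gene_signatures:
                raise ValueError(f"gene_signatures must contain {key!r}")
        self.reference_profiles = reference_profiles
        self.n_top_genes = n_top_genes
        self.ssgsea_alpha = ssgsea_alpha
        self.cyt_genes = cyt_genes
        self.cyt_offset = cyt_offset
        self.deg_thresholds = (deg_alpha, deg_lfc, deg_base_mean)
        self.cohort_name = cohort_name

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "ImmuneSubtypeModel":
        """Build the model from a :class:`~immunosubtype.synth.SyntheticCohort`,
        wiring its signature bundle and immune reference profiles."""
        from .synth import IMMUNE_POPULATIONS

        ref = cohort.panel.profiles[list(IMMUNE_POPULATIONS)]
        return cls(
            counts=cohort.counts,
            gene_lengths=cohort.gene_lengths,
            samples=cohort.samples,
            gene_signatures=cohort.signatures,
            reference_profiles=ref,
            **kwargs,
        )

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, n_restarts: int = 50) -> "ImmuneSubtypeResults":
        """Run the full analysis chain; deterministic under a fixed seed."""
        notes: list[str] = []
        counts = self.counts
        sf = preprocess.size_factors(counts)
        vst = preprocess.vst(counts, sf)
        fpkm = preprocess.counts_to_fpkm(counts, self.gene_lengths)

        scores = microenv.score_panel(
            fpkm,
            self.gene_signatures[STROMAL_KEY],
            self.gene_signatures[IMMUNE_KEY],
            cyt_genes=self.cyt_genes,
            alpha=self.ssgsea_alpha,
            cyt_offset=self.cyt_offset,
        )

        top_genes = preprocess.select_variable_genes(vst, min(self.n_top_genes,
                                                              len(vst.genes)))
        coords, varexp = subtype_mod.pca_embed(vst, top_genes)
        clustering = subtype_mod.cluster_k3(coords, seed=seed, n_restarts=n_restarts)
        call = subtype_mod.assign_subtypes(
            clustering.kmeans,
            self.samples["tissue"],
            scores["immune"],
            coordinates=coords,
            variance_explained=varexp,
        )
        if call.no_normal_fallback:
            notes.append("no normal samples: subtype assignment used the "
                         "immune-score-only fallback")

        tissue = self.samples["tissue"]
        tumors = tissue.index[tissue == "tumor"]
        normals = tissue.index[tissue == "normal"]
        called = call.subtype

        # Differential expression between called subtypes.
        a_ids = [s for s in tumors if called[s] == "A"]
        b_ids = [s for s in tumors if called[s] == "B"]
        deg_table = None
        enrichment: dict[str, pd.DataFrame] = {}
        if len(a_ids) >= 2 and len(b_ids) >= 2:
            deg_table = dge_mod.nb_test(
                counts.data[a_ids], counts.data[b_ids], sf
            )
            deg_table = dge_mod.filter_degs(deg_table, *self.deg_thresholds)
            a_up, b_up = dge_mod.deg_gene_lists(deg_table)
            universe = list(deg_table.index)
            sets_in_universe = {
                name: [g for g in genes if g in deg_table.index]
                for name, genes in self.gene_signatures.items()
            }
            sets_in_universe = {k: v for k, v in sets_in_universe.items() if v}
            for label, gene_list in (("A-UP", a_up), ("B-UP", b_up)):
                if gene_list and sets_in_universe:
                    enrichment[label] = enrich_mod.enrichment_table(
                        gene_list, sets_in_universe, universe
                    )
        else:
            notes.append("fewer than 2 tumors in a called subtype: differential "
                         "expression skipped")

        # Immune deconvolution on tumor samples.
        fractions: CellFractions | None = None
        if self.reference_profiles is not None and len(tumors):
            marker_sets = {
                name[len(TIMER_PREFIX):]: genes
                for name, genes in self.gene_signatures.items()
                if name.startswith(TIMER_PREFIX)
            }
            marker_sets = {
                k: v for k, v in marker_sets.items()
                if k in self.reference_profiles.columns
            }
            if marker_sets:
                tumor_fpkm = fpkm.data[list(tumors)]
                selected = deconv_mod.select_informative_genes(
                    tumor_fpkm, scores.loc[list(tumors), "purity"], marker_sets
                )
                union = sorted({g for genes in selected.values() for g in genes})
                ref_cols = [c for c in self.reference_profiles.columns
                            if c in marker_sets]
                fractions = deconv_mod.fit_fractions(
                    tumor_fpkm.loc[union],
                    self.reference_profiles.loc[union, ref_cols],
                )
            else:
                notes.append("no TIMER_* marker sets match the reference profiles: "
                             "deconvolution skipped")

        # Signature z-scores of tumors against normals.
        signature_z = None
        zres = None
        if len(normals) >= 2 and len(tumors):
            zres = sig_mod.zscore(fpkm.data[list(tumors)], fpkm.data[list(normals)])
            panels = {
                name: self.gene_signatures[name]
                for name in ZSCORE_PANELS
                if name in self.gene_signatures
            }
            cols = {}
            for name, genes in panels.items():
                try:
                    cols[name] = sig_mod.average_signature_z(zres, genes)
                except ValueError:
                    notes.append(f"z-score panel {name!r} has no valid genes")
            signature_z = pd.DataFrame(cols) if cols else None
        elif len(normals) < 2:
            notes.append("fewer than 2 normals: signature z-scores skipped")

        # Survival between called subtypes.
        survival = None
        if {"time", "event"}.issubset(self.samples.columns) and a_ids and b_ids:
            sub = called.loc[list(a_ids) + list(b_ids)]
            surv_tab = self.samples.loc[sub.index]
            try:
                survival = km_logrank(
                    surv_tab["time"], surv_tab["event"].astype(int), sub
                )
            except ValueError as exc:
                notes.append(f"survival analysis skipped: {exc}")

        fraction_table = subtype_fraction_table(
            {self.cohort_name: called.loc[list(tumors)]}
        )

        return ImmuneSubtypeResults(
            model=self,
            size_factors=sf,
            vst=vst,
            fpkm=fpkm,
            scores=scores,
            top_genes=list(top_genes),
            pca_coordinates=coords,
            variance_explained=varexp,
            clustering=clustering,
            subtype_call=call,
            deg_table=deg_table,
            enrichment=enrichment,
            fractions=fractions,
            zscores=zres,
            signature_z=signature_z,
            survival=survival,
            fraction_table=fraction_table,
            seed=seed,
            notes=notes,
        )


@dataclass
class ImmuneSubtypeResults:
    """Fitted results of :class:`ImmuneSubtypeModel`."""

    model: ImmuneSubtypeModel
    size_factors: pd.Series
    vst: ExpressionMatrix
    fpkm: ExpressionMatrix
    scores: pd.DataFrame
    top_genes: list[str]
    pca_coordinates: pd.DataFrame
    variance_explained: np.ndarray
    clustering: ClusterResult
    subtype_call: SubtypeCall
    deg_table: pd.DataFrame | None
    enrichment: dict[str, pd.DataFrame]
    fractions: CellFractions | None
    zscores: object | None
    signature_z: pd.DataFrame | None
    survival: SurvivalResult | None
    fraction_table: pd.DataFrame
    seed: int
    notes: list[str] = field(default_factory=list)

    @property
    def subtype(self) -> pd.Series:
        """Per-sample subtype label (A / B / noncancer)."""
        return self.subtype_call.subtype

    def score_comparison(self) -> pd.DataFrame:
        """Mean micro-environment scores of called Subtype A vs B tumors."""
        called = self.subtype
        rows = {}
        for sub in ("A", "B"):
            ids = called.index[called == sub]
            rows[sub] = self.scores.loc[ids].mean() if len(ids) else np.nan
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        """Plain-text overview of the fit."""
        lines = ["Immune subtyping results", "=" * 24]
        tissue = self.model.samples["tissue"]
        lines.append(
            f"samples: {int((tissue == 'tumor').sum())} tumors, "
            f"{int((tissue == 'normal').sum())} normals; "
            f"{len(self.model.counts.genes)} genes"
        )
        ve = ", ".join(f"PC{i + 1} {v * 100:.1f}%" for i, v in
                       enumerate(self.variance_explained))
        lines.append(f"PCA on top {len(self.top_genes)} variable genes: {ve}")
        lines.append(
            f"k-means/Ward agreement (ARI): {self.clustering.ari_kmeans_ward:.3f}"
        )
        for _, row in self.fraction_table.iterrows():
            lines.append(
                f"  Subtype {row['subtype']}: {row['count']}/{row['n']} "
                f"({row['percent']:.2f}%)"
            )
        if self.deg_table is not None:
            n_pass = int(self.deg_table["pass"].sum())
            n_b = int((self.deg_table["direction"] == "B-UP").sum())
            lines.append(
                f"DEGs (adj p < {self.model.deg_thresholds[0]}, |log2FC| >= "
                f"{self.model.deg_thresholds[1]}, baseMean >= "
                f"{self.model.deg_thresholds[2]:g}): {n_pass} "
                f"({n_b} B-UP, {n_pass - n_b} A-UP)"
            )
        comp = self.score_comparison()
        if not comp.isna().all().all():
            lines.append("mean scores (A vs B): " + "; ".join(
                f"{c}: {comp.loc['A', c]:.3g} / {comp.loc['B', c]:.3g}"
                for c in ("stromal", "immune", "purity", "cyt")
            ))
        if self.survival is not None:
            lines.append(
                f"log-rank A vs B: chi2 = {self.survival.statistic:.3f}, "
                f"p = {self.survival.pvalue:.3g}"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def manifest(self) -> dict:
        m = self.model
        return {
            "cohort": m.cohort_name,
            "seed": self.seed,
            "n_genes": int(len(m.counts.genes)),
            "n_samples": int(len(m.counts.samples)),
            "n_top_genes": len(self.top_genes),
            "ssgsea_alpha": m.ssgsea_alpha,
            "deg_thresholds": {
                "adj_p": m.deg_thresholds[0],
                "abs_log2fc": m.deg_thresholds[1],
                "base_mean": m.deg_thresholds[2],
            },
            "notes": list(self.notes),
            "stages": {
                "dge": self.deg_table is not None,
                "deconvolution": self.fractions is not None,
                "signature_z": self.signature_z is not None,
                "survival": self.survival is not None,
            },
        }

    def save(self, outdir: str | Path) -> None:
        """Write all result tables as TSV plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subtype_call.assignments.to_csv(
            outdir / "subtypes.tsv", sep="\t", index_label="sample"
        )
        self.scores.to_csv(outdir / "scores.tsv", sep="\t", index_label="sample")
        self.fraction_table.to_csv(outdir / "subtype_fractions.tsv", sep="\t",
                                   index=False)
        if self.deg_table is not None:
            self.deg_table.to_csv(outdir / "deg.tsv", sep="\t", index_label="gene")
            a_up, b_up = dge_mod.deg_gene_lists(self.deg_table)
            (outdir / "deg_A_up.txt").write_text("\n".join(a_up) + "\n")
            (outdir / "deg_B_up.txt").write_text("\n".join(b_up) + "\n")
        for label, table in self.enrichment.items():
            table.to_csv(outdir / f"enrichment_{label}.tsv", sep="\t",
                         index_label="set")
        if self.fractions is not None:
            self.fractions.raw.to_csv(outdir / "cell_fractions_raw.tsv", sep="\t",
                                      index_label="sample")
            self.fractions.simplex.to_csv(
                outdir / "cell_fractions_simplex.tsv", sep="\t", index_label="sample"
            )
        if self.signature_z is not None:
            self.signature_z.to_csv(outdir / "signature_z.tsv", sep="\t",
                                    index_label="sample")
        if self.survival is not None:
            for lab, curve in self.survival.curves.items():
                curve.to_csv(outdir / f"km_{lab}.tsv", sep="\t", index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n"
        )
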