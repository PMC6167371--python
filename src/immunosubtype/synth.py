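"""Seeded synthetic bulk RNA-seq cohorts with known ground truth.

A cohort is a purity-weighted mixture model: each bulk sample combines a
malignant profile with activated/normal stromal profiles and six immune
cell-type profiles (B, CD4+ T, CD8+ T, neutrophil, macrophage,
dendritic). Immune-competent ("B") tumors draw purity from a
stochastically lower Beta distribution than immune-deficient ("A")
tumors, so they carry more infiltrate; noncancer controls have purity 0
and high stromal/immune content. Counts are negative binomial around
length- and depth-scaled mixture means, so FPKM recovers the mixture on
the linear scale.

Everything is reproducible from a single seed; regenerating with the
same seed is bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "POPULATIONS",
    "IMMUNE_POPULATIONS",
    "ReferencePanel",
    "SyntheticCohort",
    "make_reference_panel",
    "simulate_cohort",
    "write_cohort",
]

#: Mixture populations, malignant first.
POPULATIONS = (
    "malignant",
    "activated_stroma",
    "normal_stroma",
    "B_cell",
    "CD4_T",
    "CD8_T",
    "neutrophil",
    "macrophage",
    "dendritic",
)

IMMUNE_POPULATIONS = POPULATIONS[3:]
STROMA_POPULATIONS = POPULATIONS[1:3]

#: Default Beta(a, b) purity priors per tumor subtype; the immune-competent
#: subtype B is stochastically less pure (more infiltrated) than A.
DEFAULT_PURITY_PARAMS = {"A": (18.0, 4.0), "B": (8.0, 8.0)}

#: Default Dirichlet concentrations over the eight non-malignant
#: populations (order follows POPULATIONS[1:]). Normals carry more normal
#: stroma and lymphocytes, mirroring adjacent normal lung tissue.
DEFAULT_INFILTRATION_PARAMS = {
    "tumor": (2.0, 1.0, 1.0, 1.5, 1.5, 1.0, 1.5, 0.5),
    "normal": (1.5, 3.0, 1.5, 2.0, 2.0, 1.5, 2.0, 1.0),
}

#: Genes whose geometric mean defines the cytolytic score; two CD8+ T
#: marker genes in the panel are given these ids.
CYT_GENES = ("GZMA", "PRF1")


@dataclass
class ReferencePanel:
    """Per-population linear-scale mean expression profiles.

    ``profiles`` is genes x populations; ``markers`` maps each population
    to the ids of genes elevated ``fold``-times in that population only.
    Marker sets are disjoint by construction.
    """

    profiles: pd.DataFrame
    markers: dict[str, list[str]]
    fold: float

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() <= 0).any():
            raise ValueError("reference profiles must be strictly positive")
        seen: set[str] = set()
        for pop, genes in self.markers.items():
            if not genes:
                raise ValueError(f"population {pop!r} has an empty marker set")
            overlap = seen.intersection(genes)
            if overlap:
                raise ValueError(f"marker sets overlap: {sorted(overlap)[:5]}")
            seen.update(genes)

    @property
    def genes(self) -> pd.Index:
        return self.profiles.index


@dataclass
class SyntheticCohort:
    """A simulated cohort: counts, lengths, annotation with ground truth,
    the generating reference panel and a gene-signature bundle."""

    counts: ExpressionMatrix
    gene_lengths: pd.Series
    samples: pd.DataFrame
    panel: ReferencePanel
    signatures: dict[str, list[str]]
    seed: int

    @property
    def tumor_ids(self) -> pd.Index:
        return self.samples.index[self.samples["tissue"] == "tumor"]

    @property
    def normal_ids(self) -> pd.Index:
        return self.samples.index[self.samples["tissue"] == "normal"]


def make_reference_panel(
    n_genes: int = 2000,
    n_markers_per_pop: int = 100,
    fold: float = 8.0,
    seed: int = 0,
) -> ReferencePanel:
    """Draw a reference expression panel with disjoint marker blocks.

    Baseline means are log-normal; each population's markers are
    multiplied by ``fold`` in that population's profile only. Two CD8+ T
    markers are named GZMA and PRF1 so the cytolytic score is defined on
    every cohort generated from the panel.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    n_pops = len(POPULATIONS)
    if n_genes < n_pops * n_markers_per_pop:
        raise ValueError(
            f"{n_genes} genes cannot host {n_pops} disjoint marker sets "
            f"of {n_markers_per_pop}"
        )
    if n_markers_per_pop < 1:
        raise ValueError("n_markers_per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=np.log(20.0), sigma=1.2, size=n_genes)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)
    markers_idx = {
        pop: np.sort(perm[i * n_markers_per_pop : (i + 1) * n_markers_per_pop])
        for i, pop in enumerate(POPULATIONS)
    }
    # Name two CD8+ T markers after the cytolytic genes.
    cd8 = markers_idx["CD8_T"]
    for idx, name in zip(cd8[: len(CYT_GENES)], CYT_GENES):
        gene_ids[idx] = name

    profiles = pd.DataFrame(
        np.tile(base[:, None], (1, n_pops)), index=gene_ids, columns=list(POPULATIONS)
    )
    for pop, idx in markers_idx.items():
        profiles.iloc[idx, profiles.columns.get_loc(pop)] *= fold
    markers = {pop: [gene_ids[i] for i in idx] for pop, idx in markers_idx.items()}
    return ReferencePanel(profiles=profiles, markers=markers, fold=fold)


def _signature_bundle(panel: ReferencePanel) -> dict[str, list[str]]:
    """Derive the GMT-style signature bundle the scoring stages consume."""
    markers = panel.markers
    bundle: dict[str, list[str]] = {}
    bundle["STROMAL_SIGNATURE"] = sorted(
        markers["activated_stroma"] + markers["normal_stroma"]
    )
    bundle["IMMUNE_SIGNATURE"] = sorted(
        g for pop in IMMUNE_POPULATIONS for g in markers[pop]
    )
    for pop in IMMUNE_POPULATIONS:
        bundle[f"TIMER_{pop}"] = sorted(markers[pop])
    bundle["ACTIVATED_STROMA"] = sorted(markers["activated_stroma"])
    bundle["NORMAL_STROMA"] = sorted(markers["normal_stroma"])
    mac = sorted(markers["macrophage"])
    half = max(1, len(mac) // 2)
    bundle["MACROPHAGE_M1"] = mac[:half]
    bundle["MACROPHAGE_M2"] = mac[half:] or mac[:1]
    b = sorted(markers["B_cell"])
    bundle["B_REG"] = b[: max(1, len(b) // 2)]
    # Checkpoint panel: eight T-cell markers, excluding the CYT genes.
    tc = [g for g in sorted(markers["CD8_T"] + markers["CD4_T"]) if g not in CYT_GENES]
    bundle["IMMUNE_CHECKPOINT"] = tc[:8]
    # Diagnostic set: lets over-representation of malignant-profile DEG
    # lists be exercised end-to-end on synthetic cohorts.
    bundle["MALIGNANT_MARKERS"] = sorted(markers["malignant"])
    return bundle


def simulate_cohort(
    panel: ReferencePanel,
    n_tumor_A: int = 40,
    n_tumor_B: int = 40,
    n_normal: int = 40,
    purity_params: dict[str, tuple[float, float]] | None = None,
    infiltration_params: dict[str, tuple[float, ...]] | None = None,
    nb_dispersion: float = 0.1,
    mean_lib_size: float = 2e6,
    n_de_genes: int = 100,
    de_lfc: float = 2.0,
    hazard_ratio: float = 1.0,
    survival_scale: float = 60.0,
    censor_horizon: float = 120.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate a cohort of purity-weighted mixtures with NB count noise.

    Per sample the expected linear expression is
    ``purity * malignant + sum_p fraction_p * profile_p``; expected counts
    scale that by gene length and library size, and observed counts are
    negative binomial with the given dispersion. ``n_de_genes`` malignant
    marker genes are additionally shifted by ``de_lfc`` log2 units between
    subtypes A and B (half up, half down in B) to plant a differential
    signal between tumor subtypes beyond the purity contrast.

    Survival times are exponential and independent of subtype unless
    ``hazard_ratio`` != 1, in which case subtype B's hazard is multiplied
    by it; censoring is administrative at ``censor_horizon``.
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    if min(n_tumor_A, n_tumor_B, n_normal) < 0 or n_tumor_A + n_tumor_B + n_normal == 0:
        raise ValueError("sample counts must be non-negative and not all zero")
    if mean_lib_size <= 0:
        raise ValueError("mean_lib_size must be positive")
    purity_params = dict(DEFAULT_PURITY_PARAMS if purity_params is None else purity_params)
    infiltration_params = dict(
        DEFAULT_INFILTRATION_PARAMS if infiltration_params is None else infiltration_params
    )
    for key, alphas in infiltration_params.items():
        alphas = np.asarray(alphas, dtype=float)
        if alphas.shape != (len(POPULATIONS) - 1,) or (alphas <= 0).any():
            raise ValueError(
                f"infiltration weights for {key!r} must be {len(POPULATIONS) - 1} "
                "positive Dirichlet concentrations"
            )
        infiltration_params[key] = alphas

    rng = np.random.default_rng(seed)
    genes = panel.genes
    n_genes = len(genes)
    lengths = pd.Series(
        rng.uniform(500, 5000, size=n_genes), index=genes, name="length_bp"
    )

    sample_ids, tissues, subtypes = [], [], []
    for prefix, n, tissue, sub in (
        ("TA", n_tumor_A, "tumor", "A"),
        ("TB", n_tumor_B, "tumor", "B"),
        ("N", n_normal, "normal", "none"),
    ):
        for i in range(n):
            sample_ids.append(f"{prefix}{i:03d}")
            tissues.append(tissue)
            subtypes.append(sub)
    n_samples = len(sample_ids)

    purity = np.zeros(n_samples)
    fractions = np.zeros((n_samples, len(POPULATIONS) - 1))
    for i, (tissue, sub) in enumerate(zip(tissues, subtypes)):
        if tissue == "tumor":
            a, b = purity_params[sub]
            purity[i] = rng.beta(a, b)
            alphas = infiltration_params["tumor"]
        else:
            purity[i] = 0.0
            alphas = infiltration_params["normal"]
        fractions[i] = (1.0 - purity[i]) * rng.dirichlet(alphas)

    # Plant subtype A/B differential expression in the malignant profile.
    malignant_markers = panel.markers["malignant"]
    de_pool = malignant_markers + [
        g for g in genes if g not in set().union(*panel.markers.values())
    ]
    if n_de_genes > len(de_pool):
        raise ValueError("n_de_genes exceeds available malignant-profile genes")
    de_genes = de_pool[:n_de_genes]
    loc = genes.get_indexer(de_genes)
    profiles = panel.profiles.to_numpy()  # genes x pops
    malignant = profiles[:, 0]
    # Plant the subtype contrast symmetrically: up genes get 2^(+lfc/2)
    # in B and 2^(-lfc/2) in A (down genes the reverse), alternating
    # up/down along decreasing malignant expression, and each subtype's
    # planted genes are rescaled to exactly baseline total mass. The
    # planted log2 contrast stays ~de_lfc while neither subtype's
    # library composition moves (no FPKM side effect on other genes).
    shift_a = np.ones(n_genes)
    shift_b = np.ones(n_genes)
    if n_de_genes > 0 and de_lfc != 0:
        order = loc[np.argsort(-malignant[loc], kind="stable")]
        up, down = order[0::2], order[1::2]
        half = 2.0 ** (de_lfc / 2.0)
        shift_b[up] = half
        shift_b[down] = 1.0 / half
        shift_a[up] = 1.0 / half
        shift_a[down] = half
        de_mass = float(malignant[loc].sum())
        for s in (shift_a, shift_b):
            planted = float((malignant[loc] * s[loc]).sum())
            if planted > 0:
                s[loc] *= de_mass / planted
    others = profiles[:, 1:]
    lib_sizes = rng.lognormal(np.log(mean_lib_size), 0.2, size=n_samples)

    expected = np.empty((n_genes, n_samples))
    for i in range(n_samples):
        malig = malignant * (shift_b if subtypes[i] == "B" else shift_a)
        expected[:, i] = purity[i] * malig + others @ fractions[i]

    rate = expected * lengths.to_numpy()[:, None]
    mu = rate / rate.sum(axis=0, keepdims=True) * lib_sizes[None, :]
    # NB(mu, dispersion): shape r = 1/dispersion, p = r / (r + mu).
    r = 1.0 / nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    # Survival: exponential, independent of subtype at hazard_ratio 1.
    hazard = np.where(
        [s == "B" for s in subtypes], hazard_ratio / survival_scale, 1.0 / survival_scale
    )
    latent = rng.exponential(1.0 / hazard)
    time = np.minimum(latent, censor_horizon)
    event = (latent <= censor_horizon).astype(int)

    samples = pd.DataFrame(
        {
            "tissue": tissues,
            "subtype_true": subtypes,
            "purity_true": purity,
            "lib_size": lib_sizes,
            "time": time,
            "event": event,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    for j, pop in enumerate(POPULATIONS[1:]):
        samples[f"frac_{pop}"] = fractions[:, j]

    return SyntheticCohort(
        counts=ExpressionMatrix(counts_df, unit="counts"),
        gene_lengths=lengths,
        samples=samples,
        panel=panel,
        signatures=_signature_bundle(panel),
        seed=seed,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort as plain-text artifacts (TSV, GMT, JSON)."""
    from .io import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.counts.data.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene")
    cohort.gene_lengths.rename("length_bp").to_csv(
        outdir / "gene_lengths.tsv", sep="\t", index_label="gene"
    )
    cohort.samples.to_csv(outdir / "annotation.tsv", sep="\t")
    write_gmt(cohort.signatures, outdir / "signatures.gmt")
    cohort.panel.profiles.to_csv(outdir / "reference_profiles.tsv", sep="\t",
                                 index_label="gene")
    truth = {
        "seed": cohort.seed,
        "subtype_true": cohort.samples["subtype_true"].to_dict(),
        "purity_true": cohort.samples["purity_true"].round(10).to_dict(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
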