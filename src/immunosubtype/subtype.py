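"""Unsupervised immune subtyping.

Tumors and noncancer controls are embedded together by PCA on the most
variable genes and partitioned into three clusters (k-means, with an
agglomerative Ward cut as a concordance diagnostic). The cluster that
captures the majority of normals is "normal-like": its tumor members are
called immune-competent (Subtype B), because co-clustering with normal
tissue reflects heavy stromal/immune admixture. Of the two remaining
clusters, the one with the higher mean tumor immune score is also called
B; the other is the immune-deficient Subtype A. All normals are labeled
``noncancer``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .preprocess import _as_frame

__all__ = ["pca_embed", "cluster_k3", "assign_subtypes", "SubtypeCall", "ClusterResult"]


@dataclass
class ClusterResult:
    """k-means labels (primary), Ward labels and their agreement."""

    kmeans: pd.Series
    ward: pd.Series
    ari_kmeans_ward: float


@dataclass
class SubtypeCall:
    """Per-sample subtype assignment with clustering context."""

    assignments: pd.DataFrame  # columns: cluster, subtype (+ PC coords if given)
    normal_fraction: pd.Series  # per cluster
    variance_explained: np.ndarray | None = None
    no_normal_fallback: bool = False

    @property
    def subtype(self) -> pd.Series:
        return self.assignments["subtype"]

    @property
    def cluster(self) -> pd.Series:
        return self.assignments["cluster"]


def pca_embed(matrix, genes, n_components: int = 3):
    """Centered PCA of samples on the given genes.

    Returns ``(coordinates, variance_explained)`` where coordinates is a
    samples x PC DataFrame. The sign of each component is fixed so its
    largest-magnitude gene loading is positive, making the embedding
    deterministic.
    """
    frame = _as_frame(matrix)
    sub = frame.loc[list(genes)]
    X = sub.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < n_components:
        raise ValueError(
            f"{X.shape[0]} samples cannot support {n_components} components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(n_components):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return (
        pd.DataFrame(coords, index=sub.columns, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


def cluster_k3(coordinates: pd.DataFrame, seed: int = 0, n_restarts: int = 50) -> ClusterResult:
    """Three-way partition of the PC embedding.

    k-means (best inertia over ``n_restarts`` seeded initializations) is
    the primary partition; a Ward agglomerative 3-cut is computed
    alongside and the adjusted Rand index between the two is reported as
    a stability diagnostic. Cluster ids are 1..3, relabeled in order of
    first appearance so they are stable under relabeling of the
    underlying fit.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    X = coordinates.to_numpy(dtype=float)
    if np.unique(X, axis=0).shape[0] < 3:
        raise ValueError("need at least 3 distinct points to form 3 clusters")
    km = KMeans(n_clusters=3, n_init=n_restarts, random_state=seed).fit(X)
    ward = AgglomerativeClustering(n_clusters=3, linkage="ward").fit(X)

    def _canonical(labels: np.ndarray) -> np.ndarray:
        mapping: dict[int, int] = {}
        out = np.empty_like(labels)
        for i, lab in enumerate(labels):
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            out[i] = mapping[lab]
        return out

    km_labels = pd.Series(_canonical(km.labels_), index=coordinates.index, name="cluster")
    ward_labels = pd.Series(
        _canonical(ward.labels_), index=coordinates.index, name="cluster_ward"
    )
    ari = float(adjusted_rand_score(km_labels, ward_labels))
    return ClusterResult(kmeans=km_labels, ward=ward_labels, ari_kmeans_ward=ari)


def assign_subtypes(
    clusters: pd.Series,
    tissue: pd.Series,
    immune_score: pd.Series,
    coordinates: pd.DataFrame | None = None,
    variance_explained: np.ndarray | None = None,
) -> SubtypeCall:
    """Label tumors immune-deficient (A) / immune-competent (B).

    Rule: (i) the cluster holding the largest fraction of normal samples
    is normal-like; its tumors are Subtype B; (ii) of the remaining two
    clusters the one with higher mean tumor immune score is B, the other
    A; ties on normal fraction break toward the higher-immune cluster.
    Normals are always ``noncancer``. Without any normal samples the
    rule falls back to ranking all three clusters by mean tumor immune
    score (highest B, lowest A, middle joins the nearer mean) and flags
    the result.
    """
    clusters = pd.Series(clusters)
    tissue = pd.Series(tissue).reindex(clusters.index)
    immune_score = pd.Series(immune_score).reindex(clusters.index)
    if tissue.isna().any():
        raise ValueError("tissue labels missing for some samples")
    cluster_ids = sorted(clusters.unique())
    if len(cluster_ids) != 3:
        raise ValueError(f"expected exactly 3 clusters, found {len(cluster_ids)}")
    is_tumor = tissue == "tumor"
    if immune_score[is_tumor].isna().any():
        raise ValueError("immune scores missing for some tumor samples")

    n_normal_total = int((tissue == "normal").sum())
    normal_fraction = pd.Series(
        {
            c: (float(((clusters == c) & (tissue == "normal")).sum()) / n_normal_total
                if n_normal_total else 0.0)
            for c in cluster_ids
        },
        name="normal_fraction",
    )
    mean_immune = pd.Series(
        {
            c: float(immune_score[(clusters == c) & is_tumor].mean())
            if ((clusters == c) & is_tumor).any()
            else -np.inf
            for c in cluster_ids
        }
    )

    subtype_of_cluster: dict[int, str] = {}
    fallback = n_normal_total == 0
    if not fallback:
        # Ties on normal fraction break toward the higher-immune cluster.
        best = max(cluster_ids, key=lambda c: (normal_fraction[c], mean_immune[c]))
        rest = [c for c in cluster_ids if c != best]
        hi, lo = sorted(rest, key=lambda c: mean_immune[c], reverse=True)
        subtype_of_cluster = {best: "B", hi: "B", lo: "A"}
    else:
        warnings.warn(
            "no normal samples: assigning subtypes by immune-score ranking only",
            stacklevel=2,
        )
        ranked = sorted(cluster_ids, key=lambda c: mean_immune[c], reverse=True)
        hi, mid, lo = ranked
        mid_label = "B" if abs(mean_immune[mid] - mean_immune[hi]) <= abs(
            mean_immune[mid] - mean_immune[lo]
        ) else "A"
        subtype_of_cluster = {hi: "B", mid: mid_label, lo: "A"}

    subtype = pd.Series(
        np.where(
            is_tumor, clusters.map(subtype_of_cluster), "noncancer"
        ),
        index=clusters.index,
        name="subtype",
    )
    assignments = pd.DataFrame({"cluster": clusters, "subtype": subtype})
    if coordinates is not None:
        assignments = assignments.join(coordinates)
    return SubtypeCall(
        assignments=assignments,
        normal_fraction=normal_fraction,
        variance_explained=variance_explained,
        no_normal_fallback=fallback,
    )
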