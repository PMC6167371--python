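import numpy as np
import pandas as pd
import pytest

from immunosubtype.subtype import assign_subtypes, cluster_k3, pca_embed


def _blob_frame(seed=0, n_per=20, n_genes=100, shift=6.0):
    """Two well-separated Gaussian blobs, genes x samples."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_genes, n_per))
    b = rng.normal(shift, 1, size=(n_genes, n_per))
    frame = pd.DataFrame(
        np.hstack([a, b]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(2 * n_per)],
    )
    return frame


class TestPcaEmbed:
    def test_duplicated_samples_identical_embedding(self):
        frame = _blob_frame(seed=1)
        dup = pd.concat(
            [frame, frame.add_suffix("_dup", axis=1)], axis=1
        )
        coords, _ = pca_embed(dup, dup.index)
        for s in frame.columns:
            assert np.allclose(coords.loc[s], coords.loc[s + "_dup"])

    def test_blobs_separated_on_pc1(self):
        frame = _blob_frame(seed=2)
        coords, varexp = pca_embed(frame, frame.index)
        pc1 = coords["PC1"]
        group = np.array([0] * 20 + [1] * 20)
        between = abs(pc1[group == 0].mean() - pc1[group == 1].mean())
        within = max(pc1[group == 0].std(), pc1[group == 1].std())
        assert between > 5 * within
        assert varexp[0] > varexp[1] > varexp[2]

    def test_variance_explained_properties(self):
        frame = _blob_frame(seed=3)
        _, varexp = pca_embed(frame, frame.index)
        assert (np.diff(varexp) <= 1e-12).all()
        assert varexp.sum() <= 1.0 + 1e-12

    def test_sign_convention_deterministic(self):
        frame = _blob_frame(seed=4)
        c1, _ = pca_embed(frame, frame.index)
        c2, _ = pca_embed(frame * 1.0, frame.index)
        pd.testing.assert_frame_equal(c1, c2)

    def test_too_few_samples_error(self):
        frame = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]})
        with pytest.raises(ValueError, match="samples"):
            pca_embed(frame, frame.index, n_components=3)


def _three_mass_coords():
    pts = np.array([[0.0, 0, 0]] * 5 + [[10.0, 0, 0]] * 5 + [[0.0, 10, 0]] * 5)
    return pd.DataFrame(pts, columns=["PC1", "PC2", "PC3"],
                        index=[f"s{i}" for i in range(15)])


class TestClusterK3:
    def test_three_point_masses_each_own_cluster(self):
        coords = _three_mass_coords()
        res = cluster_k3(coords, seed=0)
        labels = res.kmeans.to_numpy()
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:10])) == 1
        assert len(set(labels[10:])) == 1
        assert len(set(labels)) == 3
        assert res.ari_kmeans_ward == pytest.approx(1.0)

    def test_same_seed_identical_labels(self):
        rng = np.random.default_rng(5)
        coords = pd.DataFrame(rng.normal(size=(30, 3)),
                              columns=["PC1", "PC2", "PC3"])
        r1 = cluster_k3(coords, seed=9)
        r2 = cluster_k3(coords, seed=9)
        pd.testing.assert_series_equal(r1.kmeans, r2.kmeans)

    def test_too_few_distinct_points_error(self):
        coords = pd.DataFrame([[0.0, 0, 0]] * 10,
                              columns=["PC1", "PC2", "PC3"])
        with pytest.raises(ValueError, match="distinct"):
            cluster_k3(coords)

    def test_kmeans_ward_agreement_on_cohort(self, fitted):
        assert fitted.clustering.ari_kmeans_ward >= 0.8


def _toy_assignment(clusters, tissues, immune):
    idx = [f"s{i}" for i in range(len(clusters))]
    return assign_subtypes(
        pd.Series(clusters, index=idx),
        pd.Series(tissues, index=idx),
        pd.Series(immune, index=idx),
    )


class TestAssignSubtypes:
    def test_normal_majority_cluster_tumors_are_b(self):
        call = _toy_assignment(
            clusters=[1, 1, 1, 2, 2, 3, 3],
            tissues=["normal", "normal", "tumor", "tumor", "tumor", "tumor", "tumor"],
            immune=[np.nan, np.nan, 1.0, 5.0, 5.0, 0.0, 0.0],
        )
        sub = call.subtype
        assert sub["s0"] == sub["s1"] == "noncancer"
        assert sub["s2"] == "B"  # tumor inside the normal-like cluster
        assert sub["s3"] == sub["s4"] == "B"  # higher-immune remaining cluster
        assert sub["s5"] == sub["s6"] == "A"

    def test_tie_on_normal_fraction_breaks_to_higher_immune(self):
        call = _toy_assignment(
            clusters=[1, 2, 1, 2, 3, 3],
            tissues=["normal", "normal", "tumor", "tumor", "tumor", "tumor"],
            immune=[np.nan, np.nan, 9.0, 1.0, 5.0, 5.0],
        )
        # clusters 1 and 2 tie at 50% of normals; cluster 1 has the higher
        # tumor immune score and becomes normal-like (B).
        assert call.subtype["s2"] == "B"
        assert call.subtype["s4"] == "B"  # higher immune of the remaining two
        assert call.subtype["s3"] == "A"

    def test_no_normals_fallback_warns_and_flags(self):
        with pytest.warns(UserWarning, match="no normal samples"):
            call = _toy_assignment(
                clusters=[1, 1, 2, 2, 3, 3],
                tissues=["tumor"] * 6,
                immune=[10.0, 10.0, 5.9, 5.9, 1.0, 1.0],
            )
        assert call.no_normal_fallback
        sub = call.subtype
        assert (sub[["s0", "s1"]] == "B").all()
        assert (sub[["s4", "s5"]] == "A").all()
        # middle cluster joins the nearer mean (closer to the top here)
        assert (sub[["s2", "s3"]] == "B").all()

    def test_degenerate_forced_split_executes(self):
        # all tumors identical to normals: k=3 still forces a split; the
        # rule runs and labels everything without error.
        call = _toy_assignment(
            clusters=[1, 2, 3, 1, 2, 3],
            tissues=["normal", "normal", "normal", "tumor", "tumor", "tumor"],
            immune=[np.nan, np.nan, np.nan, 2.0, 2.0, 2.0],
        )
        assert set(call.subtype.unique()) <= {"A", "B", "noncancer"}
        assert (call.subtype[["s0", "s1", "s2"]] == "noncancer").all()

    def test_permutation_invariance(self):
        clusters = [1, 1, 2, 2, 3, 3, 1]
        tissues = ["normal", "normal", "tumor", "tumor", "tumor", "tumor", "tumor"]
        immune = [np.nan, np.nan, 3.0, 3.0, 8.0, 8.0, 1.0]
        base = _toy_assignment(clusters, tissues, immune).subtype
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(clusters))
        permuted = _toy_assignment(
            [clusters[i] for i in perm],
            [tissues[i] for i in perm],
            [immune[i] for i in perm],
        ).subtype
        for new_pos, old_pos in enumerate(perm):
            assert permuted[f"s{new_pos}"] == base[f"s{old_pos}"]

    def test_requires_three_clusters(self):
        with pytest.raises(ValueError, match="3 clusters"):
            _toy_assignment([1, 1, 2, 2], ["tumor"] * 4, [1.0] * 4)

    def test_cohort_invariants(self, cohort, fitted):
        sub = fitted.subtype
        tissue = cohort.samples["tissue"]
        assert (sub[tissue == "normal"] == "noncancer").all()
        assert sub[tissue == "tumor"].isin(["A", "B"]).all()

    def test_called_a_purer_than_called_b(self, cohort, fitted):
        from sklearn.metrics import adjusted_rand_score

        tumors = list(cohort.tumor_ids)
        called = fitted.subtype.loc[tumors]
        truth = cohort.samples.loc[tumors, "subtype_true"]
        if adjusted_rand_score(truth, called) >= 0.5:
            purity = cohort.samples.loc[tumors, "purity_true"]
            assert purity[called == "A"].mean() > purity[called == "B"].mean()
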