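import numpy as np
import pandas as pd
import pytest

from immunosubtype.preprocess import (
    ExpressionMatrix,
    counts_to_fpkm,
    log2_median_center,
    select_variable_genes,
    size_factors,
    vst,
)


def brute_force_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Independent gene-by-gene median-of-ratios computation."""
    ratios_per_sample = {s: [] for s in counts.columns}
    for g in counts.index:
        row = counts.loc[g].to_numpy(dtype=float)
        if (row > 0).all():
            geomean = np.exp(np.mean(np.log(row)))
            for s, v in zip(counts.columns, row):
                ratios_per_sample[s].append(v / geomean)
    return np.array([np.median(ratios_per_sample[s]) for s in counts.columns])


class TestExpressionMatrix:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionMatrix(pd.DataFrame({"s1": [-1], "s2": [2]}), unit="counts")

    def test_rejects_duplicate_ids(self):
        frame = pd.DataFrame([[1, 2], [3, 4]], index=["g", "g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="gene ids"):
            ExpressionMatrix(frame, unit="counts")

    def test_rejects_unknown_unit(self):
        with pytest.raises(ValueError, match="unit"):
            ExpressionMatrix(pd.DataFrame({"s": [1.0]}), unit="tpm")


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 10, 3], "s2": [5, 10, 3]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_proportional_one_two(self):
        counts = pd.DataFrame({"s1": [5, 10, 3], "s2": [10, 20, 6]})
        f = size_factors(counts).to_numpy()
        assert np.allclose(f / f[0], [1.0, 2.0])

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, size=(5, 3)) + 1,
            index=[f"g{i}" for i in range(5)],
            columns=["a", "b", "c"],
        )
        assert np.allclose(
            size_factors(counts), brute_force_size_factors(counts), atol=1e-12
        )

    def test_error_when_no_gene_covers_all_samples(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="nonzero count in every sample"):
            size_factors(counts)


class TestVst:
    def test_analytic_values(self):
        counts = pd.DataFrame({"s1": [0, 7], "s2": [0, 7]})
        out = vst(counts, pd.Series([1.0, 1.0], index=["s1", "s2"]))
        assert out.unit == "vst"
        assert out.data.iloc[0, 0] == 0.0
        assert out.data.iloc[1, 0] == pytest.approx(3.0)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            vst(pd.DataFrame({"s1": [-1.0], "s2": [1.0]}),
                pd.Series([1.0, 1.0], index=["s1", "s2"]))

    def test_monotone_in_counts(self):
        counts = pd.DataFrame({"s1": [1, 5, 20, 100]}, dtype=float)
        counts["s2"] = counts["s1"]
        out = vst(counts, pd.Series([1.0, 1.0], index=["s1", "s2"])).data["s1"]
        assert (np.diff(out) > 0).all()

    def test_variance_stabilization_on_nb_gene(self):
        # A constant-expression NB gene: the transform shrinks the
        # mean-scaled spread relative to raw counts.
        rng = np.random.default_rng(42)
        mu, disp = 200.0, 0.2
        r = 1.0 / disp
        counts = rng.negative_binomial(r, r / (r + mu), size=200).astype(float)
        frame = pd.DataFrame(
            {f"s{i}": [c] for i, c in enumerate(counts)}, index=["g"]
        )
        sf = pd.Series(1.0, index=frame.columns)
        transformed = vst(frame, sf).data.loc["g"]
        cv_raw = counts.std() / counts.mean()
        cv_vst = transformed.std() / transformed.mean()
        assert cv_vst < cv_raw


class TestFpkm:
    def test_analytic_value(self):
        counts = pd.DataFrame({"s1": [10, 999990]}, index=["g1", "g2"])
        lengths = pd.Series([1000.0, 1000.0], index=["g1", "g2"])
        out = counts_to_fpkm(counts, lengths)
        assert out.unit == "fpkm"
        assert out.data.loc["g1", "s1"] == pytest.approx(10.0)

    def test_doubling_library_at_fixed_count_halves_fpkm(self):
        # g1 keeps 10 counts while the filler gene doubles the library.
        counts = pd.DataFrame({"s1": [10, 990], "s2": [10, 1990]},
                              index=["g1", "g2"])
        lengths = pd.Series([500.0, 2000.0], index=["g1", "g2"])
        out = counts_to_fpkm(counts, lengths).data
        assert out.loc["g1", "s2"] == pytest.approx(out.loc["g1", "s1"] / 2)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"s1": [0, 10]}, index=["g1", "g2"])
        lengths = pd.Series([1000.0, 1000.0], index=["g1", "g2"])
        assert counts_to_fpkm(counts, lengths).data.loc["g1", "s1"] == 0.0

    def test_zero_library_error(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        lengths = pd.Series([1000.0, 1000.0], index=["g1", "g2"])
        with pytest.raises(ValueError, match="library"):
            counts_to_fpkm(counts, lengths)

    def test_sample_sum_conservation(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.poisson(30, size=(50, 4)), index=[f"g{i}" for i in range(50)]
        )
        lengths = pd.Series(
            rng.uniform(500, 5000, 50), index=counts.index
        )
        fpkm = counts_to_fpkm(counts, lengths).data
        lib = counts.sum(axis=0)
        expected = 1e9 * (counts.div(lengths, axis=0).sum(axis=0)) / lib
        assert np.allclose(fpkm.sum(axis=0), expected)


class TestLog2MedianCenter:
    def test_constant_gene_all_zero(self):
        frame = pd.DataFrame({"s1": [5.0], "s2": [5.0], "s3": [5.0]})
        assert (log2_median_center(frame).data == 0).all().all()

    def test_analytic_example(self):
        frame = pd.DataFrame({"s1": [1.0], "s2": [3.0], "s3": [7.0]})
        out = log2_median_center(frame, pseudocount=1.0).data
        assert np.allclose(out.to_numpy().ravel(), [-1.0, 0.0, 1.0])

    def test_row_medians_zero(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.gamma(2, 10, size=(20, 7)))
        out = log2_median_center(frame).data
        assert np.allclose(out.median(axis=1), 0.0, atol=1e-12)

    def test_rejects_nonpositive_pseudocount(self):
        with pytest.raises(ValueError):
            log2_median_center(pd.DataFrame({"s": [1.0]}), pseudocount=0.0)


class TestSelectVariableGenes:
    def test_full_selection_returns_all(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.normal(size=(10, 5)),
                             index=[f"g{i}" for i in range(10)])
        assert set(select_variable_genes(frame, 10)) == set(frame.index)

    def test_planted_high_variance_recovered(self):
        rng = np.random.default_rng(3)
        n = 1000
        frame = pd.DataFrame(
            np.zeros((n, 8)), index=[f"g{i:04d}" for i in range(n)]
        )
        planted = [f"g{i:04d}" for i in range(0, 1000, 100)]
        frame.loc[planted] = rng.normal(0, 5, size=(10, 8))
        assert set(select_variable_genes(frame, 10)) == set(planted)

    def test_tie_broken_lexicographically(self):
        frame = pd.DataFrame(
            {"s1": [0.0, 0.0, 1.0], "s2": [2.0, 2.0, 1.0]},
            index=["gB", "gA", "gC"],
        )
        assert select_variable_genes(frame, 1) == ["gA"]

    def test_error_when_n_exceeds_genes(self):
        frame = pd.DataFrame({"s1": [1.0], "s2": [2.0]})
        with pytest.raises(ValueError):
            select_variable_genes(frame, 5)
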