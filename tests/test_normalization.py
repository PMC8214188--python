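import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dgerobust.normalization import (cpm, normalized_counts, quantile_normalize,
                                     quantile_scale_factors, rle_size_factors,
                                     sample_quantiles, tmm_factors)


class TestCPM:
    def test_definition_at_known_depths(self):
        df = pd.DataFrame({"a": [5, 999_995], "b": [50, 499_950]})
        out = cpm(df)
        assert out.loc[0, "a"] == pytest.approx(5.0)
        assert out.loc[0, "b"] == pytest.approx(100.0)  # 50 / 5e5 * 1e6

    def test_identical_columns_stay_identical(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]})
        out = cpm(df)
        assert np.allclose(out["a"], out["b"])

    def test_zero_depth_sample_rejected(self):
        with pytest.raises(ValueError):
            cpm(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))

    def test_log_cpm_finite_and_monotone(self):
        df = pd.DataFrame({"a": [0, 5, 50, 500], "b": [1, 4, 40, 400]})
        out = cpm(df, log=True, prior_count=0.5)
        assert np.isfinite(out.to_numpy()).all()
        assert out["a"].is_monotonic_increasing


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30, 40], "b": [10, 20, 30, 40]})
        assert np.allclose(tmm_factors(df), 1.0)

    def test_depth_doubling_gives_unit_factors(self):
        # all M-values are 0 after depth scaling, so the trimmed mean is 0
        a = np.array([10, 20, 30, 40, 55])
        df = pd.DataFrame({"a": a, "b": 2 * a})
        assert np.allclose(tmm_factors(df), 1.0, atol=1e-12)

    def test_inflated_sample_corrected_for_composition(self):
        # a handful of 10x-inflated genes consume sequencing real estate, so
        # after depth scaling the majority genes look down in that sample;
        # TMM trims the outliers and scales the library *down* (factor < 1)
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=400)
        inflated = base.copy()
        inflated[: int(0.05 * 400)] *= 10
        df = pd.DataFrame({"a": base, "b": base, "c": base, "d": inflated})
        factors = tmm_factors(df)
        assert factors["d"] < 1.0
        assert factors["a"] == pytest.approx(factors["b"])
        assert np.isclose(np.exp(np.mean(np.log(factors))), 1.0, atol=1e-12)

    def test_disjoint_support_rejected(self):
        df = pd.DataFrame({"a": [5, 5, 0, 0], "b": [5, 5, 0, 0], "c": [0, 0, 7, 7]})
        with pytest.raises(ValueError):
            tmm_factors(df, ref_sample="a")


class TestRLE:
    def test_hand_computed_example(self):
        df = pd.DataFrame({"s1": [2, 4, 8], "s2": [4, 8, 16]})
        factors = rle_size_factors(df)
        assert factors["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        assert factors["s2"] == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_identical_samples_and_single_sample(self):
        df = pd.DataFrame({"a": [3, 6, 9], "b": [3, 6, 9]})
        assert np.allclose(rle_size_factors(df), 1.0)
        assert np.allclose(rle_size_factors(df[["a"]]), 1.0)

    def test_no_universally_expressed_gene_rejected(self):
        df = pd.DataFrame({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(ValueError):
            rle_size_factors(df)


class TestQuantileFactors:
    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"a": [1, 5, 9], "b": [1, 5, 9]})
        assert np.allclose(quantile_scale_factors(df, q=0.75), 1.0)

    def test_type7_upper_quartile(self):
        # (n-1) * q = 3 exactly -> the 4th order statistic, no interpolation
        df = pd.DataFrame({"a": [1, 2, 3, 4, 100]})
        q = sample_quantiles(df, 0.75) * df["a"].sum()
        assert q["a"] == pytest.approx(4.0)

    def test_depth_scaling_cancels(self):
        a = np.array([3, 8, 15, 40, 7])
        df = pd.DataFrame({"a": a, "b": 3 * a})
        factors = quantile_scale_factors(df, q=0.75)
        assert factors["a"] == pytest.approx(factors["b"], abs=1e-12)

    def test_geometric_mean_exactly_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.poisson(50, size=(100, 6)), columns=list("abcdef"))
        for q in (0.5, 0.75):
            factors = quantile_scale_factors(df, q=q)
            assert abs(np.mean(np.log(factors))) < 1e-12

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            quantile_scale_factors(df)


class TestQuantileNormalize:
    def test_two_column_example(self):
        out = quantile_normalize(pd.DataFrame({"a": [1, 2, 3], "b": [4, 5, 6]}))
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        assert np.allclose(quantile_normalize(df), df)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rank_order_preserved_and_columns_share_sorted_values(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(30, 4)))
        out = quantile_normalize(df).to_numpy()
        src = df.to_numpy()
        for j in range(4):
            order = np.argsort(src[:, j])
            assert (np.diff(out[order, j]) >= -1e-12).all()
        sorted_cols = np.sort(out, axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])

    def test_ties_get_common_value(self):
        out = quantile_normalize(pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]}))
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame())


@pytest.mark.parametrize("method", ["tmm", "rle", "upper_quartile", "median"])
def test_factors_invariant_to_global_library_rescaling(method):
    rng = np.random.default_rng(9)
    df = pd.DataFrame(rng.poisson(60, size=(200, 4)) + 1, columns=list("abcd"))
    fn = {
        "tmm": tmm_factors,
        "rle": rle_size_factors,
        "upper_quartile": lambda d: quantile_scale_factors(d, 0.75),
        "median": lambda d: quantile_scale_factors(d, 0.5),
    }[method]
    f1 = fn(df)
    f2 = fn(df * 3)
    if method == "rle":
        # absolute size factors scale with depth but relative factors do not
        assert np.allclose(f2 / f2.iloc[0], f1 / f1.iloc[0])
    else:
        assert np.allclose(f1, f2)


def test_normalized_counts_equalize_depth():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.poisson(60, size=(300, 4)) + 1, columns=list("abcd"))
    df["b"] *= 4  # deep library
    for method in ("library_size", "tmm", "upper_quartile", "median"):
        norm = normalized_counts(df, method=method)
        sums = norm.sum(axis=0)
        assert sums.max() / sums.min() < 1.5  # depth difference largely removed
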