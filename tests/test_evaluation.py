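import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dgerobust import (bh_adjust, call_degs, concordance, expression_strata,
                       fold_filter, relative_fdr, run_engine)
from dgerobust.evaluation import DEGSet


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.04, 0.03, 0.002])
        assert np.allclose(out, [0.02, 0.04, 0.04, 0.008])

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_adjusted_dominates_raw_and_is_monotone(self, p):
        adj = bh_adjust(p)
        assert ((adj >= np.asarray(p) - 1e-12) & (adj <= 1 + 1e-12)).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def _pvalue_result(padj, gene_ids=None, lfc=None):
    class R:
        pass

    n = len(padj)
    r = R()
    r.engine = "stub"
    r.posterior_kind = None
    r.table = pd.DataFrame(
        {
            "gene_id": gene_ids or [f"g{i}" for i in range(n)],
            "base_mean": 1.0,
            "log2fc": lfc if lfc is not None else np.zeros(n),
            "p_value": padj,
            "posterior_de": np.nan,
            "p_adjusted": padj,
            "filtered": False,
        }
    )
    r.kept = lambda: r.table
    return r


def _posterior_result(post, kind="mixture"):
    r = _pvalue_result([np.nan] * len(post))
    r.posterior_kind = kind
    r.table["p_value"] = np.nan
    r.table["p_adjusted"] = np.nan
    r.table["posterior_de"] = post
    return r


class TestCallDegs:
    def test_adjusted_p_threshold(self):
        res = _pvalue_result([0.01, 0.2, 0.049])
        assert call_degs(res, alpha=0.05).gene_ids == {"g0", "g2"}

    def test_empty_result(self):
        assert call_degs(_pvalue_result([])).gene_ids == set()

    def test_soft_posterior_fdr_rule(self):
        # cumulative mean miss-probability: 0.01, 0.015, 0.143 -> first two kept
        res = _posterior_result([0.99, 0.98, 0.6])
        assert call_degs(res, alpha=0.05).gene_ids == {"g0", "g1"}

    def test_hard_posterior_cutoff_option(self):
        res = _posterior_result([0.99, 0.98, 0.6])
        assert call_degs(res, alpha=0.05, eb_mode="hard").gene_ids == {"g0", "g1"}

    def test_noise_posterior_threshold(self):
        res = _posterior_result([0.99, 0.90, 0.96], kind="noise")
        assert call_degs(res, noiseq_q=0.95).gene_ids == {"g0", "g2"}

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            call_degs(_pvalue_result([0.1]), alpha=1.5)


class TestFoldFilter:
    def test_threshold_application(self):
        res = _pvalue_result([0.01] * 3, gene_ids=["A", "B", "C"], lfc=[2.5, 1.0, -3.0])
        degs = DEGSet(engine="stub", gene_ids={"A", "B", "C"})
        out = fold_filter(degs, res, c=2.0)
        assert out.gene_ids == {"A", "C"} and out.regime == "two_fold"

    def test_zero_threshold_keeps_all_nonzero(self):
        res = _pvalue_result([0.01] * 3, gene_ids=["A", "B", "C"], lfc=[2.5, 1.0, -3.0])
        degs = DEGSet(engine="stub", gene_ids={"A", "B", "C"})
        assert fold_filter(degs, res, c=0.0).gene_ids == {"A", "B", "C"}

    def test_all_zero_log2fc_empties_set(self):
        res = _pvalue_result([0.01] * 2, gene_ids=["A", "B"], lfc=[0.0, 0.0])
        degs = DEGSet(engine="stub", gene_ids={"A", "B"})
        assert fold_filter(degs, res, c=0.0).gene_ids == set()

    def test_missing_gene_rejected(self):
        res = _pvalue_result([0.01], gene_ids=["A"])
        with pytest.raises(ValueError):
            fold_filter(DEGSet(engine="stub", gene_ids={"A", "Z"}), res)

    def test_two_fold_always_subset_of_no_fold(self, small_dataset):
        cm, _ = small_dataset
        res = run_engine("nb_wald", cm)
        no_fold = call_degs(res)
        two_fold = fold_filter(no_fold, res, c=2.0)
        assert two_fold.gene_ids <= no_fold.gene_ids


class TestRelativeFDR:
    def test_mixed_overlap(self):
        full = DEGSet(engine="e", gene_ids={"A", "B", "C", "D"})
        sub = DEGSet(engine="e", gene_ids={"A", "B", "E"}, f=0.5, r=1)
        rec = relative_fdr(sub, full)
        assert (rec.tp, rec.fp, rec.md) == (2, 1, 2)
        assert rec.rel_fdr == pytest.approx(1 / 3)
        assert rec.mdr == pytest.approx(1.0)
        assert rec.pc == pytest.approx(150.0)

    def test_identical_sets_score_zero(self):
        s = DEGSet(engine="e", gene_ids={"A", "B"})
        rec = relative_fdr(s, s)
        assert rec.rel_fdr == 0.0 and rec.pc == 0.0 and rec.mdr == 0.0

    def test_disjoint_sets_score_one(self):
        full = DEGSet(engine="e", gene_ids={"A"})
        sub = DEGSet(engine="e", gene_ids={"B"})
        assert relative_fdr(sub, full).rel_fdr == 1.0

    def test_empty_reference_flagged_undefined(self):
        full = DEGSet(engine="e", gene_ids=set())
        sub = DEGSet(engine="e", gene_ids={"B"})
        rec = relative_fdr(sub, full)
        assert rec.undefined and rec.rel_fdr == 1.0

    def test_engine_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relative_fdr(DEGSet(engine="a", gene_ids=set()),
                         DEGSet(engine="b", gene_ids=set()))


class TestExpressionStrata:
    def test_median_split_of_four_genes(self):
        df = pd.DataFrame({"c1": [1, 5, 10, 20]}, index=["g1", "g2", "g3", "g4"])
        high, low = expression_strata(df)
        assert low == {"g1", "g2"} and high == {"g3", "g4"}

    def test_ties_assigned_to_low(self):
        df = pd.DataFrame({"c1": [7, 7, 7]}, index=["g1", "g2", "g3"])
        high, low = expression_strata(df)
        assert high == set() and low == {"g1", "g2", "g3"}

    def test_single_gene_goes_low(self):
        df = pd.DataFrame({"c1": [5]}, index=["g1"])
        high, low = expression_strata(df)
        assert low == {"g1"} and high == set()

    def test_partition_is_exact(self, small_dataset):
        cm, _ = small_dataset
        high, low = expression_strata(cm)
        assert high | low == set(cm.gene_ids) and not (high & low)


class TestConcordance:
    def test_three_set_lattice(self):
        rep = concordance({"x": {"A", "B", "C"}, "y": {"B", "C", "D"}, "z": {"C", "E"}})
        assert rep.region("x", "y", "z") == 1  # {C}
        assert rep.uniques == {"x": 1, "y": 1, "z": 1}
        assert rep.union_size == 5

    def test_identical_sets_concentrate_in_full_region(self):
        rep = concordance({"x": {"A", "B"}, "y": {"A", "B"}})
        assert rep.region("x", "y") == 2
        assert rep.uniques == {"x": 0, "y": 0}

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_region_counts_sum_to_union(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(40)]
        sets = {
            name: set(rng.choice(universe, size=rng.integers(0, 30), replace=False))
            for name in ("a", "b", "c", "d")
        }
        rep = concordance(sets)
        assert rep.union_size == len(set().union(*sets.values()))

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            concordance({"only": {"A"}})
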