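import numpy as np
import pandas as pd
import pytest

from dgerobust import (ENGINES, CountMatrix, EngineParams, SimulationConfig,
                       call_degs, generate_dataset, load_external_results,
                       run_engine)
from dgerobust.normalization import normalized_counts

from conftest import mannwhitney_auc

ALL = sorted(ENGINES)


def _score(result):
    t = result.table
    if result.posterior_kind is None:
        return -t["p_value"].fillna(1.0).to_numpy()
    return t["posterior_de"].fillna(0.0).to_numpy()


# ---------------------------------------------------------------------------
# structural contracts


@pytest.mark.parametrize("name", ALL)
def test_result_table_contract(small_dataset, name):
    cm, _ = small_dataset
    res = run_engine(name, cm)
    t = res.table
    assert list(t["gene_id"]) == cm.gene_ids
    has_p = t["p_value"].notna().any()
    has_post = t["posterior_de"].notna().any()
    assert has_p != has_post  # exactly one statistic family per engine
    filtered = t.loc[t["filtered"]]
    assert filtered["p_value"].isna().all() and filtered["posterior_de"].isna().all()


@pytest.mark.parametrize("name", ALL)
def test_identical_groups_show_no_signal(constant_matrix, name):
    res = run_engine(name, constant_matrix)
    kept = res.kept()
    assert np.allclose(kept["log2fc"], 0.0)
    if res.posterior_kind is None:
        assert np.allclose(kept["p_value"], 1.0, atol=1e-6)
    elif res.posterior_kind == "noise":
        assert np.allclose(kept["posterior_de"], 0.0)
    else:
        assert kept["posterior_de"].mean() < 0.1


@pytest.mark.parametrize("name", ALL)
def test_invariant_to_permutation_within_groups(small_dataset, name):
    cm, _ = small_dataset
    rng = np.random.default_rng(0)
    cols = []
    for level in cm.levels:
        group = cm.group_samples(level)
        cols.extend(rng.permutation(group))
    permuted = CountMatrix(cm.counts[cols], cm.condition[cols], levels=cm.levels)
    a = run_engine(name, cm).table
    b = run_engine(name, permuted).table
    for col in ("log2fc", "p_value", "posterior_de"):
        assert np.allclose(a[col].fillna(-1), b[col].fillna(-1), atol=1e-9)


@pytest.mark.parametrize("name", ALL)
def test_group_label_swap_negates_log2fc(small_dataset, name):
    cm, _ = small_dataset
    swapped = CountMatrix(cm.counts, cm.condition, levels=(cm.levels[1], cm.levels[0]))
    a = run_engine(name, cm).table
    b = run_engine(name, swapped).table
    kept = ~a["filtered"]
    assert np.allclose(a.loc[kept, "log2fc"], -b.loc[kept, "log2fc"], atol=1e-9)
    for col in ("p_value", "posterior_de"):
        assert np.allclose(a[col].fillna(-1), b[col].fillna(-1), atol=1e-9)


@pytest.mark.parametrize("name", ALL)
def test_single_sample_groups_rejected(name):
    counts = pd.DataFrame({"s0": [5, 8], "s1": [6, 9]}, index=["g0", "g1"])
    cond = pd.Series(["control", "case"], index=counts.columns)
    cm = CountMatrix(counts, cond, levels=("control", "case"))
    with pytest.raises(ValueError):
        run_engine(name, cm)


# ---------------------------------------------------------------------------
# detection power and calibration


@pytest.mark.parametrize("name", ["nb_exact", "nb_wald", "voom_lite"])
def test_roc_auc_above_090_on_standard_preset(name):
    cm, truth = generate_dataset(
        SimulationConfig(n_genes=800, n_samples_per_group=(20, 20), seed=21)
    )
    res = run_engine(name, cm)
    auc = mannwhitney_auc(truth.table["is_de"].to_numpy(), _score(res))
    assert auc > 0.90


def test_null_raw_pvalues_calibrated(null_dataset):
    cm, _ = null_dataset
    res = run_engine("nb_exact", cm)
    p = res.kept()["p_value"].to_numpy()
    assert 0.03 < (p < 0.05).mean() < 0.07


def test_null_true_fdr_controlled(null_dataset):
    """Under a no-effect simulation every engine's calls at its 0.05
    threshold are false; the engines should make (nearly) none."""
    cm, truth = null_dataset
    for name in ALL:
        degs = call_degs(run_engine(name, cm))
        fdr = len(degs.gene_ids) / max(len(degs.gene_ids), 1)  # all calls are FP
        assert len(degs.gene_ids) == 0 or fdr < 0.10, name


# ---------------------------------------------------------------------------
# noiseq_like against the brute-force noise-cloud oracle


def test_noiseq_posterior_matches_double_loop_oracle():
    cfg = SimulationConfig(n_genes=50, n_samples_per_group=(4, 4), seed=33)
    cm, _ = generate_dataset(cfg)
    params = EngineParams(low_count_filter=False)
    res = run_engine("noiseq_like", cm, params)

    norm = normalized_counts(cm.counts, "upper_quartile")
    pc = params.pseudocount
    g1 = cm.group_samples(cm.levels[0])
    g2 = cm.group_samples(cm.levels[1])
    m1 = norm[g1].mean(axis=1).to_numpy()
    m2 = norm[g2].mean(axis=1).to_numpy()
    m_sig = np.log2(m2 + pc) - np.log2(m1 + pc)
    d_sig = np.abs(m2 - m1)
    noise = []
    for group in (g1, g2):
        ids = sorted(group)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                xa, xb = norm[ids[i]].to_numpy(), norm[ids[j]].to_numpy()
                for g in range(cfg.n_genes):
                    noise.append(
                        (abs(np.log2(xa[g] + pc) - np.log2(xb[g] + pc)), abs(xa[g] - xb[g]))
                    )
    expected = np.empty(cfg.n_genes)
    for g in range(cfg.n_genes):
        wins = sum(1 for nm, nd in noise if nm < abs(m_sig[g]) and nd < d_sig[g])
        expected[g] = wins / len(noise)
    assert np.allclose(res.table["posterior_de"].to_numpy(), expected, atol=1e-12)


def test_noiseq_dominating_gene_scores_one():
    genes = [f"g{i}" for i in range(20)]
    rng = np.random.default_rng(6)
    counts = pd.DataFrame(rng.poisson(50, size=(20, 6)), index=genes,
                          columns=[f"s{j}" for j in range(6)])
    counts.iloc[0, 3:] = 100_000  # one gene vastly up in the case group
    cond = pd.Series(["control"] * 3 + ["case"] * 3, index=counts.columns)
    cm = CountMatrix(counts, cond, levels=("control", "case"))
    res = run_engine("noiseq_like", cm, EngineParams(low_count_filter=False))
    assert res.table["posterior_de"].iloc[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# eb_nb specifics


def test_eb_mixture_weight_recovery():
    cm, _ = generate_dataset(SimulationConfig(seed=5))  # de_fraction = 0.2
    res = run_engine("eb_nb", cm)
    assert res.info["converged"]
    assert 0.1 <= res.info["mixture_weight_de"] <= 0.3


def test_eb_posteriors_are_probabilities(small_dataset):
    cm, _ = small_dataset
    post = run_engine("eb_nb", cm).table["posterior_de"]
    assert ((post >= 0) & (post <= 1)).all()
    # EE and DE posteriors are complementary by construction of the mixture
    assert np.isfinite(post).all()


# ---------------------------------------------------------------------------
# external result adapter


def _write_external(tmp_path, frame):
    path = tmp_path / "external.tsv"
    frame.to_csv(path, sep="\t", index=False)
    return str(path)


def test_external_results_round_trip(tmp_path):
    frame = pd.DataFrame(
        {"gene_id": ["a", "b", "c"], "log2fc": [1.0, -2.0, 0.1],
         "p_value": [0.001, 0.5, 0.04], "extra_column": [1, 2, 3]}
    )
    res = load_external_results(_write_external(tmp_path, frame), "deseq2")
    assert res.engine == "deseq2" and len(res.table) == 3
    padj = res.table.sort_values("p_value")["p_adjusted"]
    assert padj.is_monotonic_increasing  # BH preserves the p-value order
    assert (padj >= res.table.sort_values("p_value")["p_value"]).all()


def test_external_results_without_statistics_rejected(tmp_path):
    frame = pd.DataFrame({"gene_id": ["a"], "log2fc": [1.0]})
    with pytest.raises(ValueError):
        load_external_results(_write_external(tmp_path, frame))


def test_external_results_with_bad_probability_rejected(tmp_path):
    frame = pd.DataFrame({"gene_id": ["a"], "log2fc": [1.0], "p_value": [1.7]})
    with pytest.raises(ValueError):
        load_external_results(_write_external(tmp_path, frame))
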