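import numpy as np
import pandas as pd
import pytest

from dgerobust import CountMatrix, SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset shared by fast tests: 300 genes, 8 vs 8."""
    cfg = SimulationConfig(n_genes=300, n_samples_per_group=(8, 8), seed=1)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """A no-effect dataset (de_fraction = 0) at the default study size."""
    cfg = SimulationConfig(de_fraction=0.0, seed=11)
    return generate_dataset(cfg)


@pytest.fixture
def constant_matrix():
    """Identical columns everywhere: both groups exchangeable by construction."""
    genes = [f"g{i}" for i in range(40)]
    col = np.arange(40) * 7 + 50
    counts = pd.DataFrame({f"s{j}": col for j in range(8)}, index=genes)
    condition = pd.Series(["control"] * 4 + ["case"] * 4, index=counts.columns)
    return CountMatrix(counts, condition, levels=("control", "case"))


def mannwhitney_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (probability a positive outranks a negative)."""
    from scipy.stats import rankdata

    labels = np.asarray(labels, dtype=bool)
    ranks = rankdata(scores)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
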