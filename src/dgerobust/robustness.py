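"""Leave-one-out slope populations and rank-based comparison of engines.

The depth-sensitivity of an engine on one dataset is summarised by the
slope of an ordinary least-squares line through (f, relative FDR) points
over the near-full-depth grid f in {0.8, 0.85, 0.9, 0.95, 0.99}.  A
*population* of slopes is obtained by repeating the analysis on datasets
each missing one randomly chosen sample (plus the unmodified original:
10 removals -> 11 slopes).  Engines are then compared across the
population with the Friedman rank test (blocks = datasets, treatments =
engines) followed by Conover and Nemenyi pairwise post-hocs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import CountMatrix

__all__ = [
    "SlopeRecord",
    "FriedmanResult",
    "PosthocMatrix",
    "make_population",
    "fit_fdr_slope",
    "friedman_test",
    "chi2_sf",
    "conover_posthoc",
    "nemenyi_posthoc",
]

#: near-full-depth grid used for the slope regressions
SLOPE_FRACTIONS: tuple[float, ...] = (0.8, 0.85, 0.9, 0.95, 0.99)


@dataclass
class SlopeRecord:
    engine: str
    dataset_id: str
    slope: float
    intercept: float
    points: list = field(default_factory=list)  # [(f, rel_fdr), ...]


@dataclass
class FriedmanResult:
    rank_matrix: pd.DataFrame  # blocks x treatments, within-block average ranks
    chi2: float
    df: int
    p_value: float
    tie_corrected: bool = True

    @property
    def mean_ranks(self) -> pd.Series:
        return self.rank_matrix.mean(axis=0)


@dataclass
class PosthocMatrix:
    method: str
    p_values: pd.DataFrame  # symmetric, NaN diagonal
    statistics: pd.DataFrame
    degenerate: bool = False  # Conover denominator vanished (identical rankings)

    def stars(self) -> pd.DataFrame:
        """Significance codes in the conventional banding:
        **** <0.001, *** <0.005, ** <0.01, * <0.05, NS otherwise."""
        def code(p):
            if np.isnan(p):
                return ""
            if p < 0.001:
                return "****"
            if p < 0.005:
                return "***"
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
            return "NS"
        return self.p_values.map(code)


def make_population(base: CountMatrix, reps: int = 10, seed: int = 0) -> list[tuple[str, CountMatrix]]:
    """The original dataset plus ``reps`` leave-one-out variants.

    Each variant removes one sample: the group is chosen uniformly at
    random (among groups still holding >= 3 samples, so the removal leaves
    >= 2), then the sample within it uniformly.  Returns (dataset_id,
    CountMatrix) pairs, the unmodified base first — reps = 10 gives the
    11-dataset population of the standard design.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 29]))
    n1, n2 = base.group_sizes()
    eligible = [lvl for lvl, n in zip(base.levels, (n1, n2)) if n >= 3]
    if reps > 0 and not eligible:
        raise ValueError("every group is too small to remove a sample from")
    out: list[tuple[str, CountMatrix]] = [("full", base)]
    for i in range(1, reps + 1):
        level = eligible[rng.integers(len(eligible))]
        candidates = base.group_samples(level)
        victim = candidates[rng.integers(len(candidates))]
        out.append((f"loo{i:02d}", base.drop_sample(victim)))
    return out


def fit_fdr_slope(points, engine: str = "", dataset_id: str = "") -> SlopeRecord:
    """OLS slope and intercept of relative FDR against the fraction f."""
    pts = [(float(f), float(v)) for f, v in points]
    fs = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    if len(np.unique(fs)) < 2:
        raise ValueError("need at least two distinct f values")
    slope, intercept = np.polyfit(fs, vals, 1)
    return SlopeRecord(engine=engine, dataset_id=dataset_id,
                       slope=float(slope), intercept=float(intercept), points=pts)


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution.

    Thin wrapper over the regularized upper incomplete gamma function
    Q(df/2, x/2); for df = 4 this reduces to exp(-x/2) * (1 + x/2).
    """
    if x < 0:
        raise ValueError("chi-squared statistic must be >= 0")
    return float(special.gammaincc(df / 2.0, x / 2.0))


def _rank_matrix(values: pd.DataFrame) -> pd.DataFrame:
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing cells are not supported")
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)  # average ranks for ties
    return pd.DataFrame(ranks, index=values.index, columns=values.columns)


def friedman_test(values) -> FriedmanResult:
    """Friedman omnibus test over a blocks x treatments matrix.

    Values are ranked within each block (ties get average ranks); the
    tie-corrected chi-squared statistic

        chi2 = (k - 1) * sum_j (R_j - n(k+1)/2)^2
               / (sum_ij R_ij^2 - n k (k+1)^2 / 4)

    reduces to the classic 12/(nk(k+1)) form when tie-free.  df = k - 1;
    the p-value is the chi-squared upper tail.
    """
    df_vals = pd.DataFrame(values)
    n, k = df_vals.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    ranks = _rank_matrix(df_vals)
    col_sums = ranks.sum(axis=0).to_numpy()
    num = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    den = float((ranks.to_numpy() ** 2).sum()) - n * k * (k + 1) ** 2 / 4.0
    chi2 = float(num / den) if den > 0 else 0.0
    dof = k - 1
    p = chi2_sf(chi2, dof) if den > 0 else 1.0
    return FriedmanResult(rank_matrix=ranks, chi2=chi2, df=dof, p_value=p)


def conover_posthoc(values) -> PosthocMatrix:
    """Conover all-pairs post-hoc after Friedman.

    t_ij = (R_i - R_j) / sqrt(2 n (A - B) / ((n-1)(k-1))) with A the sum of
    squared within-block ranks and B = (1/n) sum_j R_j^2; two-sided
    p-values from Student's t with (n-1)(k-1) df.  When all blocks rank the
    treatments identically A = B and the denominator vanishes; the result
    is flagged degenerate and unequal pairs get p = 0.
    """
    df_vals = pd.DataFrame(values)
    n, k = df_vals.shape
    ranks = _rank_matrix(df_vals)
    col_sums = ranks.sum(axis=0)
    a = float((ranks.to_numpy() ** 2).sum())
    b = float((col_sums ** 2).sum()) / n
    dof = (n - 1) * (k - 1)
    cols = list(df_vals.columns)
    tmat = pd.DataFrame(np.nan, index=cols, columns=cols)
    pmat = pd.DataFrame(np.nan, index=cols, columns=cols)
    degenerate = a - b <= 1e-12
    denom = np.sqrt(2.0 * n * max(a - b, 0.0) / dof) if not degenerate else 0.0
    for i, ci in enumerate(cols):
        for cj in cols[i + 1:]:
            diff = float(col_sums[ci] - col_sums[cj])
            if degenerate:
                t = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                t = diff / denom
                p = 2.0 * stats.t.sf(abs(t), dof)
            tmat.loc[ci, cj] = tmat.loc[cj, ci] = t
            pmat.loc[ci, cj] = pmat.loc[cj, ci] = min(p, 1.0)
    return PosthocMatrix(method="conover", p_values=pmat, statistics=tmat,
                         degenerate=bool(degenerate))


def nemenyi_posthoc(values) -> PosthocMatrix:
    """Nemenyi all-pairs post-hoc after Friedman.

    Mean-rank differences are referred to the studentized range
    distribution: q_ij = (Rbar_i - Rbar_j) / sqrt(k(k+1)/(12 n)), compared
    against the upper tail of the studentized range with k groups and
    infinite df.  No pooled residual denominator, hence no degenerate case.
    """
    df_vals = pd.DataFrame(values)
    n, k = df_vals.shape
    ranks = _rank_matrix(df_vals)
    mean_ranks = ranks.mean(axis=0)
    scale = np.sqrt(k * (k + 1) / (12.0 * n))
    cols = list(df_vals.columns)
    qmat = pd.DataFrame(np.nan, index=cols, columns=cols)
    pmat = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i + 1:]:
            q = float(mean_ranks[ci] - mean_ranks[cj]) / scale
            p = float(stats.studentized_range.sf(abs(q), k, np.inf))
            qmat.loc[ci, cj] = qmat.loc[cj, ci] = q
            pmat.loc[ci, cj] = pmat.loc[cj, ci] = min(max(p, 0.0), 1.0)
    return PosthocMatrix(method="nemenyi", p_values=pmat, statistics=qmat)
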