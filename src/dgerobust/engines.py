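"""Interchangeable two-group differential-expression engines.

Five engines are provided, each a deliberately simplified implementation of
one of the model families commonly used for count-based DGE:

``nb_exact``
    TMM normalization, pooled moment dispersions, exact NB conditional test
    (edgeR-family exact-test lineage).
``nb_wald``
    RLE (median-of-ratios) size factors, dispersion shrunk toward a fitted
    1/mu trend, delta-method Wald test on the log2 fold change with optional
    mean-count independent filtering (DESeq-family lineage).
``voom_lite``
    Quantile-normalized log-CPM, lowess mean-variance trend, precision
    weights, weighted two-group fit with empirical-Bayes moderated t
    (voom + limma lineage).
``noiseq_like``
    Upper-quartile normalization; a non-parametric noise cloud of
    within-condition (M, D) contrasts; the DE score of a gene is the
    fraction of noise points it dominates in both |M| and D (NOISeq
    lineage).
``eb_nb``
    Median normalization; beta prior on the NB probability parameter; a
    two-component EE/DE mixture fitted by EM; per-gene posterior DE
    probability (EBSeq lineage).

These are method-inspired simplifications: numerical agreement with the
original Bioconductor packages is neither claimed nor tested.  What the
package evaluates is the surrounding robustness framework, which treats
every engine through the same interface.  Externally computed result
tables can be injected via :func:`load_external_results`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import CountMatrix
from .dispersion import estimate_nb_dispersion, exact_p_from_totals
from .evaluation import bh_adjust
from .normalization import cpm, normalized_counts, quantile_normalize

__all__ = [
    "EngineParams",
    "EngineResult",
    "ENGINES",
    "run_engine",
    "engine_nb_exact",
    "engine_nb_wald",
    "engine_voom_lite",
    "engine_noiseq_like",
    "engine_eb_nb",
    "load_external_results",
]

RESULT_COLUMNS = [
    "gene_id", "base_mean", "log2fc", "p_value", "posterior_de", "p_adjusted", "filtered",
]


@dataclass
class EngineParams:
    """Tunable knobs shared by the engines (per-engine defaults applied
    internally where a field is None)."""

    normalization: str | None = None          # None -> engine default
    dispersion_shrinkage_weight: float = 0.5  # weight toward the common target / trend
    low_count_filter: bool = True             # apply the engine's published filter rule
    pseudocount: float = 0.5                  # added to normalized means for log2fc
    seed: int = 0                             # engines with internal sampling
    # nb_wald
    independent_filter_alpha: float = 0.05
    # noiseq_like
    noiseq_max_pairs: int = 30                # cap on within-condition pairs per group
    # eb_nb
    eb_max_iter: int = 500
    eb_tol: float = 1e-6
    eb_init_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.dispersion_shrinkage_weight < 0:
            raise ValueError("dispersion_shrinkage_weight must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class EngineResult:
    """Per-gene output of one engine run.

    ``table`` has columns gene_id, base_mean, log2fc, p_value,
    posterior_de, p_adjusted, filtered.  Exactly one of p_value /
    posterior_de is populated depending on the engine family
    (``posterior_kind`` is None for p-value engines, "noise" for
    noiseq_like, "mixture" for eb_nb).  Filtered genes carry NaN in all
    test columns.
    """

    engine: str
    table: pd.DataFrame
    posterior_kind: str | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"result table missing columns {missing}")
        self.table = self.table.loc[:, RESULT_COLUMNS].reset_index(drop=True)
        p = self.table["p_value"].dropna()
        post = self.table["posterior_de"].dropna()
        if len(p) and len(post):
            raise ValueError("a result carries either p-values or posteriors, not both")
        if len(post) and ((post < 0) | (post > 1)).any():
            raise ValueError("posterior_de outside [0, 1]")
        if len(p) and ((p < 0) | (p > 1)).any():
            raise ValueError("p-values outside [0, 1]")

    def kept(self) -> pd.DataFrame:
        return self.table.loc[~self.table["filtered"]]

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _groups(cm: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    labels = cm.condition.to_numpy()
    return labels == cm.levels[0], labels == cm.levels[1]


def _require_two_groups(cm: CountMatrix, min_per_group: int = 2) -> None:
    n1, n2 = cm.group_sizes()
    if n1 < min_per_group or n2 < min_per_group:
        raise ValueError(
            f"engine needs >= {min_per_group} samples per group, got {n1} and {n2}"
        )


def _assemble(engine, cm, base_mean, log2fc, keep, p=None, posterior=None,
              posterior_kind=None, info=None) -> EngineResult:
    n = cm.n_genes
    p_col = np.full(n, np.nan)
    post_col = np.full(n, np.nan)
    padj_col = np.full(n, np.nan)
    if p is not None:
        p_col[keep] = p
        padj_col[keep] = bh_adjust(p)
    if posterior is not None:
        post_col[keep] = posterior
    table = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p_value": p_col,
            "posterior_de": post_col,
            "p_adjusted": padj_col,
            "filtered": ~keep,
        }
    )
    return EngineResult(engine=engine, table=table, posterior_kind=posterior_kind,
                        info=info or {})


def _group_log2fc(norm: np.ndarray, g1: np.ndarray, g2: np.ndarray, pc: float):
    m1 = norm[:, g1].mean(axis=1)
    m2 = norm[:, g2].mean(axis=1)
    lfc = np.log2(m2 + pc) - np.log2(m1 + pc)
    return m1, m2, lfc


# ---------------------------------------------------------------------------
# nb_exact


def engine_nb_exact(counts: CountMatrix, params: EngineParams | None = None) -> EngineResult:
    """TMM-normalized exact NB conditional test (edgeR-style lineage).

    Low-count rule: keep genes with CPM > 1 in at least min(group sizes)
    samples.  Counts are scaled to a common (geometric-mean) effective
    library size; group totals are rounded and the exact conditional
    p-value computed per gene.
    """
    params = params or EngineParams()
    _require_two_groups(counts)
    g1, g2 = _groups(counts)
    df = counts.counts.astype(float)
    method = params.normalization or "tmm"
    norm = normalized_counts(df, method=method).to_numpy()

    if params.low_count_filter:
        c = cpm(df).to_numpy()
        keep = (c > 1).sum(axis=1) >= min(int(g1.sum()), int(g2.sum()))
    else:
        keep = np.ones(counts.n_genes, dtype=bool)

    base_mean = norm.mean(axis=1)
    _, _, lfc = _group_log2fc(norm, g1, g2, params.pseudocount)

    sub = norm[keep]
    labels = np.where(g1, "a", "b")
    phi = estimate_nb_dispersion(sub, labels, params.dispersion_shrinkage_weight)
    s1 = np.rint(sub[:, g1].sum(axis=1)).astype(np.int64)
    s2 = np.rint(sub[:, g2].sum(axis=1)).astype(np.int64)
    n1, n2 = int(g1.sum()), int(g2.sum())
    p = np.array(
        [exact_p_from_totals(int(a), int(b), n1, n2, float(ph))
         for a, b, ph in zip(s1, s2, phi)]
    )
    return _assemble("nb_exact", counts, base_mean, lfc, keep, p=p,
                     info={"normalization": method})


# ---------------------------------------------------------------------------
# nb_wald


def _dispersion_trend(phi_raw: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Fit phi(mu) = a0 + a1/mu on genes with informative moment estimates."""
    ok = (phi_raw > 0) & (mu > 0)
    if ok.sum() >= 10:
        design = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(design, phi_raw[ok], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
    else:
        a0, a1 = float(np.mean(phi_raw)), 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-8)
    return np.maximum(trend, 0.0)


def engine_nb_wald(counts: CountMatrix, params: EngineParams | None = None) -> EngineResult:
    """RLE-normalized delta-method Wald test (DESeq-style lineage).

    Dispersions are moment estimates shrunk toward a fitted a0 + a1/mu
    trend.  The Wald statistic is log2fc over its delta-method standard
    error, referred to the t distribution with n - 2 df (finite-sample
    analogue of the usual normal reference).  When ``low_count_filter`` is
    on, a mean-count independent filter picks the base-mean cutoff (over a
    quantile grid) that maximises BH rejections at
    ``independent_filter_alpha``; genes below it are reported filtered.
    """
    params = params or EngineParams()
    _require_two_groups(counts)
    g1, g2 = _groups(counts)
    df = counts.counts.astype(float)
    method = params.normalization or "rle"
    norm = normalized_counts(df, method=method).to_numpy()
    sf = (df.sum(axis=0) / df.sum(axis=0).mean()).to_numpy()  # relative depths for variance

    base_mean = norm.mean(axis=1)
    m1, m2, lfc = _group_log2fc(norm, g1, g2, params.pseudocount)

    labels = np.where(g1, "a", "b")
    phi_raw = estimate_nb_dispersion(norm, labels, shrinkage_weight=0.0)
    trend = _dispersion_trend(phi_raw, base_mean)
    w = params.dispersion_shrinkage_weight
    phi = (phi_raw + w * trend) / (1.0 + w)

    pc = params.pseudocount
    ln2sq = np.log(2.0) ** 2
    var_terms = []
    for g, m in ((g1, m1), (g2, m2)):
        inv_s = np.mean(1.0 / sf[g])
        nk = int(g.sum())
        var_mean = (m * inv_s + phi * m ** 2) / nk
        var_terms.append(var_mean / ((m + pc) ** 2 * ln2sq))
    se = np.sqrt(var_terms[0] + var_terms[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.where(lfc == 0, 0.0, np.inf))
    dof = counts.n_samples - 2
    p = 2.0 * stats.t.sf(np.abs(z), dof)
    p = np.clip(p, 0.0, 1.0)

    if params.low_count_filter:
        keep, cutoff = _independent_filter(base_mean, p, params.independent_filter_alpha)
    else:
        keep, cutoff = np.ones(counts.n_genes, dtype=bool), 0.0
    return _assemble("nb_wald", counts, base_mean, lfc, keep, p=p[keep],
                     info={"normalization": method, "filter_cutoff": cutoff})


def _independent_filter(base_mean, p, alpha, quantiles=np.arange(0.0, 0.55, 0.05)):
    """Pick the base-mean quantile cutoff maximising BH rejections."""
    best_keep, best_rej, best_cut = None, -1, 0.0
    for q in quantiles:
        cut = np.quantile(base_mean, q) if q > 0 else -np.inf
        keep = base_mean >= cut
        if keep.sum() == 0:
            continue
        rej = int((bh_adjust(p[keep]) < alpha).sum())
        if rej > best_rej:
            best_keep, best_rej, best_cut = keep, rej, (0.0 if q == 0 else float(cut))
    return best_keep, best_cut


# ---------------------------------------------------------------------------
# voom_lite


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = max(x + dif, 1e-8)
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_scaled_f(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled-F prior: returns
    (prior df d0, prior variance s0^2).  d0 = inf when variances are less
    variable than pure chi-squared noise."""
    ok = s2 > 0
    if ok.sum() < 10:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    ev = np.var(e, ddof=1) - special.polygamma(1, df_resid / 2.0)
    if ev <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(ev)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def engine_voom_lite(counts: CountMatrix, params: EngineParams | None = None) -> EngineResult:
    """Precision-weighted log-CPM linear model with moderated t.

    Pipeline: quantile-normalized log2-CPM -> per-gene two-group fit ->
    lowess trend of sqrt(residual SD) against mean log-count -> per-
    observation weights = trend(fitted)^-4 -> weighted refit -> empirical-
    Bayes moderation of the residual variances (scaled-F moment matching)
    -> moderated t with residual + prior df.  Low-count rule: total count
    >= 10 and CPM > 1 in at least min(group sizes) samples.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    params = params or EngineParams()
    _require_two_groups(counts)
    g1, g2 = _groups(counts)
    df = counts.counts.astype(float)

    if params.low_count_filter:
        c = cpm(df).to_numpy()
        keep = (df.sum(axis=1).to_numpy() >= 10) & (
            (c > 1).sum(axis=1) >= min(int(g1.sum()), int(g2.sum()))
        )
    else:
        keep = np.ones(counts.n_genes, dtype=bool)
    if not keep.any():
        raise ValueError("all genes filtered before testing")

    logcpm_all = cpm(df, log=True, prior_count=params.pseudocount)
    y_all = quantile_normalize(logcpm_all).to_numpy()
    base_mean = normalized_counts(df, method="library_size").to_numpy().mean(axis=1)

    y = y_all[keep]
    n1, n2 = int(g1.sum()), int(g2.sum())
    n = n1 + n2
    df_resid = n - 2

    mu1 = y[:, g1].mean(axis=1)
    mu2 = y[:, g2].mean(axis=1)
    fitted = np.empty_like(y)
    fitted[:, g1] = mu1[:, None]
    fitted[:, g2] = mu2[:, None]
    resid = y - fitted
    s2 = (resid ** 2).sum(axis=1) / df_resid
    sd_quarter = np.sqrt(np.sqrt(s2))

    xbar = y.mean(axis=1)
    smooth = lowess(sd_quarter, xbar, frac=0.5, it=3, return_sorted=True)
    sx, sy = smooth[:, 0], np.maximum(smooth[:, 1], 1e-4)
    trend_at = lambda v: np.interp(v, sx, sy)
    weights = trend_at(fitted) ** -4.0  # strictly positive and finite

    w1 = weights[:, g1].sum(axis=1)
    w2 = weights[:, g2].sum(axis=1)
    wm1 = (weights[:, g1] * y[:, g1]).sum(axis=1) / w1
    wm2 = (weights[:, g2] * y[:, g2]).sum(axis=1) / w2
    beta = wm2 - wm1
    wfit = np.empty_like(y)
    wfit[:, g1] = wm1[:, None]
    wfit[:, g2] = wm2[:, None]
    s2w = (weights * (y - wfit) ** 2).sum(axis=1) / df_resid

    d0, s0_sq = _fit_scaled_f(s2w, df_resid)
    if np.isinf(d0):
        s2_mod = np.full_like(s2w, s0_sq)
        df_total = 1e6
    else:
        s2_mod = (d0 * s0_sq + df_resid * s2w) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_mod * (1.0 / w1 + 1.0 / w2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                          np.where(beta == 0, 0.0, np.inf))
    p = np.clip(2.0 * stats.t.sf(np.abs(t_stat), df_total), 0.0, 1.0)

    lfc = np.full(counts.n_genes, 0.0)
    m1a, m2a, lfc_all = _group_log2fc(
        normalized_counts(df, method="library_size").to_numpy(), g1, g2, params.pseudocount
    )
    lfc = lfc_all
    return _assemble("voom_lite", counts, base_mean, lfc, keep, p=p,
                     info={"d0": float(d0), "s0_sq": float(s0_sq)})


# ---------------------------------------------------------------------------
# noiseq_like


def _dominance_fraction(abs_m, d, noise_abs_m, noise_d, chunk: int = 256) -> np.ndarray:
    """For each query (|M|, D), the fraction of noise points strictly below
    it in both coordinates.  Chunked dense comparison."""
    n_noise = len(noise_abs_m)
    out = np.empty(len(abs_m))
    if n_noise == 0:
        out[:] = 0.0
        return out
    for start in range(0, len(abs_m), chunk):
        sl = slice(start, start + chunk)
        dominated = (noise_abs_m[None, :] < abs_m[sl, None]) & (
            noise_d[None, :] < d[sl, None]
        )
        out[sl] = dominated.sum(axis=1) / n_noise
    return out


def engine_noiseq_like(counts: CountMatrix, params: EngineParams | None = None) -> EngineResult:
    """Non-parametric noise-cloud engine (NOISeq lineage).

    Upper-quartile normalized counts.  Per gene the signal is
    M = log2 ratio of condition means (with pseudocount) and
    D = |difference of condition means|.  The noise cloud pools (|M*|, D*)
    over all within-condition sample pairs and all kept genes (pairs are
    canonically ordered by sample id and capped at ``noiseq_max_pairs`` per
    condition with a seeded subsample).  posterior_de is the fraction of
    noise points a gene dominates in both coordinates.
    """
    params = params or EngineParams()
    n1, n2 = counts.group_sizes()
    if max(n1, n2) < 2:
        raise ValueError("noise estimation needs >= 2 samples in some condition")
    g1, g2 = _groups(counts)
    df = counts.counts.astype(float)
    method = params.normalization or "upper_quartile"
    norm_df = normalized_counts(df, method=method)
    norm = norm_df.to_numpy()
    pc = params.pseudocount

    if params.low_count_filter:
        c = cpm(df).to_numpy()
        keep = (c[:, g1].mean(axis=1) > 1) & (c[:, g2].mean(axis=1) > 1)
    else:
        keep = np.ones(counts.n_genes, dtype=bool)

    base_mean = norm.mean(axis=1)
    m1, m2, lfc = _group_log2fc(norm, g1, g2, pc)
    abs_m = np.abs(lfc[keep])
    d = np.abs(m2[keep] - m1[keep])

    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF, 71]))
    noise_m, noise_d = [], []
    for g in (g1, g2):
        ids = sorted(np.asarray(counts.sample_ids)[g])
        pairs = list(itertools.combinations(ids, 2))
        if len(pairs) > params.noiseq_max_pairs:
            sel = rng.choice(len(pairs), size=params.noiseq_max_pairs, replace=False)
            pairs = [pairs[i] for i in sorted(sel)]
        for a, b in pairs:
            xa = norm_df[a].to_numpy()[keep]
            xb = norm_df[b].to_numpy()[keep]
            noise_m.append(np.abs(np.log2(xa + pc) - np.log2(xb + pc)))
            noise_d.append(np.abs(xa - xb))
    if not noise_m:
        raise ValueError("no within-condition sample pair available")
    noise_m = np.concatenate(noise_m)
    noise_d = np.concatenate(noise_d)

    posterior = _dominance_fraction(abs_m, d, noise_m, noise_d)
    return _assemble("noiseq_like", counts, base_mean, lfc, keep,
                     posterior=posterior, posterior_kind="noise",
                     info={"n_noise_points": int(len(noise_m)), "normalization": method})


# ---------------------------------------------------------------------------
# eb_nb


def _eb_log_marginals(r, n1, n2, s1, s2, alpha, beta):
    """Log marginal likelihoods (up to the shared combinatorial constant)
    of the EE and DE hypotheses under a Beta(alpha, beta) prior on the NB
    probability parameter."""
    lb = special.betaln(alpha, beta)
    ee = special.betaln(alpha + (n1 + n2) * r, beta + s1 + s2) - lb
    de = (special.betaln(alpha + n1 * r, beta + s1) - lb
          + special.betaln(alpha + n2 * r, beta + s2) - lb)
    return ee, de


def engine_eb_nb(counts: CountMatrix, params: EngineParams | None = None) -> EngineResult:
    """Empirical-Bayes NB mixture engine (EBSeq lineage).

    Median-normalized counts (rounded) are modelled as NB(r_g, q_g) with
    q_g ~ Beta(alpha, beta).  Under EE both groups share q_g; under DE each
    group draws its own.  The per-sample combinatorial terms cancel between
    the hypotheses, so posteriors depend only on beta-function ratios of
    group sums.  Hyperparameters (alpha, beta) and the DE mixture weight
    are fitted by EM (generalized M-step via Nelder-Mead on the log scale);
    initialization is method-of-moments with mixture weight 0.1.  No
    low-count filter is applied, matching the convention of the method
    family it emulates.
    """
    from scipy.optimize import minimize

    params = params or EngineParams()
    _require_two_groups(counts)
    g1, g2 = _groups(counts)
    df = counts.counts.astype(float)
    method = params.normalization or "median"
    norm = normalized_counts(df, method=method).to_numpy()
    x = np.rint(norm)

    base_mean = norm.mean(axis=1)
    m1, m2, lfc = _group_log2fc(norm, g1, g2, params.pseudocount)

    labels = np.where(g1, "a", "b")
    phi = estimate_nb_dispersion(x, labels, shrinkage_weight=params.dispersion_shrinkage_weight)
    phi = np.clip(phi, 1e-3, 5.0)
    r = 1.0 / phi
    n1, n2 = int(g1.sum()), int(g2.sum())
    s1 = x[:, g1].sum(axis=1)
    s2 = x[:, g2].sum(axis=1)

    # method-of-moments init: implied per-gene q, beta-matched
    q_hat = np.clip(((n1 + n2) * r) / ((n1 + n2) * r + s1 + s2), 1e-6, 1 - 1e-6)
    m, v = float(np.mean(q_hat)), float(np.var(q_hat))
    if v > 0 and v < m * (1 - m):
        common = m * (1 - m) / v - 1.0
        alpha0, beta0 = m * common, (1 - m) * common
    else:
        alpha0, beta0 = 1.0, 1.0
    alpha = float(np.clip(alpha0, 1e-2, 1e4))
    beta = float(np.clip(beta0, 1e-2, 1e4))
    p_de = float(params.eb_init_weight)

    def loglik(a, b, w):
        ee, de = _eb_log_marginals(r, n1, n2, s1, s2, a, b)
        stack = np.stack([ee + np.log1p(-w), de + np.log(w)])
        return float(special.logsumexp(stack, axis=0).sum()), ee, de

    ll, ee, de = loglik(alpha, beta, p_de)
    converged = False
    n_iter = 0
    for n_iter in range(1, params.eb_max_iter + 1):
        # E-step
        log_num = de + np.log(p_de)
        log_den = special.logsumexp(
            np.stack([ee + np.log1p(-p_de), log_num]), axis=0
        )
        post = np.exp(log_num - log_den)
        # M-step: closed-form weight, short Nelder-Mead on hyperparameters
        p_de = float(np.clip(post.mean(), 1e-6, 1 - 1e-6))

        def neg_q(theta):
            a, b = np.exp(theta)
            ee_t, de_t = _eb_log_marginals(r, n1, n2, s1, s2, a, b)
            return -float(np.sum((1 - post) * ee_t + post * de_t))

        res = minimize(neg_q, np.log([alpha, beta]), method="Nelder-Mead",
                       options={"maxiter": 12, "xatol": 1e-4, "fatol": 1e-4})
        alpha, beta = np.exp(res.x)
        new_ll, ee, de = loglik(alpha, beta, p_de)
        if abs(new_ll - ll) < params.eb_tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    log_num = de + np.log(p_de)
    log_den = special.logsumexp(np.stack([ee + np.log1p(-p_de), log_num]), axis=0)
    posterior = np.exp(log_num - log_den)
    keep = np.ones(counts.n_genes, dtype=bool)
    return _assemble("eb_nb", counts, base_mean, lfc, keep,
                     posterior=posterior, posterior_kind="mixture",
                     info={"alpha": float(alpha), "beta": float(beta),
                           "mixture_weight_de": p_de, "em_iterations": n_iter,
                           "converged": converged, "loglik": ll})


# ---------------------------------------------------------------------------
# external results


def load_external_results(path: str, engine_label: str = "external") -> EngineResult:
    """Adapt an externally computed DGE result table to the evaluation stack.

    The TSV needs columns gene_id, log2fc and at least one of p_value /
    posterior_de.  Unknown columns are ignored; BH adjustment is applied
    when p_value is present but p_adjusted is not.
    """
    raw = pd.read_csv(path, sep="\t")
    if "gene_id" not in raw.columns or "log2fc" not in raw.columns:
        raise ValueError("external results need gene_id and log2fc columns")
    has_p = "p_value" in raw.columns
    has_post = "posterior_de" in raw.columns
    if not has_p and not has_post:
        raise ValueError("external results need p_value or posterior_de")
    n = len(raw)
    table = pd.DataFrame({
        "gene_id": raw["gene_id"],
        "base_mean": raw.get("base_mean", pd.Series(np.nan, index=raw.index)),
        "log2fc": raw["log2fc"].astype(float),
        "p_value": raw["p_value"].astype(float) if has_p else np.full(n, np.nan),
        "posterior_de": raw["posterior_de"].astype(float) if has_post else np.full(n, np.nan),
        "p_adjusted": raw["p_adjusted"].astype(float) if "p_adjusted" in raw.columns
        else np.full(n, np.nan),
        "filtered": raw["filtered"].astype(bool) if "filtered" in raw.columns
        else np.zeros(n, dtype=bool),
    })
    for col in ("p_value", "posterior_de"):
        vals = table[col].dropna()
        if len(vals) and ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1] in external table")
    if has_p and table["p_adjusted"].isna().all():
        kept = ~table["filtered"] & table["p_value"].notna()
        table.loc[kept, "p_adjusted"] = bh_adjust(table.loc[kept, "p_value"].to_numpy())
    kind = None if has_p else "external"
    return EngineResult(engine=engine_label, table=table, posterior_kind=kind)


ENGINES = {
    "nb_exact": engine_nb_exact,
    "nb_wald": engine_nb_wald,
    "voom_lite": engine_voom_lite,
    "noiseq_like": engine_noiseq_like,
    "eb_nb": engine_eb_nb,
}


def run_engine(name: str, counts: CountMatrix, params: EngineParams | None = None) -> EngineResult:
    """Run a registered engine by name."""
    try:
        fn = ENGINES[name]
    except KeyError:
        raise ValueError(f"unknown engine {name!r}; available: {sorted(ENGINES)}") from None
    return fn(counts, params)
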