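"""Between-sample normalization: CPM, TMM, RLE, quantile-based scale factors
and full quantile normalization.

Each factor method returns a pandas Series of per-sample scaling factors
(``series.name`` records the method).  TMM, upper-quartile and median
factors are rescaled to geometric mean 1 (they are *relative* corrections on
top of library size); RLE factors are absolute size factors in the
median-of-ratios sense and are used by dividing counts by the factor
directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix

__all__ = [
    "cpm",
    "tmm_factors",
    "rle_size_factors",
    "quantile_scale_factors",
    "quantile_normalize",
    "normalized_counts",
]


def _counts_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else pd.DataFrame(counts)


def cpm(counts, log: bool = False, prior_count: float = 0.5) -> pd.DataFrame:
    """Counts per million mapped reads, optionally on the log2 scale.

    The log offset follows the standard voom-style convention: the prior
    count is scaled per sample by library size relative to the mean library
    size, and the library size is inflated by twice the scaled prior, i.e.
    log2-CPM = log2((count + pc_j) / (lib_j + 2 pc_j) * 1e6).
    """
    df = _counts_frame(counts).astype(float)
    lib = df.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero-depth samples: {bad}")
    if not log:
        return df.div(lib, axis=1) * 1e6
    pc = prior_count * lib / lib.mean()
    return np.log2((df.add(pc, axis=1)).div(lib + 2 * pc, axis=1) * 1e6)


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def tmm_factors(counts, ref_sample: str | None = None,
                logratio_trim: float = 0.3, sum_trim: float = 0.05) -> pd.Series:
    """Trimmed mean of M-values scaling factors.

    For each sample against a reference sample, M (log ratio) and A (log
    abundance) values are computed over genes expressed in both; the top and
    bottom 30% by M and 5% by A are trimmed; the factor is 2 to the
    inverse-variance-weighted mean of the surviving M values.  Factors are
    rescaled to geometric mean 1.  The reference defaults to the sample
    whose 75th count percentile (depth-scaled) is closest to the mean.
    """
    df = _counts_frame(counts).astype(float)
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = df.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero-depth sample")
    if ref_sample is None:
        f75 = df.div(lib, axis=1).quantile(0.75, axis=0)
        ref_sample = (f75 - f75.mean()).abs().idxmin()
    if ref_sample not in df.columns:
        raise KeyError(ref_sample)

    xr = df[ref_sample].to_numpy()
    nr = float(lib[ref_sample])
    log_factors = {}
    for sample in df.columns:
        if sample == ref_sample:
            log_factors[sample] = 0.0
            continue
        x = df[sample].to_numpy()
        n = float(lib[sample])
        keep = (x > 0) & (xr > 0)
        if not keep.any():
            raise ValueError(
                f"sample {sample!r} shares no expressed genes with reference {ref_sample!r}"
            )
        obs, ref = x[keep] / n, xr[keep] / nr
        m = np.log2(obs / ref)
        a = 0.5 * np.log2(obs * ref)
        w = (n - x[keep]) / (n * x[keep]) + (nr - xr[keep]) / (nr * xr[keep])
        ng = keep.sum()
        lo_m = np.floor(ng * logratio_trim) + 1
        hi_m = ng + 1 - lo_m
        lo_a = np.floor(ng * sum_trim) + 1
        hi_a = ng + 1 - lo_a
        rm = rankdata(m, method="ordinal")
        ra = rankdata(a, method="ordinal")
        trimmed = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if trimmed.any() and np.sum(w[trimmed]) > 0:
            log_factors[sample] = float(np.sum(w[trimmed] * m[trimmed]) / np.sum(w[trimmed]))
        else:
            log_factors[sample] = 0.0
    factors = pd.Series(
        {s: 2.0 ** lf for s, lf in log_factors.items()}, name="tmm"
    ).reindex(df.columns)
    return factors / _geomean(factors.to_numpy())


def rle_size_factors(counts) -> pd.Series:
    """Median-of-ratios (RLE) size factors.

    Each gene's counts are divided by the gene's geometric mean across
    samples; a sample's factor is the median of those ratios over genes
    expressed in every sample.
    """
    df = _counts_frame(counts).astype(float)
    positive = (df > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    sub = df.loc[positive]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_geo, axis=0)
    factors = np.exp(ratios.median(axis=0))
    factors.name = "rle"
    return factors


def sample_quantiles(counts, q: float, include_zeros: bool = False) -> pd.Series:
    """Per-sample q-quantile (type-7 interpolation) of depth-scaled counts.

    By default only non-zero counts enter the quantile, matching the
    convention of upper-quartile scaling for sparse count data.
    """
    df = _counts_frame(counts).astype(float)
    lib = df.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero-depth sample")
    out = {}
    for sample in df.columns:
        vals = df[sample].to_numpy() / lib[sample]
        if not include_zeros:
            vals = vals[vals > 0]
        if vals.size == 0:
            raise ValueError(f"sample {sample!r} has no non-zero counts")
        out[sample] = float(np.quantile(vals, q))  # numpy default = type-7 linear
    return pd.Series(out).reindex(df.columns)


def quantile_scale_factors(counts, q: float = 0.75, include_zeros: bool = False) -> pd.Series:
    """Scale factors from a per-sample count quantile (q=0.75 upper quartile,
    q=0.5 median), rescaled to geometric mean 1."""
    quants = sample_quantiles(counts, q, include_zeros=include_zeros)
    factors = quants / _geomean(quants.to_numpy())
    factors.name = "upper_quartile" if abs(q - 0.75) < 1e-12 else ("median" if abs(q - 0.5) < 1e-12 else f"q{q:g}")
    return factors


def quantile_normalize(matrix) -> pd.DataFrame:
    """Force all columns to share the distribution of row means of sorted
    columns; tied values within a column receive the mean of their targets."""
    df = pd.DataFrame(matrix).astype(float)
    if df.size == 0:
        raise ValueError("empty matrix")
    if df.isna().any().any():
        raise ValueError("missing values are not supported")
    arr = df.to_numpy()
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = target
        # average targets over tie groups so equal inputs map to equal outputs
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalized_counts(counts, method: str = "library_size", **kwargs) -> pd.DataFrame:
    """Counts rescaled to a common depth under a chosen factor method.

    For geometric-mean-1 factor methods the effective library size is
    lib_j * factor_j and values are rescaled to the mean library size, so
    normalized counts stay on the raw-count scale.  For 'rle' counts are
    divided by the absolute size factor (median-of-ratios convention).
    """
    df = _counts_frame(counts).astype(float)
    lib = df.sum(axis=0)
    if method == "rle":
        return df.div(rle_size_factors(df), axis=1)
    if method == "library_size":
        factors = pd.Series(1.0, index=df.columns)
    elif method == "tmm":
        factors = tmm_factors(df, **kwargs)
    elif method == "upper_quartile":
        factors = quantile_scale_factors(df, q=0.75, **kwargs)
    elif method == "median":
        factors = quantile_scale_factors(df, q=0.5, **kwargs)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    eff = lib * factors
    return df.div(eff, axis=1) * float(lib.mean())
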