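# Methods

This note documents the models, parameter choices and numerical conventions
behind `dgerobust`, and what the package's tests do and do not establish.

## Count model and synthetic data

Counts are negative binomial with the quadratic mean–variance law
Var = μ + φμ², the parameterisation shared by the NB-based DGE tools the
engines emulate. Sampling uses the gamma–Poisson mixture
Poisson(Gamma(1/φ, φμ)), which supports per-gene dispersion vectors
directly; φ < 1e−12 falls back to a pure Poisson draw.

`SimulationConfig` defaults define the package's standard study conditions:

- **n_genes = 2000, 20 vs 20 samples** — large enough for stable engine
  behaviour, small enough for desk-scale grids.
- **de_fraction = 0.2 at |log2FC| = 2** — a strong, unambiguous effect
  size; DE genes are split as evenly as possible between up- and
  down-regulation so total depth is not confounded with condition.
- **baseline means log-normal(4.0, 1.5)** — median ≈ 55, mean ≈ 170 counts
  per gene, i.e. a few million reads per library for a 2,000-gene panel.
  This is a deliberate choice of a realistically skewed expression
  distribution; it is not fitted to any particular cohort.
- **dispersion φ = 0.2** (scalar default, per-gene vectors supported) — a
  biological coefficient of variation ≈ 0.45, typical of heterogeneous
  human tissue cohorts rather than cell lines.
- **library size factors log-normal(0, 0.3)** — emulates the inter-sample
  variability in sequencing depth seen in clinical libraries.

Presets `tnbc_like` (42 vs 21), `erpos_like` (42 vs 30) and `subset_like`
(5 vs 5) mirror typical breast-cancer tumour-versus-uninvolved-tissue
cohort designs; only the group sizes differ from the defaults.

What the generator does *not* emulate: isoform structure, gene length and
GC bias, batch effects, outlier samples, and correlation between genes.
Tests passing on this generator therefore demonstrate the correctness and
internal calibration of the machinery under the stated NB conditions — not
that any engine is well calibrated on arbitrary real data.

## Depth titration

Thinning retains each count with probability *f*, i.e. each cell becomes
Binomial(count, *f*). Under multinomial allocation of reads to genes this
is distributionally identical to keeping each mapped read independently
with probability *f*, which is why count-level thinning stands in for
alignment-file subsampling. The default grid is 17 fractions
{1, 0.99, 0.95, 0.9, 0.85, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.25, 0.2, 0.15,
0.1, 0.05, 0.01} × 25 iterations (425 instances, iterating at *f* = 1 as
well).

Seeds: each grid cell draws from a stream derived only from
(master seed, round(f·10⁶), r), so results are independent of evaluation
order and any cell can be regenerated in isolation. Seeding is per
(f, r) matrix rather than per cell; the finest unit of reproducibility is
one thinned matrix.

## Normalization

- **CPM / log-CPM**: count / library × 10⁶; the log offset scales the prior
  count (default 0.5) per sample by library size relative to the mean
  library, log2((x + pc_j)/(lib_j + 2pc_j)·10⁶).
- **TMM**: doubly trimmed (30% on M, 5% on A), inverse-variance-weighted
  mean of depth-scaled log ratios against a reference sample (the one whose
  depth-scaled 75th percentile is closest to the mean); genes zero in
  either sample are excluded; factors rescaled to geometric mean 1. A
  sample dominated by a few inflated genes receives a factor *below* 1 —
  the composition correction scales its library down.
- **RLE**: median over all-positive genes of count / per-gene geometric
  mean; absolute size factors in the median-of-ratios sense (counts are
  divided by the factor directly).
- **Upper-quartile / median**: the q = 0.75 / 0.5 quantile (type-7 linear
  interpolation, numpy's default) of each sample's depth-scaled non-zero
  counts, rescaled to geometric mean 1. Zeros can be included via a flag;
  excluding them is the default because sparse count panels otherwise
  collapse the lower quantiles.
- **Quantile normalization**: columns are forced onto the distribution of
  row-wise means of the sorted columns; ties within a column receive the
  mean of their target values so equal inputs map to equal outputs.

`normalized_counts` rescales to the mean library size so normalized values
stay on the raw-count scale regardless of factor method.

## Engines

All five engines are method-inspired simplifications of the major DGE model
families. They share: log2 fold change = log2((m₂ + 0.5)/(m₁ + 0.5)) on
normalized group means (pseudocount 0.5 avoids infinities), and a pooled
within-group method-of-moments dispersion estimator
φ̂ = Σₖ(nₖ−1)(vₖ−mₖ) / Σₖ(nₖ−1)mₖ², clamped at 0, optionally shrunk toward
a common target with weight w: (φ̂ + w·target)/(1+w) (default w = 0.5).

- **nb_exact** (TMM): group totals on a common effective library size are
  tested with the exact NB conditional test: given the grand total t, the
  group-1 total is distributed ∝ C(y+r₁−1, y)·C(t−y+r₂−1, t−y) with
  rₖ = nₖ/φ (binomial in the Poisson limit). The two-sided p sums all
  outcomes no more probable than the observed one; ties are judged with a
  1e−8 log-space tolerance — above the float-noise floor of the log-gamma
  evaluations, so exact mathematical ties (e.g. mirror outcomes under equal
  group sizes) are always recognised and the p-value is invariant under
  label swaps. Filter: CPM > 1 in at least min(group sizes) samples.
- **nb_wald** (RLE): per-gene moment dispersions shrunk toward a fitted
  trend φ(μ) = a₀ + a₁/μ (non-negative least squares on informative genes);
  delta-method SE of the log2FC from Var(meanₖ) ≈ (mₖ·mean(1/sⱼ) + φmₖ²)/nₖ;
  the Wald statistic is referred to t with n − 2 df as a finite-sample
  reference. Optional independent filtering scans base-mean quantile
  cutoffs 0–0.5 and keeps the one maximising BH rejections at 0.05;
  filtered genes carry no p-values.
- **voom_lite** (quantile-normalized log-CPM): two-group fit per gene;
  lowess (frac 0.5) of √SD against mean log-CPM gives per-observation
  weights trend⁻⁴; a weighted refit's variances are moderated by
  moment-matching log s² to a scaled-F prior (prior df via an inverse-
  trigamma Newton solve; infinite prior df degenerates to a common
  variance); moderated t with residual + prior df. Filter: total ≥ 10
  reads and CPM > 1 in at least min(group sizes) samples.
- **noiseq_like** (upper quartile): signal per gene is M (log2 ratio of
  condition means, with pseudocount) and D (absolute mean difference); the
  noise cloud pools (|M*|, D*) over within-condition sample pairs and all
  kept genes. Pairs are canonically ordered by sample id (so results are
  invariant to column permutations) and capped at 30 pairs per condition
  with a seeded subsample — beyond that the cloud's size grows
  quadratically with replicates while adding little resolution. The DE
  score is the fraction of noise points strictly dominated in both
  coordinates. Filter: mean CPM > 1 required in every condition.
- **eb_nb** (median): rounded normalized counts modelled as NB(r_g, q_g)
  with q_g ~ Beta(α, β); under EE both groups share q_g, under DE each
  group draws its own, so the marginal likelihoods are beta-function ratios
  of group sums (the per-sample combinatorial terms cancel). EM fits the
  DE mixture weight (closed form) and (α, β) (short Nelder–Mead on the log
  scale per M-step, a generalized EM); initialization is method-of-moments
  with weight 0.1; convergence at |Δlog L| < 1e−6, max 500 iterations,
  with iteration count and convergence flag reported. No low-count filter.

## DEG calling and metrics

p-value engines call genes at BH-adjusted p < 0.05. The mixture engine
uses soft posterior-FDR control: genes ranked by posterior DE probability,
keeping the largest prefix whose mean miss-probability (1 − posterior) is
≤ 0.05 (a hard posterior cutoff is available). The noise-cloud engine
calls posterior ≥ q with q = 0.95 by default — the original benchmark never
states its threshold, so this is a documented package choice, deliberately
conservative.

Relative FDR follows the definitions in the README; when TP = 0 the record
is flagged undefined, relative FDR is 1 if FP > 0 and 0 otherwise (this
preserves the ordering without dividing by zero). Two-fold filtering keeps
|log2FC| > 2 and is always a subset of the unfiltered set. Expression
strata split genes at the median of control-sample mean expression (CPM by
default); genes exactly at the median go to "low" so the split is
deterministic. Concordance reports exact counts for every region of the
set-inclusion lattice; region counts sum to the union size.

## Slope population and rank statistics

Leave-one-out populations remove one sample per replicate (group chosen
uniformly among groups that keep ≥ 2 samples afterwards, then the sample
uniformly; all seeded). Relative FDR is measured on the two-fold regime by
default (configurable) at f ∈ {0.8, 0.85, 0.9, 0.95, 0.99}; per-f values
are averaged over thinning iterations (default 5 in the pipeline; a
per-iteration mode exists) before the OLS fit.

The Friedman statistic is always tie-corrected,
χ² = (k−1)·Σ(R_j − n(k+1)/2)² / (ΣR_ij² − nk(k+1)²/4), which reduces to the
classic 12/(nk(k+1)) form without ties; p-values come from the chi-squared
upper tail (regularized upper incomplete gamma). Conover post-hoc t
statistics use the pooled-variance denominator √(2n(A−B)/((n−1)(k−1))) with
df = (n−1)(k−1); when all blocks rank the treatments identically the
denominator vanishes and the result is explicitly flagged degenerate rather
than silently returning p = 0. Nemenyi refers mean-rank differences to the
studentized range with infinite df and is the more conservative of the two.

## Problem sizes

The test suite exercises the full standard conditions (2,000 genes,
20 vs 20) for the depth-degradation and calibration checks, with 10
thinning iterations over f ∈ {1, 0.5, 0.25, 0.1} and 2 iterations per
fraction for the 11-dataset slope population. `scripts/acceptance.py` runs
a 1,000-gene, 10 vs 10 cohort with 3 iterations (1 for slopes) — sizes
chosen as comfortable single-CPU desk-scale analyses; all conclusions the
package tests are scale-stable in this range.

## Known limitations

- Engines are intentionally simplified; no numerical agreement with any
  released DGE package is claimed, and none is tested. External result
  tables can be scored through the same evaluation stack instead.
- The self-referential relative FDR measures *stability under depth loss*,
  not correctness; an engine that calls nothing is perfectly stable. The
  synthetic truth table exists precisely to keep the engines honest on
  detection power (ROC and true-FDR tests).
- Only two-level, single-factor designs are supported: no GLMs,
  likelihood-ratio tests, outlier imputation, or batch correction.
- The noise-cloud engine's pair cap (30 per condition) makes its posterior
  a seeded subsample estimate for groups larger than 9; below that it is
  exact.
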