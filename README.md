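# dgerobust

Depth-robustness benchmarking of differential gene expression (DGE) methods
on fixed RNA-seq count matrices.

## The problem

RNA-seq DGE results depend heavily on the analysis method, and sequencing
depth varies widely between clinical libraries. Before a DGE workflow can be
trusted in settings like molecular diagnostics, one needs to know how
*robust* its gene calls are to a shallower sequencing run of the same
samples. Real cohorts have no biological ground truth, so this package uses
a self-referential criterion: an engine's DEG calls on the full-depth data
define its own reference, and its calls on a depth-reduced version of the
same data are scored against that reference. For a reduced-depth DEG set
*S* and the full-depth set *F* of the same engine,

- TP = |S ∩ F|, FP = |S \ F|, MD = |F \ S| (miss-detected),
- **relative FDR** = FP / (FP + TP),
- MDR = MD / TP, PC = 100·(FP + MD) / TP.

Depth reduction is simulated by seeded binomial thinning: keeping every
mapped read independently with probability *f* turns each count cell into
Binomial(count, *f*), so thinning a fixed count matrix is statistically
equivalent to subsampling the alignment files, without touching BAMs. The
standard design thins over 17 fractions
{1, 0.99, 0.95, …, 0.05, 0.01} × 25 iterations (425 instances).

Robustness is summarised by the slope of an OLS fit of relative FDR against
*f* over the near-full-depth grid {0.8, 0.85, 0.9, 0.95, 0.99}. A
*population* of slopes (the original dataset plus ten leave-one-out
variants → 11 slopes per engine) is compared across engines with the
Friedman rank test (blocks = datasets, treatments = engines, df = k − 1)
followed by Conover and Nemenyi pairwise post-hocs.

## The engines

Five interchangeable two-group engines cover the main model families used
for count-based DGE (deliberately simplified implementations, not
re-implementations of any released package):

| engine | normalization | test |
|---|---|---|
| `nb_exact` | TMM | exact NB conditional test on common-depth group totals |
| `nb_wald` | RLE (median-of-ratios) | delta-method Wald on log2FC, trend-shrunk dispersions, independent filtering |
| `voom_lite` | quantile-normalized log-CPM | precision weights from a lowess mean-variance trend, moderated t |
| `noiseq_like` | upper quartile | non-parametric (\|M\|, D) dominance over a within-condition noise cloud |
| `eb_nb` | median | beta–NB mixture (EE/DE) fitted by EM, posterior DE probabilities |

All engines share the quadratic NB mean–variance law Var = μ + φμ². A
synthetic-data module generates two-condition NB counts with configurable
group sizes, DE fraction, fold changes, gene-wise dispersion and unequal
library sizes, including presets matching common breast-cancer contrast
designs (42 vs 21, 42 vs 30, 5 vs 5). Externally computed result tables
(e.g. from Bioconductor tools) can be scored through the identical
evaluation stack via `load_external_results`.

## Worked example

```python
from dgerobust import (ENGINES, SimulationConfig, SubsampleSpec,
                       depth_experiment, generate_dataset)

cm, _ = generate_dataset(SimulationConfig(n_genes=600, n_samples_per_group=(8, 8), seed=2))
spec = SubsampleSpec(fractions=(1.0, 0.5, 0.25, 0.1), iterations=3, master_seed=2)
rel = depth_experiment(cm, sorted(ENGINES), spec)
print(rel[rel.regime == "no_fold"].groupby(["engine", "f"]).rel_fdr.mean().unstack("f").round(4))
```

```
f              0.10    0.25    0.50  1.00
engine
eb_nb        0.0504  0.0395  0.0294   0.0
nb_exact     0.0368  0.0345  0.0218   0.0
nb_wald      0.0360  0.0244  0.0233   0.0
noiseq_like  0.0000  0.0000  0.0000   0.0
voom_lite    0.0406  0.0352  0.0403   0.0
```

Relative FDR is exactly 0 at *f* = 1 (the reference is compared with
itself) and grows as libraries get shallower; the growth rate is the
engine's depth sensitivity. Here the non-parametric noise-cloud engine is
the most depth-robust — its conservative, high-expression-dominated calls
barely move when reads are lost — while the parametric engines trade that
stability for far more calls. The `examples/` directory holds runnable
scripts for each capability (simulation and thinning, engine runs, relative
FDR curves, slope populations with Friedman/Conover output).

A thin CLI mirrors the pipeline stages:

```bash
dgerobust simulate --genes 2000 --group-sizes 20,20 --seed 1 --out-dir out/sim
dgerobust thin --counts out/sim/counts.tsv --samples out/sim/samples.tsv \
    --fractions 1.0,0.5,0.1 --iterations 5 --seed 1 --out-dir out/thin
dgerobust all --config config.yaml --seed 1 --out-dir out/full
```

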