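"""Synthetic two-condition RNA-seq count generator with known DE structure.

Counts follow a negative binomial with the quadratic mean-variance law
Var = mu + phi * mu**2 (the convention shared by the NB-based DGE tools this
package benchmarks), sampled as a gamma-Poisson mixture so per-gene
dispersions are supported directly.  A configurable fraction of genes is
truly differentially expressed, split evenly between up- and down-regulation
so that library sizes are not confounded with condition.  Per-sample library
size factors emulate the uneven sequencing depth of clinical libraries.

The generator's defaults define the package's standard study conditions:
2,000 genes, 20 vs 20 samples, 20% DE genes at |log2FC| = 2, dispersion 0.2,
log-normal baseline means.  Presets mirror typical breast-cancer
case-control cohort designs (42 tumours vs 21 or 30 uninvolved tissues,
and a reduced 5 vs 5 subset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, TruthTable

__all__ = ["SimulationConfig", "generate_dataset", "preset_contrast"]

#: condition labels used by all synthetic datasets (reference first)
LEVELS = ("control", "case")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic two-group dataset.

    ``log2fc_magnitude`` may be a single positive float (every DE gene gets
    that magnitude) or a ``(low, high)`` pair sampled uniformly per DE gene.
    ``dispersion`` may be a scalar or a per-gene array.
    ``library_size_factors`` may be an explicit per-sample array or ``None``,
    in which case factors are drawn log-normal(0, ``library_size_sd``).
    """

    n_genes: int = 2000
    n_samples_per_group: tuple[int, int] = (20, 20)
    de_fraction: float = 0.2
    log2fc_magnitude: float | tuple[float, float] = 2.0
    baseline_mean_log_params: tuple[float, float] = (4.0, 1.5)
    dispersion: float | Sequence[float] = 0.2
    library_size_factors: Sequence[float] | None = None
    library_size_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        n1, n2 = self.n_samples_per_group
        if int(n1) != n1 or int(n2) != n2 or n1 <= 0 or n2 <= 0:
            raise ValueError("group sizes must be positive integers")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        mag = self.log2fc_magnitude
        if isinstance(mag, (tuple, list)):
            lo, hi = mag
            if lo <= 0 or hi < lo:
                raise ValueError("log2fc range must be positive and ordered")
        elif mag <= 0:
            raise ValueError("log2fc_magnitude must be positive")
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if (disp < 0).any():
            raise ValueError("dispersions must be >= 0")
        if disp.size not in (1, self.n_genes):
            raise ValueError("dispersion must be scalar or length n_genes")
        if self.library_size_factors is not None:
            sf = np.asarray(self.library_size_factors, dtype=float)
            if sf.size != n1 + n2 or (sf <= 0).any():
                raise ValueError("library_size_factors must be positive, one per sample")
        if self.baseline_mean_log_params[1] < 0:
            raise ValueError("baseline log-scale must be >= 0")


def _dispersion_vector(config: SimulationConfig) -> np.ndarray:
    disp = np.atleast_1d(np.asarray(config.dispersion, dtype=float))
    if disp.size == 1:
        disp = np.full(config.n_genes, float(disp[0]))
    return disp


def generate_dataset(config: SimulationConfig) -> tuple[CountMatrix, TruthTable]:
    """Draw one synthetic dataset and its ground-truth table.

    Counts[g, j] ~ NB(mean = s_j * mu_g * 2**(lfc_g * [j in case group]),
    dispersion phi_g), sampled as Poisson(Gamma(1/phi, phi*mu)).  The number
    of DE genes is floor(de_fraction * n_genes); up- and down-regulated
    genes are split as evenly as possible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 11]))
    g = config.n_genes
    n1, n2 = config.n_samples_per_group
    n = n1 + n2

    loc, scale = config.baseline_mean_log_params
    mu = rng.lognormal(mean=loc, sigma=scale, size=g)

    n_de = math.floor(config.de_fraction * g)
    de_idx = rng.choice(g, size=n_de, replace=False)
    mag = config.log2fc_magnitude
    if isinstance(mag, (tuple, list)):
        magnitudes = rng.uniform(mag[0], mag[1], size=n_de)
    else:
        magnitudes = np.full(n_de, float(mag))
    signs = np.ones(n_de)
    signs[n_de // 2 :] = -1.0  # even up/down split (extra gene goes up)
    rng.shuffle(signs)
    true_lfc = np.zeros(g)
    true_lfc[de_idx] = signs * magnitudes

    if config.library_size_factors is not None:
        size_factors = np.asarray(config.library_size_factors, dtype=float)
    else:
        size_factors = rng.lognormal(mean=0.0, sigma=config.library_size_sd, size=n)

    group2 = np.zeros(n, dtype=bool)
    group2[n1:] = True
    fc = np.where(group2[None, :], 2.0 ** true_lfc[:, None], 1.0)
    mean = mu[:, None] * fc * size_factors[None, :]

    phi = _dispersion_vector(config)
    counts = np.empty((g, n), dtype=np.int64)
    poisson_like = phi < 1e-12
    if poisson_like.any():
        counts[poisson_like] = rng.poisson(mean[poisson_like])
    over = ~poisson_like
    if over.any():
        shape = (1.0 / phi[over])[:, None]
        lam = rng.gamma(shape, mean[over] * phi[over][:, None])
        counts[over] = rng.poisson(lam)

    gene_ids = [f"g{i:05d}" for i in range(g)]
    sample_ids = [f"ctrl{i:02d}" for i in range(n1)] + [f"case{i:02d}" for i in range(n2)]
    condition = pd.Series(
        [LEVELS[0]] * n1 + [LEVELS[1]] * n2, index=sample_ids, name="condition"
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        condition,
        levels=LEVELS,
    )
    truth = TruthTable(
        pd.DataFrame(
            {"gene_id": gene_ids, "is_de": true_lfc != 0.0, "true_log2fc": true_lfc}
        )
    )
    return cm, truth


#: preset group sizes mirroring the benchmark's contrasts
_PRESETS = {
    "tnbc_like": (42, 21),
    "erpos_like": (42, 30),
    "subset_like": (5, 5),
}


def preset_contrast(name: str, **overrides) -> SimulationConfig:
    """A SimulationConfig whose group sizes match a named study contrast.

    ``tnbc_like`` -> 42 tumours vs 21 uninvolved tissues; ``erpos_like`` ->
    42 vs 30; ``subset_like`` -> the reduced 5 vs 5 design.  All other
    fields take the documented defaults unless overridden.
    """
    try:
        sizes = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; expected one of {sorted(_PRESETS)}"
        ) from None
    cfg = SimulationConfig(n_samples_per_group=sizes)
    return replace(cfg, **overrides) if overrides else cfg
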