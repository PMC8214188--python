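"""DEG calling and the robustness metrics: relative FDR, PC, MDR,
fold-change filtering, expression strata and set concordance.

The central metric is the *relative* false discovery rate.  For a given
engine, the DEGs it finds on the full-depth dataset (f = 1) play the role
of "truth"; on a depth-reduced dataset, DEGs also found at full depth are
TP, DEGs found only at reduced depth are FP, and full-depth DEGs missed at
reduced depth are MD (miss-detected).  Then

    relative FDR = FP / (FP + TP)
    MDR          = MD / TP
    PC           = 100 * (FP + MD) / TP

"Relative" because the reference is the method's own full-data output, not
biological ground truth — which the clinical datasets this design targets
do not have.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .normalization import cpm, normalized_counts

__all__ = [
    "bh_adjust",
    "DEGSet",
    "RelFDRRecord",
    "ConcordanceReport",
    "call_degs",
    "fold_filter",
    "relative_fdr",
    "expression_strata",
    "concordance",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone in the raw p-values, each adjusted value >= its raw value,
    all within [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEGSet:
    """A called set of differentially expressed genes with its provenance."""

    engine: str
    gene_ids: set
    f: float = 1.0
    r: int = 0
    regime: str = "no_fold"

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class RelFDRRecord:
    engine: str
    f: float
    r: int
    regime: str
    tp: int
    fp: int
    md: int
    rel_fdr: float
    pc: float
    mdr: float
    undefined: bool = False  # PC / MDR undefined because tp == 0

    def as_dict(self) -> dict:
        return {
            "engine": self.engine, "f": self.f, "r": self.r, "regime": self.regime,
            "tp": self.tp, "fp": self.fp, "md": self.md, "rel_fdr": self.rel_fdr,
            "pc": self.pc, "mdr": self.mdr, "undefined": self.undefined,
        }


def call_degs(result, alpha: float = 0.05, noiseq_q: float = 0.95,
              f: float = 1.0, r: int = 0,
              eb_mode: str = "posterior_fdr") -> DEGSet:
    """Turn an engine result into a significant-DEG set.

    p-value engines: genes with BH-adjusted p < ``alpha``.  Mixture-
    posterior engines (``posterior_kind == "mixture"``): by default the
    largest posterior-ranked set whose mean miss-probability
    (1 - posterior) is <= ``alpha`` (soft posterior-FDR control matching an
    FDR = alpha target); ``eb_mode="hard"`` instead thresholds
    posterior_de >= 1 - alpha.  Noise-cloud engines
    (``posterior_kind == "noise"``): posterior_de >= ``noiseq_q`` (0.95 by
    default, a deliberately conservative documented choice).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    kept = result.kept() if hasattr(result, "kept") else result.table
    if result.posterior_kind is None:
        sig = kept.loc[kept["p_adjusted"] < alpha, "gene_id"]
    elif result.posterior_kind == "mixture" and eb_mode == "posterior_fdr":
        ranked = kept.dropna(subset=["posterior_de"]).sort_values(
            "posterior_de", ascending=False, kind="mergesort"
        )
        miss = 1.0 - ranked["posterior_de"].to_numpy()
        running_mean = np.cumsum(miss) / np.arange(1, len(miss) + 1)
        n_keep = int(np.max(np.nonzero(running_mean <= alpha)[0]) + 1) \
            if (running_mean <= alpha).any() else 0
        sig = ranked["gene_id"].iloc[:n_keep]
    elif result.posterior_kind == "mixture":  # hard cutoff variant
        sig = kept.loc[kept["posterior_de"] >= 1.0 - alpha, "gene_id"]
    else:  # noise-cloud posteriors and external posterior tables
        sig = kept.loc[kept["posterior_de"] >= noiseq_q, "gene_id"]
    return DEGSet(engine=result.engine, gene_ids=set(sig), f=f, r=r, regime="no_fold")


def fold_filter(degs: DEGSet, result, c: float = 2.0) -> DEGSet:
    """Keep only DEGs with |log2 fold change| > ``c`` (two-fold filtering
    in the field's terminology uses c = 2 on the log2 scale)."""
    table = result.table.set_index("gene_id")
    missing = degs.gene_ids - set(table.index)
    if missing:
        raise ValueError(f"genes in DEG set absent from result: {sorted(missing)[:5]}")
    lfc = table.loc[list(degs.gene_ids), "log2fc"]
    kept = set(lfc.index[lfc.abs() > c])
    return DEGSet(engine=degs.engine, gene_ids=kept, f=degs.f, r=degs.r,
                  regime="two_fold")


def relative_fdr(sub: DEGSet, full: DEGSet) -> RelFDRRecord:
    """Score a reduced-depth DEG set against the same engine's full-depth set."""
    if sub.engine != full.engine or sub.regime != full.regime:
        raise ValueError(
            f"mismatched engine/regime: {sub.engine}/{sub.regime} vs "
            f"{full.engine}/{full.regime}"
        )
    tp = len(sub.gene_ids & full.gene_ids)
    fp = len(sub.gene_ids - full.gene_ids)
    md = len(full.gene_ids - sub.gene_ids)
    if fp + tp > 0:
        rel = fp / (fp + tp)
    else:
        rel = 0.0
    undefined = tp == 0
    pc = 100.0 * (fp + md) / tp if tp > 0 else np.inf if (fp + md) > 0 else 0.0
    mdr = md / tp if tp > 0 else np.inf if md > 0 else 0.0
    if undefined and fp > 0:
        rel = 1.0
    return RelFDRRecord(engine=sub.engine, f=sub.f, r=sub.r, regime=sub.regime,
                        tp=tp, fp=fp, md=md, rel_fdr=rel, pc=pc, mdr=mdr,
                        undefined=undefined)


def expression_strata(control_counts, normalization: str = "cpm",
                      condition_level: str | None = None) -> tuple[set, set]:
    """Split genes into (high, low) strata by control-sample expression.

    Per-gene mean of normalized expression across control samples; genes at
    or below the median of those means are "low", the rest "high" (ties go
    to low, so the split is deterministic).  ``control_counts`` may be a
    full CountMatrix (then ``condition_level`` selects the control group,
    defaulting to the reference level) or any counts frame.
    """
    if isinstance(control_counts, CountMatrix):
        level = condition_level or control_counts.levels[0]
        cols = control_counts.group_samples(level)
        df = control_counts.counts[cols]
    else:
        df = pd.DataFrame(control_counts)
    if df.size == 0:
        raise ValueError("empty control matrix")
    if normalization == "cpm":
        normed = cpm(df)
    else:
        normed = normalized_counts(df, method=normalization)
    means = normed.mean(axis=1)
    med = float(means.median())
    low = set(means.index[means <= med])
    high = set(means.index[means > med])
    return high, low


@dataclass
class ConcordanceReport:
    """Exact counts for every region of the inclusion-exclusion lattice of
    a collection of named gene sets."""

    set_names: list
    regions: dict = field(default_factory=dict)   # frozenset(names) -> count
    uniques: dict = field(default_factory=dict)   # name -> count unique to it

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def region(self, *names) -> int:
        return self.regions.get(frozenset(names), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(k)), "n_sets": len(k), "count": v}
            for k, v in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows)


def concordance(sets: dict) -> ConcordanceReport:
    """Tabulate every non-empty region of the set lattice.

    Each element of the union is assigned to the region labelled by the
    exact combination of sets containing it, so region counts sum to the
    union size.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("concordance needs at least two sets")
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    membership: dict = {}
    for name, s in sets.items():
        for g in s:
            membership.setdefault(g, set()).add(name)
    regions: dict = {}
    for combo_size in range(1, len(names) + 1):
        for combo in combinations(names, combo_size):
            regions[frozenset(combo)] = 0
    for g, owners in membership.items():
        regions[frozenset(owners)] += 1
    uniques = {name: regions[frozenset([name])] for name in names}
    return ConcordanceReport(set_names=names, regions=regions, uniques=uniques)
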