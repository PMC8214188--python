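"""Core data containers: count matrices with two-level condition labels.

The whole package operates on fixed gene x sample integer count matrices.
Counts are held as a pandas DataFrame (rows = genes, columns = samples)
together with a per-sample condition label taking exactly two levels.  The
first level is the reference (control) group; log2 fold changes are always
expressed as the second level over the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "TruthTable"]


@dataclass
class CountMatrix:
    """A gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame of shape (n_genes, n_samples); index are unique gene ids,
        columns unique sample ids, values non-negative integers.
    condition
        Series mapping sample id -> condition label (exactly two levels).
    levels
        The two condition levels in (reference, treatment) order.  Defaults
        to first-appearance order in ``condition``.
    """

    counts: pd.DataFrame
    condition: pd.Series
    levels: tuple[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            missing = list(self.counts.columns[self.condition.isna()])
            raise ValueError(f"samples without a condition label: {missing}")
        vals = self.counts.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.integer)):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if self.counts.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        observed = list(dict.fromkeys(self.condition))
        if self.levels is None:
            self.levels = tuple(observed)  # type: ignore[assignment]
        else:
            self.levels = tuple(self.levels)  # type: ignore[assignment]
        if len(self.levels) != 2 or set(self.levels) != set(observed):
            raise ValueError(
                f"condition must have exactly the two levels {self.levels!r}; "
                f"observed {observed!r}"
            )

    # -- basic views ---------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_samples(self, level: str) -> list[str]:
        """Sample ids belonging to one condition level."""
        if level not in self.levels:
            raise KeyError(level)
        return list(self.condition.index[self.condition == level])

    def group_sizes(self) -> tuple[int, int]:
        return tuple(len(self.group_samples(l)) for l in self.levels)  # type: ignore

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def drop_sample(self, sample_id: str) -> "CountMatrix":
        """A copy with one sample column removed (condition preserved)."""
        if sample_id not in self.counts.columns:
            raise KeyError(sample_id)
        return CountMatrix(
            self.counts.drop(columns=[sample_id]),
            self.condition.drop(sample_id),
            levels=self.levels,
        )

    def with_counts(self, new_counts: np.ndarray) -> "CountMatrix":
        """Same metadata, new count values (e.g. after thinning)."""
        df = pd.DataFrame(
            new_counts, index=self.counts.index, columns=self.counts.columns
        )
        return CountMatrix(df, self.condition, levels=self.levels)

    def validate_for_testing(self) -> None:
        """Require >=2 samples per condition (needed by every engine)."""
        n1, n2 = self.group_sizes()
        if n1 < 2 or n2 < 2:
            raise ValueError(
                f"each condition level needs >=2 samples, got {n1} and {n2}"
            )


@dataclass
class TruthTable:
    """Ground-truth differential-expression labels for synthetic data.

    ``table`` has columns gene_id, is_de (bool) and true_log2fc (0.0 for
    non-DE genes).  Only synthetic datasets carry a truth table; real
    case-control cohorts have no biological ground truth, which is exactly
    why the package's headline metric is a *relative* FDR.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "is_de", "true_log2fc"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"truth table needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def de_genes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_de"], "gene_id"])

    def lookup_log2fc(self) -> pd.Series:
        return self.table.set_index("gene_id")["true_log2fc"]
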