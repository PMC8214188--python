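"""Reading and writing count matrices, sample sheets and result tables.

Counts travel as TSV (a ``gene_id`` column plus one column per sample) or as
MatrixMarket (.mtx with sidecar gene/sample index files).  Sample sheets are
two-column TSVs (sample_id, condition).  All result tables are plain TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, TruthTable

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_truth_tsv",
    "read_truth_tsv",
]


def write_counts_tsv(cm: CountMatrix, path: str) -> None:
    out = cm.counts.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def write_sample_sheet(cm: CountMatrix, path: str) -> None:
    pd.DataFrame(
        {"sample_id": cm.sample_ids, "condition": cm.condition.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str) -> pd.Series:
    sheet = pd.read_csv(path, sep="\t")
    if not {"sample_id", "condition"}.issubset(sheet.columns):
        raise ValueError("sample sheet needs columns sample_id, condition")
    return sheet.set_index("sample_id")["condition"]


def read_counts_tsv(
    counts_path: str, samples_path: str, levels: tuple[str, str] | None = None
) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("counts TSV needs a gene_id column")
    df = df.set_index("gene_id")
    condition = read_sample_sheet(samples_path)
    return CountMatrix(df, condition, levels=levels)  # type: ignore[arg-type]


def write_counts_mtx(cm: CountMatrix, prefix: str) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.genes.tsv`` / ``.samples.tsv``."""
    mat = scipy.sparse.csr_matrix(cm.values())
    scipy.io.mmwrite(prefix + ".mtx", mat, field="integer")
    pd.Series(cm.gene_ids, name="gene_id").to_csv(
        prefix + ".genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"sample_id": cm.sample_ids, "condition": cm.condition.to_numpy()}
    ).to_csv(prefix + ".samples.tsv", sep="\t", index=False)


def read_counts_mtx(prefix: str, levels: tuple[str, str] | None = None) -> CountMatrix:
    mat = scipy.io.mmread(prefix + ".mtx")
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")["gene_id"]
    sheet = pd.read_csv(prefix + ".samples.tsv", sep="\t")
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    df = pd.DataFrame(dense.astype(np.int64), index=genes, columns=sheet["sample_id"])
    condition = sheet.set_index("sample_id")["condition"]
    return CountMatrix(df, condition, levels=levels)  # type: ignore[arg-type]


def write_truth_tsv(truth: TruthTable, path: str) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str) -> TruthTable:
    return TruthTable(pd.read_csv(path, sep="\t"))


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
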