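"""TSV readers and writers for the package's tabular interchange formats."""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .quantify import CountMatrix

SAMPLE_RE = re.compile(r"^(?P<line>[^_]+)_(?P<timepoint>[^_]+)_rep(?P<rep>\d+)$")

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_annotation_tsv",
    "read_term_tsv",
    "read_intervals_tsv",
]


def metadata_from_columns(columns) -> pd.DataFrame:
    """Parse ``<line>_<timepoint>_rep<k>`` sample names into metadata."""
    rows = []
    for col in columns:
        m = SAMPLE_RE.match(col)
        if m is None:
            raise ValueError(f"cannot parse sample name {col!r}")
        rows.append(
            {
                "line": m["line"],
                "timepoint": m["timepoint"],
                "replicate": int(m["rep"]),
            }
        )
    return pd.DataFrame(rows, index=list(columns))


def read_counts_tsv(path) -> CountMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        values=table.astype(float),
        metadata=metadata_from_columns(table.columns),
    )


def write_counts_tsv(matrix: CountMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t")


def read_annotation_tsv(path) -> dict:
    """Two-column gene -> value map (chromosome, paralog cluster, ...)."""
    table = pd.read_csv(path, sep="\t")
    gene_col, value_col = table.columns[:2]
    return dict(zip(table[gene_col], table[value_col]))


def read_term_tsv(path) -> dict:
    """Two-column gene -> term table collapsed to gene -> set of terms."""
    table = pd.read_csv(path, sep="\t")
    gene_col, term_col = table.columns[:2]
    mapping: dict = {}
    for g, t in zip(table[gene_col], table[term_col]):
        mapping.setdefault(g, set()).add(t)
    return mapping


def read_intervals_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"transcript", "sample", "start", "end", "unique", "complete"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"interval table missing columns: {sorted(missing)}")
    return table
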