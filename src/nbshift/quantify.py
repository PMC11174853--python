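"""Read QC, greatest-depth transcript quantification and normalization.

Abundance is the greatest depth of coverage over a transcript: assuming
fragments of one transcript do not overlap, the maximum number of intervals
stacked on any position equals the number of transcript copies sampled.
Coordinates are 0-based half-open.  Only uniquely and completely mapped
records enter the depth computation.  Libraries are normalized toward a
housekeeping gene, with a median-of-ratios size-factor sanity check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

QUALITY_FLOOR = 3
END_SPAN = 10
MIN_LENGTH = 30

__all__ = [
    "ReadRecord",
    "CountMatrix",
    "qc_trim",
    "max_depth_count",
    "counts_from_intervals",
    "normalize_to_housekeeping",
    "size_factors",
]


@dataclass
class ReadRecord:
    """A mapped read with per-base qualities and mapping flags."""

    qualities: list[int]
    transcript: str = ""
    start: int = 0
    end: int = 0
    unique: bool = True
    complete: bool = True

    @property
    def length(self) -> int:
        return len(self.qualities)


def qc_trim(
    read: ReadRecord,
    quality_floor: int = QUALITY_FLOOR,
    end_span: int = END_SPAN,
    min_length: int = MIN_LENGTH,
) -> ReadRecord | None:
    """Quality-trim a read; returns None when it is discarded.

    Bases are trimmed from each end until the terminal ``end_span`` bases on
    both sides all exceed ``quality_floor``; reads shorter than ``min_length``
    after trimming are discarded.
    """
    q = np.asarray(read.qualities)
    lo, hi = 0, len(q)  # half-open surviving window
    while hi - lo >= end_span and np.any(q[lo : lo + end_span] <= quality_floor):
        lo += 1
    while hi - lo >= end_span and np.any(q[hi - end_span : hi] <= quality_floor):
        hi -= 1
    if hi - lo < max(min_length, end_span):
        return None
    return ReadRecord(
        qualities=list(q[lo:hi]),
        transcript=read.transcript,
        start=read.start + lo,
        end=read.start + hi,
        unique=read.unique,
        complete=read.complete,
    )


def max_depth_count(intervals) -> int:
    """Greatest depth of coverage of half-open intervals.

    ``intervals`` is an iterable of (start, end) with start < end; only
    records passing the unique/complete filters should be passed in.
    """
    iv = list(intervals)
    if not iv:
        return 0
    arr = np.asarray(iv, dtype=float)
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("intervals must satisfy start < end")
    points = np.concatenate([arr[:, 0], arr[:, 1]])
    deltas = np.concatenate([np.ones(len(arr)), -np.ones(len(arr))])
    order = np.lexsort((deltas, points))  # ends before starts at a tie
    return int(np.max(np.cumsum(deltas[order])))


@dataclass
class CountMatrix:
    """Per-gene counts for every sample, with metadata and normalization."""

    values: pd.DataFrame  # genes x samples
    metadata: pd.DataFrame  # index = sample, columns line/timepoint/replicate
    housekeeping_gene: str | None = None
    normalization_factors: pd.Series | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.metadata.index):
            raise ValueError("sample columns must match metadata index")
        if (np.asarray(self.values) < 0).any():
            raise ValueError("counts must be nonnegative")

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            values=self.values.copy(),
            metadata=self.metadata.copy(),
            housekeeping_gene=self.housekeeping_gene,
            normalization_factors=(
                None
                if self.normalization_factors is None
                else self.normalization_factors.copy()
            ),
        )


def counts_from_intervals(
    intervals: pd.DataFrame,
    metadata: pd.DataFrame,
    genes=None,
) -> CountMatrix:
    """Greatest-depth counts per (gene, sample) from an alignment table.

    ``intervals`` columns: transcript, sample, start, end, unique, complete.
    Non-unique or incompletely mapped records are excluded before the depth
    computation.
    """
    passing = intervals[
        intervals["unique"].astype(bool) & intervals["complete"].astype(bool)
    ]
    samples = list(metadata.index)
    if genes is None:
        genes = sorted(intervals["transcript"].unique())
    values = pd.DataFrame(0, index=genes, columns=samples, dtype=float)
    for (gene, sample), grp in passing.groupby(["transcript", "sample"]):
        values.loc[gene, sample] = max_depth_count(
            list(zip(grp["start"], grp["end"]))
        )
    return CountMatrix(values=values, metadata=metadata.loc[samples])


def normalize_to_housekeeping(raw: CountMatrix, hk_gene: str) -> CountMatrix:
    """Scale each sample so the housekeeping gene is constant across samples.

    The reference level is the geometric mean of the housekeeping counts, so
    the result is symmetric in the samples and the operation idempotent.
    """
    if hk_gene not in raw.values.index:
        raise ValueError(f"housekeeping gene {hk_gene!r} not in matrix")
    hk = raw.values.loc[hk_gene]
    zero = hk[hk <= 0]
    if len(zero):
        raise ValueError(
            f"zero housekeeping count in sample(s): {', '.join(map(str, zero.index))}"
        )
    reference = float(np.exp(np.mean(np.log(hk))))
    factors = reference / hk
    out = raw.copy()
    out.values = raw.values * factors
    out.housekeeping_gene = hk_gene
    out.normalization_factors = factors
    return out


def size_factors(normalized: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style sanity check).

    Genes with a zero in any sample are excluded from the reference.  On
    housekeeping-normalized null data both mean and median of the factors
    should be about 1.
    """
    vals = normalized.values
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    nonzero = vals[(vals > 0).all(axis=1)]
    if nonzero.empty:
        raise ValueError("no gene is nonzero in all samples")
    log_ref = np.log(nonzero).mean(axis=1)
    ratios = np.log(nonzero).sub(log_ref, axis=0)
    return np.exp(ratios.median(axis=0))
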