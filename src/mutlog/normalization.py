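"""Coverage-based size factors for cross-sample mutation-count comparison.

Detection of a somatic mutation depends on the read depth at its position,
so raw per-sample mutation counts are not comparable across libraries of
different depth. The correction: per target interval, coverage is
``read_length * n_reads / interval_length``; per interval the geometric
mean of coverage across samples is the reference; each sample's size
factor is the arithmetic mean over intervals of its coverage / reference
ratio, and normalized counts are raw counts divided by the size factor.
The arithmetic mean of ratios is deliberate — the median-of-ratios variant
(as in DESeq2) is available behind ``method="median"`` for robustness
comparisons.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import NormalizationError

logger = logging.getLogger(__name__)


def interval_coverage(read_length: float, n_reads: float, interval_length: float) -> float:
    """Coverage of one interval: read length x read count / interval length."""
    if interval_length <= 0:
        raise ValueError(f"interval_length must be positive, got {interval_length}")
    if read_length <= 0:
        raise ValueError(f"read_length must be positive, got {read_length}")
    if n_reads < 0:
        raise ValueError(f"n_reads must be nonnegative, got {n_reads}")
    return read_length * n_reads / interval_length


@dataclass
class CoverageMatrix:
    """Per-sample, per-target-interval coverage (depth units).

    ``values``: DataFrame indexed by sample_id with one column per interval.
    ``interval_lengths``: bp length of each interval, same column order.
    """

    values: pd.DataFrame
    interval_lengths: pd.Series

    def __post_init__(self) -> None:
        self.interval_lengths = self.interval_lengths.reindex(self.values.columns)
        if self.interval_lengths.isna().any():
            raise ValueError("interval_lengths missing entries for some intervals")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("coverage values must be nonnegative")

    @classmethod
    def from_read_counts(
        cls, read_counts: pd.DataFrame, interval_lengths: pd.Series, read_length: float
    ) -> "CoverageMatrix":
        lengths = interval_lengths.reindex(read_counts.columns)
        cov = read_counts.mul(read_length).div(lengths, axis=1)
        return cls(values=cov, interval_lengths=lengths)

    def to_tsv(self, path: str) -> None:
        # long-friendly layout: interval rows, sample columns
        out = self.values.T.copy()
        out.insert(0, "length", self.interval_lengths)
        out.index.name = "interval_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str) -> "CoverageMatrix":
        df = pd.read_csv(path, sep="\t", index_col="interval_id")
        lengths = df.pop("length")
        return cls(values=df.T, interval_lengths=lengths)


@dataclass
class SizeFactorTable:
    """Per-sample size factors and the number of usable intervals."""

    factors: pd.Series  # sample_id -> factor (> 0)
    n_intervals_used: int

    def to_tsv(self, path: str) -> None:
        out = self.factors.rename("size_factor").to_frame()
        out.index.name = "sample_id"
        out["n_intervals_used"] = self.n_intervals_used
        out.to_csv(path, sep="\t")


def size_factors(matrix: CoverageMatrix, method: str = "mean") -> SizeFactorTable:
    """Size factors from the coverage matrix.

    Intervals with zero coverage in any sample are excluded (their geometric
    mean would be zero); the exclusion count is logged. The per-interval
    geometric mean is computed in log space, so the result is invariant to
    sample ordering and safe on long interval lists.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"method must be 'mean' or 'median', got {method!r}")
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise NormalizationError("size factors need at least 2 samples")
    usable = (vals > 0).all(axis=0)
    n_used = int(usable.sum())
    n_dropped = vals.shape[1] - n_used
    if n_dropped:
        logger.info("size_factors: excluded %d zero-coverage intervals", n_dropped)
    if n_used == 0:
        raise NormalizationError(
            "no interval has positive coverage in every sample; "
            "consider a fallback size factor of 1.0"
        )
    logv = np.log(vals[:, usable])
    log_gmean = logv.mean(axis=0)  # per-interval geometric mean, log space
    ratios = np.exp(logv - log_gmean)  # sample x interval
    agg = np.mean if method == "mean" else np.median
    factors = pd.Series(agg(ratios, axis=1), index=matrix.values.index, name="size_factor")
    return SizeFactorTable(factors=factors, n_intervals_used=n_used)


def normalize_counts(
    snv_counts: Mapping[str, float] | pd.Series, factors: SizeFactorTable
) -> pd.DataFrame:
    """Raw and depth-normalized counts per sample: normalized = raw / factor."""
    counts = pd.Series(dict(snv_counts) if not isinstance(snv_counts, pd.Series) else snv_counts)
    missing = [s for s in counts.index if s not in factors.factors.index]
    if missing:
        raise KeyError(f"no size factor for sample(s): {missing}")
    out = pd.DataFrame(
        {
            "raw_count": counts,
            "size_factor": factors.factors[counts.index],
        }
    )
    out["normalized_count"] = out["raw_count"] / out["size_factor"]
    out.index.name = "sample_id"
    return out
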