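"""Read-level comparisons between a whole (GT) sample and a split/merged one.

Covers: unique/redundant read accounting (including fragments exclusive to
one setting), per-position nucleotide-composition chi-square tests,
depth-guideline abundance-ratio distributions binned on abundance, and
scaled per-window coverage differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .readset import ReadSet

__all__ = [
    "BinnedStat",
    "UniqueCounts",
    "unique_read_counts",
    "composition_chisq",
    "abundance_log_ratios",
    "window_differences",
]


@dataclass
class BinnedStat:
    """Values grouped into unit-width (by default) bins on a log2 axis."""

    edges: np.ndarray  # len = n_bins + 1, non-overlapping, covers the data
    values: list[np.ndarray]  # one array per bin
    guideline: Optional[float] = None
    table: Optional[pd.DataFrame] = None  # per-item detail, when available

    def __post_init__(self):
        if len(self.values) != len(self.edges) - 1:
            raise ValueError("need one value list per bin")

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(v) for v in self.values])

    def summary(self) -> pd.DataFrame:
        rows = []
        for lo, hi, vals in zip(self.edges[:-1], self.edges[1:], self.values):
            v = np.asarray(vals, dtype=float)
            v = v[~np.isnan(v)]
            rows.append(
                {
                    "bin_left": lo,
                    "bin_right": hi,
                    "count": len(v),
                    "median": np.median(v) if len(v) else np.nan,
                    "q1": np.percentile(v, 25) if len(v) else np.nan,
                    "q3": np.percentile(v, 75) if len(v) else np.nan,
                }
            )
        df = pd.DataFrame(rows)
        if self.guideline is not None:
            df["guideline"] = self.guideline
        return df


def _bin_values(x: np.ndarray, y: np.ndarray, bin_width: float = 1.0):
    """Unit-width bins on x covering the observed range; returns (edges, grouped y)."""
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    values = [y[idx == b] for b in range(len(edges) - 1)]
    return edges, values


@dataclass(frozen=True)
class UniqueCounts:
    unique: int
    total: int
    exclusive_a: Optional[int] = None  # distinct sequences only in the first set
    exclusive_b: Optional[int] = None  # distinct sequences only in the second set

    def __iter__(self):  # allows `unique, total = unique_read_counts(rs)`
        return iter((self.unique, self.total))


def unique_read_counts(rs: ReadSet, other: Optional[ReadSet] = None) -> UniqueCounts:
    """Non-redundant (unique) and redundant (total) read counts.

    With a second ReadSet, also reports the number of distinct sequences
    exclusive to each sample (fragments present in only one setting).
    """
    if other is None:
        return UniqueCounts(rs.n_unique, rs.n)
    seqs_a = set(rs.multiplicity)
    seqs_b = set(other.multiplicity)
    return UniqueCounts(
        rs.n_unique,
        rs.n,
        exclusive_a=len(seqs_a - seqs_b),
        exclusive_b=len(seqs_b - seqs_a),
    )


def _base_counts(rs: ReadSet) -> np.ndarray:
    """Positions x 4 matrix of A/C/G/T counts over all read instances."""
    arr = np.frombuffer("".join(rs.sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(rs.n, -1)
    return np.stack([(arr == b).sum(axis=0) for b in b"ACGT"], axis=1)


def composition_chisq(a: ReadSet, b: ReadSet, alpha: float = 0.05) -> pd.DataFrame:
    """Per-position chi-square tests on A/C/G/T frequencies of two samples.

    One 4x2 contingency test per read position; Benjamini-Hochberg adjustment
    across positions.  Returns a position-indexed frame with the statistic,
    raw and adjusted p-values and a significance flag at ``alpha``.
    """
    if a.read_length != b.read_length:
        raise ValueError("mixed read lengths; standardise the reads first")
    ca, cb = _base_counts(a), _base_counts(b)
    stats, pvals = [], []
    for pos in range(ca.shape[0]):
        table = np.stack([ca[pos], cb[pos]], axis=1)
        table = table[table.sum(axis=1) > 0]  # bases absent in both carry no dof
        if table.shape[0] < 2:
            stats.append(0.0)
            pvals.append(1.0)
            continue
        stat, p, _, _ = chi2_contingency(table, correction=False)
        stats.append(float(stat))
        pvals.append(float(p))
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "position": np.arange(len(stats)),
            "chi2": stats,
            "pval": pvals,
            "padj": padj,
            "significant": padj < alpha,
        }
    )


def abundance_log_ratios(
    a: ReadSet, b: ReadSet, bin_width: float = 1.0
) -> BinnedStat:
    """Per-sequence log2 abundance ratios b/a, binned on log2 abundance in a.

    Only sequences with non-zero count in *both* samples enter.  The
    guideline is the expected ratio under pure depth scaling,
    ``log2(N_b / N_a)``; deviations from it reveal abundance-dependent
    over/under-representation.
    """
    ma, mb = a.multiplicity, b.multiplicity
    shared = [s for s in ma if s in mb]
    if not shared:
        raise ValueError("no sequences shared between the two samples")
    m_a = np.array([ma[s] for s in shared], dtype=float)
    m_b = np.array([mb[s] for s in shared], dtype=float)
    ratios = np.log2(m_b / m_a)
    log_abn = np.log2(m_a)
    edges, values = _bin_values(log_abn, ratios, bin_width)
    table = pd.DataFrame(
        {"sequence": shared, "m_a": m_a, "m_b": m_b, "log2_ratio": ratios, "log2_abundance": log_abn}
    )
    return BinnedStat(
        edges=edges,
        values=values,
        guideline=float(np.log2(b.n / a.n)),
        table=table,
    )


def window_differences(
    cov_a: np.ndarray,
    cov_b: np.ndarray,
    window: int = 100,
    threshold: float = 0.2,
    step: int | None = None,
) -> pd.DataFrame:
    """Scaled per-window coverage differences between two samples.

    Windows are ``window``-nt tiles (``step`` defaults to the window size,
    i.e. non-overlapping).  Per window the scaled difference is

        d_w = (mean_a - mean_b) / (mean_a + mean_b),  0 when both are 0,

    so d_w in [-1, 1] and positive values mean higher coverage in sample A
    (the "whole" slot).  Rows carry the window abundance bin
    (log2 of the combined mean) and a flag for |d_w| > threshold.
    """
    cov_a = np.asarray(cov_a, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    if cov_a.shape != cov_b.shape:
        raise ValueError("coverage vectors must have equal length")
    if window > len(cov_a):
        raise ValueError("window longer than the coverage vector")
    step = step or window
    starts = np.arange(0, len(cov_a) - window + 1, step)
    mean_a = np.array([cov_a[s : s + window].mean() for s in starts])
    mean_b = np.array([cov_b[s : s + window].mean() for s in starts])
    total = mean_a + mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(total > 0, (mean_a - mean_b) / total, 0.0)
    abundance = np.where(total > 0, np.log2(total / 2 + 1), 0.0)
    return pd.DataFrame(
        {
            "start": starts,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "diff": d,
            "log2_abundance": abundance,
            "abundance_bin": np.floor(abundance).astype(int),
            "flagged": np.abs(d) > threshold,
        }
    )
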