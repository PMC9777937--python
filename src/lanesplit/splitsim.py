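"""Across-lane splitting simulator and its analytic companion.

A library sequenced across ``k`` lanes is modelled by drawing ``k``
subsamples *without replacement* from the ground-truth (GT) read multiset and
concatenating them.  Each subsample is an independent draw from the full GT
record list, so the same GT read can recur across subsamples — this is the
mechanism that erodes read diversity: a read that lands in two subsamples is
duplicated in the concatenation while some other read is lost entirely.

Three equivalent levels are provided:

* :func:`split_reads` — record-level simulation on a :class:`ReadSet`;
* :func:`split_counts` — count-level simulation: each subsample is one
  multivariate-hypergeometric draw over distinct sequences; distributionally
  identical to ``split_reads`` and orders of magnitude faster;
* :func:`expected_unique` — the exact expectation of the number of distinct
  sequences recovered, from the hypergeometric absence probability

  .. math::

     P(\\text{absent}) = \\prod_j \\binom{N-m}{s_j} \\Big/ \\binom{N}{s_j}

  for a sequence of multiplicity :math:`m` with subsample sizes
  :math:`s_1 \\dots s_k` out of depth :math:`N`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .readset import ReadSet

__all__ = [
    "SplitSpec",
    "SplitResult",
    "split_reads",
    "split_counts",
    "expected_unique",
    "expected_recovery",
    "recovery_ratio",
    "split_count_matrix",
    "subsample_counts",
    "mc_unique_counts",
]


@dataclass(frozen=True)
class SplitSpec:
    """Definition of one splitting experiment.

    Attributes
    ----------
    k : number of lanes/subsamples (>= 1).
    proportions : k positive fractions summing to 1.
    n_iterations : number of independent repetitions of the experiment.
    seed : master seed; child generators are derived per (iteration, lane).
    """

    k: int
    proportions: tuple[float, ...]
    n_iterations: int = 1
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "proportions", tuple(float(p) for p in self.proportions))
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.proportions) != self.k:
            raise ValueError("need exactly k proportions")
        if any(p <= 0 for p in self.proportions):
            raise ValueError("proportions must be positive")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @classmethod
    def equal(cls, k: int, n_iterations: int = 1, seed: int = 0) -> "SplitSpec":
        """Equal-proportion split: each lane receives N/k reads."""
        return cls(k=k, proportions=tuple([1.0 / k] * k), n_iterations=n_iterations, seed=seed)

    def subsample_sizes(self, n: int) -> np.ndarray:
        """Lane sizes: floor(p_j * N), remainder assigned to the last lane."""
        sizes = np.floor(np.asarray(self.proportions) * n).astype(int)
        sizes[-1] += n - sizes.sum()
        if (sizes <= 0).any():
            raise ValueError(f"degenerate split: subsample sizes {sizes.tolist()} for N={n}")
        return sizes


@dataclass
class SplitResult:
    """Output of one splitting iteration."""

    subsamples: list[ReadSet]
    concatenated: ReadSet
    spec: SplitSpec
    iteration: int

    @property
    def sizes(self) -> list[int]:
        return [rs.n for rs in self.subsamples]


def _child_rng(seed: int, iteration: int, lane: int) -> np.random.Generator:
    # SeedSequence spawning keeps lanes/iterations statistically independent
    return np.random.default_rng(np.random.SeedSequence((seed, iteration, lane)))


def split_reads(gt: ReadSet, spec: SplitSpec, iteration: int = 0) -> SplitResult:
    """Simulate one across-lane split of ``gt``.

    Each of the ``k`` subsamples is an independent without-replacement draw of
    ``s_j`` records from the *full* GT record list; the concatenation of the
    subsamples is the split (S) sample.  Deterministic given
    ``(spec.seed, iteration)``.
    """
    n = gt.n
    if n < spec.k:
        raise ValueError("GT depth smaller than number of splits")
    if iteration >= spec.n_iterations:
        raise ValueError("iteration index out of range for this spec")
    sizes = spec.subsample_sizes(n)
    subsamples = []
    cat_records: list[tuple[str, str]] = []
    for j, s_j in enumerate(sizes):
        rng = _child_rng(spec.seed, iteration, j)
        idx = rng.choice(n, size=int(s_j), replace=False)
        recs = [(f"{gt.ids[i]}/l{j}", gt.sequences[i]) for i in idx]
        subsamples.append(ReadSet(recs))
        cat_records.extend(recs)
    return SplitResult(
        subsamples=subsamples,
        concatenated=ReadSet(cat_records),
        spec=spec,
        iteration=iteration,
    )


def split_counts(
    multiplicities: Sequence[int] | np.ndarray,
    sizes: Sequence[int] | np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Count-level split: per-sequence counts in the concatenated S sample.

    Each subsample of size ``s_j`` is one multivariate-hypergeometric draw
    over the distinct sequences with the given multiplicities; the returned
    vector is the sum of the draws.  Distributionally identical to
    :func:`split_reads` restricted to the multiplicity view.
    """
    m = np.asarray(multiplicities, dtype=np.int64)
    sizes = np.asarray(sizes, dtype=np.int64)
    if (m < 0).any():
        raise ValueError("multiplicities must be non-negative")
    if (sizes < 0).any():
        raise ValueError("subsample sizes must be non-negative")
    n = int(m.sum())
    if (sizes > n).any():
        raise ValueError("subsample size exceeds total depth")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.zeros_like(m)
    for s_j in sizes:
        out += rng.multivariate_hypergeometric(m, int(s_j))
    return out


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def expected_unique(
    multiplicities: Sequence[int] | np.ndarray, sizes: Sequence[int] | np.ndarray
) -> float:
    """Exact expected number of distinct sequences recovered by a split.

    For each distinct sequence of multiplicity ``m`` the probability of being
    absent from every subsample is ``prod_j C(N-m, s_j) / C(N, s_j)``; the
    expectation sums the complements.  Computed with log-gamma for stability.
    """
    m = np.asarray(multiplicities, dtype=np.float64)
    sizes = np.asarray(sizes, dtype=np.float64)
    if (m < 1).any():
        raise ValueError("multiplicities must be >= 1")
    n = m.sum()
    if (sizes > n).any():
        raise ValueError("subsample size exceeds total depth")
    if (sizes < 0).any():
        raise ValueError("subsample sizes must be non-negative")
    # log P(absent from lane j) = log C(N-m, s_j) - log C(N, s_j); -inf if s_j > N-m
    log_p_absent = np.zeros_like(m)
    for s_j in sizes:
        with np.errstate(invalid="ignore"):
            term = _log_comb(n - m, s_j) - _log_comb(n, s_j)
        term = np.where(n - m < s_j, -np.inf, term)
        log_p_absent = log_p_absent + term
    return float(np.sum(1.0 - np.exp(log_p_absent)))


def expected_recovery(
    multiplicities: Sequence[int] | np.ndarray, sizes: Sequence[int] | np.ndarray
) -> float:
    """Expected recovery ratio: expected unique in S over unique in GT."""
    m = np.asarray(multiplicities)
    return expected_unique(m, sizes) / len(m)


def recovery_ratio(gt: ReadSet, s: ReadSet) -> float:
    """Unique reads in the S sample divided by unique reads in the GT sample."""
    u_gt = gt.n_unique
    if u_gt == 0:
        raise ValueError("GT sample has no reads")
    return s.n_unique / u_gt


def subsample_counts(
    multiplicities: Sequence[int] | np.ndarray,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Subsample a count vector to a lower total depth, without replacement."""
    m = np.asarray(multiplicities, dtype=np.int64)
    if depth > m.sum():
        raise ValueError("requested depth exceeds available reads")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(m, int(depth))


def mc_unique_counts(
    multiplicities: Sequence[int] | np.ndarray,
    sizes: Sequence[int] | np.ndarray,
    n_iterations: int,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo unique counts of the concatenated sample over iterations."""
    m = np.asarray(multiplicities, dtype=np.int64)
    rng = np.random.default_rng(seed)
    out = np.empty(n_iterations, dtype=np.int64)
    for i in range(n_iterations):
        out[i] = int((split_counts(m, sizes, rng) > 0).sum())
    return out


def split_count_matrix(
    cm: pd.DataFrame, spec: SplitSpec, iteration: int = 0
) -> pd.DataFrame:
    """Apply the across-lane split to the reads backing a count matrix.

    Every count in the gene x cell (or gene x sample) matrix is treated as the
    multiplicity of one distinct read category; the split redistributes the
    fixed total depth over categories exactly as :func:`split_counts` does, so
    low-count entries can drop out while others are over-represented.
    """
    values = cm.to_numpy().ravel()
    n = int(values.sum())
    sizes = spec.subsample_sizes(n)
    rng = _child_rng(spec.seed, iteration, 0)
    split = split_counts(values, sizes, rng)
    return pd.DataFrame(
        split.reshape(cm.shape), index=cm.index, columns=cm.columns
    )
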