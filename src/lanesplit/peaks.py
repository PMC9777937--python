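"""ChIP-style peak analyses: a toy caller plus matching and concordance stats.

The caller is deliberately simple plumbing (threshold + merge + minimum
length); the scientific content is in the reciprocal-midpoint matching rule
and the length-ratio / count-reduction statistics computed on its output.

Coordinates follow the BED/narrowPeak convention: 0-based, half-open
``[start, stop)``; peak length is ``stop - start``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .readset import ReadSet

__all__ = [
    "Peak",
    "PeakSet",
    "call_peaks_toy",
    "match_peaks",
    "PeakMatch",
    "peak_length_ratios",
    "peak_count_delta",
    "coverage_from_reads",
    "read_narrowpeak",
    "write_narrowpeak",
]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    stop: int
    amplitude: float = 0.0

    def __post_init__(self):
        if self.start >= self.stop:
            raise ValueError("peak start must be < stop (half-open interval)")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def midpoint(self) -> int:
        return (self.start + self.stop) // 2

    @property
    def length(self) -> int:
        return self.stop - self.start

    def contains(self, pos: int) -> bool:
        """Half-open membership: start <= pos < stop."""
        return self.start <= pos < self.stop


@dataclass
class PeakSet:
    peaks: list[Peak]
    sample_id: str = ""

    def __post_init__(self):
        if any(
            a.chrom == b.chrom and a.start > b.start
            for a, b in zip(self.peaks, self.peaks[1:])
        ):
            warnings.warn("peaks were not sorted by start; sorting", stacklevel=2)
            self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([p.length for p in self.peaks])


def call_peaks_toy(
    cov: np.ndarray,
    threshold: float,
    min_length: int = 1,
    merge_gap: int = 0,
    chrom: str = "chr1",
    sample_id: str = "",
) -> PeakSet:
    """Maximal runs of coverage >= threshold, with short gaps bridged.

    Runs separated by sub-threshold gaps of at most ``merge_gap`` bases are
    merged; runs shorter than ``min_length`` are dropped.  Amplitude is the
    mean coverage over the final interval.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cov = np.asarray(cov, dtype=float)
    above = cov >= threshold
    if not above.any():
        return PeakSet([], sample_id=sample_id)
    # run boundaries on the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    merged: list[list[int]] = [[int(starts[0]), int(stops[0])]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - merged[-1][1] <= merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    peaks = [
        Peak(chrom, s, e, amplitude=float(cov[s:e].mean()))
        for s, e in merged
        if e - s >= min_length
    ]
    return PeakSet(peaks, sample_id=sample_id)


@dataclass
class PeakMatch:
    """Result of reciprocal-midpoint matching between two PeakSets."""

    pairs: list[tuple[Peak, Peak]]
    unmatched_a: list[Peak]
    unmatched_b: list[Peak]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": p.chrom,
                "start_a": p.start,
                "stop_a": p.stop,
                "start_b": q.start,
                "stop_b": q.stop,
                "midpoint_distance": abs(p.midpoint - q.midpoint),
                "length_ratio": p.length / q.length,
            }
            for p, q in self.pairs
        ]
        return pd.DataFrame(rows)


def _reciprocal(p: Peak, q: Peak) -> bool:
    return p.chrom == q.chrom and q.contains(p.midpoint) and p.contains(q.midpoint)


def match_peaks(a: PeakSet, b: PeakSet) -> PeakMatch:
    """One-to-one reciprocal-midpoint matching.

    A pair ``(p, q)`` is a candidate iff the midpoint of ``p`` lies within
    ``q``'s boundaries *and vice versa* (half-open membership).  Candidates
    are resolved greedily by smallest midpoint distance, ties by lower start,
    which makes the result symmetric in its arguments.
    """
    candidates = []
    for i, p in enumerate(a):
        for j, q in enumerate(b):
            if _reciprocal(p, q):
                candidates.append((abs(p.midpoint - q.midpoint), min(p.start, q.start), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a.peaks[i], b.peaks[j]))
    unmatched_a = [p for i, p in enumerate(a) if i not in used_a]
    unmatched_b = [q for j, q in enumerate(b) if j not in used_b]
    return PeakMatch(pairs=pairs, unmatched_a=unmatched_a, unmatched_b=unmatched_b)


def peak_length_ratios(match: PeakMatch) -> pd.Series:
    """Length(sample 1) / length(sample 2) for every matched pair.

    Computed only on common (matched) peaks; the shortening effect of
    splitting is invisible on unmatched peaks.
    """
    if not match.pairs:
        raise ValueError("no matched pairs")
    return pd.Series([p.length / q.length for p, q in match.pairs], name="length_ratio")


def peak_count_delta(gt: PeakSet, sims: list[PeakSet]) -> tuple[float, float]:
    """Mean count difference |GT| - |S| over iterations, and percent decrease."""
    if len(gt) == 0:
        raise ValueError("empty GT peak set")
    deltas = np.array([len(gt) - len(s) for s in sims], dtype=float)
    return float(deltas.mean()), float(100.0 * deltas.mean() / len(gt))


def coverage_from_reads(
    rs: ReadSet, genome: str, read_length: int | None = None, dedup: bool = False
) -> np.ndarray:
    """Per-base coverage by exact placement of read sequences on a genome.

    Builds an index of all read-length substrings of the genome (first
    occurrence wins; on random toy genomes collisions are vanishingly rare)
    and increments coverage over each read's footprint.  With ``dedup=True``
    each distinct sequence contributes once regardless of its multiplicity —
    the duplicate-removal step peak callers apply before calling, which is
    where the loss of unique reads under splitting bites.
    """
    if rs.n == 0:
        return np.zeros(len(genome), dtype=np.int64)
    rl = read_length or rs.read_length
    index: dict[str, int] = {}
    for pos in range(len(genome) - rl + 1):
        sub = genome[pos : pos + rl]
        if sub not in index:
            index[sub] = pos
    starts = np.zeros(len(genome) + 1, dtype=np.int64)
    for seq, m in rs.multiplicity.items():
        pos = index.get(seq)
        if pos is None:
            continue
        w = 1 if dedup else m
        starts[pos] += w
        starts[pos + rl] -= w
    return np.cumsum(starts[:-1])


# -- narrowPeak IO (BED6+4) ------------------------------------------------

def write_narrowpeak(ps: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(ps):
            name = f"{ps.sample_id or 'peak'}_{i + 1}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.stop}\t{name}\t0\t.\t"
                f"{p.amplitude:.4f}\t-1\t-1\t{p.length // 2}\n"
            )


def read_narrowpeak(path: str | Path, sample_id: str = "") -> PeakSet:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            peaks.append(Peak(f[0], int(f[1]), int(f[2]), amplitude=float(f[6]) if len(f) > 6 else 0.0))
    return PeakSet(sorted(peaks, key=lambda p: (p.chrom, p.start)), sample_id=sample_id)
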