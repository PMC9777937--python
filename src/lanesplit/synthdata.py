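"""Synthetic inputs with the statistical structure the analyses assume.

Generators for:

* toy transcriptomes (random A/C/G/T sequences);
* read multisets with a heavy-tailed multiplicity profile — many singletons,
  a few highly duplicated reads — controlled per transcript by an expected
  instance count and a duplication parameter (mean reads per distinct
  fragment); distinct-fragment multiplicities are ``1 + Poisson(lambda - 1)``,
  which guarantees multiplicity >= 1 and a singleton-dominated tail;
* ChIP-like read sets: uniform background plus reads concentrated in enriched
  regions, with the true peak intervals returned for validation;
* clustered single-cell count matrices with planted per-cluster markers and a
  small "island" subpopulation driven by one dominant gene, mimicking a rare
  cell type whose identity hinges on a single highly specific transcript.

Every generator is bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peaks import Peak, PeakSet
from .readset import ReadSet

__all__ = [
    "Transcriptome",
    "AbundanceProfile",
    "ScTruth",
    "gen_transcriptome",
    "gen_reads",
    "gen_chip_coverage",
    "gen_sc_dataset",
    "gen_de_dataset",
    "heavy_tailed_profile",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Transcriptome:
    """Ordered map of transcript id -> nucleotide sequence (A/C/G/T)."""

    entries: dict[str, str]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("transcriptome must contain at least one transcript")
        for tid, seq in self.entries.items():
            if not seq:
                raise ValueError(f"empty sequence for {tid}")
            if set(seq) - set("ACGT"):
                raise ValueError(f"sequence for {tid} contains non-ACGT characters")

    @property
    def lengths(self) -> dict[str, int]:
        return {tid: len(s) for tid, s in self.entries.items()}

    def min_length(self) -> int:
        return min(len(s) for s in self.entries.values())

    def to_fasta(self, path: str | Path) -> None:
        records = (
            SeqRecord(Seq(seq), id=tid, description="") for tid, seq in self.entries.items()
        )
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Transcriptome":
        with open(path) as fh:
            return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")})


@dataclass
class AbundanceProfile:
    """Expected read count and duplication level per transcript.

    ``expected_counts[t]`` is the expected number of read *instances* from
    transcript ``t``; ``duplication[t]`` (>= 1) is the mean number of
    instances per distinct fragment, so the expected number of distinct
    fragments is ``expected_counts[t] / duplication[t]``.
    """

    expected_counts: dict[str, float]
    duplication: dict[str, float]

    def __post_init__(self):
        if sum(self.expected_counts.values()) <= 0:
            raise ValueError("total expected count must be positive")
        for tid, lam in self.duplication.items():
            if lam < 1:
                raise ValueError(f"duplication for {tid} must be >= 1")

    @classmethod
    def uniform(cls, tx: Transcriptome, total: float, duplication: float = 1.0):
        per = total / len(tx.entries)
        return cls(
            {tid: per for tid in tx.entries},
            {tid: duplication for tid in tx.entries},
        )


def heavy_tailed_profile(
    tx: Transcriptome,
    total: float,
    seed: int,
    lognorm_sigma: float = 1.5,
    duplication_range: tuple[float, float] = (1.0, 4.0),
) -> AbundanceProfile:
    """A realistic expression-like profile: log-normal abundances spanning
    several orders of magnitude, duplication increasing with abundance (highly
    expressed transcripts accumulate more PCR/optical duplicates)."""
    rng = np.random.default_rng(seed)
    tids = list(tx.entries)
    raw = rng.lognormal(mean=0.0, sigma=lognorm_sigma, size=len(tids))
    counts = raw / raw.sum() * total
    lo, hi = duplication_range
    ranks = counts.argsort().argsort() / max(len(tids) - 1, 1)
    dup = lo + (hi - lo) * ranks
    return AbundanceProfile(dict(zip(tids, counts)), dict(zip(tids, dup)))


@dataclass
class ScTruth:
    """Ground truth for a synthetic single-cell dataset."""

    counts: pd.DataFrame  # genes x cells, non-negative ints
    labels: pd.Series  # cell id -> cluster label
    planted_markers: dict[str, list[str]]  # cluster -> marker genes
    island_cells: list[str]
    island_driver_gene: str | None

    def __post_init__(self):
        if not self.labels.index.equals(self.counts.columns):
            raise ValueError("labels must cover exactly the cells of the count matrix")
        if not set(self.island_cells) <= set(self.counts.columns):
            raise ValueError("island cells must be a subset of the cells")
        genes = set(self.counts.index)
        for cl, ms in self.planted_markers.items():
            if not set(ms) <= genes:
                raise ValueError(f"planted markers for {cl} not all in the gene set")


def gen_de_dataset(
    n_genes: int = 2000,
    n_rep: int = 2,
    n_planted: int = 100,
    fold: float = 4.0,
    nb_dispersion: float = 0.02,
    base_mean: float = 50.0,
    base_sigma: float = 1.0,
    min_planted_mean: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two replicate groups of bulk-like NB counts with planted DE genes.

    Base means are log-normal around ``base_mean``; ``n_planted`` genes drawn
    from the moderately expressed ones (mean >= ``min_planted_mean``, so the
    planted effect is detectable in principle) are up-shifted ``fold``-fold in
    group B.  The dispersion default reflects replicates of genetically
    identical model systems (biological CV ~ 0.14).  ``n_planted=0`` gives a
    null dataset.  Returns (group A, group B, planted gene ids).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(np.log(base_mean), base_sigma, n_genes)
    mu_b = base.copy()
    planted: list[str] = []
    if n_planted:
        eligible = np.flatnonzero(base >= min_planted_mean)
        if len(eligible) < n_planted:
            raise ValueError("not enough expressed genes to plant effects in")
        idx = rng.choice(eligible, n_planted, replace=False)
        mu_b[idx] *= fold
        planted = [genes[i] for i in idx]

    def draw(mu: np.ndarray) -> np.ndarray:
        m = np.outer(mu, np.ones(n_rep))
        if nb_dispersion > 0:
            lam = rng.gamma(1.0 / nb_dispersion, m * nb_dispersion)
        else:
            lam = m
        return rng.poisson(lam)

    a = pd.DataFrame(draw(base), index=genes, columns=[f"A{r + 1}" for r in range(n_rep)])
    b = pd.DataFrame(draw(mu_b), index=genes, columns=[f"B{r + 1}" for r in range(n_rep)])
    return a, b, planted


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def gen_transcriptome(
    n_transcripts: int, length_range: tuple[int, int], seed: int
) -> Transcriptome:
    """Random transcriptome with ids ``T0001, T0002, ...``."""
    lo, hi = length_range
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    entries = {}
    for i in range(n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        entries[f"T{i + 1:04d}"] = _random_seq(rng, length)
    return Transcriptome(entries)


def gen_reads(
    tx: Transcriptome,
    profile: AbundanceProfile,
    read_length: int,
    seed: int,
) -> tuple[ReadSet, dict[str, str]]:
    """Draw a read multiset from a transcriptome under an abundance profile.

    Per transcript, the number of distinct fragments is Poisson with mean
    ``expected_count / duplication``; fragment start positions are uniform;
    each distinct fragment is replicated ``1 + Poisson(duplication - 1)``
    times.  Returns the reads plus the complete read-id -> transcript-id
    truth map.
    """
    if not profile.expected_counts:
        raise ValueError("empty abundance profile")
    if read_length > tx.min_length():
        raise ValueError("read length exceeds the shortest transcript")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    ridx = 0
    for tid, seq in tx.entries.items():
        expect = profile.expected_counts.get(tid, 0.0)
        if expect <= 0:
            continue
        lam = profile.duplication.get(tid, 1.0)
        n_frag = rng.poisson(expect / lam)
        if n_frag == 0:
            continue
        starts = rng.integers(0, len(seq) - read_length + 1, size=n_frag)
        mults = 1 + rng.poisson(lam - 1.0, size=n_frag)
        for start, m in zip(starts, mults):
            frag = seq[start : start + read_length]
            for _ in range(int(m)):
                rid = f"r{ridx:07d}"
                records.append((rid, frag))
                truth[rid] = tid
                ridx += 1
    return ReadSet(records), truth


def gen_chip_coverage(
    genome_length: int,
    peaks: list[tuple[int, int, float]],
    background_rate: float,
    read_length: int,
    seed: int,
    duplication: float = 1.0,
) -> tuple[ReadSet, PeakSet, str]:
    """ChIP-like reads: uniform background plus enriched regions.

    ``peaks`` is a list of ``(center, width, enrichment)``; ``enrichment`` is
    the expected number of read starts per base inside the peak footprint and
    ``background_rate`` the same quantity genome-wide.  Returns the reads, the
    true :class:`PeakSet` and the genome sequence (needed to re-derive read
    positions after splitting).  ``duplication`` >= 1 adds PCR-duplicate-like
    replication of distinct fragments as in :func:`gen_reads`.
    """
    rng = np.random.default_rng(seed)
    genome = _random_seq(rng, genome_length)
    true_peaks = []
    intervals = []
    for center, width, enrich in peaks:
        start = int(center - width // 2)
        stop = int(start + width)
        if start < 0 or stop > genome_length:
            raise ValueError("peak outside genome bounds")
        if enrich <= background_rate:
            raise ValueError("peak enrichment must exceed the background rate")
        intervals.append((start, stop))
        true_peaks.append(
            Peak("chr1", start, stop, amplitude=enrich * read_length)
        )
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            warnings.warn("overlapping peak definitions", stacklevel=2)

    starts: list[int] = []
    max_start = genome_length - read_length
    if background_rate > 0:
        n_bg = rng.poisson(background_rate * (max_start + 1))
        starts.extend(rng.integers(0, max_start + 1, size=n_bg).tolist())
    for (center, width, enrich), (start, stop) in zip(peaks, [(int(c - w // 2), int(c - w // 2) + w) for c, w, _ in peaks]):
        hi = min(stop - read_length, max_start)
        if hi < start:
            raise ValueError("peak narrower than read length")
        n_pk = rng.poisson(enrich * (hi - start + 1))
        starts.extend(rng.integers(start, hi + 1, size=n_pk).tolist())

    records: list[tuple[str, str]] = []
    ridx = 0
    for pos in starts:
        m = 1 + rng.poisson(duplication - 1.0) if duplication > 1 else 1
        frag = genome[pos : pos + read_length]
        for _ in range(int(m)):
            records.append((f"c{ridx:07d}", frag))
            ridx += 1
    return (
        ReadSet(records),
        PeakSet(sorted(true_peaks, key=lambda p: p.start), sample_id="truth"),
        genome,
    )


def gen_sc_dataset(
    n_cells: int = 500,
    n_genes: int = 1000,
    cluster_weights: tuple[float, ...] = (0.4, 0.3, 0.3),
    markers_per_cluster: int = 25,
    island_size: int = 40,
    nb_dispersion: float = 0.1,
    seed: int = 0,
    marker_fold_range: tuple[float, float] = (1.3, 8.0),
    island_driver_fold: float = 50.0,
    base_mean_sigma: float = 1.2,
    base_mean_scale: float = 4.0,
) -> ScTruth:
    """Clustered single-cell counts with planted markers and a driver island.

    Cells are assigned to clusters by ``cluster_weights``; each cluster gets
    ``markers_per_cluster`` disjoint marker genes whose expression is
    up-shifted by fold changes log-spaced over ``marker_fold_range`` (strong
    and borderline markers alike, as in real data).  The last ``island_size``
    cells form a separate small subpopulation based on cluster 0's profile
    plus one dominant driver gene (``island_driver_fold`` up-shift, the SPP1
    analogue) and a handful of mildly elevated companions.  Counts are
    negative-binomial (variance ``mu + dispersion * mu^2``); ``dispersion=0``
    gives Poisson.
    """
    if island_size >= n_cells:
        raise ValueError("island_size must be smaller than n_cells")
    weights = np.asarray(cluster_weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("cluster weights must sum to 1")
    n_clusters = len(weights)
    n_marker_blocks = n_clusters + (1 if island_size > 0 else 0)
    if markers_per_cluster * n_marker_blocks > n_genes:
        raise ValueError("not enough genes for the requested markers")

    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    cells = [f"C{i + 1:05d}" for i in range(n_cells)]
    clusters = [f"K{j}" for j in range(n_clusters)]

    n_main = n_cells - island_size
    main_labels = rng.choice(n_clusters, size=n_main, p=weights)
    labels = pd.Series(
        [clusters[j] for j in main_labels] + ["island"] * island_size,
        index=cells,
        name="cluster",
    )
    island_cells = cells[n_main:]

    base = rng.lognormal(mean=np.log(base_mean_scale), sigma=base_mean_sigma, size=n_genes)
    folds = np.geomspace(marker_fold_range[1], marker_fold_range[0], markers_per_cluster)

    # disjoint marker blocks, one per cluster (+ island companions)
    order = rng.permutation(n_genes)
    planted: dict[str, list[str]] = {}
    fold_matrix = np.ones((n_genes, n_clusters + 1))  # last column = island
    for j, cl in enumerate(clusters):
        block = order[j * markers_per_cluster : (j + 1) * markers_per_cluster]
        planted[cl] = [genes[g] for g in block]
        fold_matrix[block, j] = folds

    driver_gene = None
    if island_size > 0:
        fold_matrix[:, -1] = fold_matrix[:, 0]  # island inherits cluster 0's profile
        block = order[n_clusters * markers_per_cluster : (n_clusters + 1) * markers_per_cluster]
        driver = block[0]
        driver_gene = genes[driver]
        fold_matrix[driver, -1] = island_driver_fold
        companions = block[1:6]
        fold_matrix[companions, -1] = 4.0
        planted["island"] = [genes[g] for g in block[:6]]

    col_of_cell = np.concatenate([main_labels, np.full(island_size, n_clusters)])
    mu = base[:, None] * fold_matrix[:, col_of_cell]

    if nb_dispersion > 0:
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)

    return ScTruth(
        counts=pd.DataFrame(counts, index=genes, columns=cells),
        labels=labels,
        planted_markers=planted,
        island_cells=island_cells,
        island_driver_gene=driver_gene,
    )
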