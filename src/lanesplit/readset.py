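"""Read multisets with a distinct-sequence multiplicity view.

A :class:`ReadSet` models the reads of one sequencing sample as an ordered
multiset of (read id, sequence) records.  Two views matter throughout the
package:

* the *instance* view — every sequenced read counts, ``N = len(records)`` is
  the sequencing depth;
* the *multiplicity* view — distinct sequences with their instance counts
  ``m``; ``n_unique`` is the number of distinct (non-redundant) sequences.

Read identity for uniqueness is exact sequence-string equality; read ids and
qualities play no role in any statistic.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["ReadSet"]


class ReadSet:
    """An ordered multiset of reads.

    Parameters
    ----------
    records
        Iterable of ``(read_id, sequence)`` pairs.  Read ids must be unique;
        sequences may repeat (that is the point).
    """

    __slots__ = ("ids", "sequences", "_multiplicity")

    def __init__(self, records: Iterable[tuple[str, str]]):
        ids: list[str] = []
        seqs: list[str] = []
        for rid, seq in records:
            ids.append(rid)
            seqs.append(seq)
        if len(set(ids)) != len(ids):
            raise ValueError("read ids must be unique within a ReadSet")
        self.ids = ids
        self.sequences = seqs
        self._multiplicity: Optional[Counter[str]] = None

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_sequences(cls, sequences: Iterable[str], prefix: str = "r") -> "ReadSet":
        """Build a ReadSet from bare sequences, assigning sequential ids."""
        return cls((f"{prefix}{i}", s) for i, s in enumerate(sequences))

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], prefix: str = "r") -> "ReadSet":
        """Build a ReadSet from a sequence -> multiplicity mapping."""
        records = []
        i = 0
        for seq, m in counts.items():
            if m < 0:
                raise ValueError("multiplicities must be non-negative")
            for _ in range(int(m)):
                records.append((f"{prefix}{i}", seq))
                i += 1
        return cls(records)

    # -- views -------------------------------------------------------------

    @property
    def n(self) -> int:
        """Total number of read instances (sequencing depth)."""
        return len(self.sequences)

    @property
    def multiplicity(self) -> Counter:
        """Distinct sequence -> instance count."""
        if self._multiplicity is None:
            self._multiplicity = Counter(self.sequences)
        return self._multiplicity

    @property
    def n_unique(self) -> int:
        """Number of distinct (non-redundant) sequences."""
        return len(self.multiplicity)

    @property
    def read_length(self) -> int:
        """Common read length; raises if reads are of mixed length."""
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("ReadSet contains mixed read lengths")
        if not lengths:
            raise ValueError("ReadSet is empty")
        return lengths.pop()

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ReadSet(n={self.n}, n_unique={self.n_unique})"

    # -- FASTQ IO ----------------------------------------------------------

    def to_fastq(self, path: str | Path) -> None:
        """Write 4-line FASTQ records; qualities are constant 'I' (Q40)."""
        records = (
            SeqRecord(
                Seq(seq),
                id=rid,
                description="",
                letter_annotations={"phred_quality": [40] * len(seq)},
            )
            for rid, seq in self
        )
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fastq")

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        with open(path) as fh:
            return cls((rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq"))
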