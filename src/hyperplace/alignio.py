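"""Aligned-sequence container and FASTA round-trip.

An :class:`Alignment` is an ordered, id-keyed set of equal-length rows over
the nucleotide alphabet {A, C, G, T, -}.  IUPAC ambiguity codes are accepted
on input and treated as fully uninformative (like gaps) when encoded.
Reading and writing go through Biopython's FASTA parser so that record ids
match backbone-tree leaf labels verbatim.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment", "read_fasta", "write_fasta"]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
# gap characters plus IUPAC ambiguity codes, all encoded as uninformative
_UNINFORMATIVE = set("-.NRYSWKMBDHV?")
_LEGAL = set(_BASES) | _UNINFORMATIVE


@dataclass
class Alignment:
    """Fixed-length aligned sequences keyed by unique ids, order preserving."""

    ids: list[str]
    rows: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if self.rows and len(self.rows[0]) < 1:
            raise ValueError("alignment length must be >= 1")
        for sid, row in zip(self.ids, self.rows):
            bad = set(row) - _LEGAL
            if bad:
                pos = next(i for i, ch in enumerate(row) if ch in bad)
                raise ValueError(
                    f"illegal character {row[pos]!r} at position {pos} in sequence {sid!r}"
                )
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, sid: str) -> bool:
        return sid in self._index

    def __getitem__(self, sid: str) -> str:
        return self.rows[self._index[sid]]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.rows))

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Sub-alignment restricted to ``ids``, in the given order."""
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise KeyError(f"ids not present in alignment: {missing}")
        return Alignment(list(ids), [self.rows[self._index[i]] for i in ids])

    def one_hot(self) -> np.ndarray:
        """Encode all rows; shape (N, 4, L).  See :func:`encode_one_hot`."""
        from .encoder import encode_one_hot

        return np.stack([encode_one_hot(r) for r in self.rows])

    def duplicate_groups(self) -> list[list[str]]:
        """Groups of ids sharing an identical row (groups of size >= 2)."""
        seen: dict[str, list[str]] = {}
        for sid, row in self:
            seen.setdefault(row, []).append(sid)
        return [g for g in seen.values() if len(g) > 1]

    @classmethod
    def from_fasta(cls, source: str | Path | io.TextIOBase) -> "Alignment":
        return read_fasta(source)

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(self, path)


def read_fasta(source: str | Path | io.TextIOBase) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {source}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: Alignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(row), id=sid, description="") for sid, row in aln]
    SeqIO.write(records, str(path), "fasta")


def concatenate(alignments: Iterable[Alignment]) -> Alignment:
    """Concatenate alignments over the same id set (multi-gene input)."""
    alns = list(alignments)
    if not alns:
        raise ValueError("need at least one alignment")
    ids = alns[0].ids
    for a in alns[1:]:
        if set(a.ids) != set(ids):
            raise ValueError("alignments have differing id sets")
    return Alignment(list(ids), ["".join(a[sid] for a in alns) for sid in ids])
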