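"""Family alignments and residue/column coordinate maps.

A *family* is a named multiple sequence alignment (MSA) of protein
sequences, e.g. one CATH FunFam.  Every statistic in this package is
computed on alignment columns, so the two coordinate systems — 1-based
residue indices in the ungapped sequence and 1-based MSA columns — and the
bidirectional mapping between them live here.

Both ``-`` and ``.`` are accepted as gap characters on input and
normalised to ``-``; lowercase residues (Stockholm insert states) are
uppercased and treated as ordinary residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterator

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError, InsufficientMembersError

__all__ = [
    "GAP",
    "AlignedSequence",
    "FamilyAlignment",
    "read_alignment",
    "write_alignment",
    "column_of_residue",
    "residue_at_column",
]

GAP = "-"

log = logging.getLogger(__name__)


def _normalize(aligned: str) -> str:
    return aligned.replace(".", GAP).upper()


@dataclass(frozen=True)
class AlignedSequence:
    """One member of a family alignment.

    Parameters
    ----------
    protein_id
        Opaque identifier, used verbatim to join annotation/prediction
        tables to the alignment.
    aligned
        The gapped sequence string; normalised on construction.
    """

    protein_id: str
    aligned: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "aligned", _normalize(self.aligned))
        if self.length_ungapped < 1:
            raise AlignmentFormatError(
                f"sequence {self.protein_id!r} has no residues"
            )

    @cached_property
    def length_ungapped(self) -> int:
        """Number of non-gap characters."""
        return len(self.aligned) - self.aligned.count(GAP)

    @cached_property
    def ungapped(self) -> str:
        return self.aligned.replace(GAP, "")

    @cached_property
    def _res2col(self) -> tuple[int, ...]:
        return tuple(
            i + 1 for i, ch in enumerate(self.aligned) if ch != GAP
        )

    @cached_property
    def _col2res(self) -> tuple[int | None, ...]:
        out: list[int | None] = []
        r = 0
        for ch in self.aligned:
            if ch == GAP:
                out.append(None)
            else:
                r += 1
                out.append(r)
        return tuple(out)


def column_of_residue(seq: AlignedSequence, residue_index: int) -> int:
    """Return the 1-based MSA column of the ``residue_index``-th residue."""
    if not 1 <= residue_index <= seq.length_ungapped:
        raise IndexError(
            f"residue index {residue_index} out of range 1..{seq.length_ungapped} "
            f"for {seq.protein_id!r}"
        )
    return seq._res2col[residue_index - 1]


def residue_at_column(seq: AlignedSequence, column: int) -> int | None:
    """Return the 1-based residue index at ``column``, or ``None`` on a gap."""
    if not 1 <= column <= len(seq.aligned):
        raise IndexError(
            f"column {column} out of range 1..{len(seq.aligned)} "
            f"for {seq.protein_id!r}"
        )
    return seq._col2res[column - 1]


@dataclass(frozen=True)
class FamilyAlignment:
    """A named family of aligned member sequences."""

    family_id: str
    members: tuple[AlignedSequence, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise InsufficientMembersError(
                f"family {self.family_id!r} has {len(self.members)} member(s); "
                "at least 2 required"
            )
        lengths = {len(m.aligned) for m in self.members}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"family {self.family_id!r} has unequal aligned lengths {sorted(lengths)}"
            )
        ids = [m.protein_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError(
                f"family {self.family_id!r} has duplicate protein ids"
            )

    @property
    def n_columns(self) -> int:
        return len(self.members[0].aligned)

    @cached_property
    def _by_id(self) -> dict[str, AlignedSequence]:
        return {m.protein_id: m for m in self.members}

    def member(self, protein_id: str) -> AlignedSequence:
        return self._by_id[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


_FORMATS = {"fasta": "fasta", "stockholm": "stockholm"}


def read_alignment(
    path: str | Path, format: str = "fasta", family_id: str | None = None
) -> FamilyAlignment:
    """Read a family MSA from a FASTA or Stockholm file.

    Gap characters ``.`` are normalised to ``-`` and residues uppercased.
    Duplicate protein ids keep the first occurrence; the drop is logged.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), _FORMATS[format])
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc

    members: list[AlignedSequence] = []
    seen: set[str] = set()
    dropped = 0
    for rec in msa:
        if rec.id in seen:
            dropped += 1
            continue
        seen.add(rec.id)
        members.append(AlignedSequence(rec.id, str(rec.seq)))
    if dropped:
        log.warning("%s: dropped %d duplicate record(s), kept first", path, dropped)
    if len(members) < 2:
        raise InsufficientMembersError(
            f"{path}: {len(members)} sequence(s); at least 2 required"
        )
    return FamilyAlignment(family_id or path.stem, tuple(members))


def write_alignment(
    fam: FamilyAlignment, path: str | Path, format: str = "fasta"
) -> None:
    """Write a family MSA to FASTA or Stockholm."""
    if format not in _FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(m.aligned), id=m.protein_id, description="")
        for m in fam.members
    )
    AlignIO.write(msa, str(path), _FORMATS[format])
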