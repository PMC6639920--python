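"""Binding-residue annotations and predictions, and their column projection.

Observed annotations and per-residue binary predictions arrive as TSV
tables of 1-based residue positions keyed by protein id.  Binding labels
are purely per-residue (1D); they are never grouped into 3D sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConsistencyError, PositionParseError
from .msa_io import AlignedSequence, FamilyAlignment, column_of_residue

__all__ = [
    "AnnotationSet",
    "PredictionSet",
    "ColumnSet",
    "load_position_table",
    "write_position_table",
    "map_to_columns",
    "project_family",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSet:
    """Observed binding residues of one protein (1-based positions)."""

    protein_id: str
    positions: frozenset[int]

    def __post_init__(self) -> None:
        _check_positions(self.positions, self.protein_id)


@dataclass(frozen=True)
class PredictionSet:
    """Predicted binding residues of one protein; may be empty
    (absence of a position means predicted non-binding)."""

    protein_id: str
    positions: frozenset[int]

    def __post_init__(self) -> None:
        _check_positions(self.positions, self.protein_id)


@dataclass(frozen=True)
class ColumnSet:
    """Binding positions of one protein projected onto MSA columns."""

    family_id: str
    protein_id: str
    columns: frozenset[int]


def _check_positions(positions: Iterable[int], protein_id: str) -> None:
    for p in positions:
        if not isinstance(p, (int,)) or isinstance(p, bool) or p < 1:
            raise PositionParseError(
                f"{protein_id!r}: residue positions must be integers >= 1, got {p!r}"
            )


def _parse_position(raw: object, protein_id: str) -> int:
    text = str(raw).strip()
    try:
        value = int(text)
    except (TypeError, ValueError) as exc:
        raise PositionParseError(
            f"{protein_id!r}: cannot parse residue position {raw!r}"
        ) from exc
    if value < 1:
        raise PositionParseError(
            f"{protein_id!r}: residue positions are 1-based, got {value}"
        )
    return value


def load_position_table(
    path: str | Path, kind: str = "annotation"
) -> dict[str, AnnotationSet] | dict[str, PredictionSet]:
    """Load a TSV of per-protein residue positions.

    Two layouts are accepted, both with a header row:

    * ``protein_id`` + ``position`` — one row per position;
    * ``protein_id`` + ``positions`` — comma-joined positions per row.

    Positions are deduplicated.  For ``kind="annotation"`` proteins with no
    positions are dropped (and counted in the log); predictions may be
    empty.
    """
    if kind not in ("annotation", "prediction"):
        raise ValueError(f"kind must be 'annotation' or 'prediction', got {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "protein_id" not in df.columns:
        raise PositionParseError(f"{path}: missing required column 'protein_id'")
    if "position" in df.columns:
        wide = False
    elif "positions" in df.columns:
        wide = True
    else:
        raise PositionParseError(
            f"{path}: need a 'position' or 'positions' column"
        )

    by_protein: dict[str, set[int]] = {}
    for _, row in df.iterrows():
        pid = str(row["protein_id"]).strip()
        bucket = by_protein.setdefault(pid, set())
        if wide:
            cell = str(row["positions"]).strip()
            if cell:
                bucket.update(_parse_position(tok, pid) for tok in cell.split(","))
        else:
            cell = str(row["position"]).strip()
            if cell:
                bucket.add(_parse_position(cell, pid))

    if kind == "annotation":
        empty = [pid for pid, pos in by_protein.items() if not pos]
        if empty:
            log.info(
                "%s: dropped %d protein(s) without binding-residue annotations",
                path,
                len(empty),
            )
        return {
            pid: AnnotationSet(pid, frozenset(pos))
            for pid, pos in by_protein.items()
            if pos
        }
    return {
        pid: PredictionSet(pid, frozenset(pos)) for pid, pos in by_protein.items()
    }


def write_position_table(
    sets: Mapping[str, AnnotationSet] | Mapping[str, PredictionSet],
    path: str | Path,
) -> None:
    """Write position sets as a comma-joined TSV (``protein_id``, ``positions``)."""
    rows = [
        {
            "protein_id": pid,
            "positions": ",".join(str(p) for p in sorted(s.positions)),
        }
        for pid, s in sorted(sets.items())
    ]
    pd.DataFrame(rows, columns=["protein_id", "positions"]).to_csv(
        path, sep="\t", index=False
    )


def map_to_columns(
    pos: AnnotationSet | PredictionSet,
    seq: AlignedSequence,
    family_id: str = "",
) -> ColumnSet:
    """Project residue positions onto MSA columns of the matching sequence.

    The mapping is injective, so ``|columns| == |positions|``.  A position
    beyond the ungapped length raises :class:`ConsistencyError` (callers
    reproducing length-conflict filtering may catch it and drop the
    protein instead).
    """
    if pos.protein_id != seq.protein_id:
        raise ValueError(
            f"protein id mismatch: {pos.protein_id!r} vs {seq.protein_id!r}"
        )
    too_big = [p for p in pos.positions if p > seq.length_ungapped]
    if too_big:
        raise ConsistencyError(
            f"{pos.protein_id!r}: positions {sorted(too_big)} exceed ungapped "
            f"length {seq.length_ungapped}"
        )
    return ColumnSet(
        family_id,
        pos.protein_id,
        frozenset(column_of_residue(seq, p) for p in pos.positions),
    )


def project_family(
    fam: FamilyAlignment,
    table: Mapping[str, AnnotationSet] | Mapping[str, PredictionSet],
    on_conflict: str = "error",
) -> dict[str, ColumnSet]:
    """Project all family members present in ``table`` onto columns.

    ``on_conflict="drop"`` silently drops (and logs) proteins whose
    positions conflict with the aligned sequence length, mirroring the
    removal of entries with conflicting sequence or annotation lengths
    from curated datasets; the default fails loudly.
    """
    if on_conflict not in ("error", "drop"):
        raise ValueError("on_conflict must be 'error' or 'drop'")
    out: dict[str, ColumnSet] = {}
    dropped = 0
    for member in fam:
        entry = table.get(member.protein_id)
        if entry is None:
            continue
        try:
            out[member.protein_id] = map_to_columns(entry, member, fam.family_id)
        except ConsistencyError:
            if on_conflict == "error":
                raise
            dropped += 1
    if dropped:
        log.warning(
            "family %s: dropped %d protein(s) with conflicting lengths",
            fam.family_id,
            dropped,
        )
    return out
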