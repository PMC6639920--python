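"""Homology-based annotation transfer within one family.

The observed binding residues of one family member (the source) are
carried along MSA columns to every other member (the targets): a source
binding residue transfers to the target's residue in the same column, and
transfers nothing where the target has a gap.  Each transfer is scored as
a binary per-residue prediction against the target's own observed
annotation, over the target's ungapped length.  Iterating over all
ordered annotated pairs and averaging the scores each protein receives
yields per-protein metrics aggregated with unit = protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, PredictionSet, map_to_columns
from .errors import InsufficientMembersError
from .metrics import METRIC_NAMES, MetricsResult, aggregate, confusion, score
from .msa_io import AlignedSequence, FamilyAlignment, residue_at_column
from .stats import AggregateStat

__all__ = ["TransferResult", "transfer_annotation", "evaluate_transfer"]


@dataclass(frozen=True)
class TransferResult:
    """Per-protein table and per-metric summary of a transfer evaluation."""

    per_protein: pd.DataFrame  # one row per recipient protein
    summary: dict[str, AggregateStat]


def transfer_annotation(
    source: AlignedSequence,
    annot: AnnotationSet,
    target: AlignedSequence,
) -> PredictionSet:
    """Project one member's binding residues onto another via the MSA.

    Source and target must come from the same family alignment.  Columns
    where the target is gapped transfer nothing, so the result can be
    empty.
    """
    if annot.protein_id != source.protein_id:
        raise ValueError(
            f"annotation {annot.protein_id!r} does not match source "
            f"{source.protein_id!r}"
        )
    columns = map_to_columns(annot, source).columns
    positions = {
        r for c in columns if (r := residue_at_column(target, c)) is not None
    }
    return PredictionSet(target.protein_id, frozenset(positions))


def evaluate_transfer(
    fam: FamilyAlignment, annots: Mapping[str, AnnotationSet]
) -> TransferResult:
    """Score every ordered source→target transfer among annotated members.

    A protein's per-metric value is the mean over all transfers it
    receives (undefined values excluded); the summary aggregates those
    per-protein means with the per-protein SE convention.
    """
    annotated = [
        m for m in fam
        if m.protein_id in annots and annots[m.protein_id].positions
    ]
    if len(annotated) < 2:
        raise InsufficientMembersError(
            f"family {fam.family_id!r}: need >= 2 annotated members, "
            f"got {len(annotated)}"
        )

    received: dict[str, list[MetricsResult]] = {m.protein_id: [] for m in annotated}
    for src in annotated:
        for tgt in annotated:
            if src.protein_id == tgt.protein_id:
                continue
            pred = transfer_annotation(src, annots[src.protein_id], tgt)
            counts = confusion(
                pred, annots[tgt.protein_id], tgt.length_ungapped
            )
            received[tgt.protein_id].append(score(counts))

    rows = []
    per_protein_results: dict[str, MetricsResult] = {}
    for pid, results in received.items():
        means: dict[str, float | None] = {}
        for name in METRIC_NAMES:
            defined = [r.get(name) for r in results if r.get(name) is not None]
            means[name] = float(np.mean(defined)) if defined else None
        per_protein_results[pid] = MetricsResult(**means)
        rows.append({"protein_id": pid, "n_transfers": len(results), **means})

    per_protein = pd.DataFrame(rows, columns=["protein_id", "n_transfers", *METRIC_NAMES])
    return TransferResult(
        per_protein=per_protein,
        summary=aggregate(per_protein_results, unit="protein"),
    )
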