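"""Family consensus filter over per-residue binding predictions.

Member predictions are combined per MSA column: a column is consensus-
binding when the fraction of members predicting binding there — among the
members aligned without a gap at that column — reaches the consensus
threshold (comparison is ≥, so a threshold of 1.0 demands unanimity and a
threshold ≤ 1/M keeps any single vote).  The consensus column set is then
projected back onto each member's residue coordinates and scored against
observed annotations.

Members present in the alignment but absent from the prediction table
count as predicting non-binding everywhere while still occupying the
denominator at their non-gap columns: occupancy is defined by the
alignment, not by prediction availability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, PredictionSet, map_to_columns
from .errors import InsufficientMembersError
from .metrics import METRIC_NAMES, aggregate, confusion, score
from .msa_io import GAP, AlignedSequence, FamilyAlignment
from .stats import aggregate_values

__all__ = [
    "ConsensusConfig",
    "consensus_columns",
    "consensus_to_protein",
    "sweep_thresholds",
    "DEFAULT_THRESHOLDS",
]

log = logging.getLogger(__name__)

#: Sweep grid from "at least one member" (0.01) to "all members" (1.0).
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)


@dataclass(frozen=True)
class ConsensusConfig:
    """Consensus threshold in (0, 1]; comparison is fixed at ≥."""

    threshold: float

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")


def _vote_counts(
    fam: FamilyAlignment, preds: Mapping[str, PredictionSet]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (votes-for-binding, non-gap occupancy) counts."""
    n = fam.n_columns
    votes = np.zeros(n, dtype=np.int64)
    occupancy = np.zeros(n, dtype=np.int64)
    missing = 0
    for member in fam:
        nongap = np.frombuffer(member.aligned.encode(), dtype=np.uint8) != ord(GAP)
        occupancy += nongap
        entry = preds.get(member.protein_id)
        if entry is None:
            missing += 1
            continue
        if entry.positions:
            cols = map_to_columns(entry, member, fam.family_id).columns
            votes[np.fromiter(cols, dtype=np.int64) - 1] += 1
    if missing:
        log.debug(
            "family %s: %d member(s) without prediction records counted as "
            "all-non-binding",
            fam.family_id,
            missing,
        )
    return votes, occupancy


def _columns_at(votes: np.ndarray, occupancy: np.ndarray, threshold: float) -> frozenset[int]:
    occupied = occupancy > 0
    hits = np.zeros_like(occupied)
    hits[occupied] = votes[occupied] >= threshold * occupancy[occupied]
    return frozenset((np.flatnonzero(hits) + 1).tolist())


def consensus_columns(
    fam: FamilyAlignment,
    preds: Mapping[str, PredictionSet],
    cfg: ConsensusConfig,
) -> frozenset[int]:
    """Columns whose binding-vote fraction reaches the threshold.

    Columns where every member is gapped are never consensus-binding.
    """
    votes, occupancy = _vote_counts(fam, preds)
    return _columns_at(votes, occupancy, cfg.threshold)


def consensus_to_protein(
    columns: frozenset[int] | set[int], seq: AlignedSequence
) -> PredictionSet:
    """Project consensus columns back to one member's residue positions."""
    positions = {
        r
        for c in columns
        if (r := seq._col2res[c - 1]) is not None
    }
    return PredictionSet(seq.protein_id, frozenset(positions))


def sweep_thresholds(
    fams: Sequence[FamilyAlignment],
    preds: Mapping[str, PredictionSet],
    annots: Mapping[str, AnnotationSet],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Score the consensus filter across a threshold grid.

    For each threshold the consensus is built per family, projected onto
    every annotated member, scored against the member's observed
    annotation over its ungapped length, and aggregated per protein
    across all families.  Proteins with an empty consensus prediction
    still enter the recall/accuracy averages but drop out of precision
    (undefined when TP+FP=0); the coverage columns report how many
    proteins received at least one predicted residue and the mean number
    of predicted residues per protein.

    Returns one row per threshold with ``<metric>_mean``, ``<metric>_se``
    and ``<metric>_n`` columns plus ``mean_predicted_per_protein`` and
    ``fraction_proteins_with_prediction``.
    """
    thresholds = [float(t) for t in thresholds]
    for t in thresholds:
        ConsensusConfig(t)  # validate
    if not fams:
        raise InsufficientMembersError("no families supplied")

    counts = [(fam, *_vote_counts(fam, preds)) for fam in fams]
    rows = []
    for t in thresholds:
        per_protein = {}
        n_predicted: list[int] = []
        for fam, votes, occupancy in counts:
            cols = _columns_at(votes, occupancy, t)
            for member in fam:
                annot = annots.get(member.protein_id)
                if annot is None or not annot.positions:
                    continue
                projected = consensus_to_protein(cols, member)
                tallies = confusion(projected, annot, member.length_ungapped)
                per_protein[(fam.family_id, member.protein_id)] = score(tallies)
                n_predicted.append(len(projected.positions))
        if not per_protein:
            raise InsufficientMembersError(
                "no annotated family members to evaluate"
            )
        stats = aggregate(per_protein, unit="protein")
        row: dict[str, float] = {"threshold": t}
        for name in METRIC_NAMES:
            stat = stats.get(name)
            row[f"{name}_mean"] = stat.mean if stat else np.nan
            row[f"{name}_se"] = stat.se if stat else np.nan
            row[f"{name}_n"] = stat.n_units if stat else 0
        row["mean_predicted_per_protein"] = float(np.mean(n_predicted))
        row["fraction_proteins_with_prediction"] = float(
            np.mean([k > 0 for k in n_predicted])
        )
        row["n_proteins"] = len(n_predicted)
        rows.append(row)
    return pd.DataFrame(rows)
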