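"""Binding-residue similarity between aligned proteins.

The core statistic compares the binding residues of two proteins after
projection onto the columns of a shared MSA:

    similarity(X, Y) = 100 * |X ∩ Y| / max(|X|, |Y|)

i.e. the number of shared binding columns normalised by the larger of the
two binding-residue counts, in percent.  A family score is the mean over
all M(M−1)/2 member pairs; a group of families is summarised by the mean
± SE of per-family scores.

Also here: regrouping proteins by an external label table (EC-number-like
or Pfam-like), cross-classification subsets with seeded representative
selection, and reverse-cumulative similarity distributions.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, ColumnSet, project_family
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InsufficientMembersError,
    UndefinedSimilarityError,
)
from .msa_io import FamilyAlignment
from .stats import AggregateStat, aggregate_values

__all__ = [
    "FamilySimilarity",
    "pairwise_similarity",
    "family_similarity",
    "group_similarity",
    "regroup_by_label",
    "cross_subset",
    "reverse_cumulative",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilySimilarity:
    """Mean pairwise binding-residue similarity of one family."""

    family_id: str
    mean_similarity: float  # percent in [0, 100]
    n_pairs: int
    n_members: int  # annotated members only

    def __post_init__(self) -> None:
        expected = self.n_members * (self.n_members - 1) // 2
        if self.n_pairs != expected:
            raise ValueError(
                f"n_pairs {self.n_pairs} != M(M-1)/2 = {expected} for M={self.n_members}"
            )
        if not 0.0 <= self.mean_similarity <= 100.0 + 1e-9:
            raise ValueError(f"mean_similarity {self.mean_similarity} out of [0, 100]")


def _columns(x: ColumnSet | frozenset[int] | set[int]) -> frozenset[int]:
    if isinstance(x, ColumnSet):
        return x.columns
    return frozenset(x)


def pairwise_similarity(
    x: ColumnSet | frozenset[int] | set[int],
    y: ColumnSet | frozenset[int] | set[int],
) -> float:
    """Percent of shared binding columns, normalised by the larger set.

    Symmetric; 100 iff the two column sets are identical; raises
    :class:`UndefinedSimilarityError` if either set is empty (such
    proteins are excluded upstream).
    """
    xs, ys = _columns(x), _columns(y)
    if not xs or not ys:
        raise UndefinedSimilarityError(
            "binding-residue similarity is undefined for an empty set"
        )
    return 100.0 * len(xs & ys) / max(len(xs), len(ys))


def family_similarity(
    fam: FamilyAlignment,
    annots: Mapping[str, AnnotationSet],
    on_conflict: str = "error",
) -> FamilySimilarity:
    """Mean pairwise similarity over all annotated member pairs.

    Members without (non-empty) annotations are excluded before pairing;
    ``n_members`` counts annotated members only.
    """
    columns = project_family(fam, annots, on_conflict=on_conflict)
    columns = {pid: cs for pid, cs in columns.items() if cs.columns}
    if len(columns) < 2:
        raise InsufficientMembersError(
            f"family {fam.family_id!r}: {len(columns)} annotated member(s); "
            "at least 2 required"
        )
    ordered = [columns[m.protein_id] for m in fam if m.protein_id in columns]
    sims = [pairwise_similarity(a, b) for a, b in combinations(ordered, 2)]
    return FamilySimilarity(
        family_id=fam.family_id,
        mean_similarity=float(np.mean(sims)),
        n_pairs=len(sims),
        n_members=len(ordered),
    )


def group_similarity(families: Iterable[FamilySimilarity]) -> AggregateStat:
    """Mean ± SE of per-family mean similarities (unit = family)."""
    fams = list(families)
    if len(fams) < 2:
        raise InsufficientDataError(
            f"need >= 2 families for a group aggregate, got {len(fams)}"
        )
    return aggregate_values((f.mean_similarity for f in fams), unit="family")


AlignmentProvider = Callable[[str, Sequence[str]], FamilyAlignment]


def regroup_by_label(
    annots: Mapping[str, AnnotationSet],
    labels: Mapping[str, str],
    alignment_provider: AlignmentProvider,
) -> list[FamilySimilarity]:
    """Regroup proteins by an external label and score each group.

    ``alignment_provider(label, protein_ids)`` must return an MSA of the
    group (an externally computed alignment, or the built-in aligner from
    :mod:`bindfam.random_baseline`); a missing alignment raises
    :class:`ConfigurationError`.  Groups with fewer than two annotated
    proteins are skipped and logged.
    """
    groups: dict[str, list[str]] = {}
    for pid in annots:
        label = labels.get(pid)
        if label is None:
            continue
        groups.setdefault(label, []).append(pid)

    results: list[FamilySimilarity] = []
    skipped = 0
    for label in sorted(groups):
        pids = sorted(groups[label])
        if len(pids) < 2:
            skipped += 1
            continue
        try:
            fam = alignment_provider(label, pids)
        except (KeyError, FileNotFoundError) as exc:
            raise ConfigurationError(
                f"no alignment available for group {label!r}"
            ) from exc
        results.append(family_similarity(fam, annots))
    if skipped:
        log.info("regroup_by_label: skipped %d singleton group(s)", skipped)
    return results


def cross_subset(
    a: Mapping[str, str],
    b: Mapping[str, str],
    mode: str,
    seed: int,
) -> dict[str, str]:
    """Build a cross-classification grouping from two label tables.

    ``same_a_diff_b``: within each a-label, keep one seeded-random
    representative per b-label and return the a-groups that retain at
    least two proteins (e.g. "same EC number, different family").

    ``same_a_same_b``: intersect the two classifications; each retained
    protein is keyed by ``"<a-label>|<b-label>"``, and only keys with at
    least two proteins are kept.
    """
    if mode not in ("same_a_diff_b", "same_a_same_b"):
        raise ValueError(f"unknown mode {mode!r}")
    shared = sorted(set(a) & set(b))
    out: dict[str, str] = {}
    if mode == "same_a_same_b":
        groups: dict[str, list[str]] = {}
        for pid in shared:
            groups.setdefault(f"{a[pid]}|{b[pid]}", []).append(pid)
        for key, pids in groups.items():
            if len(pids) >= 2:
                for pid in pids:
                    out[pid] = key
    else:
        rng = random.Random(seed)
        by_a: dict[str, dict[str, list[str]]] = {}
        for pid in shared:
            by_a.setdefault(a[pid], {}).setdefault(b[pid], []).append(pid)
        for a_label in sorted(by_a):
            reps = [rng.choice(sorted(pids)) for _, pids in sorted(by_a[a_label].items())]
            if len(reps) >= 2:
                for pid in reps:
                    out[pid] = a_label
    if not out:
        log.info("cross_subset(%s): empty result", mode)
    return out


def reverse_cumulative(
    values: Iterable[float], thresholds: Sequence[float]
) -> pd.DataFrame:
    """Count values ≥ t for each threshold t (ascending).

    Returns a frame with columns ``threshold``, ``count``, ``fraction``;
    counts are non-increasing in t and the count at t=0 equals the total.
    """
    arr = np.sort(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        raise InsufficientDataError("reverse_cumulative requires at least one value")
    ts = np.asarray(list(thresholds), dtype=float)
    if ts.size == 0 or np.any(np.diff(ts) < 0):
        raise ValueError("thresholds must be non-empty and ascending")
    counts = arr.size - np.searchsorted(arr, ts, side="left")
    return pd.DataFrame(
        {
            "threshold": ts,
            "count": counts.astype(int),
            "fraction": counts / arr.size,
        }
    )
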