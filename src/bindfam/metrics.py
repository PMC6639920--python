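"""Confusion-matrix metrics for per-residue binding prediction.

Residue-level binary classification over each protein's ungapped length:
a residue is binding (positive) or non-binding (negative).  Precision,
recall and accuracy are reported in percent; F1 is the harmonic mean of
precision and recall (equivalently 2TP/(2TP+FP+FN), asserted in tests);
MCC is the Matthews correlation coefficient on its standard [−1, 1]
scale with the product denominator √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

A metric whose denominator vanishes is *undefined* (``None``) and is
excluded from per-protein averages; the number of contributing proteins
is reported per metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .annotations import AnnotationSet, PredictionSet
from .errors import ConsistencyError
from .stats import AggregateStat, aggregate_values

__all__ = [
    "ConfusionCounts",
    "MetricsResult",
    "METRIC_NAMES",
    "confusion",
    "score",
    "f1_from_precision_recall",
    "aggregate",
]

METRIC_NAMES = ("precision", "recall", "accuracy", "f1", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies for one protein."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsResult:
    """Per-protein metric values; ``None`` marks an undefined metric."""

    precision: float | None
    recall: float | None
    accuracy: float | None
    f1: float | None
    mcc: float | None

    def get(self, name: str) -> float | None:
        return getattr(self, name)


def _positions(x: AnnotationSet | PredictionSet | Iterable[int]) -> frozenset[int]:
    if isinstance(x, (AnnotationSet, PredictionSet)):
        return x.positions
    return frozenset(x)


def confusion(
    pred: PredictionSet | Iterable[int],
    obs: AnnotationSet | Iterable[int],
    length: int,
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over a protein of ``length`` residues."""
    p, o = _positions(pred), _positions(obs)
    if p and max(p) > length:
        raise ConsistencyError(f"predicted position {max(p)} exceeds length {length}")
    if o and max(o) > length:
        raise ConsistencyError(f"observed position {max(o)} exceeds length {length}")
    tp = len(p & o)
    fp = len(p - o)
    fn = len(o - p)
    return ConfusionCounts(tp=tp, fp=fp, tn=length - tp - fp - fn, fn=fn)


def f1_from_precision_recall(
    precision: float | None, recall: float | None
) -> float | None:
    """Harmonic mean of precision and recall (both in percent).

    ``None`` when either parent is undefined or both are zero.
    Equivalent to 2TP/(2TP+FP+FN) in percent.
    """
    if precision is None or recall is None or precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def score(c: ConfusionCounts) -> MetricsResult:
    """Compute all metrics from one confusion tally."""
    precision = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp else None
    recall = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    accuracy = 100.0 * (c.tp + c.tn) / c.total if c.total else None
    f1 = f1_from_precision_recall(precision, recall)

    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = None
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)

    return MetricsResult(
        precision=precision, recall=recall, accuracy=accuracy, f1=f1, mcc=mcc
    )


def aggregate(
    per_protein: Iterable[MetricsResult] | Mapping[str, MetricsResult],
    unit: str = "protein",
) -> dict[str, AggregateStat]:
    """Aggregate per-protein metrics into mean ± SE, one stat per metric.

    Undefined values are excluded; each metric's ``n_units`` therefore
    reports its own number of contributing proteins.  Metrics with fewer
    than two defined values are omitted from the result.
    """
    if isinstance(per_protein, Mapping):
        results = list(per_protein.values())
    else:
        results = list(per_protein)
    out: dict[str, AggregateStat] = {}
    for name in METRIC_NAMES:
        defined = [r.get(name) for r in results if r.get(name) is not None]
        if len(defined) >= 2:
            out[name] = aggregate_values(defined, unit=unit)
    return out
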