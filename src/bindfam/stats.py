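"""Mean ± standard-error aggregation over families or proteins.

The standard-error convention used throughout: sample standard deviation
(denominator n−1) divided by sqrt(n−1), over the distribution of per-unit
scores (unit = family for similarity statistics, protein for prediction
metrics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import InsufficientDataError

__all__ = ["AggregateStat", "aggregate_values"]


@dataclass(frozen=True)
class AggregateStat:
    """Mean ± standard error of per-unit scores."""

    mean: float
    se: float
    n_units: int
    unit: str  # "family" or "protein"

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise InsufficientDataError(
                f"standard error needs >= 2 units, got {self.n_units}"
            )
        if self.se < 0:
            raise ValueError("standard error must be non-negative")


def aggregate_values(values: Iterable[float], unit: str) -> AggregateStat:
    """Aggregate per-unit scores into mean ± SE.

    Raises :class:`InsufficientDataError` with fewer than two values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need >= 2 {unit} values for an aggregate, got {arr.size}"
        )
    sd = float(np.std(arr, ddof=1))
    return AggregateStat(
        mean=float(np.mean(arr)),
        se=sd / math.sqrt(arr.size - 1),
        n_units=int(arr.size),
        unit=unit,
    )
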