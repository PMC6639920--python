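"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — literal loops, quadratic DP —
and shares no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_pairwise(x: set[int], y: set[int]) -> float:
    """Literal transcription of the similarity definition.

    Order the two index vectors so the first has n >= m entries, then
    count entries of the larger vector occurring in the smaller.
    """
    bigger, smaller = (sorted(x), sorted(y)) if len(x) >= len(y) else (sorted(y), sorted(x))
    n = len(bigger)
    z = [1 if xi in smaller else 0 for xi in bigger]
    return 100.0 / n * sum(z)


def brute_family_mean(column_sets: list[set[int]]) -> float:
    """Exhaustive enumeration over all unordered member pairs."""
    sims = [brute_pairwise(a, b) for a, b in combinations(column_sets, 2)]
    return sum(sims) / len(sims)


def sort_and_scan_cumulative(values: list[float], thresholds: list[float]):
    """Counts of values >= t by a plain scan."""
    return [(t, sum(1 for v in values if v >= t)) for t in thresholds]


def loop_confusion(pred: set[int], obs: set[int], length: int):
    """Per-residue loop over the whole protein."""
    tp = fp = tn = fn = 0
    for i in range(1, length + 1):
        if i in pred and i in obs:
            tp += 1
        elif i in pred:
            fp += 1
        elif i in obs:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def gotoh_global_score(
    a: str,
    b: str,
    matrix,
    open_score: float = -10.0,
    extend_score: float = -0.5,
) -> float:
    """Optimal global affine-gap alignment score (quadratic DP).

    A gap of length g scores ``open_score + (g-1)*extend_score``; end
    gaps are penalised like internal ones.
    """
    n, m = len(a), len(b)
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (a residue vs gap)
    Iy = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = open_score + (i - 1) * extend_score
    for j in range(1, m + 1):
        Iy[0, j] = open_score + (j - 1) * extend_score
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] + open_score, Ix[i - 1, j] + extend_score)
            Iy[i, j] = max(M[i, j - 1] + open_score, Iy[i, j - 1] + extend_score)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def induced_pair_score(
    row_a: str,
    row_b: str,
    matrix,
    open_score: float = -10.0,
    extend_score: float = -0.5,
) -> float:
    """Score of a given pairwise alignment (gapped rows), affine gaps."""
    total = 0.0
    gap_a = gap_b = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-" and cb == "-":
            continue
        if ca == "-":
            total += extend_score if gap_a else open_score
            gap_a, gap_b = True, False
        elif cb == "-":
            total += extend_score if gap_b else open_score
            gap_b, gap_a = True, False
        else:
            total += matrix[ca, cb]
            gap_a = gap_b = False
    return total
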