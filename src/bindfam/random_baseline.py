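"""Random-family baseline: the similarity floor for unrelated proteins.

Groups randomly drawn proteins into "random families" whose size
distribution mimics a real dataset, aligns each family with a built-in
center-star progressive aligner (affine-gap Needleman–Wunsch pairwise
steps, BLOSUM62 by default), and computes the same family-similarity
statistic as for real families.  The result is the floor against which
functional-family coherence is judged.

The aligner is a baseline utility, not a contribution: any reasonable MSA
of unrelated sequences yields near-floor similarity.  An externally
computed MSA can be supplied instead wherever a
:class:`~bindfam.msa_io.FamilyAlignment` is accepted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .annotations import AnnotationSet
from .errors import ConfigurationError, InsufficientMembersError
from .msa_io import GAP, AlignedSequence, FamilyAlignment
from .similarity import family_similarity, group_similarity
from .stats import AggregateStat

__all__ = [
    "PoolEntry",
    "SizeSpec",
    "AlignerParams",
    "template_pool",
    "sample_random_families",
    "align_family",
    "random_similarity",
]


@dataclass(frozen=True)
class PoolEntry:
    """An unaligned protein with its binding-residue annotation."""

    protein_id: str
    sequence: str
    positions: frozenset[int]


@dataclass(frozen=True)
class SizeSpec:
    """Multiset of family sizes to draw (each size ≥ 2)."""

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.sizes:
            raise ConfigurationError("size spec is empty")
        if any(s < 2 for s in self.sizes):
            raise ConfigurationError("random-family sizes must be >= 2")

    @classmethod
    def mimic(cls, families: Iterable[FamilyAlignment]) -> "SizeSpec":
        """Copy the observed family-size distribution of a real dataset."""
        return cls(tuple(len(f) for f in families))


@dataclass(frozen=True)
class AlignerParams:
    """Pairwise-step parameters of the center-star aligner."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigurationError("gap penalties must be non-negative")


def _make_aligner(params: AlignerParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


_AA = "ACDEFGHIKLMNPQRSTVWY"


def template_pool(
    n_proteins: int,
    length: int,
    n_binding: int,
    seed: int,
    mutation_rate: float = 0.2,
) -> list[PoolEntry]:
    """Pool of functionally unrelated but alignable proteins.

    All sequences are point-mutated copies of one random template (like
    distant relatives within a structural superfamily), so a correct MSA
    of any subset is gap-free and columns coincide with residue
    positions; each protein's ``n_binding`` annotated residues are drawn
    uniformly and independently, so the expected pairwise similarity is
    the hypergeometric-overlap floor ``100·n_binding/length`` (see
    :func:`bindfam.synthetic.expected_random_similarity`).
    """
    if n_binding > length:
        raise ConfigurationError("n_binding cannot exceed length")
    rng = np.random.default_rng(seed)
    letters = np.array(list(_AA))
    template = rng.choice(letters, size=length)
    pool = []
    for i in range(n_proteins):
        seq = template.copy()
        mutated = rng.random(length) < mutation_rate
        seq[mutated] = rng.choice(letters, size=int(mutated.sum()))
        positions = frozenset(
            (rng.choice(length, size=n_binding, replace=False) + 1).tolist()
        )
        pool.append(PoolEntry(f"pool_{i:04d}", "".join(seq), positions))
    return pool


def sample_random_families(
    pool: Sequence[PoolEntry],
    spec: SizeSpec,
    seed: int,
) -> list[list[PoolEntry]]:
    """Draw random families per the size spec (seeded, reproducible).

    Sampling is without replacement within a family (no duplicate protein
    inside one family) and with replacement across families.
    """
    if max(spec.sizes) > len(pool):
        raise ConfigurationError(
            f"largest family size {max(spec.sizes)} exceeds pool size {len(pool)}"
        )
    rng = random.Random(seed)
    return [list(rng.sample(pool, size)) for size in spec.sizes]


def align_family(
    seqs: Sequence[PoolEntry] | Sequence[tuple[str, str]],
    params: AlignerParams = AlignerParams(),
    family_id: str = "random",
) -> FamilyAlignment:
    """Center-star progressive multiple alignment.

    The center is the sequence maximising the summed pairwise global
    alignment score against all others (ties broken by input order); each
    remaining sequence is aligned to the center and merged under the
    "once a gap, always a gap" rule.  Deleting gaps from any output row
    recovers the corresponding input sequence.
    """
    entries = [
        (e.protein_id, e.sequence) if isinstance(e, PoolEntry) else (e[0], e[1])
        for e in seqs
    ]
    if len(entries) < 2:
        raise InsufficientMembersError("alignment needs at least 2 sequences")
    if any(not s for _, s in entries):
        raise ValueError("cannot align an empty sequence")

    aligner = _make_aligner(params)
    strings = [s for _, s in entries]
    m = len(strings)

    if m == 2:
        center = 0
    else:
        totals = np.zeros(m)
        for i in range(m):
            for j in range(i + 1, m):
                s = aligner.score(strings[i], strings[j])
                totals[i] += s
                totals[j] += s
        center = int(np.argmax(totals))  # argmax takes the first maximum

    rows: dict[int, list[str]] = {center: list(strings[center])}
    center_row = rows[center]
    for j in range(m):
        if j == center:
            continue
        pairwise = aligner.align(strings[center], strings[j])[0]
        a, b = str(pairwise[0]), str(pairwise[1])
        new_row: list[str] = []
        i = k = 0
        while i < len(center_row) or k < len(a):
            if i < len(center_row) and center_row[i] == GAP:
                # column inserted by an earlier member: gap for the newcomer
                new_row.append(GAP)
                i += 1
            elif k < len(a) and a[k] == GAP:
                # newcomer inserts a column relative to the center
                for row in rows.values():
                    row.insert(i, GAP)
                new_row.append(b[k])
                i += 1
                k += 1
            else:
                new_row.append(b[k])
                i += 1
                k += 1
        rows[j] = new_row

    members = tuple(
        AlignedSequence(entries[idx][0], "".join(rows[idx])) for idx in range(m)
    )
    return FamilyAlignment(family_id, members)


def random_similarity(
    pool: Sequence[PoolEntry],
    spec: SizeSpec,
    seed: int,
    params: AlignerParams = AlignerParams(),
) -> AggregateStat:
    """Mean ± SE binding-residue similarity of random families.

    Pipeline: sample → align → per-family similarity → per-family
    aggregate (unit = family).
    """
    sampled = sample_random_families(pool, spec, seed)
    per_family = []
    for idx, entries in enumerate(sampled):
        fam = align_family(entries, params, family_id=f"random_{idx:04d}")
        annots = {
            e.protein_id: AnnotationSet(e.protein_id, e.positions) for e in entries
        }
        per_family.append(family_similarity(fam, annots))
    return group_similarity(per_family)
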