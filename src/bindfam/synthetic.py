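"""Seeded generator of functional-family-like fixtures.

Emulates the statistical structure the analyses in this package assume:
families of aligned protein sequences sharing a small set of planted
binding columns, with per-member noise — incomplete conservation of the
planted columns, member-private extra annotations, i.i.d. gaps, and
false-positive/false-negative prediction errors.  Sequence letters are
uniform random amino acids: every score in scope depends only on columns,
gaps and label sets, so biological realism of the letters is irrelevant
and keeping them random keeps the oracles exact.

Default parameters mirror a FunFam-scale setting: families of four
members (real binding-annotated families average ~3.9), alignments of
100 columns with five planted binding columns (≈5% binding residues,
matching the ~5% random-overlap floor), strong but imperfect
conservation, sparse private annotations and gaps, and prediction noise
far above annotation noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .annotations import (
    AnnotationSet,
    PredictionSet,
    write_position_table,
)
from .errors import ConfigurationError
from .msa_io import AlignedSequence, FamilyAlignment, write_alignment

__all__ = [
    "AMINO_ACIDS",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "expected_similarity",
    "expected_random_similarity",
    "write_dataset",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the family generator.

    Attributes
    ----------
    n_families, family_size
        Number of families and members per family (an int, or a sequence
        of sizes sampled uniformly per family).
    n_columns, n_binding_columns
        MSA width and number of planted binding columns per family.
    p_conserved
        Probability that a member is annotated at a planted binding
        column (where it is not gapped).
    p_extra
        Per-column probability of a member-private annotation at a
        non-planted, non-gap column.
    p_gap
        Per-cell gap probability (columns that end up all-gap are dropped).
    fp_rate, fn_rate
        Per-residue prediction noise: an annotated residue is missed with
        probability ``fn_rate``; a non-annotated residue is predicted
        binding with probability ``fp_rate``.
    """

    n_families: int = 50
    family_size: int | tuple[int, ...] = 4
    n_columns: int = 100
    n_binding_columns: int = 5
    p_conserved: float = 0.8
    p_extra: float = 0.02
    p_gap: float = 0.05
    fp_rate: float = 0.05
    fn_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_conserved": self.p_conserved,
            "p_extra": self.p_extra,
            "p_gap": self.p_gap,
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.n_binding_columns > self.n_columns:
            raise ConfigurationError(
                "n_binding_columns cannot exceed n_columns"
            )
        if self.n_binding_columns < 1 or self.n_columns < 1:
            raise ConfigurationError("column counts must be positive")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be positive")
        sizes = self._sizes
        if any(s < 2 for s in sizes):
            raise ConfigurationError("family sizes must be >= 2")
        if self.p_conserved == 0.0 and self.p_extra == 0.0:
            raise ConfigurationError(
                "infeasible config: no member can receive an annotation "
                "(p_conserved = p_extra = 0)"
            )
        if self.p_gap >= 1.0:
            raise ConfigurationError("p_gap must be < 1")

    @property
    def _sizes(self) -> tuple[int, ...]:
        if isinstance(self.family_size, int):
            return (self.family_size,)
        return tuple(self.family_size)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated families with labels and ground truth."""

    families: tuple[FamilyAlignment, ...]
    annotations: dict[str, AnnotationSet]
    predictions: dict[str, PredictionSet]
    truth: dict[str, frozenset[int]]  # family_id -> planted binding columns
    config: SyntheticConfig

    def family_annotations(self, fam: FamilyAlignment) -> dict[str, AnnotationSet]:
        return {
            m.protein_id: self.annotations[m.protein_id]
            for m in fam
            if m.protein_id in self.annotations
        }


def _member_row(
    rng: np.random.Generator, cfg: SyntheticConfig, planted: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One member's (gap mask, annotated-column mask); annotation non-empty."""
    for _ in range(_MAX_RESAMPLE):
        gaps = rng.random(cfg.n_columns) < cfg.p_gap
        if gaps.all():
            continue
        annotated = np.zeros(cfg.n_columns, dtype=bool)
        annotated[planted] = rng.random(planted.size) < cfg.p_conserved
        extra_mask = ~annotated
        extra_mask[planted] = False
        annotated |= extra_mask & (rng.random(cfg.n_columns) < cfg.p_extra)
        annotated &= ~gaps
        if annotated.any():
            return gaps, annotated
    raise ConfigurationError(
        "could not draw a non-empty annotation; config too sparse "
        f"(p_conserved={cfg.p_conserved}, p_extra={cfg.p_extra}, "
        f"p_gap={cfg.p_gap})"
    )


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate families, annotations, noisy predictions and ground truth.

    Reproducible: the same config (including seed) yields byte-identical
    output.  Every member's annotation is non-empty (members are redrawn
    until so); predictions may be empty.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg._sizes
    letters = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

    families: list[FamilyAlignment] = []
    annotations: dict[str, AnnotationSet] = {}
    predictions: dict[str, PredictionSet] = {}
    truth: dict[str, frozenset[int]] = {}

    for fi in range(cfg.n_families):
        family_id = f"F{fi:04d}"
        size = (
            cfg.family_size
            if isinstance(cfg.family_size, int)
            else int(sizes[rng.integers(len(sizes))])
        )
        planted = np.sort(
            rng.choice(cfg.n_columns, size=cfg.n_binding_columns, replace=False)
        )
        gap_rows = []
        annot_rows = []
        for _ in range(size):
            gaps, annotated = _member_row(rng, cfg, planted)
            gap_rows.append(gaps)
            annot_rows.append(annotated)
        gap_matrix = np.stack(gap_rows)

        keep = ~gap_matrix.all(axis=0)  # drop all-gap columns
        planted_mask = np.zeros(cfg.n_columns, dtype=bool)
        planted_mask[planted] = True
        truth[family_id] = frozenset(
            (np.flatnonzero(planted_mask[keep]) + 1).tolist()
        )

        members = []
        for mi in range(size):
            pid = f"{family_id}_P{mi:02d}"
            gaps = gap_rows[mi][keep]
            annotated = annot_rows[mi][keep]
            chars = letters[rng.integers(len(letters), size=keep.sum())]
            row = np.full(keep.sum(), ord("-"), dtype=np.uint8)
            row[~gaps] = chars[~gaps]
            members.append(AlignedSequence(pid, row.tobytes().decode()))

            # residue coordinates: rank of each non-gap column
            residue_index = np.cumsum(~gaps)
            annot_positions = frozenset(residue_index[annotated].tolist())
            annotations[pid] = AnnotationSet(pid, annot_positions)

            length = int((~gaps).sum())
            is_annot = np.zeros(length + 1, dtype=bool)
            is_annot[list(annot_positions)] = True
            noise = rng.random(length + 1)
            predicted = np.zeros(length + 1, dtype=bool)
            predicted[is_annot] = noise[is_annot] >= cfg.fn_rate
            predicted[~is_annot] = noise[~is_annot] < cfg.fp_rate
            predicted[0] = False
            predictions[pid] = PredictionSet(
                pid, frozenset(np.flatnonzero(predicted).tolist())
            )

        families.append(FamilyAlignment(family_id, tuple(members)))

    return SyntheticDataset(
        families=tuple(families),
        annotations=annotations,
        predictions=predictions,
        truth=truth,
        config=cfg,
    )


def expected_similarity(
    cfg: SyntheticConfig, n_pairs: int = 50_000, seed: int | None = None
) -> float:
    """Monte-Carlo expectation of the pairwise similarity under a config.

    Draws pairs of member annotation column sets directly from the
    gap-free label model (``p_gap`` must be 0) and averages their
    similarity; serves as the independent oracle for the generator and
    the similarity statistic.  Pairs where either member is empty are
    redrawn by rejection, matching the generator's resampling.
    """
    if cfg.p_gap != 0.0:
        raise ConfigurationError("expected_similarity requires p_gap = 0")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    B, L = cfg.n_binding_columns, cfg.n_columns

    sims: list[np.ndarray] = []
    collected = 0
    while collected < n_pairs:
        batch = n_pairs - collected
        kept = rng.random((2, batch, B)) < cfg.p_conserved
        extra = rng.random((2, batch, L - B)) < cfg.p_extra
        size = kept.sum(axis=2) + extra.sum(axis=2)  # (2, batch)
        valid = (size > 0).all(axis=0)
        if not valid.any():
            continue
        overlap = (
            (kept[0] & kept[1]).sum(axis=1) + (extra[0] & extra[1]).sum(axis=1)
        )[valid]
        sims.append(100.0 * overlap / size[:, valid].max(axis=0))
        collected += int(valid.sum())
    return float(np.concatenate(sims).mean())


def expected_random_similarity(k: int, L: int) -> float:
    """Exact expected similarity of two independent uniform k-subsets of L.

    The overlap is hypergeometric with mean k²/L, so the expected
    similarity is 100·k/L.
    """
    mean_overlap = float(hypergeom(M=L, n=k, N=k).mean())
    return 100.0 * mean_overlap / k


def write_dataset(
    ds: SyntheticDataset, outdir: str | Path, format: str = "fasta"
) -> None:
    """Write alignments, annotation/prediction TSVs and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "fasta" if format == "fasta" else "sto"
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for fam in ds.families:
        write_alignment(fam, aln_dir / f"{fam.family_id}.{ext}", format)
    write_position_table(ds.annotations, outdir / "annotations.tsv")
    write_position_table(ds.predictions, outdir / "predictions.tsv")
    payload = {
        "config": asdict(ds.config),
        "planted_columns": {
            fid: sorted(cols) for fid, cols in sorted(ds.truth.items())
        },
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2))
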