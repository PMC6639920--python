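from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from bindfam import AlignedSequence, AnnotationSet, FamilyAlignment, PredictionSet

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_family(family_id: str, rows: dict[str, str]) -> FamilyAlignment:
    return FamilyAlignment(
        family_id, tuple(AlignedSequence(pid, s) for pid, s in rows.items())
    )


def annots(mapping: dict[str, set[int]]) -> dict[str, AnnotationSet]:
    return {pid: AnnotationSet(pid, frozenset(p)) for pid, p in mapping.items()}


def preds(mapping: dict[str, set[int]]) -> dict[str, PredictionSet]:
    return {pid: PredictionSet(pid, frozenset(p)) for pid, p in mapping.items()}


@pytest.fixture
def toy_family() -> FamilyAlignment:
    """Three aligned members with gaps at known places."""
    return make_family(
        "toy",
        {
            "P1": "AC-DEF",
            "P2": "ACGDE-",
            "P3": "A--DEF",
        },
    )


@pytest.fixture
def small_dataset():
    from bindfam import SyntheticConfig, generate

    return generate(SyntheticConfig(n_families=12, seed=123))
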