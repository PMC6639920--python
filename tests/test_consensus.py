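from __future__ import annotations

import numpy as np
import pytest

from bindfam import (
    AlignedSequence,
    ConsensusConfig,
    SyntheticConfig,
    consensus_columns,
    consensus_to_protein,
    generate,
    sweep_thresholds,
)
from bindfam.annotations import map_to_columns
from conftest import annots, make_family, preds


class TestConsensusColumns:
    def test_gap_aware_denominator(self):
        # two of three predict binding at a column where the third is
        # gapped: fraction is 2/2, not 2/3
        fam = make_family("f", {"P1": "ACD", "P2": "ACD", "P3": "A-D"})
        table = preds({"P1": {2}, "P2": {2}, "P3": set()})
        cols = consensus_columns(fam, table, ConsensusConfig(1.0))
        assert 2 in cols

    def test_minority_below_threshold(self):
        fam = make_family("f", {"P1": "ACD", "P2": "ACD", "P3": "ACD"})
        table = preds({"P1": {2}, "P2": set(), "P3": set()})
        cols = consensus_columns(fam, table, ConsensusConfig(0.5))
        assert 2 not in cols
        assert cols == frozenset()

    def test_union_and_intersection_limits(self):
        fam = make_family("f", {"P1": "ACDE", "P2": "ACDE", "P3": "AC-E"})
        table = preds({"P1": {1, 2, 4}, "P2": {2, 4}, "P3": {3}})  # P3 res 3 = col 4
        union = consensus_columns(fam, table, ConsensusConfig(0.01))
        assert union == frozenset({1, 2, 4})
        # column 4 is the only one predicted by every non-gap member
        inter = consensus_columns(fam, table, ConsensusConfig(1.0))
        assert inter == frozenset({4})

    def test_missing_prediction_record_counts_in_denominator(self):
        fam = make_family("f", {"P1": "AC", "P2": "AC"})
        table = preds({"P1": {1}})  # P2 absent => all-non-binding
        assert consensus_columns(fam, table, ConsensusConfig(1.0)) == frozenset()
        assert consensus_columns(fam, table, ConsensusConfig(0.5)) == frozenset({1})

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ConsensusConfig(0.0)
        with pytest.raises(ValueError):
            ConsensusConfig(1.5)

    def test_monotone_shrinkage(self, small_dataset):
        for fam in small_dataset.families:
            previous = None
            for t in (0.01, 0.25, 0.5, 0.75, 1.0):
                cols = consensus_columns(
                    fam, small_dataset.predictions, ConsensusConfig(t)
                )
                if previous is not None:
                    assert cols <= previous
                previous = cols


class TestConsensusToProtein:
    def test_projection(self):
        seq = AlignedSequence("P", "A-CD")
        assert consensus_to_protein(frozenset({3}), seq).positions == frozenset({2})

    def test_all_gapped_columns_project_to_nothing(self):
        seq = AlignedSequence("P", "A-C-")
        assert consensus_to_protein(frozenset({2, 4}), seq).positions == frozenset()

    def test_round_trip_on_gap_free_sequence(self):
        seq = AlignedSequence("P", "ACDEFG")
        from bindfam import AnnotationSet

        cols = map_to_columns(AnnotationSet("P", frozenset({2, 5})), seq).columns
        assert consensus_to_protein(cols, seq).positions == frozenset({2, 5})


class TestSweepThresholds:
    def test_perfect_predictions_score_perfectly_at_union(self):
        cfg = SyntheticConfig(
            n_families=5, family_size=3, n_columns=40, n_binding_columns=4,
            p_conserved=1.0, p_extra=0.0, p_gap=0.0, fp_rate=0.0, fn_rate=0.0,
            seed=3,
        )
        ds = generate(cfg)
        table = sweep_thresholds(
            ds.families, ds.predictions, ds.annotations, [0.01, 1.0]
        )
        assert table["precision_mean"].tolist() == pytest.approx([100.0, 100.0])
        assert table["recall_mean"].tolist() == pytest.approx([100.0, 100.0])

    def test_predicted_count_non_increasing_in_threshold(self, small_dataset):
        table = sweep_thresholds(
            small_dataset.families,
            small_dataset.predictions,
            small_dataset.annotations,
            [0.01, 0.2, 0.5, 0.8, 1.0],
        )
        counts = table["mean_predicted_per_protein"].to_numpy()
        assert (np.diff(counts) <= 1e-12).all()
        fractions = table["fraction_proteins_with_prediction"].to_numpy()
        assert (np.diff(fractions) <= 1e-12).all()

    def test_unanimity_raises_precision_over_raw_predictions(self):
        # conserved truth + independent per-residue false positives:
        # unanimity filters the noise
        cfg = SyntheticConfig(
            n_families=40, family_size=5, n_columns=80, n_binding_columns=5,
            p_conserved=1.0, p_extra=0.0, p_gap=0.0, fp_rate=0.1, fn_rate=0.0,
            seed=11,
        )
        ds = generate(cfg)
        from bindfam import aggregate, confusion, score

        raw = {}
        for fam in ds.families:
            for m in fam:
                c = confusion(
                    ds.predictions[m.protein_id],
                    ds.annotations[m.protein_id],
                    m.length_ungapped,
                )
                raw[m.protein_id] = score(c)
        raw_precision = aggregate(raw)["precision"].mean
        table = sweep_thresholds(
            ds.families, ds.predictions, ds.annotations, [0.01, 1.0]
        )
        consensus_precision = table["precision_mean"].iloc[1]
        assert consensus_precision > raw_precision
        assert consensus_precision > table["precision_mean"].iloc[0]

    def test_proteins_without_consensus_excluded_from_precision_only(self):
        fam = make_family("f", {"P1": "ACDE", "P2": "ACDE", "P3": "ACDE"})
        p = preds({"P1": {1}, "P2": set(), "P3": set()})
        a = annots({"P1": {1}, "P2": {1}, "P3": {2}})
        table = sweep_thresholds([fam], p, a, [1.0])
        # nobody predicts at unanimity -> precision undefined for all
        assert table["precision_n"].iloc[0] == 0
        assert table["recall_n"].iloc[0] == 3
        assert table["recall_mean"].iloc[0] == 0.0
        assert table["fraction_proteins_with_prediction"].iloc[0] == 0.0
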