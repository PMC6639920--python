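from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bindfam import (
    FamilySimilarity,
    align_family,
    cross_subset,
    family_similarity,
    group_similarity,
    pairwise_similarity,
    regroup_by_label,
    reverse_cumulative,
)
from bindfam.errors import (
    InsufficientDataError,
    InsufficientMembersError,
    UndefinedSimilarityError,
)
from conftest import annots, make_family
from oracles import brute_family_mean, brute_pairwise, sort_and_scan_cumulative

column_sets = st.sets(st.integers(1, 30), min_size=1, max_size=15)


class TestPairwiseSimilarity:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ({1, 2, 3}, {2, 3, 4}, pytest.approx(200 / 3)),
            ({5, 9}, {5, 9}, 100.0),
            ({1}, {2}, 0.0),
            ({1, 2}, {1, 2, 3, 4}, 50.0),
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert pairwise_similarity(x, y) == expected

    def test_empty_set_is_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            pairwise_similarity(set(), {1})

    @given(column_sets, column_sets)
    def test_symmetry_and_bounds(self, x, y):
        s = pairwise_similarity(x, y)
        assert s == pairwise_similarity(y, x)
        assert 0.0 <= s <= 100.0

    @given(column_sets, column_sets)
    def test_hundred_iff_identical(self, x, y):
        s = pairwise_similarity(x, y)
        assert (s == 100.0) == (x == y)

    @given(column_sets, column_sets)
    def test_matches_definition_oracle(self, x, y):
        assert pairwise_similarity(x, y) == pytest.approx(brute_pairwise(x, y))


class TestFamilySimilarity:
    def test_mean_of_planted_pairwise_values(self):
        # columns: P1={1,2}, P2={1,2}, P3={3,4} -> sims 100, 0, 0
        fam = make_family("f", {"P1": "ABCD", "P2": "ABCD", "P3": "ABCD"})
        table = annots({"P1": {1, 2}, "P2": {1, 2}, "P3": {3, 4}})
        res = family_similarity(fam, table)
        assert res.mean_similarity == pytest.approx(100 / 3)
        assert res.n_pairs == 3
        assert res.n_members == 3

    def test_identical_sets_score_hundred(self):
        fam = make_family("f", {"P1": "AB-D", "P2": "ABCD"})
        # same columns {1, 4} despite the gap
        table = annots({"P1": {1, 3}, "P2": {1, 4}})
        assert family_similarity(fam, table).mean_similarity == 100.0

    def test_unannotated_members_excluded(self):
        fam = make_family("f", {"P1": "AB", "P2": "AB", "P3": "AB"})
        table = annots({"P1": {1}, "P2": {1}})
        res = family_similarity(fam, table)
        assert res.n_members == 2

    def test_fewer_than_two_annotated_is_error(self):
        fam = make_family("f", {"P1": "AB", "P2": "AB"})
        with pytest.raises(InsufficientMembersError):
            family_similarity(fam, annots({"P1": {1}}))

    def test_four_members_match_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        width = 12
        sets = [
            set((rng.choice(width, size=rng.integers(1, 5), replace=False) + 1).tolist())
            for _ in range(4)
        ]
        rows = {f"P{i}": "A" * width for i in range(4)}
        table = annots({f"P{i}": sets[i] for i in range(4)})
        res = family_similarity(make_family("f", rows), table)
        assert res.mean_similarity == pytest.approx(brute_family_mean(sets))
        assert res.n_pairs == 6


class TestGroupSimilarity:
    def test_stated_formula(self):
        fams = [
            FamilySimilarity(f"f{i}", v, 1, 2) for i, v in enumerate([10.0, 20.0, 30.0])
        ]
        stat = group_similarity(fams)
        assert stat.mean == pytest.approx(20.0)
        assert stat.se == pytest.approx(10.0 / np.sqrt(2))
        assert stat.unit == "family"

    def test_all_equal_gives_zero_se(self):
        fams = [FamilySimilarity(f"f{i}", 100.0, 1, 2) for i in range(5)]
        stat = group_similarity(fams)
        assert stat.mean == 100.0
        assert stat.se == 0.0

    def test_order_invariance_and_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 100, size=50)
        fams = [FamilySimilarity(f"f{i}", v, 3, 3) for i, v in enumerate(values)]
        stat = group_similarity(fams)
        assert stat.mean == pytest.approx(values.mean())
        assert stat.se == pytest.approx(np.std(values, ddof=1) / np.sqrt(49))
        assert group_similarity(reversed(fams)).mean == pytest.approx(stat.mean)

    def test_single_family_is_error(self):
        with pytest.raises(InsufficientDataError):
            group_similarity([FamilySimilarity("f", 10.0, 1, 2)])


class TestRegroupByLabel:
    def test_identical_proteins_same_label(self):
        table = annots({"P1": {2, 5}, "P2": {2, 5}, "P3": {1}})
        labels = {"P1": "G1", "P2": "G1"}

        def provider(label, pids):
            return align_family([(pid, "ACDEFG") for pid in pids], family_id=label)

        results = regroup_by_label(table, labels, provider)
        assert len(results) == 1
        assert results[0].family_id == "G1"
        assert results[0].mean_similarity == 100.0

    def test_singleton_groups_skipped(self):
        table = annots({"P1": {1}, "P2": {1}})
        labels = {"P1": "G1", "P2": "G2"}
        assert regroup_by_label(table, labels, lambda *a: None) == []


class TestCrossSubset:
    def test_one_representative_per_b_label(self):
        a = {"P1": "E1", "P2": "E1", "P3": "E1"}
        b = {"P1": "F1", "P2": "F1", "P3": "F2"}
        out = cross_subset(a, b, "same_a_diff_b", seed=0)
        assert set(out.values()) == {"E1"}
        assert "P3" in out
        assert len(out) == 2

    def test_identical_tables_give_empty(self):
        a = {"P1": "X", "P2": "X"}
        assert cross_subset(a, dict(a), "same_a_diff_b", seed=1) == {}

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        a = {f"P{i}": f"E{i % 5}" for i in range(40)}
        b = {f"P{i}": f"F{rng.integers(8)}" for i in range(40)}
        first = cross_subset(a, b, "same_a_diff_b", seed=9)
        assert first == cross_subset(a, b, "same_a_diff_b", seed=9)

    def test_intersection_mode(self):
        a = {"P1": "E1", "P2": "E1", "P3": "E1", "P4": "E2"}
        b = {"P1": "F1", "P2": "F1", "P3": "F2", "P4": "F1"}
        out = cross_subset(a, b, "same_a_same_b", seed=0)
        assert out == {"P1": "E1|F1", "P2": "E1|F1"}


class TestReverseCumulative:
    def test_worked_example(self):
        table = reverse_cumulative([10.0, 55.0, 70.0], [0.0, 50.0])
        assert table["count"].tolist() == [3, 2]
        assert table["fraction"].tolist() == pytest.approx([1.0, 2 / 3])

    def test_random_values_match_scan_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 100, size=200).tolist()
        thresholds = [0.0, 5.5, 25.0, 50.0, 60.0, 99.9, 100.0]
        table = reverse_cumulative(values, thresholds)
        expected = sort_and_scan_cumulative(values, thresholds)
        assert list(zip(table["threshold"], table["count"])) == expected
        assert (np.diff(table["count"]) <= 0).all()

    def test_empty_values_error(self):
        with pytest.raises(InsufficientDataError):
            reverse_cumulative([], [0.0])
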