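"""Connection frequencies, classification, ranking and induction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rbninfer import (
    GenePanel,
    RowSolutionSet,
    classify_connections,
    connection_frequencies,
    induction_scan,
    rank_interactions,
    true_positive_rate,
)
from rbninfer.interaction_analysis import VALUES, _classify_entry


def _rowset(rows, gene_i=0):
    rows = np.asarray(rows, dtype=np.int8)
    return RowSolutionSet(gene_i=gene_i, n=rows.shape[1], rows=rows, mode="enumerated")


rowset_strategy = st.lists(
    st.lists(st.sampled_from((-1, 0, 1)), min_size=3, max_size=3),
    min_size=1, max_size=12,
)


class TestFrequencies:
    def test_constant_column_has_unit_frequency(self):
        table = connection_frequencies(_rowset([[1, 0], [1, -1]]))
        assert table.freq[0, 0].tolist() == [0.0, 0.0, 1.0]

    def test_split_column_frequencies(self):
        table = connection_frequencies(_rowset([[1, 1], [1, -1]]))
        assert table.freq[0, 1].tolist() == [0.5, 0.0, 0.5]

    def test_empty_rowset_is_an_error(self):
        empty = RowSolutionSet(0, 2, np.zeros((0, 2), np.int8), "enumerated",
                               feasible=False)
        with pytest.raises(ValueError, match="infeasible"):
            connection_frequencies(empty)

    @given(rows=rowset_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_frequencies_normalize(self, rows):
        table = connection_frequencies(_rowset(rows))
        sums = table.freq[0].sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestClassification:
    def test_three_way_rules(self):
        assert _classify_entry(np.array([0.0, 0.3, 0.7])).kind == "partially_determined"
        assert _classify_entry(np.array([0.0, 0.0, 1.0])).kind == "determined"
        assert _classify_entry(np.array([0.2, 0.3, 0.5])).kind == "undetermined"

    def test_single_row_set_is_fully_determined(self):
        table = connection_frequencies(_rowset([[1, -1, 0]]))
        report = classify_connections(table)
        assert report.determined_any == 3
        assert report.determined_nonzero == 2
        assert report.determined_zero == 1

    def test_determined_value_and_partial_exclusion_are_reported(self):
        table = connection_frequencies(_rowset([[1, 1], [1, -1]]))
        report = classify_connections(table)
        assert report.classes[(0, 0)].value == 1
        assert report.classes[(0, 1)].excluded == 0


class TestRanking:
    def _table(self, rowsets):
        return connection_frequencies(
            {rs.gene_i: rs for rs in rowsets},
            GenePanel(tuple("ab")),
        )

    def test_rank_is_two_minus_zero_frequencies(self):
        table = self._table([
            _rowset([[0, 1], [0, 1]], gene_i=0),   # freq0(a<-b) = 0
            _rowset([[0, 0], [1, 0]], gene_i=1),   # freq0(b<-a) = 0.5
        ])
        ranks = rank_interactions(table)
        assert ranks.pairs == [(1.5, "a", "b")]

    def test_rank_equals_summed_four_term_form(self):
        # identity: inh+act in both directions == 2 - freq0 - freq0
        rows_a = [[0, 1], [0, -1], [1, 0]]
        rows_b = [[1, 0], [-1, 0]]
        table = self._table([_rowset(rows_a, 0), _rowset(rows_b, 1)])
        f = table.freq
        four_term = f[0, 1, 0] + f[0, 1, 2] + f[1, 0, 0] + f[1, 0, 2]
        assert rank_interactions(table).pairs[0][0] == pytest.approx(four_term)

    def test_extreme_ranks(self):
        both_zero = self._table([
            _rowset([[1, 0]], 0), _rowset([[0, 1]], 1),
        ])
        assert both_zero.freq0(0, 1) == 1.0
        assert rank_interactions(both_zero).pairs[0][0] == 0.0
        both_det = self._table([
            _rowset([[0, 1]], 0), _rowset([[-1, 0]], 1),
        ])
        assert rank_interactions(both_det).pairs[0][0] == 2.0

    def test_self_pairs_reported_separately(self):
        table = self._table([
            _rowset([[1, 0]], 0), _rowset([[0, 0]], 1),
        ])
        ranks = rank_interactions(table)
        assert ranks.self_ranks["a"] == 1.0
        assert ranks.self_ranks["b"] == 0.0
        assert len(ranks.pairs) == 1  # self pairs are not among the ranked pairs


class TestTruePositiveRate:
    def test_all_pairs_recovers_reference_density(self, yeast):
        from rbninfer import infer_rowsets
        rowsets = infer_rowsets([yeast.trajectory], yeast.network.self_degradation)
        table = connection_frequencies(rowsets, yeast.network.panel)
        ranks = rank_interactions(table)
        n = yeast.network.n
        k = n * (n - 1) // 2
        expected = len(yeast.edges) / k
        assert true_positive_rate(ranks, yeast.edges, k) == pytest.approx(expected)

    def test_matches_direct_set_intersection(self):
        table = connection_frequencies(
            {i: _rowset(np.random.default_rng(i).integers(-1, 2, (4, 3)), i)
             for i in range(3)},
            GenePanel(tuple("abc")),
        )
        ranks = rank_interactions(table)
        ref = {frozenset(("a", "b")), frozenset(("a", "c"))}
        for k in (1, 2, 3):
            brute = sum(1 for _, a, b in ranks.pairs[:k]
                        if frozenset((a, b)) in ref) / k
            assert true_positive_rate(ranks, ref, k) == brute

    def test_empty_reference_warns_and_returns_zero(self):
        table = connection_frequencies(
            {0: _rowset([[0, 1]], 0), 1: _rowset([[1, 0]], 1)},
            GenePanel(tuple("ab")),
        )
        ranks = rank_interactions(table)
        with pytest.warns(UserWarning):
            assert true_positive_rate(ranks, [], 1) == 0.0


class TestInduction:
    def test_worked_three_row_scan(self):
        rs = _rowset([[1, 1], [1, -1], [-1, 0]])
        result = induction_scan(rs)
        by_assignment = {(c.regulator, c.value): c.score for c in result.candidates}
        assert by_assignment[(0, -1)] == 2.0   # leaves {(-1,0)}: both determined
        assert by_assignment[(0, 1)] == 1.5    # leaves {(1,1),(1,-1)}
        assert result.best[0].regulator == 0 and result.best[0].value == -1

    def test_single_row_set_has_nothing_to_induce(self):
        result = induction_scan(_rowset([[1, -1, 0]]))
        assert result.candidates == []
        assert result.best == []

    def test_infeasible_values_are_skipped(self):
        rs = _rowset([[1, 1], [1, -1]])
        result = induction_scan(rs)
        assert all(not (c.regulator == 1 and c.value == 0)
                   for c in result.candidates)

    @given(rows=rowset_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_induction_scores_never_drop_below_base(self, rows):
        """Restricting a row set can only remove values from each column,
        so determination -- and hence the score -- is monotone."""
        result = induction_scan(_rowset(rows))
        for cand in result.candidates:
            assert cand.score >= result.base_score - 1e-12
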