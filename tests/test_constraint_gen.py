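"""Constraint families generated from observed transitions.

The transition (second) family is the complete characterisation of
consistency; the triplet and pairwise families are implied by it and
must never change the solution set.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rbninfer import (
    EmptyDomainError,
    InfeasibleTransitionError,
    build_row_csp,
    enumerate_consistent_rows,
    gene_update,
    pairwise_constraint,
    transition_constraint,
    triplet_domain_restrictions,
)
from rbninfer.constraint_gen import FULL_DOMAIN

# the four-gene worked time series
TS4 = np.array(
    [
        [1, 1, 0, 0],
        [1, 0, 0, 0],
        [1, 0, 1, 0],
        [1, 0, 1, 1],
        [0, 0, 1, 1],
    ],
    dtype=np.uint8,
)


class TestTransitionConstraint:
    def test_switch_on_requires_positive_active_sum(self):
        # x4 turns on from the state where x1 and x3 are active
        c = transition_constraint(3, TS4[2], 1, d_i=False)
        assert c.plus == frozenset({0, 2})
        assert c.minus == frozenset()
        assert (c.relation, c.bound) == (">=", 1)

    def test_hold_off_from_all_zero_state_is_vacuous(self):
        assert transition_constraint(0, np.zeros(4, int), 0, d_i=False) is None

    def test_switch_on_from_all_zero_state_is_infeasible(self):
        with pytest.raises(InfeasibleTransitionError):
            transition_constraint(0, np.zeros(4, int), 1, d_i=False)

    def test_switch_off_bound_matches_brute_force(self):
        # 1 -> 0 with active set {x2, x5}: every admissible (a2, a5) pair
        # must drive the update to 0, and vice versa
        state = np.array([1, 1, 0, 0, 1])
        c = transition_constraint(0, state, 0, d_i=False)
        assert c.plus == frozenset({0, 1, 4})
        for a2, a5 in itertools.product((-1, 0, 1), repeat=2):
            row = np.array([0, a2, 0, 0, a5])
            assert c.satisfied_by(row) == (gene_update(row, False, state, 1) == 0)

    @pytest.mark.parametrize(
        "current,nxt,d,expected",
        [
            (0, 1, False, (">=", 1)),
            (0, 0, False, ("<=", 0)),
            (1, 0, False, ("<=", -1)),
            (1, 1, False, (">=", 0)),
            (1, 0, True, ("<=", 0)),
            (1, 1, True, (">=", 1)),
        ],
    )
    def test_bounds_by_transition_type(self, current, nxt, d, expected):
        state = np.array([1, 1, 0])
        state[0] = current
        c = transition_constraint(0, state, nxt, d_i=d)
        assert (c.relation, c.bound) == expected

    @given(
        bits=st.lists(st.integers(0, 1), min_size=3, max_size=5),
        row=st.lists(st.integers(-1, 1), min_size=3, max_size=5),
        nxt=st.integers(0, 1),
        d=st.booleans(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_constraint_agrees_with_update_rule(self, bits, row, nxt, d):
        """A row satisfies the transition constraint iff the threshold
        update actually produces the observed next value."""
        n = min(len(bits), len(row))
        state = np.array(bits[:n])
        r = np.array(row[:n])
        truth = gene_update(r, d, state, int(state[0])) == nxt
        try:
            c = transition_constraint(0, state, nxt, d_i=d)
        except InfeasibleTransitionError:
            assert not truth
            return
        accepted = True if c is None else c.satisfied_by(r)
        assert accepted == truth


class TestTripletRestrictions:
    def test_single_gene_change_certifies_direct_regulation(self):
        # x2 alone changes between the first two states; x3 then switches
        assert triplet_domain_restrictions(TS4[0], TS4[1], TS4[2]) == [(2, 1)]

    def test_identical_predecessors_yield_nothing(self):
        assert triplet_domain_restrictions(TS4[0], TS4[0], TS4[1]) == []

    def test_two_gene_difference_yields_nothing(self):
        s0 = np.array([1, 1, 1, 0])
        assert triplet_domain_restrictions(s0, TS4[1], TS4[2]) == []


class TestPairwiseConstraint:
    def test_forced_activation_from_near_identical_predecessors(self):
        # gene 1 is inhibited when x4 is inactive and holds its 1 when x4
        # is active; the difference pins a_14 = 1
        t_a = (np.array([1, 1, 1, 0]), 0)  # x1: 1 -> 0
        t_b = (np.array([1, 1, 1, 1]), 1)  # x1: 1 -> 1
        c = pairwise_constraint(0, t_a, t_b, d_i=False)
        assert c.plus == frozenset()
        assert c.minus == frozenset({3})
        assert (c.relation, c.bound) == ("<=", -1)  # -a_14 <= -1, i.e. a_14 = 1
        assert [r for r in itertools.product((-1, 0, 1), repeat=4)
                if c.satisfied_by(np.array(r))] == \
            [r for r in itertools.product((-1, 0, 1), repeat=4) if r[3] == 1]

    def test_same_direction_transitions_are_uninformative(self):
        t_a = (np.array([1, 0, 0, 0]), 1)
        t_b = (np.array([0, 1, 1, 0]), 1)
        assert pairwise_constraint(0, t_a, t_b, d_i=False) is None

    @pytest.mark.parametrize(
        "ta,tb,expected",
        [
            ((1, 0), (0, 1), ("<=", -2)),
            ((0, 1), (0, 0), (">=", 1)),
            ((1, 1), (0, 0), (">=", 0)),
            ((0, 0), (0, 1), ("<=", -1)),
            ((0, 1), (1, 0), (">=", 2)),
            ((1, 1), (1, 0), (">=", 1)),
            ((0, 0), (1, 1), ("<=", 0)),
            ((1, 0), (1, 1), ("<=", -1)),
        ],
    )
    def test_difference_bounds_for_all_informative_combinations(self, ta, tb, expected):
        n = 4
        state_a = np.array([ta[0], 1, 0, 0])
        state_b = np.array([tb[0], 0, 1, 0])
        c = pairwise_constraint(0, (state_a, ta[1]), (state_b, tb[1]), d_i=False)
        assert (c.relation, c.bound) == expected


class TestBuildRowCSP:
    def test_worked_example_constraint_is_present(self):
        csp = build_row_csp(3, TS4, d_i=False)
        wanted = [c for c in csp.inequalities
                  if c.plus == frozenset({0, 2}) and c.relation == ">=" and c.bound == 1]
        assert wanted, "a_41 + a_43 >= 1 must be generated"

    def test_triplet_restriction_prunes_the_domain(self):
        csp = build_row_csp(2, TS4, d_i=False)
        assert csp.domains[1] == frozenset({-1, 1})  # a_32 != 0

    def test_identical_states_leave_full_domains(self):
        seg = np.array([[1, 0, 1], [1, 0, 1]], dtype=np.uint8)
        csp = build_row_csp(0, seg, d_i=False)
        assert all(dom == FULL_DOMAIN for dom in csp.domains)

    def test_prior_mask_pins_entries_to_zero(self):
        csp = build_row_csp(3, TS4, d_i=False, prior_mask=[(3, 1)])
        assert csp.domains[1] == frozenset({0})

    def test_prior_mask_conflicting_with_triplet_is_surfaced(self):
        with pytest.raises(EmptyDomainError):
            build_row_csp(2, TS4, d_i=False, prior_mask=[(2, 1)])

    def test_infeasibility_error_carries_time_context(self):
        seg = np.array([[0, 0, 0], [1, 0, 0]], dtype=np.uint8)
        with pytest.raises(InfeasibleTransitionError) as exc:
            build_row_csp(0, seg, d_i=False)
        assert exc.value.time == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_implied_families_never_shrink_the_solution_set(self, seed, random_instance):
        """Triplet and pairwise constraints are consequences of the
        transition constraints: enumeration with and without them agrees."""
        net, traj = random_instance(seed, n=4, m=6)
        for i in range(net.n):
            d_i = bool(net.self_degradation[i])
            base = build_row_csp(i, traj, d_i, pairwise="off", triplets=False)
            full = build_row_csp(i, traj, d_i, pairwise="all", triplets=True)
            sol_base = enumerate_consistent_rows(base).rows
            sol_full = enumerate_consistent_rows(full).rows
            assert np.array_equal(sol_base, sol_full)

    @pytest.mark.parametrize("seed", range(5))
    def test_similar_pair_scope_is_equally_sound(self, seed, random_instance):
        net, traj = random_instance(seed, n=4, m=6)
        for i in range(net.n):
            d_i = bool(net.self_degradation[i])
            a = enumerate_consistent_rows(build_row_csp(i, traj, d_i, pairwise="all")).rows
            s = enumerate_consistent_rows(build_row_csp(i, traj, d_i, pairwise="similar")).rows
            assert np.array_equal(a, s)

    def test_all_bounds_and_sums_are_integers(self):
        csp = build_row_csp(3, TS4, d_i=False)
        for c in csp.inequalities:
            assert isinstance(c.bound, int)
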