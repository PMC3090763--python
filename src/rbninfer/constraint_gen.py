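"""Translate observed state transitions into integer sign inequalities.

Three constraint families are generated from a binary time series,
assuming the data were produced by a restricted Boolean network:

* **Transition constraints** (one per observed transition): the input of
  gene *i*, restricted to the genes active at time *t*, must have the
  sign that explains ``x_i(t) -> x_i(t+1)`` under the threshold rule.
* **Triplet domain restrictions**: when two consecutive states differ in
  a single gene *k*, any gene that changes on the following step must be
  directly regulated by *k* (``a_ik != 0``).
* **Pairwise (difference) constraints**: subtracting the transition
  constraints of two transitions of the same gene cancels the regulators
  the two source states share, leaving an inequality over the symmetric
  difference of their active sets.

All inequalities are over integer variables ``a_ij in {-1, 0, 1}``, so
strict bounds are normalised to non-strict integer form (``> 0`` is
stored as ``>= 1``).  The triplet and pairwise families are logical
consequences of the transition family; they never shrink the solution
set but sharpen propagation during search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .core_model import Trajectory

__all__ = [
    "SignInequality",
    "RowCSP",
    "InfeasibleTransitionError",
    "EmptyDomainError",
    "transition_constraint",
    "triplet_domain_restrictions",
    "pairwise_constraint",
    "build_row_csp",
]

FULL_DOMAIN = frozenset((-1, 0, 1))


class InfeasibleTransitionError(ValueError):
    """An observed transition admits no row of the restricted model.

    Raised e.g. for a 0 -> 1 switch out of the all-zero state: no choice
    of regulator signs can produce a positive input when no gene is active.
    """

    def __init__(self, gene: int, message: str, time: Optional[int] = None,
                 segment: Optional[int] = None):
        self.gene = gene
        self.time = time
        self.segment = segment
        super().__init__(message)

    def with_context(self, time: int, segment: int) -> "InfeasibleTransitionError":
        return InfeasibleTransitionError(
            self.gene,
            f"{self.args[0]} (gene index {self.gene}, segment {segment}, "
            f"transition {time} -> {time + 1})",
            time=time,
            segment=segment,
        )


class EmptyDomainError(ValueError):
    """Domain restrictions wiped out every value of a variable."""

    def __init__(self, gene: int, regulator: int):
        self.gene = gene
        self.regulator = regulator
        super().__init__(
            f"no feasible value left for entry a[{gene},{regulator}]"
        )


@dataclass(frozen=True)
class SignInequality:
    """Linear inequality ``sum_{j in plus} a_ij - sum_{j in minus} a_ij  rel  bound``.

    ``relation`` is ``">="`` or ``"<="``; bounds are integers.  ``plus``
    and ``minus`` are disjoint regulator index sets.
    """

    plus: frozenset[int]
    minus: frozenset[int]
    relation: Literal[">=", "<="]
    bound: int

    def __post_init__(self) -> None:
        if self.plus & self.minus:
            raise ValueError("plus and minus index sets must be disjoint")
        if self.relation not in (">=", "<="):
            raise ValueError("relation must be '>=' or '<='")

    def lhs(self, row: Sequence[int] | np.ndarray) -> int:
        r = np.asarray(row, dtype=np.int64)
        return int(sum(r[j] for j in self.plus) - sum(r[j] for j in self.minus))

    def satisfied_by(self, row: Sequence[int] | np.ndarray) -> bool:
        v = self.lhs(row)
        return v >= self.bound if self.relation == ">=" else v <= self.bound

    def indices(self) -> frozenset[int]:
        return self.plus | self.minus

    def is_trivially_unsatisfiable(self) -> bool:
        """True when no assignment over {-1,0,1} can satisfy the inequality."""
        span = len(self.plus) + len(self.minus)
        if self.relation == ">=":
            return span < self.bound
        return -span > self.bound

    def is_vacuous(self) -> bool:
        """True when every assignment over {-1,0,1} satisfies the inequality."""
        span = len(self.plus) + len(self.minus)
        if self.relation == ">=":
            return -span >= self.bound
        return span <= self.bound

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        terms = [f"+a_{j}" for j in sorted(self.plus)]
        terms += [f"-a_{j}" for j in sorted(self.minus)]
        body = " ".join(terms) if terms else "0"
        return f"{body} {self.relation} {self.bound}"


@dataclass
class RowCSP:
    """Per-gene CSP over the entries of one regulation-matrix row.

    Variables are ``a_i1 .. a_in`` with domains contained in
    ``{-1, 0, 1}``; constraints are :class:`SignInequality` instances.
    """

    gene_i: int
    n: int
    domains: list[frozenset[int]]
    inequalities: tuple[SignInequality, ...]
    d_i: bool

    def __post_init__(self) -> None:
        if len(self.domains) != self.n:
            raise ValueError("one domain per regulator required")
        for j, dom in enumerate(self.domains):
            if not dom:
                raise EmptyDomainError(self.gene_i, j)
            if not dom <= FULL_DOMAIN:
                raise ValueError(f"domain of a[{self.gene_i},{j}] not in {{-1,0,1}}")
        for ineq in self.inequalities:
            bad = [j for j in ineq.indices() if not 0 <= j < self.n]
            if bad:
                raise ValueError(f"inequality references invalid indices {bad}")

    @property
    def search_space(self) -> int:
        out = 1
        for dom in self.domains:
            out *= len(dom)
        return out


def _prop2_bound(current: int, nxt: int, d_i: bool) -> tuple[str, int]:
    """Relation and bound on the active-gene input sum for one transition."""
    if nxt == 1:
        # switching or staying ON needs a positive input, except that a
        # non-decaying gene may also hold a 1 on a null input
        return (">=", 1) if (current == 0 or d_i) else (">=", 0)
    # switching or staying OFF needs a negative input, except that a
    # null input suffices for a decaying gene or for holding a 0
    return ("<=", 0) if (current == 0 or d_i) else ("<=", -1)


def transition_constraint(
    i: int,
    state: Sequence[int] | np.ndarray,
    x_i_next: int,
    d_i: bool,
) -> Optional[SignInequality]:
    """Constraint on row *i* implied by one observed transition.

    With active set ``A(t) = {j : x_j(t) = 1}`` the sum
    ``sum_{j in A(t)} a_ij`` must satisfy:

    ====== =========== ===========
    change ``d_i`` off ``d_i`` on
    ====== =========== ===========
    0 -> 1 ``>= 1``    ``>= 1``
    0 -> 0 ``<= 0``    ``<= 0``
    1 -> 0 ``<= -1``   ``<= 0``
    1 -> 1 ``>= 0``    ``>= 1``
    ====== =========== ===========

    Returns ``None`` for vacuous constraints; raises
    :class:`InfeasibleTransitionError` when the active set is empty but
    the required relation cannot hold (no row explains the data).
    """
    s = np.asarray(state)
    if x_i_next not in (0, 1):
        raise ValueError("x_i_next must be 0 or 1")
    current = int(s[i])
    relation, bound = _prop2_bound(current, int(x_i_next), d_i)
    active = frozenset(int(j) for j in np.nonzero(s)[0])
    if not active:
        ok = (0 >= bound) if relation == ">=" else (0 <= bound)
        if ok:
            return None
        raise InfeasibleTransitionError(
            i,
            f"transition {current} -> {int(x_i_next)} of gene index {i} from an "
            "all-zero state cannot be produced by any restricted Boolean network",
        )
    return SignInequality(plus=active, minus=frozenset(), relation=relation, bound=bound)


def triplet_domain_restrictions(
    s_prev: Sequence[int] | np.ndarray,
    s_t: Sequence[int] | np.ndarray,
    s_next: Sequence[int] | np.ndarray,
) -> list[tuple[int, int]]:
    """Direct-regulation certificates from three consecutive states.

    If ``s_prev`` and ``s_t`` differ in exactly one gene *k*, every gene
    *i* that changes between ``s_t`` and ``s_next`` must be directly
    regulated by *k*; returns the ``(i, k)`` pairs meaning ``a_ik != 0``.
    Otherwise returns an empty list.
    """
    a, b, c = (np.asarray(x) for x in (s_prev, s_t, s_next))
    if not (a.shape == b.shape == c.shape):
        raise ValueError("states must have equal length")
    diff = np.nonzero(a != b)[0]
    if diff.shape[0] != 1:
        return []
    k = int(diff[0])
    return [(int(i), k) for i in np.nonzero(b != c)[0]]


def pairwise_constraint(
    i: int,
    transition_a: tuple[Sequence[int] | np.ndarray, int],
    transition_b: tuple[Sequence[int] | np.ndarray, int],
    d_i: bool,
) -> Optional[SignInequality]:
    """Difference constraint from two transitions of the same gene.

    Subtracting the transition constraints of ``transition_a`` (an upper
    bound) and ``transition_b`` (a lower bound), or vice versa, cancels
    the regulators active in both source states.  With
    ``P = A(t_a) \\ A(t_b)`` and ``Q = A(t_b) \\ A(t_a)`` the result
    bounds ``D = sum_{j in P} a_ij - sum_{j in Q} a_ij``.  Two
    transitions whose constraints bound the sum in the same direction
    yield nothing (``None``), as do vacuous differences.
    """
    state_a, next_a = transition_a
    state_b, next_b = transition_b
    sa = np.asarray(state_a)
    sb = np.asarray(state_b)
    if sa.shape != sb.shape:
        raise ValueError("states must have equal length")
    rel_a, bound_a = _prop2_bound(int(sa[i]), int(next_a), d_i)
    rel_b, bound_b = _prop2_bound(int(sb[i]), int(next_b), d_i)
    if rel_a == rel_b:
        return None
    active_a = frozenset(int(j) for j in np.nonzero(sa)[0])
    active_b = frozenset(int(j) for j in np.nonzero(sb)[0])
    plus = active_a - active_b
    minus = active_b - active_a
    # sum_a <= u and sum_b >= l  ==>  D <= u - l ; the >= case mirrors it
    relation = rel_a
    bound = bound_a - bound_b
    ineq = SignInequality(plus=plus, minus=minus, relation=relation, bound=bound)
    if ineq.is_vacuous():
        return None
    return ineq


def _segment_states(segment: Trajectory | np.ndarray) -> np.ndarray:
    if isinstance(segment, Trajectory):
        return segment.states
    st = np.asarray(segment)
    if st.ndim != 2:
        raise ValueError("a segment must be a 2-D (time x gene) array")
    return st


def build_row_csp(
    i: int,
    segments: Iterable[Trajectory | np.ndarray] | Trajectory | np.ndarray,
    d_i: bool,
    prior_mask: Optional[Iterable[tuple[int, int]]] = None,
    pairwise: Literal["all", "similar", "off"] = "all",
    triplets: bool = True,
) -> RowCSP:
    """Assemble the CSP for row *i* from one or more trajectory segments.

    Every consecutive pair contributes a transition constraint, every
    consecutive triple a (possible) domain restriction, and -- depending
    on ``pairwise`` -- ordered transition pairs within a segment
    contribute difference constraints (``"similar"`` limits them to pairs
    whose source states differ in at most one gene).  Prior-knowledge
    pairs ``(i, j)`` in ``prior_mask`` pin the domain of ``a_ij`` to
    ``{0}``.  Duplicate inequalities are dropped.  Constraints from
    multiple segments are conjoined (intersection semantics); union-mode
    pooling across segments is handled by the caller.
    """
    if isinstance(segments, (Trajectory, np.ndarray)):
        segments = [segments]
    seg_states = [_segment_states(s) for s in segments]
    if not seg_states:
        raise ValueError("at least one segment required")
    n = seg_states[0].shape[1]
    for st in seg_states:
        if st.shape[1] != n:
            raise ValueError("all segments must cover the same genes")
        if st.shape[0] < 2:
            raise ValueError("segments need at least two states")

    domains: list[frozenset[int]] = [FULL_DOMAIN] * n
    if prior_mask is not None:
        for (ti, tj) in prior_mask:
            if ti == i:
                domains[tj] = frozenset((0,))

    ineqs: dict[SignInequality, None] = {}
    for seg_idx, st in enumerate(seg_states):
        m = st.shape[0]
        for t in range(m - 1):
            try:
                c = transition_constraint(i, st[t], int(st[t + 1, i]), d_i)
            except InfeasibleTransitionError as err:
                raise err.with_context(time=t + 1, segment=seg_idx) from None
            if c is not None:
                ineqs[c] = None
        if triplets:
            for t in range(1, m - 1):
                for (gi, k) in triplet_domain_restrictions(st[t - 1], st[t], st[t + 1]):
                    if gi != i:
                        continue
                    restricted = domains[k] - {0}
                    if not restricted:
                        raise EmptyDomainError(i, k)
                    domains[k] = restricted
        if pairwise != "off":
            transitions = [(st[t], int(st[t + 1, i])) for t in range(m - 1)]
            for a in range(len(transitions)):
                for b in range(len(transitions)):
                    if a == b:
                        continue
                    if pairwise == "similar":
                        ham = int((transitions[a][0] != transitions[b][0]).sum())
                        if ham > 1:
                            continue
                    c = pairwise_constraint(i, transitions[a], transitions[b], d_i)
                    if c is not None:
                        ineqs[c] = None

    return RowCSP(
        gene_i=i,
        n=n,
        domains=domains,
        inequalities=tuple(ineqs),
        d_i=bool(d_i),
    )
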