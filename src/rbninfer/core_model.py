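"""Restricted (threshold) Boolean networks and their synchronous dynamics.

A restricted Boolean network over ``n`` genes is defined by a signed
regulation matrix ``A`` with entries in ``{-1, 0, 1}``: ``a_ij = 1`` means
gene *j* activates gene *i*, ``a_ij = -1`` means *j* inhibits *i*, and
``a_ij = 0`` means no direct regulation.  The *input* of gene *i* at time
*t* is the integer sum ``sum_j a_ij * x_j(t)`` over the current binary
state.  Under the synchronous update rule a gene switches ON when its
input is positive, OFF when negative, and on a zero (null) input it
either holds its previous value or -- if the gene carries the
self-degradation flag -- decays to 0.

Only threshold functions of this form are expressible, which is what
makes the model "restricted" relative to general Boolean networks; the
restriction is exactly what makes consistency with observed transitions
expressible as integer sign inequalities (see :mod:`rbninfer.constraint_gen`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GenePanel",
    "BooleanNetwork",
    "Trajectory",
    "AttractorReport",
    "SimulationResult",
    "gene_input",
    "gene_update",
    "network_step",
    "simulate",
    "find_attractors",
    "is_consistent_network",
]


@dataclass(frozen=True)
class GenePanel:
    """Ordered collection of unique gene names; fixes the index convention.

    The position of a name in ``names`` is the gene's index everywhere in
    this package (rows/columns of the regulation matrix, bits of a state).
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(str(x) for x in self.names))
        if len(self.names) < 1:
            raise ValueError("a gene panel needs at least one gene")
        if len(set(self.names)) != len(self.names):
            raise ValueError("gene names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def _as_bits(state: Sequence[int] | np.ndarray, n: int | None = None) -> np.ndarray:
    bits = np.asarray(state)
    if bits.ndim != 1:
        raise ValueError("a network state must be a 1-D binary vector")
    if n is not None and bits.shape[0] != n:
        raise ValueError(f"state has {bits.shape[0]} genes, expected {n}")
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("state entries must be 0 or 1")
    return bits.astype(np.uint8)


def _as_row(row: Sequence[int] | np.ndarray) -> np.ndarray:
    r = np.asarray(row)
    if r.ndim != 1:
        raise ValueError("a regulator row must be a 1-D vector")
    if not np.isin(r, (-1, 0, 1)).all():
        raise ValueError("regulation entries must be -1, 0 or 1")
    return r.astype(np.int8)


@dataclass
class BooleanNetwork:
    """A restricted Boolean network: panel + regulation matrix + decay flags.

    Parameters
    ----------
    panel
        Gene names; fixes dimension ``n``.
    matrix
        ``n x n`` integer array with entries in ``{-1, 0, 1}``; row *i*
        lists the regulators of gene *i*.
    self_degradation
        Length-``n`` booleans; ``True`` means the gene decays to 0 when
        its input is null instead of holding its value.
    """

    panel: GenePanel
    matrix: np.ndarray
    self_degradation: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.panel)
        A = np.asarray(self.matrix)
        if A.shape != (n, n):
            raise ValueError(f"regulation matrix must be {n}x{n}, got {A.shape}")
        if not np.isin(A, (-1, 0, 1)).all():
            raise ValueError("regulation matrix entries must be -1, 0 or 1")
        d = np.asarray(self.self_degradation, dtype=bool)
        if d.shape != (n,):
            raise ValueError("self-degradation flags must have one entry per gene")
        self.matrix = A.astype(np.int8)
        self.self_degradation = d

    @property
    def n(self) -> int:
        return len(self.panel)

    def row(self, i: int) -> np.ndarray:
        return self.matrix[i]

    def edges(self) -> list[tuple[str, str, int]]:
        """Nonzero entries as (target, regulator, sign) triples."""
        out = []
        for i, tgt in enumerate(self.panel):
            for j, reg in enumerate(self.panel):
                if self.matrix[i, j] != 0:
                    out.append((tgt, reg, int(self.matrix[i, j])))
        return out

    def undirected_edges(self) -> frozenset[frozenset[str]]:
        """Sign- and direction-agnostic edge set, for validation."""
        return frozenset(
            frozenset((t, r)) for t, r, _ in self.edges() if t != r
        ) | frozenset(frozenset((t,)) for t, r, _ in self.edges() if t == r)


@dataclass
class Trajectory:
    """An ordered sequence of network states (rows = time points)."""

    states: np.ndarray
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        st = np.asarray(self.states)
        if st.ndim != 2:
            raise ValueError("trajectory states must be a 2-D (time x gene) array")
        if not np.isin(st, (0, 1)).all():
            raise ValueError("trajectory entries must be 0 or 1")
        self.states = st.astype(np.uint8)
        if self.labels is not None:
            self.labels = tuple(str(x) for x in self.labels)
            if len(self.labels) != st.shape[0]:
                raise ValueError("one label per time point required")

    @property
    def m(self) -> int:
        return self.states.shape[0]

    @property
    def n(self) -> int:
        return self.states.shape[1]

    def transitions(self):
        """Iterate ``(S(t), S(t+1))`` pairs."""
        for t in range(self.m - 1):
            yield self.states[t], self.states[t + 1]


@dataclass
class SimulationResult:
    """Orbit produced by :func:`simulate`.

    ``closed`` is True when the orbit revisited a state within the step
    budget; ``cycle_entry`` is the trajectory index of the revisited
    state (the attractor entry point).
    """

    trajectory: Trajectory
    closed: bool
    cycle_entry: Optional[int]


@dataclass
class AttractorReport:
    """All attractors of a network with their basin sizes.

    Attractors are ordered by descending basin size, ties broken by the
    lexicographically smallest state of the cycle.  Each cycle is stored
    as an ``(L, n)`` array whose rows follow the synchronous dynamics and
    whose first row is the cycle's lexicographically smallest state.
    """

    attractors: list[np.ndarray]
    basin_sizes: list[int]

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    def fixed_points(self) -> list[np.ndarray]:
        return [a[0] for a in self.attractors if a.shape[0] == 1]


def gene_input(row: Sequence[int] | np.ndarray, state: Sequence[int] | np.ndarray) -> int:
    """Integer input of a gene: ``sum_j a_ij * x_j(t)``."""
    r = _as_row(row)
    s = _as_bits(state, r.shape[0])
    return int(r.astype(np.int64) @ s.astype(np.int64))


def gene_update(
    row: Sequence[int] | np.ndarray,
    d_i: bool,
    state: Sequence[int] | np.ndarray,
    current_value: int,
) -> int:
    """Next value of one gene under the threshold rule.

    Returns 1 on positive input, 0 on negative input; a null input decays
    to 0 when ``d_i`` is set and otherwise holds ``current_value``.
    """
    if current_value not in (0, 1):
        raise ValueError("current_value must be 0 or 1")
    u = gene_input(row, state)
    if u > 0:
        return 1
    if u < 0:
        return 0
    return 0 if d_i else int(current_value)


def _step_states(net: BooleanNetwork, states: np.ndarray) -> np.ndarray:
    """Vectorised synchronous step applied to each row of ``states``."""
    inputs = states.astype(np.int64) @ net.matrix.T.astype(np.int64)
    hold = np.where(net.self_degradation, 0, states)
    return np.where(inputs > 0, 1, np.where(inputs < 0, 0, hold)).astype(np.uint8)


def network_step(net: BooleanNetwork, state: Sequence[int] | np.ndarray) -> np.ndarray:
    """Apply one synchronous update to every gene from the same source state."""
    s = _as_bits(state, net.n)
    return _step_states(net, s[None, :])[0]


def simulate(
    net: BooleanNetwork,
    initial: Sequence[int] | np.ndarray,
    max_steps: int,
) -> SimulationResult:
    """Follow the synchronous orbit from ``initial``.

    The orbit is truncated at ``max_steps`` transitions or at the first
    revisited state (cycle closure), whichever comes first.  The revisited
    state is not appended again, so an orbit that enters a fixed point at
    its ``k``-th state yields a trajectory of exactly ``k`` states.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    s = _as_bits(initial, net.n)
    states = [s]
    seen = {s.tobytes(): 0}
    closed = False
    entry: Optional[int] = None
    for _ in range(max_steps):
        s = network_step(net, s)
        key = s.tobytes()
        if key in seen:
            closed = True
            entry = seen[key]
            break
        seen[key] = len(states)
        states.append(s)
    return SimulationResult(Trajectory(np.array(states)), closed, entry)


def find_attractors(net: BooleanNetwork, max_genes: int = 20) -> AttractorReport:
    """Exhaustive attractor and basin analysis over all ``2^n`` states.

    States are encoded as integers with gene index 0 as the most
    significant bit.  Every orbit is followed to its cycle; basins
    partition the full state space, so basin sizes sum to ``2^n``.
    """
    n = net.n
    if n > max_genes:
        raise ValueError(
            f"exhaustive search over 2^{n} states exceeds the bound of "
            f"{max_genes} genes; raise max_genes explicitly if intended"
        )
    N = 1 << n
    shifts = np.arange(n - 1, -1, -1, dtype=np.int64)
    codes = np.arange(N, dtype=np.int64)
    states = ((codes[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
    succ_states = _step_states(net, states)
    succ = (succ_states.astype(np.int64) << shifts[None, :]).sum(axis=1)

    color = np.full(N, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for s0 in range(N):
        if color[s0] != -1:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        cur = s0
        while color[cur] == -1 and cur not in pos:
            pos[cur] = len(path)
            path.append(cur)
            cur = int(succ[cur])
        if color[cur] != -1:
            aid = int(color[cur])
        else:
            aid = len(cycles)
            cycles.append(path[pos[cur]:])
        for p in path:
            color[p] = aid
    basins = np.bincount(color, minlength=len(cycles))

    # canonical rotation: cycle starts at its smallest code
    def _rotate(cyc: list[int]) -> list[int]:
        k = cyc.index(min(cyc))
        return cyc[k:] + cyc[:k]

    order = sorted(
        range(len(cycles)),
        key=lambda a: (-int(basins[a]), min(cycles[a])),
    )
    attractors = []
    sizes = []
    for a in order:
        cyc = _rotate(cycles[a])
        arr = ((np.array(cyc, dtype=np.int64)[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
        attractors.append(arr)
        sizes.append(int(basins[a]))
    return AttractorReport(attractors, sizes)


def is_consistent_network(net: BooleanNetwork, traj: Trajectory) -> bool:
    """True iff one synchronous step maps every observed state to its successor."""
    if traj.n != net.n:
        raise ValueError("trajectory and network dimensions differ")
    if traj.m < 2:
        return True
    pred = _step_states(net, traj.states[:-1])
    return bool((pred == traj.states[1:]).all())
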