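"""Connection frequencies, classification, interaction ranks and induction.

Given per-gene sets of consistent regulator rows, each matrix entry
``a_ij`` has an empirical distribution over ``{-1, 0, 1}``.  A connection
is *determined* when a single value has frequency 1, *partially
determined* when exactly one value has frequency 0 (and none has 1), and
*undetermined* when all three occur.  Frequencies from enumerated row
sets are exact; from sampled sets they are estimates whose quality grows
with the sample size, which every report therefore carries.

Undirected pairs are ranked by summing the nonzero-connection
frequencies in both directions,

    rank({i, j}) = inh(i<-j) + act(i<-j) + inh(j<-i) + act(j<-i)
                 = 2 - freq0(a_ij) - freq0(a_ji),

a score in [0, 2] that is large when the data insist some interaction
exists between the two genes, whatever its direction or sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import GenePanel
from .csp_solver import RowSolutionSet

__all__ = [
    "ConnectionFrequencyTable",
    "ConnectionClass",
    "ClassificationReport",
    "InteractionRankTable",
    "InductionCandidate",
    "InductionResult",
    "connection_frequencies",
    "classify_connections",
    "rank_interactions",
    "true_positive_rate",
    "induction_scan",
]

VALUES = (-1, 0, 1)  # frequency-axis order used throughout


def _column_frequencies(rows: np.ndarray) -> np.ndarray:
    """(n, 3) frequencies of -1/0/1 per column of a row set."""
    k = rows.shape[0]
    return np.stack([(rows == v).sum(axis=0) / k for v in VALUES], axis=-1)


@dataclass
class ConnectionFrequencyTable:
    """Per-entry value frequencies over row sets.

    ``freq[i, j, v]`` is the frequency of value ``VALUES[v]`` for entry
    ``a_ij``; rows of targets without data are NaN.  ``counts[i]`` is the
    number of rows behind target *i* (0 = no data), ``modes[i]`` whether
    they were enumerated (exact frequencies) or sampled (estimates).
    """

    panel: GenePanel
    freq: np.ndarray
    counts: np.ndarray
    modes: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.panel)

    def has_target(self, i: int) -> bool:
        return self.counts[i] > 0

    def freq0(self, i: int, j: int) -> float:
        """Frequency of the value 0 (no connection) for entry ``a_ij``."""
        return float(self.freq[i, j, 1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: target, regulator, value, frequency, n_rows."""
        records = []
        for i, tgt in enumerate(self.panel):
            if not self.has_target(i):
                continue
            for j, reg in enumerate(self.panel):
                for v_idx, v in enumerate(VALUES):
                    records.append(
                        (tgt, reg, v, float(self.freq[i, j, v_idx]), int(self.counts[i]))
                    )
        return pd.DataFrame(
            records, columns=["target", "regulator", "value", "frequency", "n_rows"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, panel: Optional[GenePanel] = None
                   ) -> "ConnectionFrequencyTable":
        if panel is None:
            names = list(dict.fromkeys(df["regulator"]))
            panel = GenePanel(tuple(names))
        n = len(panel)
        freq = np.full((n, n, 3), np.nan)
        counts = np.zeros(n, dtype=np.int64)
        for _, rec in df.iterrows():
            i = panel.index(str(rec["target"]))
            j = panel.index(str(rec["regulator"]))
            freq[i, j, VALUES.index(int(rec["value"]))] = float(rec["frequency"])
            counts[i] = int(rec["n_rows"])
        modes = tuple("unknown" for _ in range(n))
        return cls(panel, freq, counts, modes)


def connection_frequencies(
    rowsets: RowSolutionSet | Mapping[int, RowSolutionSet] | Iterable[RowSolutionSet],
    panel: Optional[GenePanel] = None,
) -> ConnectionFrequencyTable:
    """Empirical value frequencies per regulation-matrix entry.

    Accepts a single row set, a mapping ``gene -> rowset`` or an iterable
    of row sets.  An empty (infeasible) row set is an error: frequencies
    of an empty collection are undefined and silently skipping an
    infeasible gene would misrepresent the analysis.
    """
    if isinstance(rowsets, RowSolutionSet):
        rowsets = [rowsets]
    elif isinstance(rowsets, Mapping):
        rowsets = list(rowsets.values())
    else:
        rowsets = list(rowsets)
    if not rowsets:
        raise ValueError("no row sets given")
    n = rowsets[0].n
    if panel is None:
        panel = GenePanel(tuple(f"g{k + 1}" for k in range(n)))
    if len(panel) != n:
        raise ValueError("panel size does not match row length")
    freq = np.full((n, n, 3), np.nan)
    counts = np.zeros(n, dtype=np.int64)
    modes = ["absent"] * n
    for rs in rowsets:
        if rs.n != n:
            raise ValueError("row sets cover different gene panels")
        if len(rs) == 0:
            raise ValueError(
                f"gene index {rs.gene_i} has an empty (infeasible) row set; "
                "frequencies are undefined"
            )
        freq[rs.gene_i] = _column_frequencies(rs.rows)
        counts[rs.gene_i] = len(rs)
        modes[rs.gene_i] = rs.mode
    return ConnectionFrequencyTable(panel, freq, counts, tuple(modes))


@dataclass(frozen=True)
class ConnectionClass:
    """Three-way classification of one matrix entry.

    ``kind`` is ``"determined"`` (one value has frequency 1, stored in
    ``value``), ``"partially_determined"`` (exactly one value has
    frequency 0, stored in ``excluded``) or ``"undetermined"``.
    """

    kind: str
    value: Optional[int] = None
    excluded: Optional[int] = None

    @property
    def determination(self) -> float:
        """Determination weight: 1, 0.5 or 0."""
        return {"determined": 1.0, "partially_determined": 0.5,
                "undetermined": 0.0}[self.kind]


def _classify_entry(f: np.ndarray) -> ConnectionClass:
    present = [v for v, p in zip(VALUES, f) if p > 0.0]
    if len(present) == 1:
        return ConnectionClass("determined", value=present[0])
    if len(present) == 2:
        missing = next(v for v, p in zip(VALUES, f) if p == 0.0)
        return ConnectionClass("partially_determined", excluded=missing)
    return ConnectionClass("undetermined")


@dataclass
class ClassificationReport:
    """Classification of every entry with data, plus summary counts.

    ``determined_nonzero`` counts entries pinned to an activation or an
    inhibition -- the connections one can draw as arrows; a determined
    absence (value 0) is counted separately in ``determined_zero``.
    """

    classes: dict[tuple[int, int], ConnectionClass]
    determined_nonzero: int
    determined_zero: int
    partially_determined: int
    undetermined: int

    @property
    def determined_any(self) -> int:
        return self.determined_nonzero + self.determined_zero


def classify_connections(table: ConnectionFrequencyTable) -> ClassificationReport:
    """Classify every connection of every target gene that has data."""
    classes: dict[tuple[int, int], ConnectionClass] = {}
    det_nz = det_z = part = undet = 0
    for i in range(table.n):
        if not table.has_target(i):
            continue
        for j in range(table.n):
            c = _classify_entry(table.freq[i, j])
            classes[(i, j)] = c
            if c.kind == "determined":
                if c.value == 0:
                    det_z += 1
                else:
                    det_nz += 1
            elif c.kind == "partially_determined":
                part += 1
            else:
                undet += 1
    return ClassificationReport(classes, det_nz, det_z, part, undet)


@dataclass
class InteractionRankTable:
    """Unordered gene pairs sorted by the two-way nonzero-frequency rank.

    ``pairs`` holds ``(rank, name_a, name_b)`` with ``name_a < name_b``
    lexicographically, sorted by descending rank and then by the name
    pair; ``self_ranks`` reports ``1 - freq0(a_ii)`` for the diagonal
    entries separately (a self-pair has only one direction).
    """

    pairs: list[tuple[float, str, str]]
    self_ranks: dict[str, float]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def top(self, k: int) -> list[tuple[float, str, str]]:
        return self.pairs[:k]

    def rank_of(self, gene_a: str, gene_b: str) -> float:
        key = tuple(sorted((gene_a, gene_b)))
        for r, a, b in self.pairs:
            if (a, b) == key:
                return r
        raise KeyError(f"pair {key} not ranked")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, b, r) for r, a, b in self.pairs],
            columns=["gene_a", "gene_b", "rank"],
        )


def rank_interactions(table: ConnectionFrequencyTable) -> InteractionRankTable:
    """Rank all unordered pairs by ``2 - freq0(a_ij) - freq0(a_ji)``.

    Pairs with a missing direction (target without data) are skipped and
    listed in ``skipped``.
    """
    pairs = []
    skipped = []
    names = table.panel.names
    for i in range(table.n):
        for j in range(i + 1, table.n):
            if not (table.has_target(i) and table.has_target(j)):
                skipped.append(tuple(sorted((names[i], names[j]))))
                continue
            rank = 2.0 - table.freq0(i, j) - table.freq0(j, i)
            a, b = sorted((names[i], names[j]))
            pairs.append((float(rank), a, b))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    self_ranks = {
        names[i]: 1.0 - table.freq0(i, i)
        for i in range(table.n)
        if table.has_target(i)
    }
    return InteractionRankTable(pairs, self_ranks, skipped)


def true_positive_rate(
    ranks: InteractionRankTable,
    reference_edges: Iterable[Iterable[str]] | frozenset,
    k: int,
) -> float:
    """Fraction of the top-``k`` ranked pairs present in a reference edge set.

    The comparison is direction- and sign-agnostic: a reference edge is
    any unordered gene pair.  An empty reference yields 0 with a warning.
    """
    ref = {frozenset(e) for e in reference_edges}
    if not ref:
        warnings.warn("empty reference edge set; true positive rate is 0",
                      stacklevel=2)
        return 0.0
    if k < 1 or k > len(ranks.pairs):
        raise ValueError(f"k must be between 1 and {len(ranks.pairs)}")
    hits = sum(1 for _, a, b in ranks.top(k) if frozenset((a, b)) in ref)
    return hits / k


@dataclass(frozen=True)
class InductionCandidate:
    """One candidate assignment ``a_ij = value`` with its induction score."""

    regulator: int
    value: int
    score: float
    n_rows: int


@dataclass
class InductionResult:
    """Outcome of an induction scan over one gene's row set.

    ``base_score`` is the summed determination of the unrestricted set;
    ``candidates`` are sorted by descending score; ``best`` lists every
    candidate attaining the maximum (ties reported together).
    """

    gene_i: int
    base_score: float
    candidates: list[InductionCandidate]
    best: list[InductionCandidate]


def _rowset_score(rows: np.ndarray) -> float:
    freqs = _column_frequencies(rows)
    return float(sum(_classify_entry(f).determination for f in freqs))


def induction_scan(rowset: RowSolutionSet) -> InductionResult:
    """Score every feasible single assignment of a non-determined connection.

    For each connection ``a_ij`` of gene *i* that is not already
    determined, and each value *v* occurring in the row set, the rows are
    restricted to ``a_ij = v`` and the summed determination of all
    connections on the restricted set is the score: the assignment that
    determines the most other connections wins.  Restricting can only
    remove values from each column, so every score is at least
    ``base_score``.  An all-determined row set yields an empty scan.
    """
    if len(rowset) == 0:
        raise ValueError("cannot scan an empty (infeasible) row set")
    rows = rowset.rows
    freqs = _column_frequencies(rows)
    base = float(sum(_classify_entry(f).determination for f in freqs))
    candidates: list[InductionCandidate] = []
    for j in range(rowset.n):
        cls = _classify_entry(freqs[j])
        if cls.kind == "determined":
            continue
        for v_idx, v in enumerate(VALUES):
            if freqs[j, v_idx] == 0.0:
                continue  # value not feasible: restriction would be empty
            sub = rows[rows[:, j] == v]
            candidates.append(
                InductionCandidate(j, v, _rowset_score(sub), sub.shape[0])
            )
    candidates.sort(key=lambda c: (-c.score, c.regulator, c.value))
    best: list[InductionCandidate] = []
    if candidates:
        top = candidates[0].score
        best = [c for c in candidates if c.score == top]
    return InductionResult(rowset.gene_i, base, candidates, best)
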