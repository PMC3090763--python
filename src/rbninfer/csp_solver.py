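"""Exact enumeration and randomized sampling of consistent regulator rows.

The per-gene CSPs of :mod:`rbninfer.constraint_gen` are small (at most
``3^n`` candidate rows) but numerous, so two solution modes are offered:

* :func:`enumerate_consistent_rows` -- the exact solution set, obtained
  by vectorised filtration of the domain-restricted candidate grid.
* :func:`sample_consistent_rows` -- with-replacement draws via randomized
  backtracking: uniformly random variable order, uniformly random value
  order, pruning by bounds consistency on the sum inequalities.  The
  descent distribution is close to, but not exactly, uniform over
  solutions; it is the estimator behind connection frequencies at scales
  where enumeration is out of reach.

:func:`row_oracle` is the independent ground truth: it checks a candidate
row directly against the update rule, bypassing the constraint algebra
entirely, and is what the enumeration is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .core_model import Trajectory
from .constraint_gen import (
    EmptyDomainError,
    InfeasibleTransitionError,
    RowCSP,
    build_row_csp,
)

__all__ = [
    "RowSolutionSet",
    "row_oracle",
    "enumerate_consistent_rows",
    "sample_consistent_rows",
    "infer_rowsets",
]


@dataclass
class RowSolutionSet:
    """Rows of ``{-1,0,1}^n`` consistent with one gene's CSP.

    In ``enumerated`` mode ``rows`` is the exact, duplicate-free solution
    set in canonical (lexicographic, ``-1 < 0 < 1``) order.  In
    ``sampled`` mode rows are with-replacement draws and ``sample_meta``
    records the seed and requested count.  ``feasible`` is False when the
    CSP admits no solution at all.
    """

    gene_i: int
    n: int
    rows: np.ndarray
    mode: Literal["enumerated", "sampled"]
    feasible: bool = True
    sample_meta: Optional[dict] = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rows, dtype=np.int8)
        if r.size == 0:
            r = r.reshape(0, self.n)
        if r.ndim != 2 or r.shape[1] != self.n:
            raise ValueError("rows must be a (k, n) array")
        self.rows = r

    def __len__(self) -> int:
        return self.rows.shape[0]

    def distinct(self) -> np.ndarray:
        """Distinct rows, canonically sorted."""
        if len(self) == 0:
            return self.rows
        return np.unique(self.rows, axis=0)


def _seg_list(segments) -> list[np.ndarray]:
    if isinstance(segments, (Trajectory, np.ndarray)):
        segments = [segments]
    return [s.states if isinstance(s, Trajectory) else np.asarray(s) for s in segments]


def row_oracle(
    row: Sequence[int] | np.ndarray,
    d_i: bool,
    segments,
    i: int,
) -> bool:
    """Ground-truth consistency of one row, by direct simulation.

    True iff for every consecutive pair of states in every segment the
    threshold update of gene *i* with regulators ``row`` maps
    ``x_i(t)`` to the observed ``x_i(t+1)``.
    """
    r = np.asarray(row, dtype=np.int64)
    for st in _seg_list(segments):
        if st.shape[0] < 2:
            continue
        inputs = st[:-1].astype(np.int64) @ r
        cur = st[:-1, i].astype(np.int64)
        hold = np.zeros_like(cur) if d_i else cur
        pred = np.where(inputs > 0, 1, np.where(inputs < 0, 0, hold))
        if not (pred == st[1:, i]).all():
            return False
    return True


def _candidate_grid(domains: Sequence[frozenset[int]]) -> np.ndarray:
    """Cartesian product of the domains, lexicographic with -1 < 0 < 1."""
    arrs = [np.array(sorted(dom), dtype=np.int8) for dom in domains]
    grids = np.meshgrid(*arrs, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=-1)


def enumerate_consistent_rows(csp: RowCSP, max_genes: int = 13) -> RowSolutionSet:
    """Exact solution set of a row CSP by vectorised filtration.

    All rows of the domain-restricted grid (at most ``3^n``) are tested
    against every inequality at once.  Refuses when ``n`` exceeds
    ``max_genes`` (default 13, about 1.6M candidates); use
    :func:`sample_consistent_rows` beyond that.
    """
    if csp.n > max_genes:
        raise ValueError(
            f"enumeration over 3^{csp.n} candidate rows exceeds the "
            f"{max_genes}-gene bound; use sample_consistent_rows instead"
        )
    cands = _candidate_grid(csp.domains)
    mask = np.ones(cands.shape[0], dtype=bool)
    for ineq in csp.inequalities:
        plus = list(ineq.plus)
        minus = list(ineq.minus)
        lhs = np.zeros(cands.shape[0], dtype=np.int64)
        if plus:
            lhs += cands[:, plus].astype(np.int64).sum(axis=1)
        if minus:
            lhs -= cands[:, minus].astype(np.int64).sum(axis=1)
        mask &= (lhs >= ineq.bound) if ineq.relation == ">=" else (lhs <= ineq.bound)
    rows = cands[mask]
    return RowSolutionSet(
        gene_i=csp.gene_i,
        n=csp.n,
        rows=rows,
        mode="enumerated",
        feasible=rows.shape[0] > 0,
    )


def _normalized_inequalities(csp: RowCSP):
    """Rewrite every inequality as ``sum_j c_j a_j >= b`` with c_j = +/-1."""
    out = []
    for ineq in csp.inequalities:
        if ineq.relation == ">=":
            coeffs = {j: 1 for j in ineq.plus}
            coeffs.update({j: -1 for j in ineq.minus})
            out.append((coeffs, ineq.bound))
        else:
            coeffs = {j: -1 for j in ineq.plus}
            coeffs.update({j: 1 for j in ineq.minus})
            out.append((coeffs, -ineq.bound))
    return out


def sample_consistent_rows(
    csp: RowCSP,
    count: int,
    seed: int | np.random.SeedSequence,
    distinct: bool = False,
) -> RowSolutionSet:
    """Draw ``count`` consistent rows by randomized backtracking.

    Each draw restarts a depth-first descent with a fresh uniformly
    random variable order; values are tried in uniformly random order,
    and a partial assignment is abandoned as soon as some inequality's
    best attainable completion falls short of its bound.  Draws are with
    replacement (``distinct=True`` keeps drawing until ``count`` distinct
    rows are found or the attempt budget runs out).  An infeasible CSP is
    reported as an empty, flagged result, never an exception --
    infeasibility is a legitimate outcome on noisy data.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    n = csp.n
    doms = [sorted(d) for d in csp.domains]
    ineqs = _normalized_inequalities(csp)
    meta = {
        "seed": seed if isinstance(seed, int) else "seed-sequence",
        "requested": count,
        "distinct": distinct,
    }

    # structural infeasibility: an empty-support inequality that 0 violates
    for coeffs, bound in ineqs:
        if not coeffs and 0 < bound:
            return RowSolutionSet(csp.gene_i, n, np.zeros((0, n), np.int8),
                                  "sampled", feasible=False, sample_meta=meta)

    assign = [0] * n
    assigned = [False] * n

    def _feasible() -> bool:
        for coeffs, bound in ineqs:
            total = 0
            for j, c in coeffs.items():
                if assigned[j]:
                    total += c * assign[j]
                else:
                    dom = doms[j]
                    total += c * dom[-1] if c > 0 else c * dom[0]
            if total < bound:
                return False
        return True

    def _descend() -> Optional[list[int]]:
        assigned[:] = [False] * n
        order = rng.permutation(n)

        def bt(k: int) -> bool:
            if k == n:
                return True
            j = int(order[k])
            values = list(doms[j])
            rng.shuffle(values)
            for v in values:
                assign[j] = v
                assigned[j] = True
                if _feasible() and bt(k + 1):
                    return True
                assigned[j] = False
            return False

        return list(assign) if bt(0) else None

    rows: list[list[int]] = []
    seen: set[tuple[int, ...]] = set()
    budget = max(50 * count, 1000) if distinct else count
    attempts = 0
    while len(rows) < count and attempts < budget:
        attempts += 1
        sol = _descend()
        if sol is None:
            # the descent is a complete search: exhausting it proves infeasibility
            return RowSolutionSet(csp.gene_i, n, np.zeros((0, n), np.int8),
                                  "sampled", feasible=False, sample_meta=meta)
        if distinct:
            key = tuple(sol)
            if key in seen:
                continue
            seen.add(key)
        rows.append(sol)
    meta["attempts"] = attempts
    return RowSolutionSet(
        gene_i=csp.gene_i,
        n=n,
        rows=np.array(rows, dtype=np.int8),
        mode="sampled",
        feasible=True,
        sample_meta=meta,
    )


def infer_rowsets(
    segments,
    self_degradation: Sequence[bool] | np.ndarray,
    mode: Literal["enumerate", "sample"] = "enumerate",
    count: int = 100,
    seed: int = 0,
    prior_mask: Optional[Iterable[tuple[int, int]]] = None,
    pairwise: Literal["all", "similar", "off"] = "all",
    segment_mode: Literal["union", "intersection"] = "union",
    genes: Optional[Iterable[int]] = None,
    max_genes: int = 13,
) -> dict[int, RowSolutionSet]:
    """Solve the row CSP of every gene over one or more segments.

    In ``union`` mode (the default for independent cycles) each segment
    is solved separately and the per-segment row sets are pooled --
    deduplicated for enumeration, concatenated for sampling.  In
    ``intersection`` mode a single CSP conjoins all segments.  Per-gene
    infeasibility (e.g. from noisy data) is captured in the returned
    :class:`RowSolutionSet` rather than raised, so one bad gene does not
    abort the run.
    """
    segs = _seg_list(segments)
    d = np.asarray(self_degradation, dtype=bool)
    n = segs[0].shape[1]
    if d.shape != (n,):
        raise ValueError("one self-degradation flag per gene required")
    prior = list(prior_mask) if prior_mask is not None else None
    gene_ids = list(genes) if genes is not None else list(range(n))
    children = np.random.SeedSequence(seed).spawn(n)

    out: dict[int, RowSolutionSet] = {}
    for i in gene_ids:
        groups = [[s] for s in segs] if segment_mode == "union" else [segs]
        pooled: list[np.ndarray] = []
        feasible_any = False
        error: Optional[str] = None
        meta_parts = []
        for g_idx, group in enumerate(groups):
            try:
                csp = build_row_csp(i, group, bool(d[i]), prior_mask=prior,
                                    pairwise=pairwise)
            except (InfeasibleTransitionError, EmptyDomainError) as err:
                error = str(err)
                continue
            if mode == "enumerate":
                sol = enumerate_consistent_rows(csp, max_genes=max_genes)
            else:
                child = children[i] if len(groups) == 1 else \
                    children[i].spawn(len(groups))[g_idx]
                sol = sample_consistent_rows(csp, count, child)
                meta_parts.append(sol.sample_meta)
            if sol.feasible:
                feasible_any = True
                pooled.append(sol.rows)
        if pooled:
            rows = np.vstack(pooled)
            if mode == "enumerate":
                rows = np.unique(rows, axis=0)
        else:
            rows = np.zeros((0, n), dtype=np.int8)
        meta: Optional[dict] = None
        if mode == "sample":
            meta = {"seed": seed, "requested": count, "parts": meta_parts}
        if error is not None:
            meta = dict(meta or {}, error=error)
        out[i] = RowSolutionSet(
            gene_i=i,
            n=n,
            rows=rows,
            mode="enumerated" if mode == "enumerate" else "sampled",
            feasible=feasible_any,
            sample_meta=meta,
        )
    return out
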