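"""Binarization, attractor-run collapsing and prior-knowledge compilation.

Continuous expression time courses are made Boolean by thresholding each
gene at the arithmetic mean of its own profile (strictly above the mean
= ON).  Runs of near-identical consecutive binary states -- a cell
population sitting in a stationary attractor between cycles -- can be
collapsed to single representative states, which segments the series
into candidate cycles.  Phase-level prior knowledge ("genes of phase P
are not regulated by genes of phase Q") compiles down to matrix entries
pinned to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .core_model import GenePanel, Trajectory

__all__ = [
    "BinarizationResult",
    "SegmentationResult",
    "binarize_mean",
    "collapse_attractor_runs",
    "compile_prior_mask",
]


@dataclass
class BinarizationResult:
    panel: GenePanel
    trajectory: Trajectory
    constant_genes: list[str]


def binarize_mean(expression: pd.DataFrame) -> BinarizationResult:
    """Binarize an expression matrix (rows = time points, columns = genes).

    Each gene is thresholded at the mean of its own profile: values
    strictly exceeding the mean become 1, everything else (including
    values equal to the mean) becomes 0.  Constant-profile genes --
    whose binary profile is necessarily all zeros -- are listed in
    ``constant_genes`` as a warning.
    """
    if expression.isna().any().any():
        raise ValueError("expression matrix has missing values; impute or drop first")
    if expression.shape[0] < 2:
        raise ValueError("at least two time points required")
    values = expression.to_numpy(dtype=float)
    means = values.mean(axis=0)
    bits = (values > means).astype(np.uint8)
    constant = [str(c) for c, flat
                in zip(expression.columns, np.ptp(values, axis=0) == 0) if flat]
    panel = GenePanel(tuple(str(c) for c in expression.columns))
    labels = tuple(str(x) for x in expression.index)
    return BinarizationResult(panel, Trajectory(bits, labels), constant)


@dataclass
class SegmentationResult:
    """Run-collapsed trajectory and its segmentation.

    ``runs`` are (start, end) inclusive index ranges of the original
    trajectory that were collapsed (each to one representative state);
    ``segments`` are the maximal index ranges between runs -- the
    candidate cycles.  ``collapsed`` is the full trajectory with each
    run replaced by its representative.
    """

    collapsed: Trajectory
    segments: list[tuple[int, int]]
    runs: list[tuple[int, int]]


def collapse_attractor_runs(traj: Trajectory, max_hamming: int = 0) -> SegmentationResult:
    """Collapse maximal runs of near-identical consecutive states.

    A run is a maximal block of consecutive states each within Hamming
    distance ``max_hamming`` of the block's *first* state; blocks of
    length one are not runs.  Each run is replaced by a per-gene
    majority vote over its states (ties keep the first state's bit).
    With ``max_hamming=0`` only exactly repeated states collapse.
    """
    if max_hamming < 0:
        raise ValueError("max_hamming must be non-negative")
    if traj.m < 2:
        raise ValueError("need at least two states")
    st = traj.states
    m = traj.m
    runs: list[tuple[int, int]] = []
    t = 0
    while t < m:
        end = t
        while end + 1 < m and int((st[end + 1] != st[t]).sum()) <= max_hamming:
            end += 1
        if end > t:
            runs.append((t, end))
            t = end + 1
        else:
            t += 1

    def _representative(a: int, b: int) -> np.ndarray:
        block = st[a:b + 1]
        ones = block.sum(axis=0)
        half = block.shape[0] / 2
        rep = np.where(ones > half, 1, np.where(ones < half, 0, st[a]))
        return rep.astype(np.uint8)

    in_run = np.zeros(m, dtype=bool)
    for a, b in runs:
        in_run[a:b + 1] = True
    collapsed_states: list[np.ndarray] = []
    collapsed_labels: list[str] = []
    labels = traj.labels or tuple(str(k + 1) for k in range(m))
    t = 0
    run_iter = iter(runs)
    next_run = next(run_iter, None)
    while t < m:
        if next_run is not None and t == next_run[0]:
            a, b = next_run
            collapsed_states.append(_representative(a, b))
            collapsed_labels.append(f"{labels[a]}..{labels[b]}")
            t = b + 1
            next_run = next(run_iter, None)
        else:
            collapsed_states.append(st[t])
            collapsed_labels.append(labels[t])
            t += 1

    segments: list[tuple[int, int]] = []
    t = 0
    while t < m:
        if in_run[t]:
            t += 1
            continue
        start = t
        while t + 1 < m and not in_run[t + 1]:
            t += 1
        segments.append((start, t))
        t += 1

    return SegmentationResult(
        Trajectory(np.array(collapsed_states), tuple(collapsed_labels)),
        segments,
        runs,
    )


def compile_prior_mask(
    rules: Iterable[tuple[str, str]],
    groups: Mapping[str, str],
    panel: GenePanel,
) -> frozenset[tuple[int, int]]:
    """Expand group-level forbidden regulations to fixed-zero entry pairs.

    ``rules`` are (target_group, regulator_group) pairs meaning "genes of
    the target group are not regulated by genes of the regulator group";
    ``groups`` maps each gene name to its group.  Returns the set of
    matrix index pairs ``(i, j)`` whose domain should be pinned to
    ``{0}``.  Rules naming groups that no gene carries raise an error
    listing the offenders.
    """
    rules = list(rules)
    known = set(groups.values())
    missing = sorted(
        {g for rule in rules for g in rule if g not in known}
    )
    if missing:
        raise ValueError(f"unknown group names in rules: {missing}")
    mask: set[tuple[int, int]] = set()
    for tgt_group, reg_group in rules:
        targets = [i for i, name in enumerate(panel) if groups.get(name) == tgt_group]
        regulators = [j for j, name in enumerate(panel) if groups.get(name) == reg_group]
        mask.update((i, j) for i in targets for j in regulators)
    return frozenset(mask)
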