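"""Random restricted Boolean networks with known ground truth, plus the
packaged budding-yeast cell-cycle fixture.

The generator emulates the statistical shape of the benchmark study:
eleven genes, a quarter of the matrix entries nonzero with balanced
signs, roughly half the genes self-degrading, and a 13-state synchronous
trajectory.  Optional symmetric bit flips model measurement noise after
simulation.  Every draw is reproducible from a single integer seed, and
the generated network is the ground truth against which pipeline
soundness (true-row recovery, no false determinations) is tested.

The yeast fixture is the eleven-regulator cell-cycle network of
*Saccharomyces cerevisiae* (Cln3, MBF, SBF, Cln1/2, Cdh1, Swi5,
Cdc20/Cdc14, Clb5/6, Sic1, Clb1/2, Mcm1/SFF), shipped as TSV data files
and validated by the test suite against its published dynamics: seven
fixed-point attractors (largest basin 1,764 of the 2,048 states) and the
13-state biological trajectory from the excited-G1 state back to the
stationary G1 state.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .core_model import (
    AttractorReport,
    BooleanNetwork,
    GenePanel,
    Trajectory,
    simulate,
)

__all__ = [
    "GeneratorConfig",
    "YeastFixture",
    "random_network",
    "random_trajectory",
    "yeast_fixture",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic benchmark generator.

    Defaults mirror the yeast benchmark conditions: 11 genes, edge
    density ~0.25 (the yeast matrix has 28 nonzero entries out of 121),
    balanced activation/inhibition, self-degradation on about half the
    genes (5 of 11 in the yeast model), 13 time points and no noise.
    """

    n: int = 11
    edge_density: float = 0.25
    sign_balance: float = 0.5
    selfdeg_prob: float = 0.45
    trajectory_length: int = 13
    noise_flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two genes")
        if self.trajectory_length < 2:
            raise ValueError("need at least two time points")
        for name in ("edge_density", "sign_balance", "selfdeg_prob", "noise_flip_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")


def random_network(cfg: GeneratorConfig) -> BooleanNetwork:
    """Seeded draw of a random restricted Boolean network.

    Each matrix entry (diagonal included -- the model allows explicit
    self-edges) is independently nonzero with probability
    ``edge_density`` and positive with probability ``sign_balance``;
    self-degradation flags are independent Bernoulli draws.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    nonzero = rng.random((cfg.n, cfg.n)) < cfg.edge_density
    signs = np.where(rng.random((cfg.n, cfg.n)) < cfg.sign_balance, 1, -1)
    matrix = np.where(nonzero, signs, 0).astype(np.int8)
    selfdeg = rng.random(cfg.n) < cfg.selfdeg_prob
    panel = GenePanel(tuple(f"g{k + 1}" for k in range(cfg.n)))
    return BooleanNetwork(panel, matrix, selfdeg)


def random_trajectory(net: BooleanNetwork, cfg: GeneratorConfig) -> Trajectory:
    """Simulate from a seeded random initial state, then inject bit flips.

    The noise-free orbit (``noise_flip_prob = 0``) is consistent with the
    network by construction.  Flips are applied independently per bit
    after simulation, the simplest symmetric model of measurement noise.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    initial = rng.integers(0, 2, size=net.n, dtype=np.uint8)
    m = cfg.trajectory_length
    states = [initial]
    s = initial
    from .core_model import network_step  # local import avoids cycle at module load

    for _ in range(m - 1):
        s = network_step(net, s)
        states.append(s)
    arr = np.array(states, dtype=np.uint8)
    if cfg.noise_flip_prob > 0:
        flips = rng.random(arr.shape) < cfg.noise_flip_prob
        arr = arr ^ flips.astype(np.uint8)
    return Trajectory(arr)


@dataclass
class YeastFixture:
    """Packaged yeast cell-cycle benchmark: network, data and references."""

    network: BooleanNetwork
    trajectory: Trajectory
    attractors: AttractorReport
    edges: frozenset[frozenset[str]]


def _data_path(name: str):
    return resources.files("rbninfer.data").joinpath(name)


def yeast_fixture() -> YeastFixture:
    """Load the packaged eleven-gene budding-yeast cell-cycle benchmark.

    Returns the network (transcribed as a TSV edge list with per-gene
    self-degradation flags), the 13-state biological trajectory, the
    published attractor table (seven fixed points with basin sizes
    1764/151/109/9/7/7/1) and the undirected edge set used for
    true-positive validation of interaction ranks.
    """
    from .fileio import read_network, read_trajectory  # deferred: fileio imports core types

    with resources.as_file(_data_path("yeast_edges.tsv")) as edges_path, \
            resources.as_file(_data_path("yeast_genes.tsv")) as genes_path:
        net = read_network(edges_path, genes_path)
    with resources.as_file(_data_path("yeast_trajectory.tsv")) as traj_path:
        panel, traj = read_trajectory(traj_path)
    if panel.names != net.panel.names:
        raise RuntimeError("packaged trajectory and network disagree on gene order")

    import pandas as pd

    with resources.as_file(_data_path("yeast_attractors.tsv")) as attr_path:
        df = pd.read_csv(attr_path, sep="\t")
    genes = [c for c in df.columns if c != "basin_size"]
    if tuple(genes) != net.panel.names:
        raise RuntimeError("packaged attractor table and network disagree on gene order")
    attractors = [df[genes].to_numpy(dtype=np.uint8)[k:k + 1] for k in range(len(df))]
    basins = [int(x) for x in df["basin_size"]]
    report = AttractorReport(attractors, basins)

    return YeastFixture(net, traj, report, net.undirected_edges())
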