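"""Readers and writers for the package's plain-text formats.

Canonical dialect is TSV with a header row; comma-separated files are
accepted on read (delimiter is sniffed).  Time indices in trajectory
files are 1-based labels, matching the convention of printed state
tables; in memory all indexing is 0-based.

Formats
-------
network edge list
    columns ``target``, ``regulator``, ``sign`` (-1/1), one row per
    nonzero matrix entry; a companion gene table (columns ``gene``,
    ``self_degradation``) fixes gene order and decay flags.
dense matrix
    header ``gene <name...>``, one row per target gene.
trajectory
    first column a time label, remaining columns gene values 0/1,
    header carries the gene names.
row sets
    TSV (one consistent row per line, columns = regulators) and a JSON
    document embedding gene names, mode, seed and row counts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .core_model import BooleanNetwork, GenePanel, Trajectory
from .csp_solver import RowSolutionSet
from .interaction_analysis import ConnectionFrequencyTable, InteractionRankTable

__all__ = [
    "read_network",
    "write_network",
    "read_dense_matrix",
    "write_dense_matrix",
    "read_trajectory",
    "write_trajectory",
    "read_expression",
    "read_groups",
    "read_rules",
    "write_rowset_tsv",
    "read_rowset_tsv",
    "write_rowsets_json",
    "read_rowsets_json",
    "write_frequencies_csv",
    "read_frequencies_csv",
    "write_ranks_csv",
]


def _read_table(path) -> pd.DataFrame:
    # sep=None sniffs tab vs comma
    return pd.read_csv(path, sep=None, engine="python")


def read_network(edges_path, genes_path) -> BooleanNetwork:
    """Read an edge-list network: gene table fixes order and decay flags."""
    genes = _read_table(genes_path)
    for col in ("gene", "self_degradation"):
        if col not in genes.columns:
            raise ValueError(f"{genes_path}: missing column '{col}'")
    panel = GenePanel(tuple(str(g) for g in genes["gene"]))
    selfdeg = genes["self_degradation"].astype(int).to_numpy().astype(bool)
    edges = _read_table(edges_path)
    for col in ("target", "regulator", "sign"):
        if col not in edges.columns:
            raise ValueError(f"{edges_path}: missing column '{col}'")
    n = len(panel)
    matrix = np.zeros((n, n), dtype=np.int8)
    for line, rec in enumerate(edges.itertuples(index=False), start=2):
        tgt, reg, sign = str(rec.target), str(rec.regulator), int(rec.sign)
        if tgt not in panel.names or reg not in panel.names:
            raise ValueError(
                f"{edges_path}, line {line}: unknown gene in edge "
                f"({tgt}, {reg}); expected names from the gene table"
            )
        if sign not in (-1, 1):
            raise ValueError(
                f"{edges_path}, line {line}: sign must be -1 or 1, got {sign}"
            )
        matrix[panel.index(tgt), panel.index(reg)] = sign
    return BooleanNetwork(panel, matrix, selfdeg)


def write_network(net: BooleanNetwork, edges_path, genes_path) -> None:
    with open(genes_path, "w") as f:
        f.write("gene\tself_degradation\n")
        for name, flag in zip(net.panel, net.self_degradation):
            f.write(f"{name}\t{int(flag)}\n")
    with open(edges_path, "w") as f:
        f.write("target\tregulator\tsign\n")
        for tgt, reg, sign in net.edges():
            f.write(f"{tgt}\t{reg}\t{sign}\n")


def read_dense_matrix(path) -> tuple[GenePanel, np.ndarray]:
    """Dense-matrix TSV: header = regulator names, first column = target."""
    df = _read_table(path)
    names = tuple(str(c) for c in df.columns[1:])
    panel = GenePanel(names)
    rows = tuple(str(x) for x in df.iloc[:, 0])
    if rows != names:
        raise ValueError(f"{path}: row order must match the header gene order")
    matrix = df.iloc[:, 1:].to_numpy(dtype=np.int64)
    if not np.isin(matrix, (-1, 0, 1)).all():
        raise ValueError(f"{path}: matrix entries must be -1, 0 or 1")
    return panel, matrix.astype(np.int8)


def write_dense_matrix(panel: GenePanel, matrix: np.ndarray, path) -> None:
    with open(path, "w") as f:
        f.write("gene\t" + "\t".join(panel.names) + "\n")
        for name, row in zip(panel, np.asarray(matrix)):
            f.write(name + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


def read_trajectory(path) -> tuple[GenePanel, Trajectory]:
    """Trajectory TSV: first column time labels, remaining columns genes."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a time column plus gene columns")
    panel = GenePanel(tuple(str(c) for c in df.columns[1:]))
    labels = tuple(str(x) for x in df.iloc[:, 0])
    states = df.iloc[:, 1:].to_numpy(dtype=np.int64)
    if not np.isin(states, (0, 1)).all():
        raise ValueError(f"{path}: trajectory entries must be 0 or 1")
    return panel, Trajectory(states.astype(np.uint8), labels)


def write_trajectory(panel: GenePanel, traj: Trajectory, path) -> None:
    labels = traj.labels or tuple(str(t + 1) for t in range(traj.m))
    with open(path, "w") as f:
        f.write("time\t" + "\t".join(panel.names) + "\n")
        for label, row in zip(labels, traj.states):
            f.write(str(label) + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


def read_expression(path, transpose: bool = False) -> pd.DataFrame:
    """Continuous expression table; rows = time, columns = genes.

    ``transpose=True`` accepts the genes-as-rows orientation.
    """
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    if transpose:
        df = df.T
    return df.astype(float)


def read_groups(path) -> dict[str, str]:
    """Gene-to-group map: columns ``gene``, ``group``."""
    df = _read_table(path)
    for col in ("gene", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    return {str(r.gene): str(r.group) for r in df.itertuples(index=False)}


def read_rules(path) -> list[tuple[str, str]]:
    """Forbidden-regulation rules: columns ``target_group``, ``regulator_group``."""
    df = _read_table(path)
    for col in ("target_group", "regulator_group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    return [(str(r.target_group), str(r.regulator_group))
            for r in df.itertuples(index=False)]


def write_rowset_tsv(rowset: RowSolutionSet, panel: GenePanel, path) -> None:
    with open(path, "w") as f:
        f.write("\t".join(panel.names) + "\n")
        for row in rowset.rows:
            f.write("\t".join(str(int(x)) for x in row) + "\n")


def read_rowset_tsv(path, gene: str) -> tuple[GenePanel, RowSolutionSet]:
    """Read a row-set TSV; ``gene`` names the target the rows belong to."""
    df = _read_table(path)
    panel = GenePanel(tuple(str(c) for c in df.columns))
    rows = df.to_numpy(dtype=np.int64)
    if rows.size and not np.isin(rows, (-1, 0, 1)).all():
        raise ValueError(f"{path}: row entries must be -1, 0 or 1")
    rs = RowSolutionSet(
        gene_i=panel.index(gene), n=len(panel), rows=rows.astype(np.int8),
        mode="enumerated", feasible=rows.shape[0] > 0,
    )
    return panel, rs


def write_rowsets_json(
    rowsets: Mapping[int, RowSolutionSet],
    panel: GenePanel,
    path,
    config: Optional[dict] = None,
) -> None:
    doc = {
        "genes": list(panel.names),
        "config": config or {},
        "rowsets": {
            panel.names[i]: {
                "mode": rs.mode,
                "feasible": rs.feasible,
                "n_rows": len(rs),
                "sample_meta": rs.sample_meta,
                "rows": rs.rows.tolist(),
            }
            for i, rs in rowsets.items()
        },
    }
    with open(path, "w") as f:
        json.dump(doc, f)


def read_rowsets_json(path) -> tuple[GenePanel, dict[int, RowSolutionSet], dict]:
    with open(path) as f:
        doc = json.load(f)
    panel = GenePanel(tuple(doc["genes"]))
    out: dict[int, RowSolutionSet] = {}
    for name, rec in doc["rowsets"].items():
        i = panel.index(name)
        out[i] = RowSolutionSet(
            gene_i=i,
            n=len(panel),
            rows=np.array(rec["rows"], dtype=np.int8).reshape(-1, len(panel)),
            mode=rec["mode"],
            feasible=rec["feasible"],
            sample_meta=rec.get("sample_meta"),
        )
    return panel, out, doc.get("config", {})


def write_frequencies_csv(table: ConnectionFrequencyTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_frequencies_csv(path, panel: Optional[GenePanel] = None) -> ConnectionFrequencyTable:
    df = pd.read_csv(path)
    return ConnectionFrequencyTable.from_frame(df, panel)


def write_ranks_csv(ranks: InteractionRankTable, path) -> None:
    ranks.to_frame().to_csv(path, index=False)
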