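"""Readers and writers: edge-list TSV/CSV, positions CSV, JSON reports.

The interchange object is an undirected edge list — two id columns plus an
optional positive weight column, tab- or comma-delimited, header optional,
arbitrary string ids.  Duplicate undirected pairs collapse with weight
summation (logged); self-loops are dropped (logged).  Internal node ids are
contiguous integers; the original string ids are preserved and restored on
write.  Canonical output (ids sorted, smaller endpoint first) is byte-stable
across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import SpatialGraph

logger = logging.getLogger(__name__)

__all__ = [
    "read_graph",
    "write_graph",
    "read_positions",
    "write_positions",
    "write_report",
    "read_report",
]

REPORT_SCHEMA_VERSION = 1


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "\t" if "\t" in line else ","
    return "\t"


def _looks_like_header(row) -> bool:
    """A header is a first row whose third column (if any) is not a number."""
    tokens = [str(t).strip().lower() for t in row]
    if tokens[:2] == ["source", "target"] or tokens[:2] == ["from", "to"]:
        return True
    if len(tokens) >= 3:
        try:
            float(tokens[2])
            return False
        except ValueError:
            return True
    return False


def read_graph(
    edge_path,
    positions_path=None,
    parts_path=None,
    delimiter: str | None = None,
) -> SpatialGraph:
    """Read a SpatialGraph from an edge-list file (+ optional side files).

    Node ids may be arbitrary strings; they are mapped to contiguous integers
    (sorted order) and kept as ``node_names``.  A third column is parsed as a
    positive real weight; duplicate undirected pairs collapse with weight
    summation.
    """
    edge_path = Path(edge_path)
    if delimiter is None:
        delimiter = _sniff_delimiter(edge_path)
    df = pd.read_csv(
        edge_path, sep=delimiter, header=None, dtype=str, comment="#",
        skip_blank_lines=True,
    )
    if df.shape[1] < 2:
        raise ValueError(f"{edge_path}: need at least two columns")
    if df.shape[0] and _looks_like_header(df.iloc[0]):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[0] == 0:
        raise ValueError(f"{edge_path}: no edges")

    src = df[0].astype(str).str.strip()
    dst = df[1].astype(str).str.strip()
    has_weights = df.shape[1] >= 3 and df[2].notna().any()
    if has_weights:
        try:
            w = df[2].astype(float).to_numpy()
        except ValueError as exc:
            bad = df.index[pd.to_numeric(df[2], errors="coerce").isna()][0]
            raise ValueError(
                f"{edge_path}: malformed weight at line {bad + 1}"
            ) from exc
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            bad = int(np.flatnonzero(~np.isfinite(w) | (w <= 0))[0])
            raise ValueError(
                f"{edge_path}: non-positive weight at line {bad + 1}"
            )
    else:
        w = None

    names = sorted(set(src) | set(dst))
    index = {name: i for i, name in enumerate(names)}
    u = src.map(index).to_numpy(dtype=np.int64)
    v = dst.map(index).to_numpy(dtype=np.int64)

    loops = u == v
    if loops.any():
        logger.warning("%s: dropped %d self-loop(s)", edge_path, int(loops.sum()))
        u, v = u[~loops], v[~loops]
        if w is not None:
            w = w[~loops]
    if u.size == 0:
        raise ValueError(f"{edge_path}: no edges after dropping self-loops")

    lo, hi = np.minimum(u, v), np.maximum(u, v)
    pairs = lo.astype(np.int64) * len(names) + hi
    uniq, inverse, counts = np.unique(pairs, return_inverse=True, return_counts=True)
    n_dup = int(u.size - uniq.size)
    if n_dup:
        logger.warning(
            "%s: collapsed %d duplicate undirected pair(s)%s",
            edge_path, n_dup, " (weights summed)" if w is not None else "",
        )
    edges = np.column_stack([uniq // len(names), uniq % len(names)])
    if w is not None:
        weights = np.zeros(uniq.size)
        np.add.at(weights, inverse, w)
    else:
        weights = None

    positions = None
    if positions_path is not None:
        pos_df = read_positions(positions_path)
        missing = [n for n in names if n not in pos_df.index]
        if missing:
            raise ValueError(
                f"{positions_path}: missing coordinates for {len(missing)} node(s), "
                f"e.g. {missing[:3]}"
            )
        positions = pos_df.loc[names].to_numpy(dtype=float)

    part_labels = None
    if parts_path is not None:
        parts_df = pd.read_csv(parts_path, dtype=str)
        parts_df.columns = [c.strip().lower() for c in parts_df.columns]
        parts_df = parts_df.set_index(parts_df.columns[0])
        labels_raw = parts_df.iloc[:, 0].str.strip()
        uniq_labels = sorted(labels_raw.unique())
        if len(uniq_labels) != 2:
            raise ValueError(f"{parts_path}: expected exactly two part labels")
        mapping = {uniq_labels[0]: 0, uniq_labels[1]: 1}
        try:
            part_labels = np.array(
                [mapping[labels_raw.loc[n]] for n in names], dtype=np.int64
            )
        except KeyError as exc:
            raise ValueError(f"{parts_path}: missing part label for node {exc}") from exc

    return SpatialGraph(
        n_nodes=len(names),
        edges=edges,
        weights=weights,
        part_labels=part_labels,
        positions=positions,
        node_names=tuple(names),
    )


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def write_graph(graph: SpatialGraph, path, delimiter: str = "\t") -> None:
    """Write a canonical edge list (smaller endpoint first, rows sorted)."""
    names = (
        graph.node_names
        if graph.node_names is not None
        else tuple(str(i) for i in range(graph.n_nodes))
    )
    path = Path(path)
    with open(path, "w") as fh:
        cols = ["source", "target"] + (["weight"] if graph.weights is not None else [])
        fh.write(delimiter.join(cols) + "\n")
        for k, (u, v) in enumerate(graph.edges):
            a, b = names[u], names[v]
            row = [a, b]
            if graph.weights is not None:
                row.append(_fmt(graph.weights[k]))
            fh.write(delimiter.join(row) + "\n")


def read_positions(path) -> pd.DataFrame:
    """Node positions CSV: node_id, x, y[, z]; returns an id-indexed frame."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need node_id plus at least two coordinates")
    df.columns = [str(c).strip().lower() for c in df.columns]
    df[df.columns[0]] = df[df.columns[0]].astype(str).str.strip()
    return df.set_index(df.columns[0]).astype(float)


def write_positions(graph: SpatialGraph, path) -> None:
    if graph.positions is None:
        raise ValueError("graph has no positions to write")
    names = (
        graph.node_names
        if graph.node_names is not None
        else tuple(str(i) for i in range(graph.n_nodes))
    )
    dim = graph.positions.shape[1]
    cols = ["node_id", "x", "y", "z"][: dim + 1]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for name, row in zip(names, graph.positions):
            fh.write(",".join([name] + [_fmt(c) for c in row]) + "\n")


def write_report(report_dict: dict, path, seed: int | None = None, config: dict | None = None) -> None:
    """Write a JSON report with schema version, seed, and config echo."""
    payload = dict(report_dict)
    payload.setdefault("schema_version", REPORT_SCHEMA_VERSION)
    if seed is not None:
        payload["seed"] = seed
    if config is not None:
        payload["config"] = config
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
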