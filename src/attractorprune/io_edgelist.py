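"""Edge-list serialization of weight matrices.

The on-disk format is a directed edge list, one row per nonzero entry,
with header ``source<TAB>target<TAB>weight`` and 0-based node indices.
``source`` is the sending node j and ``target`` the receiving node i, so a
row (j, i, v) corresponds to the matrix entry W[i, j] = v.  Round-tripping
through :func:`write_edgelist` / :func:`read_edgelist` is lossless given
the node count (isolated trailing nodes carry no rows, so N itself is
stored in the run's ``meta.json`` and may be passed explicitly).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_edgelist", "read_edgelist", "write_meta", "read_meta"]


def write_edgelist(w: np.ndarray, path: str | Path) -> None:
    w = np.asarray(w)
    rows, cols = np.nonzero(w)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i, j in zip(rows, cols):
            fh.write(f"{j}\t{i}\t{int(w[i, j])}\n")


def read_edgelist(path: str | Path, n_nodes: int | None = None) -> np.ndarray:
    """Read a TSV edge list back into a dense weight matrix.

    If ``n_nodes`` is omitted it is inferred as 1 + the largest node index
    present, which undercounts when trailing nodes are isolated.
    """
    sources: list[int] = []
    targets: list[int] = []
    weights: list[int] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["source", "target", "weight"]:
            raise ValueError(f"unexpected edge-list header {header!r} in {path}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            j, i, v = line.split("\t")
            sources.append(int(j))
            targets.append(int(i))
            weights.append(int(v))
    if n_nodes is None:
        n_nodes = 1 + max(max(sources, default=-1), max(targets, default=-1))
        if n_nodes < 1:
            raise ValueError(f"empty edge list {path} and no n_nodes given")
    w = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    for j, i, v in zip(sources, targets, weights):
        w[i, j] = v
    return w


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_meta(meta: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(meta), fh, indent=2)
        fh.write("\n")


def read_meta(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
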