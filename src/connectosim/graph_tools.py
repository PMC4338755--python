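"""Structural graph queries: efferent edge bookmarking and shortest paths.

Edge "length" for pathfinding inverts the connection weight — strong
fiber-density connections are short — either as 1/w (default, the usual
convention for fiber-density matrices) or as -log(w / w_max).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import Atlas
from .connectome import Connectome

__all__ = ["PathResult", "efferent_edges", "shortest_path", "region_span"]


@dataclass(frozen=True)
class PathResult:
    """A weighted shortest path between two nodes (1-based IDs)."""

    nodes: tuple            # node sequence; empty when no path exists
    length: float           # sum of per-edge lengths; inf when no path
    edge_weights: tuple     # weights of consecutive edges
    length_mode: str = "inverse"

    @property
    def found(self) -> bool:
        return len(self.nodes) > 0

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "length": self.length,
            "edge_weights": list(self.edge_weights),
            "mode": self.length_mode,
        }


def efferent_edges(connectome: Connectome, node_set: Sequence[int]) -> list:
    """All unordered nonzero pairs touching the node set.

    Returns ``(id_a, id_b, weight)`` tuples with id_a < id_b, deduplicated
    and sorted by (id_a, id_b).
    """
    ids = np.asarray(sorted(set(int(i) for i in node_set)), dtype=np.int64)
    if ids.size == 0:
        return []
    sel = np.zeros(connectome.n_nodes, bool)
    sel[connectome.index_of(ids)] = True
    w = connectome.weights
    iu, ju = np.nonzero(np.triu(w, k=1))
    touched = sel[iu] | sel[ju]
    out = []
    node_ids = connectome.node_ids
    for i, j in zip(iu[touched].tolist(), ju[touched].tolist()):
        a, b = int(node_ids[i]), int(node_ids[j])
        if a > b:
            a, b = b, a
        out.append((a, b, float(w[i, j])))
    out.sort(key=lambda e: (e[0], e[1]))
    return out


def _edge_lengths(connectome: Connectome, mode: str) -> np.ndarray:
    w = connectome.weights
    if mode == "inverse":
        with np.errstate(divide="ignore"):
            return np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    if mode == "neglog":
        w_max = w.max()
        if w_max <= 0:
            return np.full_like(w, np.inf)
        with np.errstate(divide="ignore"):
            return np.where(w > 0, -np.log(np.where(w > 0, w, 1.0) / w_max), np.inf)
    raise ValueError(f"unknown length mode {mode!r}")


def shortest_path(
    connectome: Connectome,
    source: int,
    target: int,
    length_mode: str = "inverse",
) -> PathResult:
    """Dijkstra shortest path on inverse-weight edge lengths.

    Ties in total length are broken deterministically by the
    lexicographically smallest node sequence.  A disconnected pair yields a
    no-path result (``found`` False, infinite length) rather than an error.
    """
    if source == target:
        raise ValueError("source and target must differ")
    src = int(connectome.index_of(np.asarray([source]))[0])
    dst = int(connectome.index_of(np.asarray([target]))[0])
    lengths = _edge_lengths(connectome, length_mode)
    n = connectome.n_nodes
    neighbors = [np.nonzero(connectome.weights[i] > 0)[0] for i in range(n)]

    # Heap keyed on (distance, path); the path tuple is the lexicographic
    # tie-break, in external 1-based IDs so the order matches reported paths.
    ids = connectome.node_ids
    settled = np.zeros(n, bool)
    heap = [(0.0, (int(ids[src]),), src)]
    while heap:
        dist, path, u = heapq.heappop(heap)
        if settled[u]:
            continue
        settled[u] = True
        if u == dst:
            weights = tuple(
                float(connectome.weights[
                    connectome.index_of([path[k]])[0],
                    connectome.index_of([path[k + 1]])[0],
                ])
                for k in range(len(path) - 1)
            )
            return PathResult(path, float(dist), weights, length_mode)
        for v in neighbors[u]:
            if not settled[v]:
                heapq.heappush(
                    heap, (dist + float(lengths[u, v]), path + (int(ids[v]),), int(v))
                )
    return PathResult((), float("inf"), (), length_mode)


def region_span(connectome: Connectome, atlas: Atlas, node_set: Sequence[int]) -> pd.DataFrame:
    """Regions reached in one hop from a node set.

    Counts, per region, the endpoints outside ``node_set`` of the set's
    efferent edges (edges internal to the set contribute nothing).  Returns
    a DataFrame with columns ``region`` and ``n_endpoints``, sorted by
    descending count; counts sum to the number of boundary edges.
    """
    inside = set(int(i) for i in node_set)
    counts: dict[str, int] = {}
    for a, b, _w in efferent_edges(connectome, node_set):
        for end in (a, b):
            if end not in inside:
                counts[atlas.region_of_node(end).name] = (
                    counts.get(atlas.region_of_node(end).name, 0) + 1
                )
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["region", "n_endpoints"],
    )
    return df
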