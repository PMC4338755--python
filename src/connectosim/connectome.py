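"""Weighted structural connectome container and GraphML I/O.

A connectome is an undirected, weighted graph of neural regions of interest:
a symmetric non-negative weight matrix (normalized white-matter fiber counts,
dimensionless, in (0, 1] after max-normalization), per-node 3D coordinates in
Talairach millimetres, and per-node region labels tied to an
:class:`~connectosim.atlas.Atlas`.

Node identity is 1-based in all user-facing I/O (matching how atlas tables
print node numbers); internal array storage is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx
import numpy as np

from .atlas import Atlas

__all__ = [
    "Connectome",
    "ConnectomeFormatError",
    "ConnectomeValidationError",
    "read_graphml",
    "write_graphml",
]

SYMMETRY_TOL = 1e-9


class ConnectomeFormatError(ValueError):
    """Malformed connectome file (missing attributes, bad structure)."""


class ConnectomeValidationError(ValueError):
    """Connectome violates a structural invariant."""


@dataclass
class Connectome:
    """An undirected weighted connectome.

    Attributes
    ----------
    weights : (n, n) float64 array
        Symmetric, zero-diagonal, non-negative connection weights.
    coordinates : (n, 3) float64 array
        Node coordinates, millimetres.
    region_labels : list of str
        Per-node region name (e.g. ``rCUN``).
    node_ids : (n,) int64 array
        External 1-based node identifiers.
    atlas : Atlas, optional
        The parcellation the labels are drawn from.
    lesion_mask : (n,) bool array, optional
        True for nodes disconnected by a lesion.
    """

    weights: np.ndarray
    coordinates: np.ndarray
    region_labels: list
    node_ids: np.ndarray = None  # type: ignore[assignment]
    atlas: Optional[Atlas] = None
    lesion_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.weights = np.ascontiguousarray(self.weights, dtype=np.float64)
        self.coordinates = np.ascontiguousarray(self.coordinates, dtype=np.float64)
        if self.node_ids is None:
            self.node_ids = np.arange(1, self.n_nodes + 1, dtype=np.int64)
        else:
            self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.region_labels = list(self.region_labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edge_pairs(self) -> int:
        """Number of unordered node pairs with nonzero weight."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def index_of(self, node_ids) -> np.ndarray:
        """Map external 1-based IDs to 0-based array indices."""
        order = np.argsort(self.node_ids)
        pos = np.searchsorted(self.node_ids, node_ids, sorter=order)
        pos = np.clip(pos, 0, len(order) - 1)
        idx = order[pos]
        if not np.array_equal(self.node_ids[idx], np.asarray(node_ids)):
            raise KeyError("unknown node id(s)")
        return idx

    def validate(self) -> None:
        n = self.n_nodes
        if self.weights.shape != (n, n):
            raise ConnectomeValidationError("weight matrix is not square")
        if self.coordinates.shape != (n, 3):
            raise ConnectomeValidationError("coordinates must be n x 3")
        if len(self.region_labels) != n or len(self.node_ids) != n:
            raise ConnectomeValidationError("labels/ids length mismatch")
        if not np.isfinite(self.weights).all():
            raise ConnectomeValidationError("non-finite weights")
        if not np.isfinite(self.coordinates).all():
            raise ConnectomeValidationError("non-finite coordinates")
        if (self.weights < 0).any():
            raise ConnectomeValidationError("negative weights")
        if np.abs(np.diagonal(self.weights)).max(initial=0.0) > 0:
            raise ConnectomeValidationError("nonzero diagonal (self-loops)")
        asym = np.abs(self.weights - self.weights.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ConnectomeValidationError(
                f"weight matrix asymmetric (max |W - W.T| = {asym:.3g})"
            )
        if len(set(self.node_ids.tolist())) != n:
            raise ConnectomeValidationError("duplicate node ids")
        if self.atlas is not None:
            valid = {r.name for r in self.atlas.regions}
            bad = sorted(set(self.region_labels) - valid)
            if bad:
                raise ConnectomeValidationError(
                    f"region labels not in atlas: {bad[:5]}"
                )

    def copy(self) -> "Connectome":
        return replace(
            self,
            weights=self.weights.copy(),
            coordinates=self.coordinates.copy(),
            region_labels=list(self.region_labels),
            node_ids=self.node_ids.copy(),
            lesion_mask=None if self.lesion_mask is None else self.lesion_mask.copy(),
        )


def write_graphml(connectome: Connectome, path) -> None:
    """Write a connectome as undirected GraphML.

    Node attributes: ``x``, ``y``, ``z`` (double, mm), ``region`` (string),
    ``id`` (int, 1-based).  Edge attribute: ``weight`` (double).  Each
    unordered pair with nonzero weight appears once.  Weights are written at
    full double precision so a round-trip through :func:`read_graphml` is
    bit-exact.
    """
    g = nx.Graph()
    for i in range(connectome.n_nodes):
        g.add_node(
            int(connectome.node_ids[i]),
            x=float(connectome.coordinates[i, 0]),
            y=float(connectome.coordinates[i, 1]),
            z=float(connectome.coordinates[i, 2]),
            region=str(connectome.region_labels[i]),
            id=int(connectome.node_ids[i]),
        )
    ii, jj = np.nonzero(np.triu(connectome.weights, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        g.add_edge(
            int(connectome.node_ids[i]),
            int(connectome.node_ids[j]),
            weight=float(connectome.weights[i, j]),
        )
    nx.write_graphml(g, path)


def read_graphml(path, symmetrize_policy: str = "strict", atlas: Atlas | None = None) -> Connectome:
    """Read a connectome from GraphML.

    Parameters
    ----------
    path : path-like
        GraphML file.  Nodes must carry ``x``, ``y``, ``z`` and ``region``
        attributes; edges must carry ``weight``.
    symmetrize_policy : {"strict", "average"}
        Directed or asymmetric input is an error under ``"strict"``
        (tolerance 1e-9); under ``"average"`` weights are replaced by
        (W + W.T)/2.
    atlas : Atlas, optional
        Attach and validate labels against this parcellation.
    """
    if symmetrize_policy not in ("strict", "average"):
        raise ValueError(f"unknown symmetrize policy {symmetrize_policy!r}")
    g = nx.read_graphml(path)

    nodes = list(g.nodes)
    # Order by the 1-based 'id' attribute when present, else by key.
    def node_key(k):
        data = g.nodes[k]
        if "id" in data:
            return int(data["id"])
        try:
            return int(k)
        except (TypeError, ValueError):
            return k

    nodes.sort(key=node_key)
    n = len(nodes)
    coords = np.empty((n, 3))
    labels = []
    ids = np.empty(n, dtype=np.int64)
    index = {}
    for pos, k in enumerate(nodes):
        data = g.nodes[k]
        for attr in ("x", "y", "z"):
            if attr not in data:
                raise ConnectomeFormatError(
                    f"node {k!r} missing coordinate attribute {attr!r}"
                )
        if "region" not in data:
            raise ConnectomeFormatError(f"node {k!r} missing 'region' attribute")
        coords[pos] = (float(data["x"]), float(data["y"]), float(data["z"]))
        labels.append(str(data["region"]))
        ids[pos] = int(data.get("id", node_key(k)))
        index[k] = pos

    w = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        if "weight" not in data:
            raise ConnectomeFormatError(f"edge ({u!r}, {v!r}) missing 'weight'")
        i, j = index[u], index[v]
        w[i, j] = float(data["weight"])
        if not g.is_directed():
            w[j, i] = w[i, j]

    if g.is_directed():
        asym = np.abs(w - w.T).max(initial=0.0)
        if symmetrize_policy == "strict" and asym > SYMMETRY_TOL:
            raise ConnectomeValidationError(
                f"directed weights asymmetric (max deviation {asym:.3g}) "
                "under policy 'strict'"
            )
        w = (w + w.T) / 2.0

    conn = Connectome(w, coords, labels, node_ids=ids, atlas=atlas)
    conn.validate()
    return conn
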