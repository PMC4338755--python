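"""Lesion and stimulation protocols.

A lesion disconnects a set of nodes: every row and column of the weight
matrix touching a lesioned node is zeroed, but the nodes themselves stay in
the network (uncoupled), so indexing and plotting over all nodes remain
valid.  Focal lesions take whole named regions (stroke-like, spatially
clustered); diffuse lesions sample nodes uniformly at random across the
network (multiple-sclerosis-like).

A stimulation injects a constant current (nA, signed; negative inhibits)
into a node set over a time window, modeling e.g. a transcranial magnetic
stimulation pulse train as a transient applied current.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .atlas import Atlas, nodes_of_regions
from .connectome import Connectome

__all__ = [
    "Lesion",
    "Stimulation",
    "focal_lesion",
    "diffuse_lesion",
    "apply_lesion",
    "lesion_connection_fraction",
    "make_stimulation",
]


@dataclass(frozen=True)
class Lesion:
    """A set of disconnected nodes (1-based IDs)."""

    node_set: tuple
    kind: str  # "focal" or "diffuse"
    provenance: str = ""

    def __post_init__(self):
        ids = tuple(int(i) for i in self.node_set)
        if len(set(ids)) != len(ids):
            raise ValueError("lesion node IDs must be distinct")
        object.__setattr__(self, "node_set", tuple(sorted(ids)))

    @property
    def n_nodes(self) -> int:
        return len(self.node_set)


@dataclass(frozen=True)
class Stimulation:
    """Constant applied current on a node set over [t_on, t_off) seconds."""

    node_set: tuple
    amplitude: float  # nA; negative = inhibitory
    t_on: float
    t_off: float

    def __post_init__(self):
        object.__setattr__(self, "node_set", tuple(sorted(int(i) for i in self.node_set)))
        if not self.t_on < self.t_off:
            raise ValueError(f"inverted stimulation window [{self.t_on}, {self.t_off})")
        if self.t_on < 0:
            raise ValueError("t_on must be non-negative")


def focal_lesion(atlas: Atlas, region_names: Sequence[str]) -> Lesion:
    """Disconnect all nodes of the named regions (e.g. rCUN, rLOCC, rPCUN)."""
    nodes = nodes_of_regions(atlas, region_names)
    return Lesion(tuple(nodes.tolist()), kind="focal", provenance=",".join(region_names))


def diffuse_lesion(
    connectome: Connectome,
    n_nodes: int,
    seed: int = 0,
    exclude: Sequence[int] = (),
) -> Lesion:
    """Disconnect ``n_nodes`` nodes sampled uniformly without replacement."""
    pool = np.setdiff1d(connectome.node_ids, np.asarray(list(exclude), dtype=np.int64))
    if n_nodes > pool.size:
        raise ValueError(
            f"cannot sample {n_nodes} nodes from {pool.size} available"
        )
    rng = np.random.Generator(np.random.Philox(seed))
    picks = rng.choice(pool, size=n_nodes, replace=False)
    return Lesion(tuple(np.sort(picks).tolist()), kind="diffuse", provenance=f"seed={seed}")


def apply_lesion(connectome: Connectome, lesion: Lesion) -> Connectome:
    """Zero all connections of the lesioned nodes; nodes are retained.

    Returns a copy with the lesion mask attached (cumulative when the input
    already carries one).  Idempotent, symmetry-preserving.
    """
    out = connectome.copy()
    if lesion.n_nodes:
        idx = out.index_of(np.asarray(lesion.node_set, dtype=np.int64))
        out.weights[idx, :] = 0.0
        out.weights[:, idx] = 0.0
        mask = out.lesion_mask if out.lesion_mask is not None else np.zeros(out.n_nodes, bool)
        mask = mask.copy()
        mask[idx] = True
        out.lesion_mask = mask
    elif out.lesion_mask is None:
        out.lesion_mask = np.zeros(out.n_nodes, bool)
    return out


def lesion_connection_fraction(
    connectome: Connectome, lesion: Lesion, mode: str = "count"
) -> float:
    """Fraction of connections removed by a lesion.

    ``mode="count"``: unordered nonzero pairs with at least one lesioned
    endpoint, over all unordered nonzero pairs.  ``mode="weight"``: the same
    ratio on summed weights.
    """
    if connectome.n_nodes == 0:
        raise ValueError("empty connectome")
    if mode not in ("count", "weight"):
        raise ValueError(f"unknown mode {mode!r}")
    w = connectome.weights
    iu, ju = np.triu_indices(connectome.n_nodes, k=1)
    vals = w[iu, ju]
    nz = vals > 0
    if not nz.any():
        return 0.0
    hit = np.zeros(connectome.n_nodes, bool)
    if lesion.n_nodes:
        hit[connectome.index_of(np.asarray(lesion.node_set, dtype=np.int64))] = True
    touched = hit[iu] | hit[ju]
    if mode == "count":
        return float((nz & touched).sum() / nz.sum())
    return float(vals[nz & touched].sum() / vals[nz].sum())


def make_stimulation(
    node_set: Sequence[int],
    amplitude_na: float,
    t_on: float,
    t_off: float,
) -> Stimulation:
    """Constant current ``amplitude_na`` on ``node_set`` during [t_on, t_off).

    Stimulations compose additively in the simulators' applied current.
    """
    return Stimulation(tuple(node_set), amplitude_na, t_on, t_off)
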