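"""Built-in cortical parcellation: 33 regions per hemisphere over 998 ROIs.

The atlas maps each of the 998 regions of interest (ROIs, ~1.5 cm^2 cortical
patches) to one of 66 named anatomical regions (33 per hemisphere).  Node IDs
are 1-based: the right hemisphere occupies nodes 1-500 and the left hemisphere
nodes 501-998.  Region names are addressed by a hemisphere prefix plus the
abbreviation, e.g. ``rCUN`` (right cuneus) or ``lPCUN`` (left precuneus).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Region",
    "Atlas",
    "AtlasError",
    "load_builtin_atlas",
    "nodes_of_regions",
]


class AtlasError(KeyError):
    """Raised when a region name does not resolve in the atlas."""


# (id, abbreviation, full name, right range, left range); ranges are inclusive
# and 1-based.
_BUILTIN_REGIONS = (
    (1, "BSTS", "Bank of the superior temporal sulcus", (463, 469), (961, 965)),
    (2, "CAC", "Caudal anterior cingulate cortex", (191, 194), (692, 695)),
    (3, "CMF", "Caudal middle frontal cortex", (126, 138), (628, 640)),
    (4, "CUN", "Cuneus", (335, 344), (835, 842)),
    (5, "ENT", "Entorhinal cortex", (419, 420), (918, 920)),
    (6, "FP", "Frontal pole", (26, 27), (527, 528)),
    (7, "FUS", "Fusiform gyrus", (391, 412), (890, 911)),
    (8, "IP", "Inferior parietal cortex", (284, 311), (787, 811)),
    (9, "IT", "Inferior temporal cortex", (424, 442), (925, 941)),
    (10, "ISTC", "Isthmus of the cingulate cortex", (202, 209), (703, 710)),
    (11, "LOCC", "Lateral occipital cortex", (355, 373), (852, 873)),
    (12, "LOF", "Lateral orbitofrontal cortex", (1, 19), (501, 520)),
    (13, "LING", "Lingual gyrus", (374, 390), (874, 889)),
    (14, "MOF", "Medial orbitofrontal cortex", (28, 39), (529, 540)),
    (15, "MT", "Middle temporal cortex", (443, 462), (942, 960)),
    (16, "PARC", "Paracentral lobule", (175, 186), (677, 687)),
    (17, "PARH", "Parahippocampal cortex", (413, 418), (912, 917)),
    (18, "POPE", "Pars opercularis", (48, 57), (548, 558)),
    (19, "PORB", "Pars orbitalis", (20, 25), (521, 526)),
    (20, "PTRI", "Pars triangularis", (40, 47), (541, 547)),
    (21, "PCAL", "Pericalcarine cortex", (345, 354), (843, 851)),
    (22, "PSTC", "Postcentral gyrus", (210, 240), (711, 740)),
    (23, "PC", "Posterior cingulate cortex", (195, 201), (696, 702)),
    (24, "PREC", "Precentral gyrus", (139, 174), (641, 676)),
    (25, "PCUN", "Precuneus", (312, 334), (812, 834)),
    (26, "RAC", "Rostral anterior cingulate cortex", (187, 190), (688, 691)),
    (27, "RMF", "Rostral middle frontal cortex", (58, 79), (559, 577)),
    (28, "SF", "Superior frontal cortex", (80, 125), (578, 627)),
    (29, "SP", "Superior parietal cortex", (257, 283), (760, 786)),
    (30, "ST", "Superior temporal cortex", (470, 497), (966, 994)),
    (31, "SMAR", "Supramarginal gyrus", (241, 256), (741, 759)),
    (32, "TP", "Temporal pole", (421, 423), (921, 924)),
    (33, "TT", "Transverse temporal cortex", (498, 500), (995, 998)),
)


@dataclass(frozen=True)
class Region:
    """One named region: a contiguous, inclusive 1-based node range."""

    region_id: int
    hemisphere: str  # "R" or "L"
    abbreviation: str
    full_name: str
    node_range: tuple[int, int]

    @property
    def name(self) -> str:
        """Prefixed name, e.g. ``rCUN`` for the right cuneus."""
        return self.hemisphere.lower() + self.abbreviation

    @property
    def size(self) -> int:
        lo, hi = self.node_range
        return hi - lo + 1

    def nodes(self) -> np.ndarray:
        """1-based node IDs of this region."""
        lo, hi = self.node_range
        return np.arange(lo, hi + 1, dtype=np.int64)


@dataclass(frozen=True)
class Atlas:
    """A node-range parcellation over 1..n_nodes."""

    regions: tuple[Region, ...]
    _by_name: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_by_name", {r.name: r for r in self.regions}
        )

    @property
    def n_nodes(self) -> int:
        return sum(r.size for r in self.regions)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region(self, name: str) -> Region:
        """Look up a region by prefixed name (``rCUN``, ``lPCUN``)."""
        try:
            return self._by_name[name]
        except KeyError:
            valid = ", ".join(sorted(self._by_name))
            raise AtlasError(
                f"unknown region {name!r}; valid names: {valid}"
            ) from None

    def region_of_node(self, node_id: int) -> Region:
        """Region containing a 1-based node ID."""
        for r in self.regions:
            lo, hi = r.node_range
            if lo <= node_id <= hi:
                return r
        raise AtlasError(f"node {node_id} outside atlas coverage")

    def node_labels(self) -> list[str]:
        """Per-node region name, ordered by node ID (length n_nodes)."""
        labels: list[str | None] = [None] * self.n_nodes
        for r in self.regions:
            lo, hi = r.node_range
            for i in range(lo, hi + 1):
                labels[i - 1] = r.name
        return labels  # type: ignore[return-value]

    def validate(self) -> None:
        """Check that region ranges disjointly tile 1..n_nodes."""
        seen = np.zeros(self.n_nodes, dtype=np.int64)
        for r in self.regions:
            lo, hi = r.node_range
            if not 1 <= lo <= hi <= self.n_nodes:
                raise ValueError(f"region {r.name} range {r.node_range} out of bounds")
            seen[lo - 1 : hi] += 1
        if (seen > 1).any():
            raise ValueError("overlapping region node ranges")
        if (seen == 0).any():
            raise ValueError("gaps in atlas node coverage")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "abbr", "name", "hemisphere", "node_start", "node_end"])
            for r in self.regions:
                w.writerow(
                    [r.region_id, r.abbreviation, r.full_name, r.hemisphere,
                     r.node_range[0], r.node_range[1]]
                )


def load_builtin_atlas() -> Atlas:
    """The built-in 66-region / 998-node cortical atlas.

    Returns 33 regions per hemisphere whose node ranges disjointly tile
    1..998 (right hemisphere first).
    """
    regions = []
    for rid, abbr, name, r_range, l_range in _BUILTIN_REGIONS:
        regions.append(Region(rid, "R", abbr, name, r_range))
        regions.append(Region(rid, "L", abbr, name, l_range))
    atlas = Atlas(tuple(regions))
    atlas.validate()
    assert atlas.n_regions == 66 and atlas.n_nodes == 998
    return atlas


def nodes_of_regions(atlas: Atlas, region_names) -> np.ndarray:
    """Union of the named regions' nodes, as sorted 1-based IDs.

    Names carry a hemisphere prefix: ``rCUN`` = right cuneus.  Region node
    ranges are disjoint so the union has no duplicates.
    """
    parts = [atlas.region(name).nodes() for name in region_names]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))
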