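"""Areal lattices: study units, their geometries and adjacency.

An :class:`AreaLattice` plays the role of a digital boundary file for a set of
small areas (SA2-like statistical areas): it carries polygon geometries and/or
an undirected adjacency structure, an urbanicity label per area (major city vs
regional) and a coarse state label.  Synthetic lattices are regular grids of
unit squares, which reproduce the topological features the analysis cares
about (Queen contiguity, connected components) without any real geography.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon, box, mapping, shape

__all__ = [
    "AreaLattice",
    "generate_lattice",
    "read_geojson",
    "write_geojson",
    "read_gal",
    "write_gal",
]


@dataclass
class AreaLattice:
    """A set of areal units with geometry and/or adjacency.

    Parameters
    ----------
    area_ids : list of str
        Unique identifiers, one per area.
    geometries : list of shapely Polygon, optional
        Planar polygons in arbitrary units.  Either geometries or adjacency
        must be supplied.
    adjacency : list of (str, str), optional
        Undirected, irreflexive area pairs.
    urbanicity : list of str
        One of ``"major_city"`` or ``"regional"`` per area.
    state_label : list of str
        Coarse region label per area (stands in for state/territory).
    """

    area_ids: list[str]
    geometries: list[Polygon] | None = None
    adjacency: list[tuple[str, str]] | None = None
    urbanicity: list[str] = field(default_factory=list)
    state_label: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("area_ids must be unique")
        if self.geometries is None and self.adjacency is None:
            raise ValueError("either geometries or adjacency must be given")
        if not self.urbanicity:
            self.urbanicity = ["major_city"] * len(self.area_ids)
        if not self.state_label:
            self.state_label = ["S1"] * len(self.area_ids)
        if self.adjacency is not None:
            known = set(self.area_ids)
            for a, b in self.adjacency:
                if a == b:
                    raise ValueError(f"self-adjacency for area {a!r}")
                if a not in known or b not in known:
                    raise ValueError(f"adjacency refers to unknown area ({a!r}, {b!r})")

    @property
    def n(self) -> int:
        return len(self.area_ids)

    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.area_ids)}

    def adjacency_indices(self) -> np.ndarray:
        """Adjacency as an (m, 2) integer array (i < j), from stored pairs.

        Requires ``adjacency`` to be populated (use
        :func:`arealepi.spatial.queen_contiguity` to derive it from polygons).
        """
        if self.adjacency is None:
            raise ValueError("lattice has no adjacency pairs; build Queen contiguity first")
        ix = self.index()
        pairs = sorted({tuple(sorted((ix[a], ix[b]))) for a, b in self.adjacency})
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)

    def component_ids(self) -> np.ndarray:
        """Connected-component label per area (0-based, from adjacency)."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        pairs = self.adjacency_indices()
        n = self.n
        if len(pairs) == 0:
            return np.arange(n)
        data = np.ones(len(pairs))
        a = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, labels = connected_components(a, directed=False)
        return labels


def generate_lattice(n_side: int, regional_fraction: float = 0.0, seed: int = 0) -> AreaLattice:
    """Generate an ``n_side`` x ``n_side`` grid of unit-square areas.

    A contiguous peripheral block of ``ceil(regional_fraction * n_side**2)``
    cells is labelled ``regional`` (outer rings first, partial rings filled in
    angular order so the block stays connected); the rest are ``major_city``.
    State labels split the grid into west/east halves.  Deterministic given
    ``seed`` (the seed only fixes tie-breaking conventions; the layout itself
    is deterministic).
    """
    if n_side < 2:
        raise ValueError("n_side must be >= 2")
    if not 0.0 <= regional_fraction <= 1.0:
        raise ValueError("regional_fraction must be in [0, 1]")
    n = n_side * n_side
    ids = []
    geoms = []
    rows = []
    cols = []
    for r in range(n_side):
        for c in range(n_side):
            ids.append(f"A{r * n_side + c:04d}")
            geoms.append(box(c, r, c + 1, r + 1))
            rows.append(r)
            cols.append(c)
    centre = (n_side - 1) / 2.0
    ring = np.maximum(np.abs(np.asarray(rows) - centre), np.abs(np.asarray(cols) - centre))
    angle = np.arctan2(np.asarray(rows) - centre, np.asarray(cols) - centre)
    order = np.lexsort((angle, -ring))  # outermost ring first, then by angle
    k = math.ceil(regional_fraction * n)
    urb = np.full(n, "major_city", dtype=object)
    urb[order[:k]] = "regional"
    states = ["W" if c < n_side / 2 else "E" for c in cols]
    return AreaLattice(
        area_ids=ids,
        geometries=geoms,
        urbanicity=list(urb),
        state_label=states,
    )


# ---------------------------------------------------------------------------
# IO: GeoJSON polygons and GAL adjacency
# ---------------------------------------------------------------------------

def write_geojson(lattice: AreaLattice, path: str) -> None:
    if lattice.geometries is None:
        raise ValueError("lattice has no geometries to write")
    feats = []
    for aid, geom, urb, st in zip(
        lattice.area_ids, lattice.geometries, lattice.urbanicity, lattice.state_label
    ):
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"area_id": aid, "urbanicity": urb, "state": st},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path: str) -> AreaLattice:
    with open(path) as fh:
        fc = json.load(fh)
    ids, geoms, urbs, states = [], [], [], []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        ids.append(str(props["area_id"]))
        geoms.append(shape(feat["geometry"]))
        urbs.append(props.get("urbanicity", "major_city"))
        states.append(props.get("state", "S1"))
    return AreaLattice(area_ids=ids, geometries=geoms, urbanicity=urbs, state_label=states)


def write_gal(area_ids: Sequence[str], neighbors: Mapping[str, Sequence[str]], path: str) -> None:
    """Write a GAL adjacency file (one header line with n, then id/degree and
    neighbour lines per area)."""
    with open(path, "w") as fh:
        fh.write(f"{len(area_ids)}\n")
        for aid in area_ids:
            nbrs = list(neighbors.get(aid, []))
            fh.write(f"{aid} {len(nbrs)}\n")
            fh.write(" ".join(nbrs) + "\n")


def read_gal(path: str) -> AreaLattice:
    """Read a GAL adjacency file into an AreaLattice (no geometries)."""
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh.read().splitlines() if ln.strip()]
    header = tokens_by_line[0]
    n = int(header[-1]) if len(header) > 1 else int(header[0])
    ids: list[str] = []
    pairs: set[tuple[str, str]] = set()
    i = 1
    while i < len(tokens_by_line):
        aid, deg = tokens_by_line[i][0], int(tokens_by_line[i][1])
        ids.append(aid)
        if deg > 0:
            nbrs = tokens_by_line[i + 1]
            if len(nbrs) != deg:
                raise ValueError(f"GAL degree mismatch for area {aid}")
            for b in nbrs:
                pairs.add(tuple(sorted((aid, b))))
            i += 2
        else:
            # zero-neighbour areas may or may not have an empty line following
            if i + 1 < len(tokens_by_line) and len(tokens_by_line[i + 1]) == 0:
                i += 2
            else:
                i += 1
    if len(ids) != n:
        raise ValueError(f"GAL header announces {n} areas, found {len(ids)}")
    return AreaLattice(area_ids=ids, adjacency=sorted(pairs))
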