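"""Areal geometries: lattices, polygon maps, centroid distances and contiguity.

An areal map is represented by :class:`ArealGeometry` — an ordered set of areas
with shapes (polygons or lattice cells) and centroids.  From it one derives the
two primitives every spatial weights matrix is built from: the matrix of
pairwise Euclidean centroid distances and the contiguity (neighbourhood) graph,
optionally extended to higher adjacency orders by shortest-path length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform, pdist
from shapely.geometry import shape as _shapely_shape
from shapely.geometry import Polygon, mapping

__all__ = [
    "ArealGeometry",
    "ContiguityGraph",
    "UNREACHABLE",
    "grid_lattice",
    "pairwise_centroid_distance",
    "contiguity",
    "adjacency_order",
    "read_geojson",
    "write_geojson",
    "read_gal",
    "write_gal",
]

#: Sentinel in the adjacency-order matrix for pairs beyond ``max_order`` or
#: in different connected components.
UNREACHABLE = -1


@dataclass
class ArealGeometry:
    """An ordered collection of areal units.

    Parameters
    ----------
    area_ids
        Unique identifiers, one per area; their order fixes all matrix indexing.
    shapes
        Shapely polygons, one per area, or ``None`` for centroid-only geometries.
    centroids
        ``(N, 2)`` array of planar centroid coordinates.
    units
        Length-unit tag carried through for transparency (e.g. ``"km"`` or
        ``"lattice steps"``); the decay-scale rule in the weights module makes
        results invariant to this choice.
    """

    area_ids: list
    centroids: np.ndarray
    shapes: list | None = None
    units: str = "unspecified"
    lattice_dims: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.area_ids) != len(set(map(str, self.area_ids))):
            raise ValueError("area_ids must be unique")
        n = len(self.area_ids)
        if n < 1:
            raise ValueError("geometry needs at least one area")
        if self.centroids.shape != (n, 2):
            raise ValueError("centroids must be an (N, 2) array matching area_ids")
        if self.shapes is not None:
            if len(self.shapes) != n:
                raise ValueError("shapes length must match area_ids")
            for sid, geom in zip(self.area_ids, self.shapes):
                if geom.area <= 0:
                    raise ValueError(f"area {sid!r}: polygon is degenerate (non-positive area)")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)


@dataclass
class ContiguityGraph:
    """First-order neighbour sets plus an adjacency-order matrix.

    ``order[i, j]`` is the shortest-path length between areas ``i`` and ``j``
    in the first-order graph (0 on the diagonal, :data:`UNREACHABLE` for pairs
    beyond the computed horizon or in different components).
    """

    neighbour_sets: list[set[int]]
    order: np.ndarray

    def __post_init__(self) -> None:
        for i, nbrs in enumerate(self.neighbour_sets):
            if i in nbrs:
                raise ValueError(f"area {i} listed as its own neighbour")
            for j in nbrs:
                if i not in self.neighbour_sets[j]:
                    raise ValueError(f"asymmetric neighbour pair ({i}, {j})")

    @property
    def n_areas(self) -> int:
        return len(self.neighbour_sets)

    def adjacency_matrix(self) -> np.ndarray:
        """Binary first-order adjacency matrix (dense, symmetric, zero diagonal)."""
        n = self.n_areas
        a = np.zeros((n, n))
        for i, nbrs in enumerate(self.neighbour_sets):
            for j in nbrs:
                a[i, j] = 1.0
        return a


def grid_lattice(rows: int, cols: int, spacing: float = 1.0) -> ArealGeometry:
    """Regular rectangular lattice of ``rows × cols`` square cells.

    Cells are squares of side ``spacing`` centred on a regular grid, ordered
    row-major; this ordering fixes the area indexing for all derived matrices.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ids, cents, shapes = [], [], []
    h = spacing / 2.0
    for r in range(rows):
        for c in range(cols):
            ids.append(f"r{r}c{c}")
            cx, cy = c * spacing, r * spacing
            cents.append((cx, cy))
            shapes.append(Polygon([(cx - h, cy - h), (cx + h, cy - h),
                                   (cx + h, cy + h), (cx - h, cy + h)]))
    return ArealGeometry(ids, np.array(cents), shapes,
                         units="lattice steps", lattice_dims=(rows, cols))


def pairwise_centroid_distance(geom: ArealGeometry) -> np.ndarray:
    """Symmetric matrix of Euclidean distances between area centroids."""
    if geom.n_areas == 1:
        return np.zeros((1, 1))
    return squareform(pdist(geom.centroids, metric="euclidean"))


def contiguity(geom: ArealGeometry, include_vertex: bool = True,
               snap: float = 1e-9) -> ContiguityGraph:
    """First-order contiguity from shared boundaries.

    Two areas are neighbours when their boundaries intersect: with
    ``include_vertex`` a single shared point suffices (queen contiguity on a
    lattice), otherwise the shared boundary must have positive length (rook).
    ``snap`` is the tolerance for floating-point boundary matching.
    """
    if geom.shapes is None:
        raise ValueError("contiguity requires shapes; this geometry has centroids only")
    n = geom.n_areas
    nbrs: list[set[int]] = [set() for _ in range(n)]
    if geom.lattice_dims is not None:
        rows, cols = geom.lattice_dims
        for r in range(rows):
            for c in range(cols):
                i = r * cols + c
                steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
                if include_vertex:
                    steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        nbrs[i].add(rr * cols + cc)
    else:
        from shapely.strtree import STRtree

        tree = STRtree(geom.shapes)
        for i, gi in enumerate(geom.shapes):
            for j in tree.query(gi.buffer(snap)):
                j = int(j)
                if j == i:
                    continue
                gj = geom.shapes[j]
                if gi.distance(gj) > snap:
                    continue
                if include_vertex:
                    nbrs[i].add(j)
                else:
                    inter = gi.intersection(gj)
                    if not inter.is_empty and inter.length > snap:
                        nbrs[i].add(j)
                    elif inter.is_empty:
                        # near-miss boundaries within snap: a shared edge leaves a
                        # buffered-overlap strip of area ≈ 2·snap·L, a vertex only ≈ π·snap²
                        strip = gi.buffer(snap).intersection(gj.buffer(snap))
                        if strip.area > 10.0 * snap * snap:
                            nbrs[i].add(j)
        for i in range(n):
            for j in list(nbrs[i]):
                nbrs[j].add(i)
    order = _order_matrix(nbrs, max_order=1)
    return ContiguityGraph(nbrs, order)


def _order_matrix(nbrs: list[set[int]], max_order: int) -> np.ndarray:
    n = len(nbrs)
    rows, cols = [], []
    for i, s in enumerate(nbrs):
        for j in s:
            rows.append(i)
            cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    sp = shortest_path(adj, method="D", unweighted=True)
    order = np.full((n, n), UNREACHABLE, dtype=int)
    finite = np.isfinite(sp) & (sp <= max_order)
    order[finite] = sp[finite].astype(int)
    return order


def adjacency_order(graph: ContiguityGraph, max_order: int) -> np.ndarray:
    """Shortest-path adjacency orders up to ``max_order``.

    Entry ``(i, j)`` is the graph distance in the first-order contiguity graph
    when it is ≤ ``max_order``; otherwise :data:`UNREACHABLE`.
    """
    if max_order < 1:
        raise ValueError("max_order must be positive")
    return _order_matrix(graph.neighbour_sets, max_order)


# ---------------------------------------------------------------------------
# File formats: GeoJSON polygons and GAL adjacency lists


def read_geojson(path, id_property: str = "area_id", units: str = "unspecified") -> ArealGeometry:
    """Read a GeoJSON FeatureCollection of polygons into an :class:`ArealGeometry`."""
    with open(path) as fh:
        gj = json.load(fh)
    ids, shapes = [], []
    for feat in gj["features"]:
        ids.append(feat["properties"][id_property])
        geom = _shapely_shape(feat["geometry"])
        shapes.append(geom)
    cents = np.array([(g.centroid.x, g.centroid.y) for g in shapes])
    return ArealGeometry(ids, cents, shapes, units=units)


def write_geojson(geom: ArealGeometry, path, properties: dict | None = None) -> None:
    """Write polygons (with optional per-area property columns) as GeoJSON."""
    if geom.shapes is None:
        raise ValueError("geometry has no shapes to write")
    feats = []
    for i, (aid, g) in enumerate(zip(geom.area_ids, geom.shapes)):
        props = {"area_id": aid}
        if properties:
            props.update({k: v[i] for k, v in properties.items()})
        feats.append({"type": "Feature", "properties": props, "geometry": mapping(g)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_gal(path) -> ContiguityGraph:
    """Read a GAL adjacency list (spdep/PySAL dialect, 0- or 4-token header)."""
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    header = tokens_by_line[0]
    n = int(header[1]) if len(header) == 4 else int(header[0])
    id_to_idx: dict[str, int] = {}
    entries: list[tuple[str, list[str]]] = []
    k = 1
    while k < len(tokens_by_line):
        aid, deg = tokens_by_line[k][0], int(tokens_by_line[k][1])
        k += 1
        nb: list[str] = []
        if deg > 0:
            nb = tokens_by_line[k]
            k += 1
            if len(nb) != deg:
                raise ValueError(f"GAL entry for {aid!r}: expected {deg} neighbours, got {len(nb)}")
        entries.append((aid, nb))
        id_to_idx.setdefault(aid, len(id_to_idx))
    if len(entries) != n:
        raise ValueError(f"GAL header declares {n} areas, file lists {len(entries)}")
    for aid, nb in entries:
        for b in nb:
            id_to_idx.setdefault(b, len(id_to_idx))
    nbrs: list[set[int]] = [set() for _ in range(len(id_to_idx))]
    for aid, nb in entries:
        i = id_to_idx[aid]
        for b in nb:
            nbrs[i].add(id_to_idx[b])
    # symmetrise defensively; a valid GAL is already symmetric
    for i in range(len(nbrs)):
        for j in list(nbrs[i]):
            nbrs[j].add(i)
    return ContiguityGraph(nbrs, _order_matrix(nbrs, max_order=1))


def write_gal(graph: ContiguityGraph, path, area_ids: list | None = None) -> None:
    """Write a ContiguityGraph as a GAL adjacency list."""
    ids = area_ids if area_ids is not None else list(range(graph.n_areas))
    with open(path, "w") as fh:
        fh.write(f"{graph.n_areas}\n")
        for i, nb in enumerate(graph.neighbour_sets):
            fh.write(f"{ids[i]} {len(nb)}\n")
            fh.write(" ".join(str(ids[j]) for j in sorted(nb)) + "\n")
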