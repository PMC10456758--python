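"""Neighbor graphs over 2-D point configurations.

Two neighbor definitions are supported, matching the two interaction rules
used in flocking models:

* **topological** — two agents are neighbors iff their Voronoi cells share an
  edge (equivalently, they are adjacent in the Delaunay triangulation);
* **metric** — two agents are neighbors iff their separation is at most a
  fixed radius ``R``.

Both work under open or periodic boundaries.  Periodic tessellation is
realized by tiling the box 3×3 with ghost copies and keeping ridges incident
to the canonical copy; all periodic distances use the minimum-image
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .errors import ConfigurationError, ConsistencyError, GeometryError

# Deterministic tie-break for co-circular point quadruples (e.g. square
# lattices): coordinates are jittered by _TIE_BREAK_SCALE x box before
# tessellation, from a fixed-seed generator, while all reported distances are
# computed on the unperturbed coordinates.
_TIE_BREAK_SEED = 230726
_TIE_BREAK_SCALE = 1e-9

_ZERO_NORM = 1e-12


@dataclass(frozen=True)
class PointSet:
    """Positions of N agents in a rectangular domain.

    Parameters
    ----------
    coords : (N, 2) float array
        Agent positions, in a single length unit (pixels for tracked data,
        simulation units otherwise).
    boundary : {"open", "periodic"}
        Boundary condition used for neighbor construction and distances.
    box : (Lx, Ly), optional
        Domain extents; required iff ``boundary == "periodic"``.  Periodic
        coordinates are canonically wrapped into ``[0, Lx) x [0, Ly)``.
    """

    coords: np.ndarray
    boundary: str = "open"
    box: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ConfigurationError(f"coords must be (N, 2); got shape {coords.shape}")
        if coords.shape[0] < 1:
            raise ConfigurationError("at least one point is required")
        if not np.all(np.isfinite(coords)):
            bad = np.flatnonzero(~np.isfinite(coords).all(axis=1))
            raise ConfigurationError(f"non-finite coordinates at indices {bad.tolist()}")
        if self.boundary not in ("open", "periodic"):
            raise ConfigurationError(f"unknown boundary mode {self.boundary!r}")
        if self.boundary == "periodic":
            if self.box is None:
                raise ConfigurationError("periodic boundary requires a box")
            box = (float(self.box[0]), float(self.box[1]))
            if box[0] <= 0 or box[1] <= 0:
                raise ConfigurationError(f"box extents must be positive; got {box}")
            object.__setattr__(self, "box", box)
            coords = np.mod(coords, np.asarray(box))
        coords = np.ascontiguousarray(coords)
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def displacement(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Displacement vectors coords[j] - coords[i] (minimum image if periodic)."""
        disp = self.coords[j] - self.coords[i]
        if self.boundary == "periodic":
            disp = minimum_image(disp, self.box)
        return disp

    def distance(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.displacement(i, j), axis=-1)


def minimum_image(disp: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    """Map displacement vectors to their nearest periodic image."""
    box_arr = np.asarray(box, dtype=float)
    return disp - box_arr * np.round(disp / box_arr)


@dataclass(frozen=True)
class NeighborGraph:
    """Undirected adjacency over agents with per-edge separation distances."""

    n_agents: int
    edges: np.ndarray          # (M, 2) int, each row sorted i < j, rows unique
    edge_distances: np.ndarray  # (M,) float, minimum-image if periodic

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        dist = np.asarray(self.edge_distances, dtype=float).reshape(-1)
        if edges.shape[0] != dist.shape[0]:
            raise ConsistencyError("edges and edge_distances lengths differ")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "edge_distances", dist)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Per-agent neighbor count n_i."""
        deg = np.zeros(self.n_agents, dtype=np.intp)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def directed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Both orientations of every edge: (src, dst, distance) arrays."""
        src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        dist = np.concatenate([self.edge_distances, self.edge_distances])
        return src, dst, dist


@dataclass(frozen=True)
class DistanceSample:
    """Multiset of agent-neighbor distances drawn from one configuration."""

    values: np.ndarray
    counting_convention: str = "per_agent_directed"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).reshape(-1)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _check_duplicates(points: PointSet) -> None:
    # complex view gives a 1-D exact-equality key per point (fast unique)
    keys = points.coords[:, 0] + 1j * points.coords[:, 1]
    _, inverse, counts = np.unique(keys, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        dup_groups = np.flatnonzero(counts > 1)
        offenders = [np.flatnonzero(inverse == g).tolist() for g in dup_groups]
        raise GeometryError(f"duplicate points at index groups {offenders}")


def _check_not_collinear(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    scale = np.abs(centered).max()
    if scale == 0:
        raise GeometryError("all points coincide")
    s = np.linalg.svd(centered / scale, compute_uv=False)
    if s[-1] < 1e-12:
        raise GeometryError("all points are collinear; Voronoi tessellation undefined")


def _tie_break_jitter(coords: np.ndarray, scale: float) -> np.ndarray:
    rng = np.random.default_rng(_TIE_BREAK_SEED)
    return coords + rng.uniform(-1.0, 1.0, size=coords.shape) * (_TIE_BREAK_SCALE * scale)


def _simplices_to_edges(simplices: np.ndarray) -> np.ndarray:
    edges = np.vstack([simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]])
    return edges


def build_voronoi_graph(points: PointSet) -> NeighborGraph:
    """Topological (Voronoi/Delaunay) neighbor graph.

    Two agents are neighbors iff their Voronoi cells share an edge.  Under
    periodic boundaries the tessellation runs on the 3x3 ghost tiling and
    adjacency is mapped back to canonical indices with minimum-image
    distances; under open boundaries, adjacencies involving unbounded cells
    are retained.
    """
    _check_duplicates(points)
    n = points.n

    if points.boundary == "open":
        if n < 3:
            raise GeometryError("open-boundary Voronoi tessellation needs >= 3 points")
        _check_not_collinear(points.coords)
        scale = max(float(np.ptp(points.coords, axis=0).max()), 1.0)
        jittered = _tie_break_jitter(points.coords, scale)
        try:
            tri = Delaunay(jittered)
        except QhullError as exc:  # pragma: no cover - jitter makes this rare
            raise GeometryError(f"degenerate geometry: {exc}") from exc
        edges = _simplices_to_edges(tri.simplices)
    else:
        lx, ly = points.box
        offsets = np.array(
            [(0, 0), (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
            dtype=float,
        ) * np.array([lx, ly])
        jittered = _tie_break_jitter(points.coords, max(lx, ly))
        tiled = (jittered[None, :, :] + offsets[:, None, :]).reshape(-1, 2)
        try:
            tri = Delaunay(tiled)
        except QhullError as exc:  # pragma: no cover
            raise GeometryError(f"degenerate geometry: {exc}") from exc
        raw = _simplices_to_edges(tri.simplices)
        # keep ridges touching the canonical copy (tile 0 = indices < n)
        keep = (raw[:, 0] < n) | (raw[:, 1] < n)
        edges = raw[keep] % n
        edges = edges[edges[:, 0] != edges[:, 1]]

    if edges.size == 0:
        edges = np.empty((0, 2), dtype=np.intp)
    else:
        lo = edges.min(axis=1).astype(np.int64)
        hi = edges.max(axis=1).astype(np.int64)
        keys = np.unique(lo * n + hi)
        edges = np.column_stack([keys // n, keys % n]).astype(np.intp)
    distances = points.distance(edges[:, 0], edges[:, 1]) if edges.size else np.empty(0)
    return NeighborGraph(n_agents=n, edges=edges, edge_distances=distances)


def build_metric_graph(points: PointSet, radius: float) -> NeighborGraph:
    """Metric neighbor graph: edge (i, j) present iff dist(i, j) <= radius."""
    radius = float(radius)
    if radius < 0:
        raise ConfigurationError(f"radius must be non-negative; got {radius}")
    _check_duplicates(points)
    n = points.n

    if points.boundary == "periodic":
        lx, ly = points.box
        if radius <= min(lx, ly) / 2:
            tree = cKDTree(points.coords, boxsize=(lx, ly))
            pairs = tree.query_pairs(radius, output_type="ndarray")
        else:
            # radius beyond cKDTree's periodic limit: dense minimum-image scan
            ii, jj = np.triu_indices(n, k=1)
            d = points.distance(ii, jj)
            keep = d <= radius
            pairs = np.column_stack([ii[keep], jj[keep]])
    else:
        tree = cKDTree(points.coords)
        pairs = tree.query_pairs(radius, output_type="ndarray")

    if pairs.size == 0:
        pairs = np.empty((0, 2), dtype=np.intp)
    pairs = np.sort(pairs.astype(np.intp), axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    distances = points.distance(pairs[:, 0], pairs[:, 1]) if pairs.size else np.empty(0)
    return NeighborGraph(n_agents=n, edges=pairs, edge_distances=distances)


def neighbor_distances(points: PointSet, graph: NeighborGraph) -> DistanceSample:
    """Distances of all agent-neighbor incidences.

    Uses the per-agent directed convention: each undirected edge contributes
    one distance per endpoint, so the sample size is sum_i n_i = 2|edges|.
    Downstream probabilities are identical to a per-edge count because the
    uniform factor of 2 cancels in p_i = X_i / X.
    """
    if graph.n_agents != points.n:
        raise ConsistencyError(
            f"graph has {graph.n_agents} agents but point set has {points.n}"
        )
    values = np.repeat(graph.edge_distances, 2)
    return DistanceSample(values=values, counting_convention="per_agent_directed")


def brute_force_delaunay_edges(coords: np.ndarray) -> set[tuple[int, int]]:
    """O(n^4) empty-circumcircle Delaunay adjacency, for cross-checking.

    A pair (i, j) is adjacent iff some circle through i, j and a third point
    — or through i, j alone as diameter when n == 2 — contains no other
    point.  Intended for small open-boundary instances only.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n == 2:
        return {(0, 1)}
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(n):
                if k in (i, j):
                    continue
                center, r2 = _circumcircle(coords[i], coords[j], coords[k])
                if center is None:
                    continue
                d2 = np.sum((coords - center) ** 2, axis=1)
                others = np.ones(n, dtype=bool)
                others[[i, j, k]] = False
                if np.all(d2[others] > r2 * (1 - 1e-12)):
                    edges.add((i, j))
                    break
    return edges


def _circumcircle(a, b, c):
    """Center and squared radius of the circle through a, b, c (None if collinear)."""
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-14 * max(1.0, np.abs([a, b, c]).max() ** 2):
        return None, None
    a2, b2, c2 = np.sum(a**2), np.sum(b**2), np.sum(c**2)
    ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
    uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
    center = np.array([ux, uy])
    return center, float(np.sum((a - center) ** 2))
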