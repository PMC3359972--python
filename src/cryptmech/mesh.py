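"""Periodic Delaunay connectivity and dual Voronoi geometry for cell centres.

Cell centres live on a strip that is periodic in ``x`` (period ``width``) and
unbounded in ``y``.  Connectivity is the Delaunay triangulation of the
periodically replicated point set, folded back onto the canonical copy, with
edges longer than an interaction cutoff discarded (long edges carry no spring
and play no part in anoikis detection).  Cell shapes and areas are given by
the dual Voronoi tessellation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay, Voronoi
from scipy.spatial._qhull import QhullError

__all__ = [
    "CellType",
    "CellNode",
    "PeriodicDomain",
    "Triangulation",
    "DegenerateGeometryError",
    "ConfigurationError",
    "MeshInternalError",
    "build_periodic_triangulation",
    "voronoi_cell_areas",
]

#: Default interaction cutoff in cell widths.  Delaunay edges longer than this
#: carry no spring force and do not count as contacts for anoikis detection;
#: 1.5 cell widths is the conventional choice for cell-centre models and
#: suppresses spurious long-range edges across the lumen.
DEFAULT_CUTOFF = 1.5


class CellType(enum.IntEnum):
    EPITHELIAL = 0
    STROMAL = 1


class DegenerateGeometryError(ValueError):
    """Fewer than three points, or all points collinear."""


class ConfigurationError(ValueError):
    """A scenario or domain specification that cannot be realised."""


class MeshInternalError(RuntimeError):
    """An internal geometric failure (e.g. an unclosable Voronoi region)."""


@dataclass
class CellNode:
    """A cell centre.

    Positions are measured in cell widths; ``x`` is periodic, ``y`` vertical.
    Stromal cells are terminally differentiated and never carry a cycle.
    """

    id: int
    position: np.ndarray
    cell_type: CellType = CellType.EPITHELIAL
    pinned: bool = False
    cycle: "object | None" = None
    birth_time: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.cell_type == CellType.STROMAL and self.cycle is not None:
            raise ValueError("stromal cells are terminally differentiated and carry no cycle")


@dataclass(frozen=True)
class PeriodicDomain:
    """A strip periodic in x with the given period; y is unbounded."""

    width: float

    def wrap(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.mod(x, self.width)

    def delta(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image separation vectors for raw differences ``d``."""
        d = np.array(d, dtype=float, copy=True)
        d[..., 0] -= self.width * np.round(d[..., 0] / self.width)
        return d

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = self.delta(np.asarray(b, float) - np.asarray(a, float))
        return np.hypot(d[..., 0], d[..., 1])


@dataclass
class Triangulation:
    """Periodic Delaunay connectivity over cell centres.

    ``edges`` holds positional indices (lo < hi) into ``points``/``ids``.
    The edge relation is symmetric, irreflexive and cutoff-filtered.
    """

    points: np.ndarray              # (N, 2), x wrapped into [0, width)
    ids: np.ndarray                 # (N,) node ids
    edges: np.ndarray               # (E, 2) positional indices, lo < hi
    cutoff: float
    domain: PeriodicDomain
    cell_types: np.ndarray | None = None   # (N,) CellType codes
    pinned: np.ndarray | None = None       # (N,) bool
    #: full Delaunay edge set before the cutoff filter
    edges_all: np.ndarray | None = None
    _adjacency: dict | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def edge_id_pairs(self) -> set[tuple[int, int]]:
        """Edges as unordered pairs of node ids."""
        a = self.ids[self.edges[:, 0]]
        b = self.ids[self.edges[:, 1]]
        return {(int(min(i, j)), int(max(i, j))) for i, j in zip(a, b)}

    def index_of(self, node_id: int) -> int:
        idx = np.flatnonzero(self.ids == node_id)
        if len(idx) == 0:
            raise KeyError(f"node id {node_id} not in triangulation")
        return int(idx[0])

    def neighbor_indices(self, pos_index: int) -> np.ndarray:
        if self._adjacency is None:
            adj: dict[int, list[int]] = {}
            for a, b in self.edges:
                adj.setdefault(int(a), []).append(int(b))
                adj.setdefault(int(b), []).append(int(a))
            self._adjacency = {k: np.array(v, dtype=int) for k, v in adj.items()}
        return self._adjacency.get(int(pos_index), np.empty(0, dtype=int))

    def neighbors(self, node_id: int) -> np.ndarray:
        """Ids of the Delaunay neighbours of ``node_id`` within the cutoff."""
        return self.ids[self.neighbor_indices(self.index_of(node_id))]

    def edge_lengths(self) -> np.ndarray:
        d = self.domain.delta(self.points[self.edges[:, 1]] - self.points[self.edges[:, 0]])
        return np.hypot(d[:, 0], d[:, 1])


def _augmented_points(points: np.ndarray, width: float, margin: float | None):
    """Canonical points plus periodic images within ``margin`` of the walls.

    ``margin=None`` replicates the full strip at +/- width (the exact oracle
    construction); a finite margin replicates only the boundary bands, which
    yields the same cutoff-filtered edge set for any margin comfortably larger
    than the cutoff and is much cheaper.
    """
    n = len(points)
    if margin is None or margin * 2.0 >= width:
        aug = np.concatenate([points, points + (width, 0.0), points - (width, 0.0)])
        src = np.concatenate([np.arange(n)] * 3)
        return aug, src
    left = np.flatnonzero(points[:, 0] < margin)
    right = np.flatnonzero(points[:, 0] > width - margin)
    aug = np.concatenate([points, points[right] - (width, 0.0), points[left] + (width, 0.0)])
    src = np.concatenate([np.arange(n), right, left])
    return aug, src


def build_periodic_triangulation(
    positions: Sequence | np.ndarray,
    domain: PeriodicDomain,
    cutoff: float = DEFAULT_CUTOFF,
    *,
    ids: np.ndarray | None = None,
    cell_types: np.ndarray | None = None,
    pinned: np.ndarray | None = None,
    margin: float | None = None,
) -> Triangulation:
    """Delaunay edges of the x-periodic point set, filtered to ``cutoff``.

    The triangulation is computed on the point set augmented with periodic
    image copies; image edges are folded back to canonical node pairs.  Edges
    longer than ``cutoff`` (periodic metric) are dropped.

    Raises
    ------
    DegenerateGeometryError
        For fewer than three points or an all-collinear arrangement.
    ConfigurationError
        If ``domain.width <= 2 * cutoff`` (the strip would interact with its
        own image).
    """
    points = np.atleast_2d(np.asarray(positions, dtype=float))
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("positions must be an (N, 2) array")
    if len(points) < 3:
        raise DegenerateGeometryError("need at least 3 points to triangulate")
    if np.isfinite(cutoff) and domain.width <= 2.0 * cutoff:
        raise ConfigurationError(
            f"domain width {domain.width} must exceed twice the cutoff {cutoff}"
        )
    points = points.copy()
    points[:, 0] = np.mod(points[:, 0], domain.width)

    aug, src = _augmented_points(points, domain.width, margin)
    try:
        tri = Delaunay(aug)
    except QhullError as err:
        raise DegenerateGeometryError(f"degenerate point configuration: {err}") from None
    s = tri.simplices
    e = np.concatenate([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    # Keep only edges with a canonical endpoint: every true periodic edge has
    # one, while convex-hull artifacts at a truncated image band do not.
    e = e[(e[:, 0] < len(points)) | (e[:, 1] < len(points))]
    a = src[e[:, 0]]
    b = src[e[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    keep = lo != hi                       # folds a point's edge to its own image away
    key = np.unique(lo[keep].astype(np.int64) * len(points) + hi[keep])
    edges = np.column_stack([key // len(points), key % len(points)]).astype(np.intp)

    d = points[edges[:, 1]] - points[edges[:, 0]]
    d[:, 0] -= domain.width * np.round(d[:, 0] / domain.width)
    lengths = np.hypot(d[:, 0], d[:, 1])
    edges_all = edges
    edges = edges[lengths <= cutoff]

    if ids is None:
        ids = np.arange(len(points))
    return Triangulation(
        points=points,
        ids=np.asarray(ids),
        edges=edges,
        cutoff=cutoff,
        domain=domain,
        cell_types=None if cell_types is None else np.asarray(cell_types),
        pinned=None if pinned is None else np.asarray(pinned),
        edges_all=edges_all,
    )


def _region_area(vor: Voronoi, point_index: int) -> float:
    region = vor.regions[vor.point_region[point_index]]
    if len(region) == 0 or -1 in region:
        return np.nan
    verts = vor.vertices[region]
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def voronoi_cell_areas(
    tri: Triangulation,
    domain: PeriodicDomain | None = None,
    *,
    ghost_points: np.ndarray | None = None,
    indices: Iterable[int] | None = None,
    margin: float | None = None,
) -> Mapping[int, float]:
    """Dual Voronoi areas (cell-width^2) keyed by node id.

    Interior areas are the exact dual Voronoi polygon areas of the periodic
    point set.  Cells on the open boundaries (the epithelial surface and the
    region below the pinned row) have unbounded dual regions; these are closed
    with ``ghost_points`` — a layer mirrored across the free surfaces, built
    by the caller (the simulator reflects each surface cell one cell width
    along the outward surface normal).  When no ghosts are supplied, a default
    closure reflects every unbounded-region point one cell width outward in
    ``y``, away from the point cloud's median.  Boundary areas are therefore
    convention-dependent; interior areas are exact.

    ``indices`` restricts the computation to the given positional indices.
    """
    if domain is None:
        domain = tri.domain
    pts = tri.points
    wanted = list(range(len(pts))) if indices is None else [int(i) for i in indices]
    ghosts = (
        np.empty((0, 2))
        if ghost_points is None or not len(ghost_points)
        else np.atleast_2d(np.asarray(ghost_points, float))
    )
    med = np.median(pts[:, 1])
    for attempt in range(3):
        aug, _ = _augmented_points(pts, domain.width, margin)
        if len(ghosts):
            gw = ghosts.copy()
            gw[:, 0] = np.mod(gw[:, 0], domain.width)
            gaug, _ = _augmented_points(gw, domain.width, margin)
            aug = np.concatenate([aug, gaug])
        vor = Voronoi(aug)
        areas: dict[int, float] = {}
        missing: list[int] = []
        for i in wanted:
            a = _region_area(vor, i)
            if np.isfinite(a) and a > 0:
                areas[int(tri.ids[i])] = a
            else:
                missing.append(i)
        if not missing:
            return areas
        # Close remaining open regions by mirroring the offenders one cell
        # width outward in y (away from the cloud's median).
        off = pts[missing]
        extra = off + np.column_stack(
            [np.zeros(len(off)), np.where(off[:, 1] >= med, 1.0, -1.0)]
        )
        ghosts = np.concatenate([ghosts, extra]) if len(ghosts) else extra
    raise MeshInternalError(
        f"Voronoi regions of nodes {missing[:5]} remain unbounded after ghost closure"
    )
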