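"""Forces and overdamped dynamics.

Cell-cell interactions are linear springs along the Delaunay edges,

    F_i = sum_j mu_ij (|r_ij| - s_ij) r_hat_ij ,

attractive when stretched beyond the rest length ``s`` and repulsive when
compressed.  The basement membrane is a piecewise-linear curve through the
midpoints of epithelial-stromal springs; it exerts a restoring force on each
epithelial cell proportional to the difference between the local discrete
curvature of that curve and a spatially varying spontaneous curvature.
Positions evolve by an overdamped forward Euler step, eta dr/dt = F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import CellType, PeriodicDomain, Triangulation

__all__ = [
    "SpringParams",
    "BMParams",
    "IntegratorParams",
    "MembraneCurve",
    "SpontaneousCurvatureField",
    "ZeroLengthSpringError",
    "CurvatureUndefinedError",
    "IntegrationError",
    "spring_forces",
    "spring_force_on_node",
    "membrane_curve",
    "discrete_curvature",
    "curve_curvatures",
    "basement_membrane_forces",
    "membrane_force_array",
    "advance_positions",
]


class ZeroLengthSpringError(ValueError):
    """Two connected cell centres coincide."""


class CurvatureUndefinedError(ValueError):
    """The membrane curve has too few points for a curvature estimate."""


class IntegrationError(RuntimeError):
    """A non-finite force reached the integrator."""


@dataclass(frozen=True)
class SpringParams:
    """Spring strengths per edge-type pair and the mature rest length.

    The baseline model uses a single strength mu=15 for every pair; the
    E-E/S-S ratio is varied in the stiffness experiments.  Rest length is 1
    cell width for mature springs; newborn daughter pairs override it while
    their connecting spring grows.
    """

    mu_EE: float = 15.0
    mu_ES: float = 15.0
    mu_SS: float = 15.0
    rest_length: float = 1.0

    def __post_init__(self) -> None:
        if min(self.mu_EE, self.mu_ES, self.mu_SS) <= 0 or self.rest_length <= 0:
            raise ValueError("spring strengths and rest length must be positive")

    def mu_table(self) -> np.ndarray:
        # indexed by type_i + type_j with EPITHELIAL=0, STROMAL=1
        return np.array([self.mu_EE, self.mu_ES, self.mu_SS])


@dataclass(frozen=True)
class BMParams:
    """Basement-membrane force strength and spontaneous-curvature levels.

    The discrete curvature is used unclamped: its spikes where midpoints
    crowd together are what make the membrane force resist a cell being
    squeezed radially out of the layer, the mechanism behind post-mitotic
    extrusion at the compressed base.  Numerical safety against a spike
    teleporting a cell is provided by the integrator's per-step
    displacement cap instead (see :class:`IntegratorParams`).
    """

    beta: float = 10.0
    kappa_c: float = 0.4          # 1/cell-width; base radius ~ 1/kappa_c
    f_base: float = 0.2           # crypt-base fraction of the dynamic crypt height

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass(frozen=True)
class IntegratorParams:
    """Overdamped forward-Euler settings.

    ``max_step`` optionally caps the displacement of any cell in one step
    (cell widths).  It is unlimited by default: the rare force spikes from
    near-coincident membrane midpoints eject an extruded cell clear of the
    layer within a single step, and that instantaneous ejection-and-removal
    is part of the model's extrusion behaviour — truncating it leaves
    half-ejected cells lingering inside the tissue and measurably distorts
    the death statistics.  A finite cap is available for experiments that
    need bounded displacements.
    """

    eta: float = 1.0              # drag coefficient
    dt: float = 0.0042            # hours
    max_step: float = float("inf")   # cell widths per step

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.dt <= 0:
            raise ValueError("eta and dt must be positive")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")


# ---------------------------------------------------------------------------
# Springs


def spring_forces(
    positions: np.ndarray,
    edges: np.ndarray,
    domain: PeriodicDomain,
    params: SpringParams,
    *,
    cell_types: np.ndarray | None = None,
    rest_lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Net spring force on every node (vectorised over edges).

    ``rest_lengths`` optionally overrides the rest length per edge (used for
    growing daughter-pair springs).
    """
    n = len(positions)
    forces = np.zeros((n, 2))
    if len(edges) == 0:
        return forces
    a, b = edges[:, 0], edges[:, 1]
    d = domain.delta(positions[b] - positions[a])
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r == 0.0):
        ai = a[r == 0.0][0]
        raise ZeroLengthSpringError(f"coincident neighbouring cell centres (node index {ai})")
    if cell_types is None:
        mu = np.full(len(edges), params.mu_EE)
    else:
        mu = params.mu_table()[cell_types[a] + cell_types[b]]
    s = np.full(len(edges), params.rest_length) if rest_lengths is None else rest_lengths
    f = (mu * (r - s) / r)[:, None] * d     # on node a, toward b when stretched
    forces[:, 0] = np.bincount(a, f[:, 0], n) - np.bincount(b, f[:, 0], n)
    forces[:, 1] = np.bincount(a, f[:, 1], n) - np.bincount(b, f[:, 1], n)
    return forces


def spring_force_on_node(node_id: int, tri: Triangulation, params: SpringParams) -> np.ndarray:
    """Spring force on a single node: sum_j mu_ij (|r_ij| - s) r_hat_ij."""
    i = tri.index_of(node_id)
    nbr = tri.neighbor_indices(i)
    if len(nbr) == 0:
        return np.zeros(2)
    d = tri.domain.delta(tri.points[nbr] - tri.points[i])
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r == 0.0):
        raise ZeroLengthSpringError(f"node {node_id} has a coincident neighbour")
    if tri.cell_types is None:
        mu = np.full(len(nbr), params.mu_EE)
    else:
        mu = params.mu_table()[tri.cell_types[i] + tri.cell_types[nbr]]
    return ((mu * (r - params.rest_length) / r)[:, None] * d).sum(axis=0)


# ---------------------------------------------------------------------------
# Basement-membrane curve and discrete curvature


@dataclass
class MembraneCurve:
    """Ordered midpoints of the epithelial-stromal springs.

    The traversal follows the epithelial layer with the stroma kept on the
    same side throughout (ascending x for the flat scenarios; collar ->
    wall -> base -> wall -> collar for the crypt).  ``points`` carries
    x-unwrapped coordinates so that chord lengths across the periodic seam
    are correct; ``closed`` marks a curve that wraps around the domain.
    """

    points: np.ndarray            # (M, 2), x unwrapped along the traversal
    epithelial_ids: np.ndarray    # (M,) id of the epithelial partner
    stromal_ids: np.ndarray       # (M,) id of the stromal partner
    closed: bool = True
    period: float | None = None   # x-extent added when wrapping (domain width)

    def __len__(self) -> int:
        return len(self.points)


def _order_epithelial_by_x(tri: Triangulation, epi_idx: np.ndarray) -> np.ndarray:
    return epi_idx[np.argsort(tri.points[epi_idx, 0], kind="stable")]


def membrane_curve(
    tri: Triangulation,
    *,
    epithelial_order: np.ndarray | None = None,
    closed: bool = True,
) -> MembraneCurve:
    """Build the basement-membrane curve from the current triangulation.

    One midpoint per epithelial-stromal edge.  Midpoints are grouped by
    epithelial cell in layer-traversal order and, within a cell, ordered by
    their projection onto the local traversal direction, which keeps the
    traversal orientation consistent between timesteps.

    ``epithelial_order`` gives the traversal as positional indices of the
    epithelial cells (the crypt scenario maintains this chain explicitly);
    by default epithelial cells are traversed in ascending x, the flat-layer
    convention.
    """
    if tri.cell_types is None:
        raise ValueError("triangulation carries no cell types")
    types = tri.cell_types
    a, b = tri.edges[:, 0], tri.edges[:, 1]
    es = types[a] + types[b] == 1        # one epithelial, one stromal
    if es.sum() < 3:
        raise CurvatureUndefinedError("fewer than 3 epithelial-stromal springs")
    ea, eb = a[es], b[es]
    epi = np.where(types[ea] == CellType.EPITHELIAL, ea, eb)
    stro = np.where(types[ea] == CellType.EPITHELIAL, eb, ea)

    if epithelial_order is None:
        order = _order_epithelial_by_x(tri, np.unique(epi))
    else:
        order = np.asarray(epithelial_order, dtype=int)

    pts = tri.points
    width = tri.domain.width
    npts = len(order)
    # Unwrap epithelial x along the traversal so chords never jump the seam.
    dx = np.diff(pts[order, 0])
    dx -= width * np.round(dx / width)
    ex = np.concatenate([[pts[order[0], 0]], pts[order[0], 0] + np.cumsum(dx)])
    ey = pts[order, 1]

    # local traversal direction at each chain position (clamped at the ends)
    ip = np.minimum(np.arange(npts) + 1, npts - 1)
    im = np.maximum(np.arange(npts) - 1, 0)
    tang = np.column_stack([ex[ip] - ex[im], ey[ip] - ey[im]])
    degenerate = (tang[:, 0] == 0.0) & (tang[:, 1] == 0.0)
    tang[degenerate] = (1.0, 0.0)

    # rank of each midpoint's epithelial cell along the traversal
    rank_of = np.full(tri.n_nodes, -1, dtype=int)
    rank_of[order] = np.arange(npts)
    rank = rank_of[epi]
    keep = rank >= 0                 # drop cells outside the supplied traversal
    epi, stro, rank = epi[keep], stro[keep], rank[keep]

    rel = tri.domain.delta(pts[stro] - pts[epi])
    mid = np.column_stack([ex[rank], ey[rank]]) + 0.5 * rel
    proj = np.einsum("ij,ij->i", rel, tang[rank])
    m_order = np.lexsort((proj, rank))

    return MembraneCurve(
        points=mid[m_order],
        epithelial_ids=tri.ids[epi[m_order]],
        stromal_ids=tri.ids[stro[m_order]],
        closed=closed,
        period=width if closed else None,
    )


def _nonuniform_central_diffs(p_prev, p_mid, p_next):
    """First/second coordinate derivatives w.r.t. chord arc length.

    Non-uniform central-difference stencil over three points; second-order
    accurate on smooth curves, exact reduction to the classical stencil when
    the two chords are equal.
    """
    h1 = np.linalg.norm(np.asarray(p_mid) - np.asarray(p_prev), axis=-1)
    h2 = np.linalg.norm(np.asarray(p_next) - np.asarray(p_mid), axis=-1)
    if np.any(h1 == 0) or np.any(h2 == 0):
        raise ZeroLengthSpringError("coincident consecutive membrane midpoints")
    h1 = h1[..., None] if np.ndim(h1) else h1
    h2 = h2[..., None] if np.ndim(h2) else h2
    denom = h1 * h2 * (h1 + h2)
    d1 = (h1**2 * np.asarray(p_next) + (h2**2 - h1**2) * np.asarray(p_mid)
          - h2**2 * np.asarray(p_prev)) / denom
    d2 = 2.0 * (h1 * np.asarray(p_next) - (h1 + h2) * np.asarray(p_mid)
                + h2 * np.asarray(p_prev)) / denom
    return d1, d2


def _signed_curvature(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    num = d1[..., 0] * d2[..., 1] - d1[..., 1] * d2[..., 0]
    return num / (d1[..., 0] ** 2 + d1[..., 1] ** 2) ** 1.5


def curve_curvatures(curve: MembraneCurve) -> np.ndarray:
    """Signed discrete curvature at every midpoint of the curve.

    kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2) with derivatives taken by
    central differences with respect to cumulative chord length.  With the
    stroma kept on the right of the traversal, kappa is positive where the
    curve bows into the stroma (a crypt-base valley) and negative where it
    bows into the lumen.  On a closed curve every point has both neighbours
    (the seam wraps with the x-period added); on an open curve the two
    endpoints get kappa = 0 by convention.
    """
    pts = curve.points
    m = len(pts)
    if m < 3:
        raise CurvatureUndefinedError("need at least 3 midpoints")

    # Distinct springs can share a midpoint (the membrane passes through one
    # geometric point twice); collapse exact duplicates and give every spring
    # at that point the same curvature.  A fully degenerate curve still
    # raises the zero-arc-length error.
    chord = np.hypot(*(np.diff(pts, axis=0).T))
    dup = np.concatenate([[False], chord < 1e-9])
    upts = pts[~dup]
    if len(upts) < 3:
        raise ZeroLengthSpringError("coincident consecutive membrane midpoints")
    src = np.cumsum(~dup) - 1

    if curve.closed:
        prev_pt = np.roll(upts, 1, axis=0).copy()
        next_pt = np.roll(upts, -1, axis=0).copy()
        span = curve.period if curve.period else 0.0
        prev_pt[0, 0] -= span
        next_pt[-1, 0] += span
        d1, d2 = _nonuniform_central_diffs(prev_pt, upts, next_pt)
        return _signed_curvature(d1, d2)[src]
    kappa = np.zeros(len(upts))
    d1, d2 = _nonuniform_central_diffs(upts[:-2], upts[1:-1], upts[2:])
    kappa[1:-1] = _signed_curvature(d1, d2)
    return kappa[src]


def discrete_curvature(curve: MembraneCurve, k: int) -> float:
    """Signed discrete curvature at interior midpoint ``k`` (1/cell-width)."""
    m = len(curve)
    if m < 3:
        raise CurvatureUndefinedError("need at least 3 midpoints")
    if not curve.closed and (k <= 0 or k >= m - 1):
        raise CurvatureUndefinedError(f"midpoint {k} has no two neighbours on the open curve")
    return float(curve_curvatures(curve)[k])


# ---------------------------------------------------------------------------
# Spontaneous curvature


@dataclass(frozen=True)
class SpontaneousCurvatureField:
    """kappa_0 as a function of epithelial cell position.

    ``kind='central-band'`` assigns kappa_c inside a central x-band covering
    ``band_fraction`` of the domain width (half the width for the basic flat
    scenario, 20% for the flat-to-crypt deformation) and zero outside.
    ``kind='crypt-base'`` assigns kappa_c to cells within the lowest
    ``f_base`` fraction of the current crypt height, zero elsewhere; the
    height is supplied dynamically each step.
    """

    kind: str = "central-band"
    kappa_c: float = 0.4
    band_fraction: float = 0.5
    f_base: float = 0.2
    width: float | None = None

    def evaluate(
        self,
        positions: np.ndarray,
        *,
        y_base: float | None = None,
        crypt_height: float | None = None,
    ) -> np.ndarray:
        positions = np.atleast_2d(positions)
        if self.kind == "central-band":
            if self.width is None:
                raise ValueError("central-band field needs the domain width")
            half_band = 0.5 * self.band_fraction * self.width
            inside = np.abs(positions[:, 0] - 0.5 * self.width) <= half_band
        elif self.kind == "crypt-base":
            if y_base is None or crypt_height is None or crypt_height <= 0:
                raise ValueError("crypt-base field needs y_base and a positive crypt height")
            inside = positions[:, 1] <= y_base + self.f_base * crypt_height
        else:
            raise ValueError(f"unknown spontaneous-curvature field kind {self.kind!r}")
        return np.where(inside, self.kappa_c, 0.0)


def spontaneous_curvature(
    position: np.ndarray,
    field: SpontaneousCurvatureField,
    *,
    y_base: float | None = None,
    crypt_height: float | None = None,
) -> float:
    """kappa_0 at a single cell position (total function; never raises on position)."""
    return float(
        field.evaluate(np.atleast_2d(position), y_base=y_base, crypt_height=crypt_height)[0]
    )


# ---------------------------------------------------------------------------
# Basement-membrane force


def basement_membrane_forces(
    curve: MembraneCurve,
    tri: Triangulation,
    bm: BMParams,
    kappa0_at_nodes: np.ndarray | dict,
) -> dict[int, np.ndarray]:
    """Membrane force on each epithelial node, keyed by node id.

    For every epithelial node i and stromal neighbour j, a contribution
    beta * (kappa_ij - kappa_0(r_i)) along the unit vector from j to i,
    where kappa_ij is the discrete curvature at the (i, j) spring midpoint.
    With the sign conventions of :func:`curve_curvatures` this restores a
    perturbed flat layer (kappa_0 = 0) and drives a base region with
    kappa_0 = kappa_c > 0 into a bulge of radius ~ 1/kappa_c toward the
    stroma.  Open-curve endpoints contribute zero force.

    ``kappa0_at_nodes`` maps node id -> kappa_0 evaluated at that cell.
    """
    if isinstance(kappa0_at_nodes, dict):
        k0 = np.array([kappa0_at_nodes[int(i)] for i in curve.epithelial_ids])
    else:
        k0 = np.asarray(kappa0_at_nodes)
    sorter = np.argsort(tri.ids)
    epi_idx = sorter[np.searchsorted(tri.ids, curve.epithelial_ids, sorter=sorter)]
    stro_idx = sorter[np.searchsorted(tri.ids, curve.stromal_ids, sorter=sorter)]
    arr = membrane_force_array(curve, tri.points, epi_idx, stro_idx, tri.domain, bm, k0)
    return {int(tri.ids[i]): arr[i] for i in np.unique(epi_idx)}


def membrane_force_array(
    curve: MembraneCurve,
    points: np.ndarray,
    epi_idx: np.ndarray,
    stro_idx: np.ndarray,
    domain: PeriodicDomain,
    bm: BMParams,
    kappa0_per_midpoint: np.ndarray,
) -> np.ndarray:
    """Vectorised membrane forces as an (N, 2) array over positional indices."""
    kappa = curve_curvatures(curve)
    d = domain.delta(points[epi_idx] - points[stro_idx])     # stromal -> epithelial
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r == 0.0):
        raise ZeroLengthSpringError("coincident epithelial/stromal centres")
    f = (bm.beta * (kappa - kappa0_per_midpoint) / r)[:, None] * d
    out = np.zeros_like(points)
    out[:, 0] = np.bincount(epi_idx, f[:, 0], len(points))
    out[:, 1] = np.bincount(epi_idx, f[:, 1], len(points))
    return out


# ---------------------------------------------------------------------------
# Integration


def advance_positions(
    positions: np.ndarray,
    forces: np.ndarray,
    pinned: np.ndarray,
    ip: IntegratorParams,
    domain: PeriodicDomain,
) -> np.ndarray:
    """One overdamped forward Euler step; pinned nodes never move.

    Displacements are capped at ``ip.max_step`` per step (direction
    preserved); the cap never engages in regular dynamics.
    """
    if not np.all(np.isfinite(forces)):
        bad = int(np.flatnonzero(~np.isfinite(forces).all(axis=1))[0])
        raise IntegrationError(f"non-finite force on node index {bad}")
    delta = (ip.dt / ip.eta) * forces
    if np.isfinite(ip.max_step):
        norm = np.hypot(delta[:, 0], delta[:, 1])
        over = norm > ip.max_step
        if np.any(over):
            delta[over] *= (ip.max_step / norm[over])[:, None]
    new = positions + delta
    new[pinned] = positions[pinned]
    new[:, 0] = np.mod(new[:, 0], domain.width)
    return new
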