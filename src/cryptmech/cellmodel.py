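"""Cell cycle, division, Wnt gating, anoikis and sloughing.

Proliferative epithelial cells run a simple stochastic cycle: G1 sampled
uniformly, then fixed S, G2 and M phases, for a total duration of 11-13 h.
With density-dependent inhibition enabled, a cell whose Voronoi area is below
the division threshold holds at the end of G1 (arrest) until it regains
enough room.  Division is polarity-directed: the daughters are placed along
the axis joining the parent's two nearest epithelial neighbours, and their
connecting spring matures over one hour.

Cell removal has two channels: anoikis — an epithelial cell that has lost
every stromal contact in the triangulation has detached from the basement
membrane and is removed — and random sloughing within a prescribed region
(the collar in the crypt), with a fixed per-hour hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh import CellNode, CellType, Triangulation

__all__ = [
    "CellCycleState",
    "WntField",
    "DeathRule",
    "PHASE_DURATIONS_FIXED",
    "EQUILIBRIUM_AREA",
    "sample_cycle_phases",
    "sample_g1_durations",
    "update_cell_cycle",
    "division_axis",
    "perform_division",
    "wnt_level",
    "is_proliferative",
    "detect_anoikis",
    "apply_random_sloughing",
]

#: Fixed phase durations in hours: S, G2, M.  G1 is sampled per cell.
PHASE_DURATIONS_FIXED = {"S": 5.0, "G2": 4.0, "M": 1.0}

G1_RANGE = (1.0, 3.0)   # forced by the fixed 10 h of S+G2+M and the 11-13 h total

#: Voronoi area of a cell in a hexagonally packed layer at unit rest length.
EQUILIBRIUM_AREA = np.sqrt(3.0) / 2.0

PHASES = ("G1", "S", "G2", "M")


@dataclass
class CellCycleState:
    """Phase bookkeeping for one proliferative cell."""

    g1: float
    s: float = PHASE_DURATIONS_FIXED["S"]
    g2: float = PHASE_DURATIONS_FIXED["G2"]
    m: float = PHASE_DURATIONS_FIXED["M"]
    age: float = 0.0          # hours since cycle start (arrest time excluded)
    arrested: bool = False

    @property
    def total(self) -> float:
        return self.g1 + self.s + self.g2 + self.m

    @property
    def phase(self) -> str:
        t = self.age
        for name, dur in zip(PHASES, (self.g1, self.s, self.g2, self.m)):
            if t < dur:
                return name
            t -= dur
        return "M"


@dataclass(frozen=True)
class WntField:
    """Linear Wnt gradient: 1 at the crypt base, 0 at the collar.

    Cells below ``threshold`` Wnt are terminally differentiated.  The crypt
    height is measured dynamically each step from the epithelial span.
    """

    threshold: float = 0.65
    y_base: float = 0.0
    crypt_height: float = 1.0


@dataclass(frozen=True)
class DeathRule:
    """Region-restricted random sloughing with per-hour probability ``p``."""

    p: float = 0.1
    top_fraction: float = 0.10       # crypt: top fraction of the crypt height
    outer_band: float = 0.25         # flat layer: outer fraction of width per side

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("sloughing probability must lie in [0, 1]")


def sample_g1_durations(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    return rng.uniform(*G1_RANGE, size=n)


def sample_cycle_phases(rng: np.random.Generator) -> CellCycleState:
    """Fresh cycle: G1 ~ U(1, 3) h, S = 5 h, G2 = 4 h, M = 1 h."""
    return CellCycleState(g1=float(sample_g1_durations(rng, 1)[0]))


def update_cell_cycle(
    state: CellCycleState,
    dt: float,
    voronoi_area: float | None,
    *,
    density_inhibition: bool = True,
    division_area: float = 0.8 * EQUILIBRIUM_AREA,
) -> tuple[CellCycleState, bool]:
    """Advance one timestep; return (new state, division-ready flag).

    At the G1/S boundary, a cell with area below ``division_area`` holds in
    G1 (arrested) and does not age until its area recovers.  Division-ready
    when M completes.
    """
    if (
        density_inhibition
        and state.age < state.g1
        and state.age + dt >= state.g1
        and voronoi_area is not None
        and voronoi_area < division_area
    ):
        # Hold at the G1/S boundary: age frozen, so the gate re-fires every
        # step until the area recovers (arrest only ever happens in G1).
        return replace(state, arrested=True), False
    new_age = state.age + dt
    return replace(state, age=new_age, arrested=False), new_age >= state.total


def division_axis(
    parent_index: int,
    tri: Triangulation,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Unit division axis: parallel to the vector joining the parent's two
    nearest epithelial neighbours (planar polarity).

    Falls back to a uniformly random axis when fewer than two epithelial
    neighbours exist; the flag in the return marks the fallback.
    """
    nbr = tri.neighbor_indices(parent_index)
    if tri.cell_types is not None and len(nbr):
        nbr = nbr[tri.cell_types[nbr] == CellType.EPITHELIAL]
    if len(nbr) >= 2:
        d = tri.domain.delta(tri.points[nbr] - tri.points[parent_index])
        dist = np.hypot(d[:, 0], d[:, 1])
        two = nbr[np.argsort(dist, kind="stable")[:2]]
        axis = tri.domain.delta(tri.points[two[1]] - tri.points[two[0]])
        n = np.hypot(axis[0], axis[1])
        if n > 0:
            return axis / n, False
    theta = rng.uniform(0.0, np.pi)
    return np.array([np.cos(theta), np.sin(theta)]), True


def perform_division(
    parent: CellNode,
    tri: Triangulation,
    rng: np.random.Generator,
    *,
    next_id: int,
    time: float,
    epsilon: float = 0.05,
) -> tuple[CellNode, CellNode, dict, bool]:
    """Replace a division-ready parent with two daughters.

    The daughters sit at +/- epsilon along the polarity axis, inherit the
    parent's type, and each samples a fresh cycle.  The returned growing-
    spring record carries the pair and the division time; its rest length
    grows linearly from s0 to the mature rest length over M phase (1 h).
    """
    axis, fallback = division_axis(tri.index_of(parent.id), tri, rng)
    p = parent.position
    d1 = CellNode(
        id=next_id,
        position=p - epsilon * axis,
        cell_type=parent.cell_type,
        cycle=sample_cycle_phases(rng),
        birth_time=time,
    )
    d2 = CellNode(
        id=next_id + 1,
        position=p + epsilon * axis,
        cell_type=parent.cell_type,
        cycle=sample_cycle_phases(rng),
        birth_time=time,
    )
    spring = {"pair": (d1.id, d2.id), "t_division": time}
    return d1, d2, spring, fallback


def wnt_level(y: float | np.ndarray, field: WntField) -> float | np.ndarray:
    """Wnt concentration at height y: clamp(1 - (y - y_base)/height, 0, 1)."""
    if field.crypt_height <= 0:
        raise ValueError("crypt height must be positive")
    return np.clip(1.0 - (np.asarray(y, float) - field.y_base) / field.crypt_height, 0.0, 1.0)


def is_proliferative(cell: CellNode, field: WntField | None) -> bool:
    """Wnt gate: epithelial and local Wnt >= threshold.

    A ``None`` field means no Wnt gating (the flat scenarios give every
    epithelial cell unlimited proliferative capacity).
    """
    if cell.cell_type != CellType.EPITHELIAL:
        return False
    if field is None:
        return True
    return bool(wnt_level(cell.position[1], field) >= field.threshold)


def detect_anoikis(tri: Triangulation) -> list[int]:
    """Ids of epithelial cells with no stromal neighbour within the cutoff.

    A cell has detached from the basement membrane when none of its
    retained (cutoff-filtered) Delaunay edges reaches a stromal cell — the
    same edge set that carries spring forces, so a cell dies exactly when
    nothing anchors it mechanically.
    """
    if tri.cell_types is None:
        raise ValueError("triangulation carries no cell types")
    types = tri.cell_types
    n = tri.n_nodes
    edges = tri.edges
    has_stromal = np.zeros(n, dtype=bool)
    if len(edges):
        a, b = edges[:, 0], edges[:, 1]
        es = types[a] + types[b] == 1
        epi_side = np.where(types[a[es]] == CellType.EPITHELIAL, a[es], b[es])
        has_stromal[epi_side] = True
    doomed = (types == CellType.EPITHELIAL) & ~has_stromal
    return [int(i) for i in tri.ids[doomed]]


def apply_random_sloughing(
    ids: np.ndarray,
    in_region: np.ndarray,
    rule: DeathRule,
    dt: float,
    rng: np.random.Generator,
) -> list[int]:
    """Bernoulli thinning: each cell in the region dies with probability
    p * dt this step, giving a per-hour hazard of p."""
    if rule.p == 0.0 or not np.any(in_region):
        return []
    u = rng.random(len(ids))
    dead = in_region & (u < rule.p * dt)
    return [int(i) for i in np.asarray(ids)[dead]]
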