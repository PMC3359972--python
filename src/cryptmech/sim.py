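"""Timestep loop, event logging and snapshots.

Within each step of size dt:

1. rebuild the periodic Delaunay triangulation (every ``k`` steps; always
   after the cell population changed);
2. remove anoikis cells (epithelial cells with no stromal contact — this
   reflects the movement of the previous step) and sample sloughing deaths;
3. evaluate Voronoi areas for cells at the G1/S gate and advance the cell
   cycles (Wnt-gated in the crypt, density arrest when enabled);
4. perform divisions (polarity-directed daughter placement);
5. evaluate spring + basement-membrane forces and take one overdamped
   forward Euler step (pinned cells never move, x re-wrapped);
6. log events and periodic snapshots.

All stochastic draws come from named substreams spawned from the master
seed (cycle sampling, division-axis fallback, sloughing), and cells are
processed in id order, so runs are bit-reproducible for a fixed seed and
toggling one stochastic feature does not shift the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cellmodel, mechanics, mesh
from .cellmodel import EQUILIBRIUM_AREA
from .mesh import CellType, PeriodicDomain, Triangulation
from .scenarios import ROW_PITCH, SimulationConfig, build_scenario

__all__ = ["EventLog", "SimulationState", "initialise", "step", "run_simulation"]


@dataclass
class EventLog:
    """Append-only event rows plus periodic state snapshots."""

    events: list = field(default_factory=list)       # (time, kind, cell_id, x, y, note)
    snapshots: list = field(default_factory=list)    # dicts of per-cell arrays

    def add(self, time: float, kind: str, cell_id: int, x: float, y: float, note: str = "") -> None:
        self.events.append((time, kind, cell_id, x, y, note))

    def snapshot(self, state: "SimulationState", areas: dict | None = None) -> None:
        self.snapshots.append(
            {
                "time": state.time,
                "id": state.ids.copy(),
                "x": state.pos[:, 0].copy(),
                "y": state.pos[:, 1].copy(),
                "cell_type": state.ctype.copy(),
                "pinned": state.pinned.copy(),
                "area": None
                if areas is None
                else np.array([areas.get(int(i), np.nan) for i in state.ids]),
            }
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.events, columns=["time_h", "event", "cell_id", "x", "y", "note"]
        )

    def snapshots_frame(self) -> pd.DataFrame:
        frames = []
        for snap in self.snapshots:
            n = len(snap["id"])
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": np.full(n, snap["time"]),
                        "cell_id": snap["id"],
                        "x": snap["x"],
                        "y": snap["y"],
                        "cell_type": snap["cell_type"],
                        "pinned": snap["pinned"],
                        "area": np.full(n, np.nan) if snap["area"] is None else snap["area"],
                    }
                )
            )
        if not frames:
            return pd.DataFrame(
                columns=["time_h", "cell_id", "x", "y", "cell_type", "pinned", "area"]
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class SimulationState:
    """Live cells as flat arrays (ids kept sorted ascending)."""

    time: float
    ids: np.ndarray          # (N,) int64, sorted
    pos: np.ndarray          # (N, 2)
    ctype: np.ndarray        # (N,) int8 CellType codes
    pinned: np.ndarray       # (N,) bool
    birth: np.ndarray        # (N,) hours
    g1: np.ndarray           # (N,) G1 duration; nan for non-cycling cells
    total: np.ndarray        # (N,) full cycle duration; nan for non-cycling
    age: np.ndarray          # (N,) hours progressed through the cycle
    arrested: np.ndarray     # (N,) bool
    chain: np.ndarray | None # epithelial ids in membrane-traversal order (crypt)
    growing: list            # [(id_a, id_b, t_division), ...] immature springs
    next_id: int
    rng_cycle: np.random.Generator
    rng_axis: np.random.Generator
    rng_slough: np.random.Generator
    log: EventLog
    tri: Triangulation | None = None
    step_count: int = 0
    n_divisions: int = 0
    n_anoikis: int = 0
    n_sloughed: int = 0
    initial_count: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    @property
    def epithelial_mask(self) -> np.ndarray:
        return self.ctype == CellType.EPITHELIAL

    def index_of(self, ids: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.ids, ids)

    def census_consistent(self) -> bool:
        return self.initial_count + 2 * self.n_divisions - self.n_divisions \
            - self.n_anoikis - self.n_sloughed == self.n_cells


def initialise(config: SimulationConfig) -> SimulationState:
    """Build the scenario and assign initial cycles.

    Construction is deterministic; the stochastic initial cycle stagger
    (each proliferative cell starts at a uniformly random point of its
    cycle, avoiding artificial division synchrony) comes from the seeded
    cycle stream.
    """
    nodes, config = build_scenario(config)
    n = len(nodes)
    ids = np.array([c.id for c in nodes], dtype=np.int64)
    order = np.argsort(ids)
    nodes = [nodes[i] for i in order]
    ids = ids[order]

    ss = np.random.SeedSequence(config.seed)
    s_cycle, s_axis, s_slough = ss.spawn(3)
    rng_cycle = np.random.default_rng(s_cycle)

    pos = np.array([c.position for c in nodes], dtype=float)
    ctype = np.array([int(c.cell_type) for c in nodes], dtype=np.int8)
    pinned = np.array([c.pinned for c in nodes], dtype=bool)
    epi = ctype == CellType.EPITHELIAL

    g1 = np.full(n, np.nan)
    total = np.full(n, np.nan)
    age = np.zeros(n)
    n_epi = int(epi.sum())
    g1[epi] = cellmodel.sample_g1_durations(rng_cycle, n_epi)
    total[epi] = g1[epi] + 10.0
    age[epi] = rng_cycle.random(n_epi) * total[epi]

    chain = None
    if config.scenario.kind == "crypt":
        chain = ids[epi]          # built in traversal order with ascending ids

    state = SimulationState(
        time=0.0,
        ids=ids,
        pos=pos,
        ctype=ctype,
        pinned=pinned,
        birth=np.zeros(n),
        g1=g1,
        total=total,
        age=age,
        arrested=np.zeros(n, dtype=bool),
        chain=chain,
        growing=[],
        next_id=int(ids.max()) + 1,
        rng_cycle=rng_cycle,
        rng_axis=np.random.default_rng(s_axis),
        rng_slough=np.random.default_rng(s_slough),
        log=EventLog(),
        initial_count=n,
    )
    return state


# ---------------------------------------------------------------------------
# step internals


def _rebuild(state: SimulationState, config: SimulationConfig) -> None:
    state.tri = mesh.build_periodic_triangulation(
        state.pos,
        config.domain(),
        config.cutoff,
        ids=state.ids,
        cell_types=state.ctype,
        pinned=state.pinned,
        margin=config.mesh_margin,
    )


def _remove_rows(state: SimulationState, idx: np.ndarray) -> None:
    keep = np.ones(state.n_cells, dtype=bool)
    keep[idx] = False
    removed_ids = state.ids[~keep]
    for name in ("ids", "ctype", "pinned", "birth", "g1", "total", "age", "arrested"):
        setattr(state, name, getattr(state, name)[keep])
    state.pos = state.pos[keep]
    if state.chain is not None:
        state.chain = state.chain[~np.isin(state.chain, removed_ids)]
    if state.growing:
        gone = set(int(i) for i in removed_ids)
        state.growing = [g for g in state.growing if not (g[0] in gone or g[1] in gone)]


def _append_rows(state: SimulationState, **cols) -> None:
    state.ids = np.concatenate([state.ids, cols["ids"]])
    state.pos = np.concatenate([state.pos, cols["pos"]])
    for name in ("ctype", "pinned", "birth", "g1", "total", "age", "arrested"):
        setattr(state, name, np.concatenate([getattr(state, name), cols[name]]))


def _crypt_metrics(state: SimulationState) -> tuple[float, float]:
    epi_y = state.pos[state.epithelial_mask, 1]
    y_base = float(epi_y.min())
    height = float(epi_y.max() - y_base)
    return y_base, max(height, 1e-9)


def _epithelial_order_indices(state: SimulationState) -> np.ndarray:
    """Positional indices of epithelial cells in membrane-traversal order."""
    if state.chain is not None:
        return state.index_of(state.chain)
    epi_idx = np.flatnonzero(state.epithelial_mask)
    return epi_idx[np.argsort(state.pos[epi_idx, 0], kind="stable")]


def _surface_ghosts(state: SimulationState, order_idx: np.ndarray) -> np.ndarray:
    """Ghost closure for Voronoi areas: epithelial cells reflected one cell
    width along the outward (lumen-side) surface normal, and the pinned row
    reflected one row pitch downward."""
    pts = state.pos[order_idx]
    fwd = np.roll(pts, -1, axis=0) - pts
    bwd = pts - np.roll(pts, 1, axis=0)
    if state.tri is not None:
        w = state.tri.domain.width
        for d in (fwd, bwd):
            d[:, 0] -= w * np.round(d[:, 0] / w)
    tang = fwd + bwd
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    tang /= norm[:, None]
    outward = np.column_stack([-tang[:, 1], tang[:, 0]])   # left of traversal = lumen
    top = pts + outward
    bottom = state.pos[state.pinned] + np.array([0.0, -ROW_PITCH])
    return np.concatenate([top, bottom])


def _areas(
    state: SimulationState,
    config: SimulationConfig,
    order_idx: np.ndarray,
    indices: np.ndarray | None,
) -> dict[int, float]:
    ghosts = _surface_ghosts(state, order_idx)
    return mesh.voronoi_cell_areas(
        state.tri,
        ghost_points=ghosts,
        indices=indices,
        margin=config.mesh_margin,
    )


def _growing_rest_lengths(
    state: SimulationState, config: SimulationConfig
) -> np.ndarray | None:
    """Per-edge rest lengths with immature daughter springs overridden."""
    tri = state.tri
    if not state.growing:
        return None
    s = np.full(len(tri.edges), config.spring.rest_length)
    edge_a = state.ids[tri.edges[:, 0]]
    edge_b = state.ids[tri.edges[:, 1]]
    s0 = config.newborn_rest_length
    mature = config.spring.rest_length
    for ida, idb, t0 in state.growing:
        lo, hi = (ida, idb) if ida < idb else (idb, ida)
        match = (edge_a == lo) & (edge_b == hi)
        frac = min((state.time - t0) / cellmodel.PHASE_DURATIONS_FIXED["M"], 1.0)
        s[match] = s0 + (mature - s0) * frac
    return s


def _perform_divisions(
    state: SimulationState, config: SimulationConfig, ready_ids: list[int]
) -> None:
    """Replace each division-ready parent with two daughters (id order)."""
    for parent_id in sorted(ready_ids):
        tri = state.tri
        i = int(state.index_of(np.array([parent_id]))[0])
        axis, fallback = cellmodel.division_axis(tri.index_of(parent_id), tri, state.rng_axis)
        p = state.pos[i].copy()
        eps = config.division_epsilon
        d_ids = np.array([state.next_id, state.next_id + 1], dtype=np.int64)
        d_pos = np.array([p - eps * axis, p + eps * axis])
        d_g1 = cellmodel.sample_g1_durations(state.rng_cycle, 2)
        state.next_id += 2

        if state.chain is not None:
            k = int(np.flatnonzero(state.chain == parent_id)[0])
            prev_id = state.chain[k - 1] if k > 0 else state.chain[-1]
            prev_pos = state.pos[state.index_of(np.array([prev_id]))[0]]
            d = tri.domain.delta(d_pos - prev_pos)
            first, second = (0, 1) if np.hypot(*d[0]) <= np.hypot(*d[1]) else (1, 0)
            state.chain = np.concatenate(
                [state.chain[:k], d_ids[[first, second]], state.chain[k + 1:]]
            )

        _remove_rows(state, np.array([i]))
        _append_rows(
            state,
            ids=d_ids,
            pos=d_pos,
            ctype=np.full(2, CellType.EPITHELIAL, dtype=np.int8),
            pinned=np.zeros(2, dtype=bool),
            birth=np.full(2, state.time),
            g1=d_g1,
            total=d_g1 + 10.0,
            age=np.zeros(2),
            arrested=np.zeros(2, dtype=bool),
        )
        state.growing.append((int(d_ids[0]), int(d_ids[1]), state.time))
        state.n_divisions += 1
        note = "fallback-axis" if fallback else ""
        state.log.add(state.time, "division", parent_id, p[0], p[1], note)
        # ids stay sorted: daughters get the largest ids and are appended.
        _rebuild(state, config)


def _process_deaths(
    state: SimulationState, config: SimulationConfig, domain: PeriodicDomain, dt: float
) -> None:
    """Anoikis detection (reflecting the previous movement) and sloughing."""
    doomed = cellmodel.detect_anoikis(state.tri)
    for cid in doomed:
        i = int(state.index_of(np.array([cid]))[0])
        state.log.add(state.time, "anoikis", cid, state.pos[i, 0], state.pos[i, 1])
    state.n_anoikis += len(doomed)

    sloughed: list[int] = []
    if config.sloughing and config.death.p > 0:
        epi = state.epithelial_mask
        if config.scenario.kind == "crypt":
            y_base, height = _crypt_metrics(state)
            in_region = epi & (
                state.pos[:, 1] >= y_base + (1.0 - config.death.top_fraction) * height
            )
        else:
            w = domain.width
            band = config.death.outer_band * w
            in_region = epi & ((state.pos[:, 0] < band) | (state.pos[:, 0] >= w - band))
        if doomed:
            in_region &= ~np.isin(state.ids, np.array(doomed, dtype=np.int64))
        sloughed = cellmodel.apply_random_sloughing(
            state.ids, in_region, config.death, dt, state.rng_slough
        )
        for cid in sloughed:
            i = int(state.index_of(np.array([cid]))[0])
            state.log.add(state.time, "sloughing", cid, state.pos[i, 0], state.pos[i, 1])
        state.n_sloughed += len(sloughed)

    removals = np.asarray(sorted(set(doomed) | set(sloughed)), dtype=np.int64)
    if len(removals):
        _remove_rows(state, state.index_of(removals))
        _rebuild(state, config)


def _process_cycles_and_divisions(
    state: SimulationState, config: SimulationConfig, dt: float
) -> None:
    """Wnt gating, density-arrest bookkeeping, cycle advance, divisions."""
    epi = state.epithelial_mask
    if config.scenario.kind == "crypt":
        y_base, height = _crypt_metrics(state)
        wnt = np.clip(1.0 - (state.pos[:, 1] - y_base) / height, 0.0, 1.0)
        prolif = epi & (wnt >= config.wnt_threshold)
    else:
        prolif = epi.copy()

    order_idx = _epithelial_order_indices(state)

    at_gate = prolif & (state.age < state.g1) & (state.age + dt >= state.g1)
    if config.density_inhibition:
        # Newly gated cells are checked at once; arrested cells re-check on a
        # coarse cadence (their area evolves slowly relative to the timestep).
        check = at_gate & ~state.arrested
        if state.step_count % config.arrest_check_interval == 0:
            check |= state.arrested & prolif
        if np.any(check):
            check_idx = np.flatnonzero(check)
            areas = _areas(state, config, order_idx, check_idx)
            a = np.array([areas[int(state.ids[i])] for i in check_idx])
            state.arrested[check_idx] = a < config.division_area
    else:
        state.arrested[:] = False
    advance = prolif & ~state.arrested
    state.age[advance] += dt
    ready = np.flatnonzero(prolif & ~state.arrested & (state.age >= state.total))

    if len(ready):
        _perform_divisions(state, config, [int(state.ids[i]) for i in ready])


def step(state: SimulationState, config: SimulationConfig) -> SimulationState:
    """Advance one timestep of model time (mutates and returns ``state``)."""
    dt = config.integrator.dt
    domain = config.domain()

    if state.tri is None or state.step_count % config.triangulation_interval == 0:
        _rebuild(state, config)
    else:
        # Connectivity is reused between rebuilds, but geometry is current.
        state.tri.points = state.pos

    # --- removals: anoikis (reflecting the previous movement), sloughing
    if config.deaths_before_divisions:
        _process_deaths(state, config, domain, dt)
        _process_cycles_and_divisions(state, config, dt)
    else:
        _process_cycles_and_divisions(state, config, dt)
        _process_deaths(state, config, domain, dt)
    # --- forces and movement
    state.growing = [
        g for g in state.growing
        if state.time - g[2] < cellmodel.PHASE_DURATIONS_FIXED["M"]
    ]
    rest = _growing_rest_lengths(state, config)
    tri = state.tri
    forces = mechanics.spring_forces(
        state.pos, tri.edges, domain, config.spring,
        cell_types=state.ctype, rest_lengths=rest,
    )
    order_idx = _epithelial_order_indices(state)
    if config.bm.beta > 0:
        curve = mechanics.membrane_curve(tri, epithelial_order=order_idx)
        if len(curve) >= 3:
            field = config.curvature_field()
            if config.scenario.kind == "crypt":
                y_base, height = _crypt_metrics(state)
                k0_nodes = field.evaluate(state.pos, y_base=y_base, crypt_height=height)
            else:
                k0_nodes = field.evaluate(state.pos)
            epi_m = state.index_of(curve.epithelial_ids)
            stro_m = state.index_of(curve.stromal_ids)
            forces += mechanics.membrane_force_array(
                curve, state.pos, epi_m, stro_m, domain, config.bm, k0_nodes[epi_m]
            )
    state.pos = mechanics.advance_positions(
        state.pos, forces, state.pinned, config.integrator, domain
    )

    state.time = (state.step_count + 1) * dt
    state.step_count += 1
    return state


def run_simulation(config: SimulationConfig) -> tuple[SimulationState, EventLog]:
    """Run ``config.duration`` cell hours; snapshots at the configured cadence."""
    state = initialise(config)
    n_steps = int(round(config.duration / config.integrator.dt))
    snap_every = max(int(round(config.snapshot_interval / config.integrator.dt)), 1)

    _rebuild(state, config)
    order_idx = _epithelial_order_indices(state)
    state.log.snapshot(state, _areas(state, config, order_idx, None))

    for k in range(n_steps):
        step(state, config)
        if (k + 1) % snap_every == 0:
            if state.tri is None:
                _rebuild(state, config)
            order_idx = _epithelial_order_indices(state)
            state.log.snapshot(state, _areas(state, config, order_idx, None))
        if not np.all(np.isfinite(state.pos)):
            raise mechanics.IntegrationError(
                f"non-finite position at step {state.step_count}"
            )
    return state, state.log
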