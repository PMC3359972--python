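"""Initial geometries and run configuration.

Three scenario builders reproduce the study set-ups:

* ``rectangular`` — a periodic block of cells (default 20 columns x 10 rows,
  200 cells) with a single proliferating epithelial row on top of a stromal
  bed, the bottom row pinned, and a non-zero spontaneous-curvature band over
  the central half of the width.
* ``deformation`` — a wider, deeper variant of the same block whose central
  spontaneous-curvature band covers 20% of the width, used to deform an
  initially flat monolayer into a test-tube crypt.
* ``crypt`` — a cross-section of a crypt: a 1D epithelial chain tracing
  collar -> wall -> semicircular base -> wall -> collar, embedded in a
  hexagonally packed stromal block, with a linear Wnt gradient, dynamic
  crypt-base curvature region and collar sloughing.

Cells are packed hexagonally (row pitch sqrt(3)/2, alternate rows offset by
half a cell width): that packing is the mechanical equilibrium of the
unit-rest-length spring network, so a freshly built block is force-balanced.
All builders are deterministic — no randomness at construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cellmodel import DeathRule, EQUILIBRIUM_AREA, WntField
from .mechanics import BMParams, IntegratorParams, SpontaneousCurvatureField, SpringParams
from .mesh import CellNode, CellType, ConfigurationError, PeriodicDomain

__all__ = [
    "ScenarioSpec",
    "SimulationConfig",
    "ROW_PITCH",
    "build_rectangular_scenario",
    "build_deformation_scenario",
    "build_crypt_scenario",
    "build_scenario",
]

#: Vertical spacing between rows of a hexagonally packed block of unit-width cells.
ROW_PITCH = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Geometry specification for one of the three scenarios."""

    kind: str = "rectangular"          # rectangular | deformation | crypt
    # flat scenarios
    columns: int = 20
    rows: int = 10
    # crypt scenario
    depth: float = 15.0                # crypt height, collar to base (cell widths)
    base_radius: float = 2.5
    domain_width: float = 14.0
    stromal_margin: float = 2.5        # stroma below the lowest epithelial point

    def __post_init__(self) -> None:
        if self.kind not in ("rectangular", "deformation", "crypt"):
            raise ConfigurationError(f"unknown scenario kind {self.kind!r}")


def _default_scenario() -> ScenarioSpec:
    return ScenarioSpec()


@dataclass
class SimulationConfig:
    """Everything a run needs: scenario, model parameters, toggles, seed.

    Defaults follow the baseline parameter set (mu = 15, eta = 1, s = 1,
    dt = 0.0042 h) with the package's calibration choices for the occluded
    magnitudes (beta, kappa_c, division-area threshold, Wnt threshold,
    sloughing hazard).  The config round-trips losslessly through YAML.
    """

    scenario: ScenarioSpec = field(default_factory=_default_scenario)
    spring: SpringParams = field(default_factory=SpringParams)
    bm: BMParams = field(default_factory=BMParams)
    integrator: IntegratorParams = field(default_factory=IntegratorParams)
    death: DeathRule = field(default_factory=DeathRule)
    wnt_threshold: float = 0.65
    division_area_fraction: float = 0.8      # A_div = fraction * A_eq
    density_inhibition: bool = True
    sloughing: bool = True
    duration: float = 60.0                   # cell hours
    equilibration: float = 0.0               # hours discarded by analyses
    seed: int = 0
    snapshot_interval: float = 1.0           # hours between state snapshots
    division_epsilon: float = 0.15           # daughter offset from parent
    newborn_rest_length: float = 0.3         # s0 of the growing daughter spring
    cutoff: float = 1.5                      # interaction cutoff (cell widths)
    mesh_margin: float = 2.0                 # periodic-image band for triangulation
    triangulation_interval: int = 3          # rebuild connectivity every k steps
    arrest_check_interval: int = 10          # steps between re-checks of arrested cells
    #: intra-step convention: detect deaths before divisions (the default) or
    #: after; steady-state statistics are insensitive to the order (tested).
    deaths_before_divisions: bool = True

    @property
    def division_area(self) -> float:
        return self.division_area_fraction * EQUILIBRIUM_AREA

    @classmethod
    def for_scenario(cls, kind: str, **overrides) -> "SimulationConfig":
        """Calibrated defaults per scenario.

        The flat scenarios use the class defaults (beta = 10, kappa_c band,
        division threshold 0.8 A_eq, outer-band sloughing at 0.1/h).  The
        crypt uses the homeostasis calibration: the smallest effective
        membrane force (beta = 5, so the collar corners are not flattened),
        a proliferative compartment covering the lower half of the crypt
        (Wnt threshold 0.5), division threshold 0.7 A_eq and a collar
        sloughing hazard of 0.05/h, which balance turnover at the default
        geometry.
        """
        cfg = cls(scenario=ScenarioSpec(kind=kind))
        if kind == "deformation":
            cfg.scenario = ScenarioSpec(kind="deformation", columns=30, rows=14)
        if kind == "crypt":
            cfg.bm = BMParams(beta=5.0, kappa_c=0.4)
            cfg.wnt_threshold = 0.5
            cfg.division_area_fraction = 0.7
            cfg.death = DeathRule(p=0.05)
        for key, val in overrides.items():
            setattr(cfg, key, val)
        return cfg

    # -- structured-text round trip -------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        parts = {
            "scenario": ScenarioSpec,
            "spring": SpringParams,
            "bm": BMParams,
            "integrator": IntegratorParams,
            "death": DeathRule,
        }
        for key, typ in parts.items():
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))

    # -- derived model pieces -------------------------------------------
    def domain(self) -> PeriodicDomain:
        if self.scenario.kind == "crypt":
            return PeriodicDomain(self.scenario.domain_width)
        return PeriodicDomain(float(self.scenario.columns))

    def curvature_field(self) -> SpontaneousCurvatureField:
        kind = self.scenario.kind
        if kind == "crypt":
            return SpontaneousCurvatureField(
                kind="crypt-base", kappa_c=self.bm.kappa_c, f_base=self.bm.f_base
            )
        fraction = 0.5 if kind == "rectangular" else 0.2
        return SpontaneousCurvatureField(
            kind="central-band",
            kappa_c=self.bm.kappa_c,
            band_fraction=fraction,
            width=self.domain().width,
        )

    def wnt_field(self, y_base: float, crypt_height: float) -> WntField | None:
        if self.scenario.kind != "crypt":
            return None              # flat layers: unlimited proliferative capacity
        return WntField(threshold=self.wnt_threshold, y_base=y_base, crypt_height=crypt_height)


# ---------------------------------------------------------------------------
# Builders


def _hex_block(columns: int, rows: int) -> np.ndarray:
    """Hexagonally packed ``columns x rows`` block; unit spacing within rows."""
    xs, ys = [], []
    for j in range(rows):
        xs.append(np.arange(columns, dtype=float) + 0.25 + 0.5 * (j % 2))
        ys.append(np.full(columns, j * ROW_PITCH))
    return np.column_stack([np.concatenate(xs), np.concatenate(ys)])


def _flat_nodes(columns: int, rows: int) -> list[CellNode]:
    pts = _hex_block(columns, rows)
    top = (rows - 1) * ROW_PITCH
    nodes = []
    for i, p in enumerate(pts):
        epithelial = np.isclose(p[1], top)
        nodes.append(
            CellNode(
                id=i,
                position=p.copy(),
                cell_type=CellType.EPITHELIAL if epithelial else CellType.STROMAL,
                pinned=bool(np.isclose(p[1], 0.0)),
            )
        )
    return nodes


def build_rectangular_scenario(
    spec: ScenarioSpec | None = None, config: SimulationConfig | None = None
) -> tuple[list[CellNode], SimulationConfig]:
    """Periodic block with a proliferating epithelial top row.

    Top row epithelial (no Wnt gating), everything else stromal, bottom row
    pinned; the central half of the width carries the non-zero spontaneous
    curvature.
    """
    spec = spec or ScenarioSpec(kind="rectangular")
    if spec.kind != "rectangular":
        raise ConfigurationError(f"expected a rectangular spec, got {spec.kind!r}")
    if spec.columns < 4 or spec.rows < 3:
        raise ConfigurationError("rectangular scenario needs >= 4 columns and >= 3 rows")
    config = config or SimulationConfig()
    config = dataclasses.replace(config, scenario=spec)
    return _flat_nodes(spec.columns, spec.rows), config


def build_deformation_scenario(
    spec: ScenarioSpec | None = None, config: SimulationConfig | None = None
) -> tuple[list[CellNode], SimulationConfig]:
    """Wide flat monolayer whose central 20%-of-width band carries kappa_c.

    The stromal bed is deep enough to contain the fully invaginated crypt
    (depth ~ width of the curvature band).
    """
    spec = spec or ScenarioSpec(kind="deformation", columns=30, rows=14)
    if spec.kind != "deformation":
        raise ConfigurationError(f"expected a deformation spec, got {spec.kind!r}")
    if spec.columns < 10:
        raise ConfigurationError("deformation scenario needs a sufficiently wide layer")
    if (spec.rows - 1) * ROW_PITCH < 0.2 * spec.columns:
        raise ConfigurationError(
            "stromal bed too shallow to contain the deformed crypt: "
            f"need (rows-1)*{ROW_PITCH:.3f} >= 0.2*columns"
        )
    config = config or SimulationConfig()
    config = dataclasses.replace(config, scenario=spec)
    return _flat_nodes(spec.columns, spec.rows), config


def _crypt_chain_points(spec: ScenarioSpec) -> np.ndarray:
    """Unit-spaced points tracing collar -> wall -> base arc -> wall -> collar."""
    W, H, r = spec.domain_width, spec.depth, spec.base_radius
    cx = 0.5 * W
    overhang = cx - r                     # collar length per side
    wall = H - r
    lengths = np.array([overhang, wall, np.pi * r, wall, overhang])
    total = lengths.sum()
    n = int(round(total))
    s_vals = np.arange(n) * (total / n)   # the final point wraps onto the first

    pts = np.empty((n, 2))
    bounds = np.concatenate([[0.0], np.cumsum(lengths)])
    for i, s in enumerate(s_vals):
        if s < bounds[1]:                 # left collar, walking right
            pts[i] = (s, H)
        elif s < bounds[2]:               # left wall, walking down
            pts[i] = (cx - r, H - (s - bounds[1]))
        elif s < bounds[3]:               # base arc, counterclockwise around the lumen
            phi = np.pi + (s - bounds[2]) / r     # angle from circle centre (cx, r)
            pts[i] = (cx + r * np.cos(phi), r + r * np.sin(phi))
        elif s < bounds[4]:               # right wall, walking up
            pts[i] = (cx + r, r + (s - bounds[3]))
        else:                             # right collar
            pts[i] = (cx + r + (s - bounds[4]), H)
    return pts


def _lumen_signed_distance(pts: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    """Signed distance to the lumen boundary (negative inside the lumen)."""
    W, r = spec.domain_width, spec.base_radius
    cx = 0.5 * W
    x, y = pts[:, 0], pts[:, 1]
    d_tube = np.abs(x - cx) - r                                 # vertical-wall part
    d_cap = np.hypot(x - cx, y - r) - r                         # base-cap part
    return np.where(y >= r, d_tube, d_cap)


def build_crypt_scenario(
    spec: ScenarioSpec | None = None, config: SimulationConfig | None = None
) -> tuple[list[CellNode], SimulationConfig]:
    """Cross-sectional crypt: epithelial chain in a stromal block.

    The epithelial cells are created in chain order (ids ascending along the
    collar -> wall -> base -> wall -> collar traversal); the simulator keeps
    that order as the membrane traversal.  Stromal cells fill the block
    outside the lumen at hexagonal packing; the bottom row is pinned.
    """
    spec = spec or ScenarioSpec(kind="crypt")
    if spec.kind != "crypt":
        raise ConfigurationError(f"expected a crypt spec, got {spec.kind!r}")
    W, H, r, m = spec.domain_width, spec.depth, spec.base_radius, spec.stromal_margin
    if H <= r:
        raise ConfigurationError("crypt depth must exceed the base radius")
    if W <= 2 * r + 2.0:
        raise ConfigurationError("domain width must exceed lumen width plus stromal margin")

    chain = _crypt_chain_points(spec)
    nodes = [
        CellNode(id=i, position=p.copy(), cell_type=CellType.EPITHELIAL)
        for i, p in enumerate(chain)
    ]

    # Stromal bed: hexagonal packing clipped away from the lumen and the
    # chain.  Clearances match the spring rest length (1 from the epithelial
    # chain, one row pitch below the collar) so the block starts unstressed.
    n_rows = int(np.floor((H - ROW_PITCH + m) / ROW_PITCH)) + 1
    grid = _hex_block(int(np.ceil(W)), n_rows)
    grid[:, 1] -= m                                  # lowest row sits margin below y=0
    grid = grid[grid[:, 0] < W - 1e-9]
    keep = (_lumen_signed_distance(grid, spec) >= 0.95) & (grid[:, 1] <= H - ROW_PITCH)
    grid = grid[keep]
    y_min = grid[:, 1].min()
    next_id = len(nodes)
    for p in grid:
        nodes.append(
            CellNode(
                id=next_id,
                position=p.copy(),
                cell_type=CellType.STROMAL,
                pinned=bool(np.isclose(p[1], y_min)),
            )
        )
        next_id += 1

    config = config or SimulationConfig()
    config = dataclasses.replace(config, scenario=spec)
    return nodes, config


def build_scenario(
    config: SimulationConfig,
) -> tuple[list[CellNode], SimulationConfig]:
    """Dispatch on ``config.scenario.kind``."""
    builders = {
        "rectangular": build_rectangular_scenario,
        "deformation": build_deformation_scenario,
        "crypt": build_crypt_scenario,
    }
    return builders[config.scenario.kind](config.scenario, config)
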