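"""Summary statistics from event logs and snapshots.

Arc-length coordinates along the epithelial layer, binned event
distributions, epithelial count series, per-cell migration tracks, and
dimensionalised Voronoi-area histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import CellType, ConfigurationError

__all__ = [
    "ArcLengthFrame",
    "BinnedDistribution",
    "arc_length_coordinates",
    "attach_arc_length",
    "bin_events",
    "membrane_profile",
    "cell_count_series",
    "migration_tracks",
    "area_histogram",
]

#: Conventional epithelial cell width used to dimensionalise areas.
DEFAULT_CELL_WIDTH_UM = 10.0


@dataclass
class ArcLengthFrame:
    """Signed arc length of each epithelial cell along the interpolated chain,
    measured from the chain's mid-length point (s = 0 at the layer centre)."""

    cell_ids: np.ndarray
    s: np.ndarray                 # signed arc length, cell widths
    total_length: float


@dataclass
class BinnedDistribution:
    edges: np.ndarray
    counts: np.ndarray            # mean count per bin over replicates
    replicates: int = 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def arc_length_coordinates(
    chain_positions: np.ndarray, cell_ids: np.ndarray | None = None
) -> ArcLengthFrame:
    """Piecewise-linear cumulative chord length along an ordered chain,
    re-centred so s = 0 falls at the chain's mid-length point."""
    pts = np.asarray(chain_positions, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need an ordered chain of at least 2 positions")
    seg = np.hypot(*(np.diff(pts, axis=0).T))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])
    s -= 0.5 * total
    if cell_ids is None:
        cell_ids = np.arange(len(pts))
    return ArcLengthFrame(cell_ids=np.asarray(cell_ids), s=s, total_length=total)


def attach_arc_length(
    events: pd.DataFrame,
    snapshots: pd.DataFrame,
    domain_width: float,
) -> pd.DataFrame:
    """Add an ``arc_length`` column to an event table (flat-layer convention).

    Each event is assigned the signed arc length of the nearest epithelial
    cell centre along the chain (ordered by x, centred at the chain's
    mid-length point) in the snapshot closest in time to the event.
    """
    events = events.copy()
    s_vals = np.full(len(events), np.nan)
    times = np.sort(snapshots["time_h"].unique())
    epi = snapshots[snapshots["cell_type"] == int(CellType.EPITHELIAL)]
    for t, group in events.groupby(
        times[np.searchsorted(times, events["time_h"], side="right") - 1]
    ):
        snap = epi[epi["time_h"] == t].sort_values("x")
        chain = snap[["x", "y"]].to_numpy()
        if len(chain) < 2:
            continue
        frame = arc_length_coordinates(chain)
        ex = group["x"].to_numpy()[:, None] - chain[:, 0][None, :]
        ex -= domain_width * np.round(ex / domain_width)
        ey = group["y"].to_numpy()[:, None] - chain[:, 1][None, :]
        nearest = np.argmin(np.hypot(ex, ey), axis=1)
        s_vals[events.index.get_indexer(group.index)] = frame.s[nearest]
    events["arc_length"] = s_vals
    return events


def bin_events(
    events: pd.DataFrame | list[pd.DataFrame],
    *,
    coordinate: str = "arc_length",
    bin_width: float = 1.0,
    extent: tuple[float, float] | None = None,
    kind: str | None = None,
) -> BinnedDistribution:
    """Histogram event positions; multiple logs are averaged per replicate.

    ``coordinate`` selects the binning axis: a column name (``"x"``/``"y"``,
    the crypt convention bins along y) or ``"arc_length"`` when the events
    carry a precomputed ``arc_length`` column (flat-layer convention).
    Bin edges are aligned on multiples of ``bin_width`` around zero.  The
    outermost bins can clip the tail of the layer and are best read with
    care.  An empty range yields an empty distribution.
    """
    frames = [events] if isinstance(events, pd.DataFrame) else list(events)
    if kind is not None:
        frames = [f[f["event"] == kind] for f in frames]
    values = [f[coordinate].to_numpy(dtype=float) for f in frames]
    allv = np.concatenate(values) if values else np.empty(0)
    if extent is None:
        if len(allv) == 0:
            return BinnedDistribution(np.array([0.0, bin_width]), np.zeros(1), len(frames))
        extent = (allv.min(), allv.max())
    # bins centred on multiples of the bin width (a central bin sits at 0)
    lo = (np.floor(extent[0] / bin_width + 0.5) - 0.5) * bin_width
    hi = (np.ceil(extent[1] / bin_width - 0.5) + 0.5) * bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for v in values:
        counts += np.histogram(v, bins=edges)[0]
    return BinnedDistribution(edges, counts / max(len(frames), 1), len(frames))


def membrane_profile(
    curve, kappa0_per_midpoint: np.ndarray | None = None
) -> pd.DataFrame:
    """Tabulate a basement-membrane curve: midpoint coordinates, the spring
    pair, the local discrete curvature and (optionally) the spontaneous
    curvature — the per-snapshot membrane profile used for depth/curvature
    plots."""
    from .mechanics import curve_curvatures

    frame = pd.DataFrame(
        {
            "x": curve.points[:, 0],
            "y": curve.points[:, 1],
            "epithelial_id": curve.epithelial_ids,
            "stromal_id": curve.stromal_ids,
            "kappa": curve_curvatures(curve),
        }
    )
    if kappa0_per_midpoint is not None:
        frame["kappa0"] = np.asarray(kappa0_per_midpoint, dtype=float)
    return frame


def cell_count_series(
    snapshots: pd.DataFrame, *, discard_before: float = 0.0
) -> pd.Series:
    """Epithelial cell count per snapshot time, optionally discarding an
    equilibration window."""
    epi = snapshots[snapshots["cell_type"] == int(CellType.EPITHELIAL)]
    series = epi.groupby("time_h")["cell_id"].count()
    return series[series.index >= discard_before]


def migration_tracks(
    snapshots: pd.DataFrame, cell_ids: list[int] | np.ndarray
) -> dict[int, pd.DataFrame]:
    """(t, x, y) table per requested cell, from first to last appearance."""
    known = set(snapshots["cell_id"].unique())
    out: dict[int, pd.DataFrame] = {}
    for cid in cell_ids:
        if cid not in known:
            raise KeyError(f"cell id {cid} never appears in the snapshots")
        rows = snapshots[snapshots["cell_id"] == cid]
        out[int(cid)] = rows[["time_h", "x", "y"]].reset_index(drop=True)
    return out


def area_histogram(
    areas: np.ndarray,
    cell_width_um: float = DEFAULT_CELL_WIDTH_UM,
    *,
    bin_width_um2: float = 10.0,
) -> BinnedDistribution:
    """Dimensionalised cell-area histogram as proportions of the population.

    Model areas (cell-width^2) are scaled by ``cell_width_um**2`` to um^2 and
    the frequency is averaged over the total cell number, so the counts are
    proportions summing to 1.
    """
    if cell_width_um <= 0:
        raise ConfigurationError("cell width must be positive")
    a = np.asarray(areas, dtype=float) * cell_width_um**2
    a = a[np.isfinite(a)]
    if len(a) == 0:
        return BinnedDistribution(np.array([0.0, bin_width_um2]), np.zeros(1))
    hi = np.ceil(a.max() / bin_width_um2) * bin_width_um2
    edges = np.arange(0.0, hi + 0.5 * bin_width_um2, bin_width_um2)
    counts = np.histogram(a, bins=edges)[0].astype(float)
    return BinnedDistribution(edges, counts / counts.sum())
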