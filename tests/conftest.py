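import numpy as np
import pytest

import cryptmech as cm
from cryptmech.scenarios import ROW_PITCH, _hex_block


@pytest.fixture
def hex_lattice_tri():
    """10x9 hexagonally packed periodic block at unit spacing."""
    pts = _hex_block(10, 9)
    dom = cm.PeriodicDomain(10.0)
    tri = cm.build_periodic_triangulation(pts, dom, 1.5)
    return pts, dom, tri


@pytest.fixture
def small_rect_config():
    """A small, fast rectangular scenario used by the loop tests."""
    cfg = cm.SimulationConfig(scenario=cm.ScenarioSpec(kind="rectangular", columns=10, rows=6))
    cfg.duration = 2.0
    return cfg


def circle_curve(radius: float, n: int) -> cm.MembraneCurve:
    """An open membrane curve sampled uniformly from a circle, traversed
    counterclockwise (the 'stroma' side is the outside)."""
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = radius * np.column_stack([np.cos(th), np.sin(th)])
    return cm.MembraneCurve(
        points=pts,
        epithelial_ids=np.arange(len(pts)),
        stromal_ids=np.arange(len(pts)) + 1000,
        closed=False,
        period=None,
    )
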