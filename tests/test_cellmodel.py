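"""Cell cycle, division geometry, Wnt gating, anoikis and sloughing."""

import numpy as np
import pytest

import cryptmech as cm
from cryptmech.cellmodel import (
    apply_random_sloughing,
    division_axis,
    sample_g1_durations,
    update_cell_cycle,
)
from cryptmech.mesh import CellType


class TestCycleSampling:
    def test_total_duration_bounds_and_fixed_phases(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            st = cm.sample_cycle_phases(rng)
            assert 11.0 <= st.total <= 13.0
            assert st.s == 5.0 and st.g2 == 4.0 and st.m == 1.0
            assert st.phase == "G1" and st.age == 0.0

    def test_g1_mean_matches_uniform_1_3(self):
        rng = np.random.default_rng(1)
        g1 = sample_g1_durations(rng, 10_000)
        assert g1.mean() == pytest.approx(2.0, abs=0.02)
        assert g1.min() >= 1.0 and g1.max() <= 3.0


class TestCycleUpdate:
    def test_arrest_below_division_area(self):
        st = cm.CellCycleState(g1=2.0, age=1.999)
        new, ready = update_cell_cycle(st, 0.01, 0.5, division_area=0.7)
        assert new.arrested and not ready
        assert new.age == st.age            # held in G1
        assert new.phase == "G1"

    def test_release_when_area_recovers(self):
        st = cm.CellCycleState(g1=2.0, age=1.999, arrested=True)
        new, ready = update_cell_cycle(st, 0.01, 0.9, division_area=0.7)
        assert not new.arrested and not ready
        assert new.age > 2.0                # progressed into S

    def test_division_ready_after_all_phases(self):
        st = cm.CellCycleState(g1=1.5, age=12.49)
        new, ready = update_cell_cycle(st, 0.02, 1.0)
        assert ready

    def test_no_density_inhibition_ignores_area(self):
        st = cm.CellCycleState(g1=2.0, age=1.999)
        new, ready = update_cell_cycle(st, 0.01, 0.1, density_inhibition=False)
        assert not new.arrested


class TestDivision:
    @staticmethod
    def _parent_tri():
        # parent (id 0) flanked by epithelial neighbours along x, stroma below
        pts = np.array([
            [5.0, 1.0],     # parent
            [4.0, 1.05],    # epithelial
            [6.0, 0.95],    # epithelial
            [4.5, 0.0],     # stromal
            [5.5, 0.0],     # stromal
        ])
        types = np.array([0, 0, 0, 1, 1], dtype=np.int8)
        return cm.build_periodic_triangulation(
            pts, cm.PeriodicDomain(50.0), cutoff=1.6, cell_types=types
        )

    def test_axis_parallel_to_nearest_epithelial_neighbours(self):
        tri = self._parent_tri()
        rng = np.random.default_rng(0)
        axis, fallback = division_axis(0, tri, rng)
        assert not fallback
        expected = np.array([2.0, -0.1])
        expected /= np.linalg.norm(expected)
        assert min(np.linalg.norm(axis - expected), np.linalg.norm(axis + expected)) < 1e-9

    def test_daughters_midpoint_is_parent(self):
        tri = self._parent_tri()
        rng = np.random.default_rng(0)
        parent = cm.CellNode(id=0, position=np.array([5.0, 1.0]),
                             cycle=cm.sample_cycle_phases(rng))
        d1, d2, spring, fallback = cm.perform_division(
            parent, tri, rng, next_id=10, time=3.0
        )
        assert np.allclose(0.5 * (d1.position + d2.position), parent.position)
        assert d1.cell_type == d2.cell_type == CellType.EPITHELIAL
        assert spring["pair"] == (10, 11)
        assert 11.0 <= d1.cycle.total <= 13.0

    def test_fallback_axis_with_isolated_parent(self):
        pts = np.array([[5.0, 1.0], [4.6, 0.0], [5.4, 0.0], [5.0, -1.0]])
        types = np.array([0, 1, 1, 1], dtype=np.int8)
        tri = cm.build_periodic_triangulation(
            pts, cm.PeriodicDomain(50.0), cutoff=1.5, cell_types=types
        )
        axis, fallback = division_axis(0, tri, np.random.default_rng(5))
        assert fallback
        assert np.isclose(np.linalg.norm(axis), 1.0)

    def test_newborn_spring_matures_to_unit_rest_length(self):
        """The daughter-pair rest length reaches s = 1 at the end of M phase."""
        s0, mature = 0.1, 1.0
        for t in (0.0, 0.5, 1.0):
            s = s0 + (mature - s0) * min(t / 1.0, 1.0)
            assert s0 <= s <= mature
        assert s == mature


class TestWnt:
    def test_linear_gradient_levels(self):
        field = cm.WntField(threshold=0.65, y_base=0.0, crypt_height=15.0)
        assert cm.wnt_level(0.0, field) == 1.0
        assert cm.wnt_level(15.0, field) == 0.0
        assert cm.wnt_level(7.5, field) == 0.5
        assert cm.wnt_level(20.0, field) == 0.0      # clamped above the collar

    def test_proliferative_gate(self):
        field = cm.WntField(threshold=0.65, y_base=0.0, crypt_height=10.0)
        low = cm.CellNode(id=0, position=np.array([0.0, 1.0]))
        high = cm.CellNode(id=1, position=np.array([0.0, 9.0]))
        stromal = cm.CellNode(id=2, position=np.array([0.0, 1.0]),
                              cell_type=CellType.STROMAL)
        assert cm.is_proliferative(low, field)
        assert not cm.is_proliferative(high, field)
        assert not cm.is_proliferative(stromal, field)
        assert cm.is_proliferative(high, None)        # flat layers: no gating


class TestAnoikis:
    def test_detached_epithelial_removed_attached_retained(self):
        # cell 0 has only epithelial contacts; cell 1 touches stroma
        pts = np.array([
            [5.0, 2.2],     # epithelial, pushed out of the layer
            [4.5, 1.2],     # epithelial, in the layer
            [5.5, 1.2],     # epithelial, in the layer
            [4.2, 0.1],     # stromal
            [5.8, 0.1],     # stromal
        ])
        types = np.array([0, 0, 0, 1, 1], dtype=np.int8)
        tri = cm.build_periodic_triangulation(
            pts, cm.PeriodicDomain(50.0), cutoff=1.5, cell_types=types
        )
        assert cm.detect_anoikis(tri) == [0]

    def test_stromal_cells_never_candidates(self):
        pts = np.array([[5.0, 0.0], [6.0, 0.0], [5.5, 0.9]])
        types = np.array([1, 1, 1], dtype=np.int8)
        tri = cm.build_periodic_triangulation(
            pts, cm.PeriodicDomain(50.0), cutoff=1.5, cell_types=types
        )
        assert cm.detect_anoikis(tri) == []


class TestSloughing:
    def test_zero_probability_never_kills(self):
        rng = np.random.default_rng(0)
        ids = np.arange(100)
        region = np.ones(100, dtype=bool)
        rule = cm.DeathRule(p=0.0)
        assert apply_random_sloughing(ids, region, rule, 0.0042, rng) == []

    def test_outside_region_unaffected(self):
        rng = np.random.default_rng(0)
        ids = np.arange(1000)
        region = np.zeros(1000, dtype=bool)
        rule = cm.DeathRule(p=1.0)
        for _ in range(50):
            assert apply_random_sloughing(ids, region, rule, 0.0042, rng) == []

    def test_per_hour_hazard_matches_p(self):
        """Empirical per-hour death fraction over ~10^4 cell-hours ~ p."""
        rng = np.random.default_rng(42)
        rule = cm.DeathRule(p=0.1)
        dt = 0.0042
        steps_per_hour = int(round(1.0 / dt))
        n_cells, n_hours = 100, 100
        deaths = 0
        for _ in range(n_hours):
            alive = np.ones(n_cells, dtype=bool)
            for _ in range(steps_per_hour):
                ids = np.flatnonzero(alive)
                dead = apply_random_sloughing(
                    ids, np.ones(len(ids), dtype=bool), rule, dt, rng
                )
                alive[dead] = False
            deaths += n_cells - alive.sum()
        rate = deaths / (n_cells * n_hours)
        # per-hour hazard p gives death fraction 1 - (1 - p dt)^(1/dt) ~ 9.5%
        assert rate == pytest.approx(0.095, abs=0.01)
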