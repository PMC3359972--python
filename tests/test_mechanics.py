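"""Spring law, membrane curve, discrete curvature and the Euler step."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cryptmech as cm
from cryptmech.mechanics import (
    CurvatureUndefinedError,
    IntegrationError,
    ZeroLengthSpringError,
    curve_curvatures,
    membrane_force_array,
)
from conftest import circle_curve


def _two_node_tri(distance, width=100.0, types=(0, 0)):
    pts = np.array([[50.0, 0.0], [50.0 + distance, 0.0], [50.5, 50.0]])
    tri = cm.build_periodic_triangulation(
        pts, cm.PeriodicDomain(width), cutoff=np.inf,
        cell_types=np.array([types[0], types[1], 1]),
    )
    return tri


class TestSpringForce:
    def test_zero_at_rest_length(self):
        tri = _two_node_tri(1.0)
        f = cm.spring_force_on_node(0, tri, cm.SpringParams())
        # only the far node contributes; subtract its pull to isolate the pair
        pair = f - cm.spring_force_on_node(0, tri, cm.SpringParams())
        assert np.allclose(pair, 0.0)

    def test_stretched_pair_attracts_with_linear_law(self):
        pts = np.array([[50.0, 0.0], [51.5, 0.0], [50.75, 40.0]])
        tri = cm.build_periodic_triangulation(pts, cm.PeriodicDomain(100.0), cutoff=2.0)
        f = cm.spring_force_on_node(0, tri, cm.SpringParams())
        # neighbour 2 is beyond the cutoff; only the stretched pair acts
        assert f[0] == pytest.approx(15.0 * 0.5, rel=1e-12)   # mu (r - s) toward +x
        assert f[1] == pytest.approx(0.0, abs=1e-12)

    def test_hexagon_centre_balances(self):
        th = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts = np.vstack([[50.0, 0.0], np.column_stack([50 + np.cos(th), np.sin(th)])])
        tri = cm.build_periodic_triangulation(pts, cm.PeriodicDomain(200.0), cutoff=1.2)
        f = cm.spring_force_on_node(0, tri, cm.SpringParams())
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_compressed_pair_repels(self):
        pts = np.array([[50.0, 0.0], [50.5, 0.0], [50.25, 30.0]])
        tri = cm.build_periodic_triangulation(pts, cm.PeriodicDomain(100.0), cutoff=1.0)
        f = cm.spring_force_on_node(0, tri, cm.SpringParams())
        assert f[0] < 0          # pushed away from the too-close neighbour

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_newtons_third_law_totals_zero(self, seed):
        """Sum of spring forces over a periodic domain vanishes."""
        rng = np.random.default_rng(seed)
        pts = rng.random((30, 2)) * np.array([12.0, 6.0])
        dom = cm.PeriodicDomain(12.0)
        tri = cm.build_periodic_triangulation(pts, dom, cutoff=1.5)
        types = rng.integers(0, 2, 30).astype(np.int8)
        f = cm.spring_forces(pts, tri.edges, dom, cm.SpringParams(), cell_types=types)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)

    def test_coincident_neighbours_raise(self):
        pts = np.array([[50.0, 0.0], [50.0, 0.0], [50.5, 0.8]])
        dom = cm.PeriodicDomain(100.0)
        edges = np.array([[0, 1], [0, 2]])
        with pytest.raises(ZeroLengthSpringError):
            cm.spring_forces(pts, edges, dom, cm.SpringParams())


class TestMembraneCurve:
    @staticmethod
    def _flat_bilayer(n=8, width=8.0):
        # offset rows (hexagonal pitch), the packing the scenarios use
        top = np.column_stack([np.arange(n) + 0.5, np.ones(n)])
        bot = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        pts = np.vstack([top, bot])
        types = np.array([0] * n + [1] * n, dtype=np.int8)
        return cm.build_periodic_triangulation(
            pts, cm.PeriodicDomain(width), cutoff=1.5, cell_types=types
        )

    def test_flat_bilayer_midpoints_collinear(self):
        tri = self._flat_bilayer()
        curve = cm.membrane_curve(tri)
        assert np.allclose(curve.points[:, 1], 0.5)

    def test_one_midpoint_per_epithelial_stromal_edge(self):
        tri = self._flat_bilayer()
        curve = cm.membrane_curve(tri)
        types = tri.cell_types
        n_es = sum(
            1 for a, b in tri.edges if types[a] + types[b] == 1
        )
        assert len(curve) == n_es

    def test_traversal_independent_of_insertion_order(self):
        tri = self._flat_bilayer()
        curve = cm.membrane_curve(tri)
        # rebuild with the node list reversed: geometry identical
        n = tri.n_nodes
        perm = np.arange(n)[::-1]
        tri2 = cm.build_periodic_triangulation(
            tri.points[perm],
            tri.domain,
            cutoff=1.5,
            cell_types=tri.cell_types[perm],
        )
        curve2 = cm.membrane_curve(tri2)
        assert np.allclose(curve.points, curve2.points)

    def test_too_few_midpoints_raise(self):
        pts = np.array([[5.0, 1.0], [5.0, 0.0], [6.0, 0.5], [7.0, 2.0]])
        types = np.array([0, 1, 1, 1], dtype=np.int8)
        tri = cm.build_periodic_triangulation(
            pts, cm.PeriodicDomain(50.0), cutoff=1.3, cell_types=types
        )
        with pytest.raises(CurvatureUndefinedError):
            cm.membrane_curve(tri)


class TestDiscreteCurvature:
    def test_collinear_points_zero(self):
        curve = cm.MembraneCurve(
            points=np.array([[0.0, 0.0], [1.0, 0.0], [2.5, 0.0], [4.0, 0.0]]),
            epithelial_ids=np.arange(4),
            stromal_ids=np.arange(4) + 10,
            closed=False,
        )
        assert cm.discrete_curvature(curve, 1) == 0.0
        assert cm.discrete_curvature(curve, 2) == 0.0

    @pytest.mark.parametrize("radius", [1.0, 2.0, 5.0])
    def test_circle_oracle_refinement(self, radius):
        """|kappa - 1/R| shrinks under refinement, at second order."""
        errors = []
        for n in (16, 32, 64):
            curve = circle_curve(radius, n)
            kappa = curve_curvatures(curve)[1:-1]
            errors.append(np.abs(np.abs(kappa) - 1.0 / radius).mean())
        assert errors[0] > errors[1] > errors[2]
        assert errors[1] / errors[2] > 3.0       # ~O(theta^2) convergence
        assert errors[2] < 0.01 / radius

    def test_orientation_flip_negates_kappa(self):
        curve = circle_curve(2.0, 24)
        flipped = cm.MembraneCurve(
            points=curve.points[::-1].copy(),
            epithelial_ids=curve.epithelial_ids[::-1].copy(),
            stromal_ids=curve.stromal_ids[::-1].copy(),
            closed=False,
        )
        k1 = curve_curvatures(curve)[1:-1]
        k2 = curve_curvatures(flipped)[1:-1]
        assert np.allclose(k1, -k2[::-1])

    def test_nonuniform_spacing_circle(self):
        rng = np.random.default_rng(3)
        th = np.sort(rng.uniform(0, 2 * np.pi, 80))
        pts = 2.0 * np.column_stack([np.cos(th), np.sin(th)])
        curve = cm.MembraneCurve(
            points=pts, epithelial_ids=np.arange(80), stromal_ids=np.arange(80) + 100,
            closed=False,
        )
        kappa = curve_curvatures(curve)[1:-1]
        assert np.abs(np.abs(kappa) - 0.5).mean() < 0.05

    def test_endpoints_undefined_on_open_curve(self):
        curve = circle_curve(1.0, 10)
        with pytest.raises(CurvatureUndefinedError):
            cm.discrete_curvature(curve, 0)

    def test_coincident_midpoints_raise(self):
        curve = cm.MembraneCurve(
            points=np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]),
            epithelial_ids=np.arange(3),
            stromal_ids=np.arange(3) + 10,
            closed=False,
        )
        with pytest.raises(ZeroLengthSpringError):
            curve_curvatures(curve)


class TestSpontaneousCurvature:
    def test_central_band(self):
        field = cm.SpontaneousCurvatureField(
            kind="central-band", kappa_c=0.4, band_fraction=0.5, width=20.0
        )
        assert cm.spontaneous_curvature(np.array([10.0, 0.0]), field) == 0.4
        assert cm.spontaneous_curvature(np.array([2.0, 0.0]), field) == 0.0
        assert cm.spontaneous_curvature(np.array([18.5, 3.0]), field) == 0.0

    def test_crypt_base_region(self):
        field = cm.SpontaneousCurvatureField(kind="crypt-base", kappa_c=0.4, f_base=0.2)
        kw = dict(y_base=0.0, crypt_height=15.0)
        assert cm.spontaneous_curvature(np.array([5.0, 1.0]), field, **kw) == 0.4
        assert cm.spontaneous_curvature(np.array([5.0, 3.1]), field, **kw) == 0.0
        assert cm.spontaneous_curvature(np.array([5.0, 15.0]), field, **kw) == 0.0


class TestMembraneForce:
    @staticmethod
    def _bilayer_state(n=10, width=10.0, lift=None):
        # offset rows (hexagonal pitch), the packing the scenarios use
        top = np.column_stack([np.arange(n) + 0.5, np.ones(n)])
        if lift is not None:
            top[lift[0], 1] += lift[1]
        bot = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        pts = np.vstack([top, bot])
        types = np.array([0] * n + [1] * n, dtype=np.int8)
        tri = cm.build_periodic_triangulation(
            pts, cm.PeriodicDomain(width), cutoff=1.5, cell_types=types
        )
        return pts, tri

    def test_flat_layer_zero_force(self):
        _, tri = self._bilayer_state()
        curve = cm.membrane_curve(tri)
        k0 = {int(i): 0.0 for i in curve.epithelial_ids}
        forces = cm.basement_membrane_forces(curve, tri, cm.BMParams(beta=10.0), k0)
        for f in forces.values():
            assert np.allclose(f, 0.0, atol=1e-10)

    def test_matching_curvature_zero_force(self):
        """kappa == kappa_0 at every midpoint nulls the membrane force."""
        _, tri = self._bilayer_state()
        curve = cm.membrane_curve(tri)
        kappa = curve_curvatures(curve)
        epi_m = tri.ids[np.searchsorted(tri.ids, curve.epithelial_ids)]
        forces = membrane_force_array(
            curve, tri.points,
            np.searchsorted(tri.ids, curve.epithelial_ids),
            np.searchsorted(tri.ids, curve.stromal_ids),
            tri.domain, cm.BMParams(beta=10.0), kappa,
        )
        assert np.allclose(forces, 0.0, atol=1e-12)

    def test_displaced_cell_restored(self):
        """A lifted epithelial cell feels a net downward membrane force, and
        relaxation under the overdamped dynamics restores flatness."""
        pts, tri = self._bilayer_state(lift=(4, 0.3))
        curve = cm.membrane_curve(tri)
        k0 = {int(i): 0.0 for i in curve.epithelial_ids}
        forces = cm.basement_membrane_forces(curve, tri, cm.BMParams(beta=10.0), k0)
        assert forces[4][1] < 0

        # relaxation oracle: integrate membrane force only
        ip = cm.IntegratorParams(dt=0.01)
        p = pts.copy()
        types = tri.cell_types
        pinned = np.array([False] * 10 + [True] * 10)
        for _ in range(2000):
            t = cm.build_periodic_triangulation(
                p, tri.domain, cutoff=1.5, cell_types=types
            )
            c = cm.membrane_curve(t)
            farr = membrane_force_array(
                c, p,
                np.searchsorted(t.ids, c.epithelial_ids),
                np.searchsorted(t.ids, c.stromal_ids),
                t.domain, cm.BMParams(beta=10.0), np.zeros(len(c)),
            )
            p = cm.advance_positions(p, farr, pinned, ip, t.domain)
        assert np.abs(p[:10, 1] - 1.0).max() < 0.05

    def test_base_region_bulges_toward_stroma(self):
        """kappa_0 = kappa_c > 0 in a flat band drives the band downward."""
        pts, tri = self._bilayer_state()
        curve = cm.membrane_curve(tri)
        k0 = {int(i): (0.4 if 3 <= i <= 6 else 0.0) for i in curve.epithelial_ids}
        forces = cm.basement_membrane_forces(curve, tri, cm.BMParams(beta=10.0), k0)
        for i in (4, 5):
            assert forces[i][1] < 0       # pushed into the stroma below


class TestAdvancePositions:
    def test_zero_force_no_motion_and_pinning(self):
        pos = np.array([[1.0, 1.0], [2.0, 2.0]])
        dom = cm.PeriodicDomain(10.0)
        ip = cm.IntegratorParams()
        out = cm.advance_positions(pos, np.zeros((2, 2)), np.array([False, False]), ip, dom)
        assert np.allclose(out, pos)
        out = cm.advance_positions(
            pos, np.array([[5.0, 5.0], [5.0, 5.0]]), np.array([True, True]), ip, dom
        )
        assert np.allclose(out, pos)

    def test_explicit_euler_step_and_wrap(self):
        dom = cm.PeriodicDomain(10.0)
        ip = cm.IntegratorParams(eta=1.0, dt=0.0042)
        out = cm.advance_positions(
            np.array([[9.999, 0.0]]), np.array([[1.0, 0.0]]), np.array([False]), ip, dom
        )
        assert out[0, 0] == pytest.approx((9.999 + 0.0042) % 10.0)

    def test_nonfinite_force_raises(self):
        dom = cm.PeriodicDomain(10.0)
        with pytest.raises(IntegrationError):
            cm.advance_positions(
                np.zeros((1, 2)), np.array([[np.nan, 0.0]]), np.array([False]),
                cm.IntegratorParams(), dom,
            )
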