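"""Shape-metric oracles: curvature, nuclear position, convergence fit."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wingdisc.builder import make_arc_fixture
from wingdisc.quantify import (
    MengerProfile,
    SurfacePolyline,
    asymptotic_fit,
    circumcircle_curvature,
    global_curvature,
    menger_profile,
    nuclear_position,
    point_polyline_distance,
)


def _circumradius_from_bisectors(p1, p2, p3):
    """Independent circumcenter solve: perpendicular-bisector intersection."""
    p1, p2, p3 = map(np.asarray, (p1, p2, p3))
    m12, m23 = (p1 + p2) / 2, (p2 + p3) / 2
    d12, d23 = p2 - p1, p3 - p2
    # solve m12 + t*rot(d12) = m23 + s*rot(d23)
    rot = np.array([[0.0, -1.0], [1.0, 0.0]])
    A = np.column_stack([rot @ d12, -(rot @ d23)])
    t, _ = np.linalg.solve(A, m23 - m12)
    center = m12 + t * (rot @ d12)
    return np.linalg.norm(p1 - center)


class TestCircumcircle:
    def test_circle_points_give_reciprocal_radius(self):
        R = 10.0
        th = np.array([0.3, 1.1, 2.0])
        pts = R * np.column_stack([np.cos(th), np.sin(th)])
        assert np.isclose(abs(circumcircle_curvature(*pts)), 1.0 / R, atol=1e-12)

    def test_collinear_points_are_flat(self):
        assert circumcircle_curvature((0, 0), (1, 0), (2, 0)) == 0.0

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            circumcircle_curvature((0, 0), (0, 0), (1, 1))

    @pytest.mark.parametrize("seed", range(10))
    def test_against_perpendicular_bisector_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, (3, 2))
        kappa = circumcircle_curvature(*pts)
        if abs(kappa) < 1e-12:
            return
        R = _circumradius_from_bisectors(*pts)
        assert np.isclose(abs(kappa), 1.0 / R, rtol=1e-10)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        coords=st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=6, max_size=6
        ),
        angle=st.floats(min_value=-np.pi, max_value=np.pi),
        dx=st.floats(min_value=-100, max_value=100),
        dy=st.floats(min_value=-100, max_value=100),
    )
    def test_rigid_motion_invariance_property(self, coords, angle, dx, dy):
        pts = np.array(coords).reshape(3, 2)
        a = np.linalg.norm(pts[0] - pts[1])
        b = np.linalg.norm(pts[1] - pts[2])
        c = np.linalg.norm(pts[0] - pts[2])
        if min(a, b, c) < 1e-3:
            return
        kappa = circumcircle_curvature(*pts)
        Q = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = pts @ Q.T + np.array([dx, dy])
        assert np.isclose(circumcircle_curvature(*moved), kappa, rtol=1e-6, atol=1e-9)
        reflected = pts * np.array([1.0, -1.0])
        assert np.isclose(circumcircle_curvature(*reflected), -kappa, rtol=1e-9, atol=1e-12)

    def test_orientation_sets_sign(self):
        ccw = circumcircle_curvature((0, 0), (1, -1), (2, 0))
        cw = circumcircle_curvature((2, 0), (1, -1), (0, 0))
        assert ccw > 0 and np.isclose(ccw, -cw)


class TestGlobalCurvature:
    def test_semicircular_arc(self):
        pts, kappa = make_arc_fixture(radius=20.0, span_angle=np.pi, n_points=201)
        assert np.isclose(abs(global_curvature(pts)), 0.05, rtol=1e-6)

    def test_straight_segment_is_flat(self):
        pts, kappa = make_arc_fixture(radius=np.inf, n_points=50)
        assert kappa == 0.0
        assert global_curvature(pts) == 0.0

    def test_reflection_flips_sign_preserves_magnitude(self):
        pts, _ = make_arc_fixture(radius=12.0, span_angle=1.2, n_points=101)
        k = global_curvature(pts)
        mirrored = pts * np.array([1.0, -1.0])
        assert np.isclose(global_curvature(mirrored), -k, rtol=1e-12)

    def test_window_averaged_option_matches_three_point_on_circle(self):
        pts, _ = make_arc_fixture(radius=8.0, span_angle=2.0, n_points=500)
        three_point = global_curvature(pts)
        averaged = global_curvature(pts, window=2.0)
        assert np.isclose(abs(averaged), abs(three_point), rtol=1e-3)

    def test_rigid_motion_invariance(self):
        pts, _ = make_arc_fixture(radius=7.0, span_angle=1.0, n_points=80)
        k = global_curvature(pts)
        th = 0.7
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ Q.T + np.array([3.0, -2.0])
        assert np.isclose(global_curvature(moved), k, atol=1e-9)


class TestMengerProfile:
    def test_noiseless_circle_recovers_constant_curvature(self):
        # dense sampling keeps the chordal-interpolation error below 1e-6
        pts, kappa = make_arc_fixture(radius=5.0, span_angle=2.5, n_points=4000)
        prof = menger_profile(pts, window_halfwidth=1.0)
        assert isinstance(prof, MengerProfile)
        assert np.allclose(np.abs(prof.curvature), 0.2, atol=1e-6)

    def test_straight_line_is_zero_everywhere(self):
        pts, _ = make_arc_fixture(radius=np.inf, n_points=100)
        prof = menger_profile(pts, window_halfwidth=3.0)
        assert np.allclose(prof.curvature, 0.0, atol=1e-12)

    def test_noisy_circle_mean_within_five_percent(self):
        pts, kappa = make_arc_fixture(
            radius=5.0, span_angle=2.5, n_points=200, noise_sd=0.05, seed=3
        )
        prof = menger_profile(pts, window_halfwidth=2.0)
        assert abs(np.abs(prof.curvature).mean() - 0.2) < 0.05 * 0.2 + 0.01

    def test_piecewise_arc_recovers_both_plateaus(self):
        # two tangent arcs of radius 10 and 5 joined smoothly
        r1, r2 = 10.0, 5.0
        th1 = np.linspace(-0.9, 0.0, 150)
        a1 = r1 * np.column_stack([np.sin(th1), 1 - np.cos(th1)])
        th2 = np.linspace(0.0, 0.9, 150)[1:]
        a2 = r2 * np.column_stack([np.sin(th2), 1 - np.cos(th2)])
        pts = np.vstack([a1, a2])
        prof = menger_profile(pts, window_halfwidth=1.0)
        s_junction = abs(th1[0]) * r1
        far_left = prof.arc_length < s_junction - 2.0
        far_right = prof.arc_length > s_junction + 2.0
        assert np.allclose(np.abs(prof.curvature[far_left]), 1 / r1, rtol=0.05)
        assert np.allclose(np.abs(prof.curvature[far_right]), 1 / r2, rtol=0.05)

    def test_menger_equals_circumcircle_on_random_triples(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            pts = rng.uniform(-3, 3, (3, 2))
            if min(
                np.linalg.norm(pts[0] - pts[1]),
                np.linalg.norm(pts[1] - pts[2]),
                np.linalg.norm(pts[0] - pts[2]),
            ) < 1e-6:
                continue
            k = circumcircle_curvature(*pts)
            a = np.linalg.norm(pts[1] - pts[0])
            b = np.linalg.norm(pts[2] - pts[1])
            c = np.linalg.norm(pts[0] - pts[2])
            area2 = (pts[1, 0] - pts[0, 0]) * (pts[2, 1] - pts[0, 1]) - (
                pts[1, 1] - pts[0, 1]
            ) * (pts[2, 0] - pts[0, 0])
            menger = 4 * (area2 / 2) / (a * b * c)
            assert np.isclose(k, menger, rtol=1e-10, atol=1e-12)

    def test_window_must_fit(self):
        pts, _ = make_arc_fixture(radius=5.0, span_angle=0.3, n_points=10)
        with pytest.raises(ValueError):
            menger_profile(pts, window_halfwidth=50.0)


class TestNuclearPosition:
    apical = np.array([[0.0, 25.0], [2.5, 25.0]])
    basal = np.array([[0.0, 0.0], [2.5, 0.0]])

    def test_on_basal_surface_is_zero(self):
        m = nuclear_position(self.apical, self.basal, np.array([1.2, 0.0]))
        assert m.fraction == 0.0

    def test_on_apical_surface_is_one(self):
        m = nuclear_position(self.apical, self.basal, np.array([1.2, 25.0]))
        assert m.fraction == 1.0

    def test_midpoint_of_rectangular_cell(self):
        m = nuclear_position(self.apical, self.basal, np.array([1.25, 12.5]))
        assert np.isclose(m.L_A, 12.5) and np.isclose(m.L_B, 12.5)
        assert np.isclose(m.fraction, 0.5) and np.isclose(m.height, 25.0)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError):
            nuclear_position(self.basal, self.basal, np.array([1.0, 0.0]))

    def test_polyline_distance_brute_force(self):
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.uniform(0.1, 1.0, (20, 2)), axis=0)
        p = rng.uniform(0, 10, 2)
        d = point_polyline_distance(p, pts)
        dense = []
        for a, b in zip(pts[:-1], pts[1:]):
            ts = np.linspace(0, 1, 2001)[:, None]
            seg = a + ts * (b - a)
            dense.append(np.linalg.norm(seg - p, axis=1).min())
        assert np.isclose(d, min(dense), atol=1e-5)


class TestAsymptoticFit:
    def test_recovers_exact_exponential_plateau(self):
        t = np.linspace(0, 30000, 100)
        c = 0.04 * (1 - np.exp(-t / 5000.0))
        c_inf, tau, resid = asymptotic_fit(t, c)
        assert np.isclose(c_inf, 0.04, atol=1e-6)
        assert np.isclose(tau, 5000.0, rtol=1e-3)
        assert resid < 1e-8

    def test_constant_series_is_its_own_plateau(self):
        t = np.linspace(0, 10, 20)
        c_inf, tau, resid = asymptotic_fit(t, np.full(20, 0.025))
        assert c_inf == 0.025 and resid == 0.0

    def test_noisy_recovery_within_three_percent(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0, 40000, 200)
        clean = 0.05 * (1 - np.exp(-t / 6000.0))
        noisy = clean + rng.normal(scale=0.001, size=t.size)
        c_inf, _, _ = asymptotic_fit(t, noisy)
        assert abs(c_inf - 0.05) < 0.03 * 0.05

    def test_polyline_validation(self):
        with pytest.raises(ValueError):
            SurfacePolyline(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError):
            asymptotic_fit([0, 1, 2], [1, 2, 3])  # too few samples
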