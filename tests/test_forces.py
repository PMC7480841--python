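"""Force kernel oracles: every analytic force must match the energy gradient."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

import wingdisc as wd
from wingdisc.forces import (
    DegeneratePairError,
    area_constraint_force,
    compute_total_forces,
    morse_energy,
    morse_force,
    spring_energy,
    spring_force,
    total_energy,
)
from wingdisc.params import MorsePairParams, SpringParams
from wingdisc.state import Cell, NodeClass, Region, TissueState


def _fd_gradient(f, x, h=1e-6):
    """Central finite differences of a scalar function of one 2-vector."""
    g = np.zeros(2)
    for k in range(2):
        e = np.zeros(2)
        e[k] = h
        g[k] = (f(x + e) - f(x - e)) / (2 * h)
    return g


MORSE = MorsePairParams(
    repulsion_amplitude=2.0,
    repulsion_scale=0.3,
    attraction_amplitude=1.0,
    attraction_scale=0.8,
    cutoff=2.5,
)


class TestMorseForce:
    def test_vanishes_at_numerical_equilibrium(self):
        # solve U0/xi e^(-r/xi) = W0/gamma e^(-r/gamma) independently
        p = MORSE

        def imbalance(r):
            return (
                p.repulsion_amplitude / p.repulsion_scale * np.exp(-r / p.repulsion_scale)
                - p.attraction_amplitude / p.attraction_scale * np.exp(-r / p.attraction_scale)
            )

        r_star = brentq(imbalance, 0.1, 2.4)
        f = morse_force(np.array([r_star, 0.0]), p)
        assert np.linalg.norm(f) < 1e-12

    def test_zero_beyond_cutoff(self):
        f = morse_force(np.array([MORSE.cutoff * 1.01, 0.0]), MORSE)
        assert np.all(f == 0.0)

    def test_repulsive_short_range_attractive_past_equilibrium(self):
        short = morse_force(np.array([0.2, 0.0]), MORSE)
        assert short[0] > 0  # pushes the first node away
        lng = morse_force(np.array([1.5, 0.0]), MORSE)
        assert lng[0] < 0  # pulls it back

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_difference_gradient(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(0.2, MORSE.cutoff * 0.95, 2) * rng.choice([-1, 1], 2)
        d = np.linalg.norm(r)
        f = morse_force(r, MORSE)
        grad = _fd_gradient(lambda x: float(morse_energy(np.linalg.norm(x), MORSE)), r)
        assert np.allclose(f, -grad, rtol=1e-6, atol=1e-9 * max(1, d))

    def test_zero_separation_is_degenerate(self):
        with pytest.raises(DegeneratePairError):
            morse_force(np.zeros(2), MORSE)


class TestSpringForce:
    def test_zero_at_rest_length(self):
        p = SpringParams(stiffness=5.0, rest_length=1.3)
        f = spring_force(np.array([1.3, 0.0]), p)
        assert np.allclose(f, 0.0)

    def test_contractility_scale(self):
        # a 9 nN/μm zero-rest-length spring at 1 μm pulls with 9 nN
        p = SpringParams(stiffness=9.0, rest_length=0.0)
        f = spring_force(np.array([1.0, 0.0]), p)
        assert np.isclose(f[0], -9.0)
        assert f[1] == 0.0

    def test_zero_rest_length_zero_separation(self):
        p = SpringParams(stiffness=9.0, rest_length=0.0)
        assert np.all(spring_force(np.zeros(2), p) == 0.0)

    def test_breakable_beyond_break_distance(self):
        p = SpringParams(stiffness=5.0, rest_length=1.0, breakable=True,
                         break_distance=3.0)
        assert np.all(spring_force(np.array([3.5, 0.0]), p) == 0.0)
        assert spring_force(np.array([2.9, 0.0]), p)[0] < 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_difference_gradient(self, seed):
        rng = np.random.default_rng(seed)
        p = SpringParams(stiffness=rng.uniform(1, 20), rest_length=rng.uniform(0, 2))
        r = rng.uniform(0.5, 3.0, 2)
        f = spring_force(r, p)
        grad = _fd_gradient(lambda x: float(spring_energy(np.linalg.norm(x), p)), r)
        assert np.allclose(f, -grad, rtol=1e-8, atol=1e-8)


def _single_cell_state(poly, target_area):
    n = len(poly)
    return TissueState(
        pos=np.asarray(poly, dtype=float),
        node_class=np.full(n, NodeClass.MEMBRANE, dtype=np.int8),
        cell_id=np.zeros(n, dtype=np.int32),
        region=np.full(n, Region.BASAL, dtype=np.int8),
        cells=[Cell("columnar", np.arange(n), np.empty(0, np.intp), target_area)],
        ecm_chain=np.empty(0, dtype=np.intp),
        ecm_adherent=np.zeros(n, bool),
    )


class TestAreaConstraint:
    def test_zero_at_target_area(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1)]
        st = _single_cell_state(square, 1.0)
        F = area_constraint_force(st.cells[0], st, k_vol=5.0)
        assert np.allclose(F, 0.0)

    def test_expansion_forces_respect_square_symmetry(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1)]
        st = _single_cell_state(square, 1.21)  # target 10% above actual
        F = area_constraint_force(st.cells[0], st, k_vol=5.0)
        mags = np.linalg.norm(F, axis=1)
        assert np.allclose(mags, mags[0])  # same magnitude on all corners
        center = np.array([0.5, 0.5])
        outward = st.pos - center
        assert np.all(np.einsum("ij,ij->i", F, outward) > 0)  # expanding
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-12)  # no net force

    def test_matches_finite_difference_gradient(self):
        rng = np.random.default_rng(0)
        theta = np.sort(rng.uniform(0, 2 * np.pi, 7))
        poly = np.column_stack([np.cos(theta), np.sin(theta)]) * rng.uniform(1, 2, 7)[:, None]
        st = _single_cell_state(poly, 2.5)
        k_vol = 3.0
        F = area_constraint_force(st.cells[0], st, k_vol)

        def energy(flat):
            st2 = _single_cell_state(flat.reshape(-1, 2), 2.5)
            a = st2.cell_areas()[0]
            return 0.5 * k_vol * (a - 2.5) ** 2

        h = 1e-6
        x0 = st.pos.ravel().copy()
        for i in range(x0.size):
            e = np.zeros_like(x0)
            e[i] = h
            g = (energy(x0 + e) - energy(x0 - e)) / (2 * h)
            assert np.isclose(F.ravel()[i], -g, rtol=1e-6, atol=1e-8)

    def test_zero_area_polygon_rejected(self):
        degenerate = [(0, 0), (1, 0), (2, 0)]
        st = _single_cell_state(degenerate, 1.0)
        with pytest.raises(ValueError, match="zero-area"):
            area_constraint_force(st.cells[0], st, k_vol=1.0)

    def test_self_intersecting_polygon_warns(self):
        bowtie = [(0, 0), (3, 2), (3, 0), (0, 1)]  # crossing, nonzero area
        st = _single_cell_state(bowtie, 0.5)
        with pytest.warns(RuntimeWarning, match="self-intersecting"):
            area_constraint_force(st.cells[0], st, k_vol=1.0)


class TestTotalForces:
    def test_freshly_built_tissue_is_force_free(self, mini_tissue_factory):
        state, ep = mini_tissue_factory()
        F = compute_total_forces(state, ep)
        assert np.abs(F).max() < 1e-8

    def test_momentum_neutrality_on_random_rig(self, jiggled_rig):
        state, ep = jiggled_rig
        F = compute_total_forces(state, ep.with_k_cont(6.0))
        total = F.sum(axis=0)
        scale = np.abs(F).sum()
        assert np.linalg.norm(total) < 1e-9 * max(scale, 1.0)

    def test_matches_gradient_of_total_energy(self, jiggled_rig):
        state, ep = jiggled_rig
        ep = ep.with_k_cont(4.0)
        F = compute_total_forces(state, ep)
        rng = np.random.default_rng(7)
        # spot-check a random subset of coordinates with central differences
        h = 1e-6
        idx = rng.choice(state.n_nodes, size=25, replace=False)
        for i in idx:
            for k in range(2):
                old = state.pos[i, k]
                state.pos[i, k] = old + h
                e_plus = total_energy(state, ep)
                state.pos[i, k] = old - h
                e_minus = total_energy(state, ep)
                state.pos[i, k] = old
                g = (e_plus - e_minus) / (2 * h)
                assert np.isclose(F[i, k], -g, rtol=1e-5, atol=5e-5), (i, k)

    def test_energy_decreases_under_small_euler_step(self, jiggled_rig):
        state, ep = jiggled_rig
        ep = ep.with_k_cont(6.0)
        dp = wd.default_damping_params()
        e0 = total_energy(state, ep)
        wd.step(state, ep, dp, dt=1e-4)
        assert total_energy(state, ep) <= e0 + 1e-12

    def test_locality_of_perturbation(self, mini_tissue_factory):
        state, ep = mini_tissue_factory()
        F0 = compute_total_forces(state, ep)
        # move one nucleus node slightly; only nodes within one interaction
        # cutoff or one bond may feel it
        node = int(state.cells[0].nucleus_nodes[0])
        state.pos[node] += np.array([0.05, 0.0])
        F1 = compute_total_forces(state, ep)
        changed = np.flatnonzero(np.abs(F1 - F0).max(axis=1) > 1e-12)
        reach = max(ep.volume_exclusion.cutoff, ep.nucleus.cutoff)
        dist = np.linalg.norm(state.pos - state.pos[node], axis=1)
        assert np.all(dist[changed] <= reach + 0.1)

    def test_coincident_nodes_reported(self, mini_tissue_factory):
        state, ep = mini_tissue_factory()
        # collapse one nucleus pair onto the same point
        a, b = state.nucleus_pairs[0]
        state.pos[b] = state.pos[a]
        with pytest.raises(DegeneratePairError) as err:
            compute_total_forces(state, ep)
        assert set(err.value.node_ids) == {int(a), int(b)}
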