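"""Integrator oracles: Euler closed form, determinism, frame invariance."""

from __future__ import annotations

import numpy as np
import pytest

import wingdisc as wd
from wingdisc.engine import (
    SimConfig,
    SimulationBlowUpError,
    check_stability,
    damping_vector,
    refresh_pairs,
    run,
    step,
)
from wingdisc.params import SpringParams
from wingdisc.scenarios import ScenarioSpec
from wingdisc.state import Cell, NodeClass, Region, TissueState


def _two_node_spring_rig(k, x0):
    """Two membrane nodes joined by a zero-rest-length spring."""
    from dataclasses import replace

    ep = wd.default_energy_params()
    ep = replace(
        ep,
        membrane=SpringParams(stiffness=k, rest_length=0.0),
        area_constraint_stiffness=0.0,
    )
    st = TissueState(
        pos=np.array([[0.0, 0.0], [x0, 0.0]]),
        node_class=np.full(2, NodeClass.MEMBRANE, dtype=np.int8),
        cell_id=np.zeros(2, dtype=np.int32),
        region=np.full(2, Region.BASAL, dtype=np.int8),
        cells=[],
        ecm_chain=np.empty(0, dtype=np.intp),
        ecm_adherent=np.zeros(2, bool),
        membrane_bonds=np.array([[0, 1]], dtype=np.intp),
        membrane_r0=np.zeros(1),
    )
    return st, ep


class TestStep:
    def test_zero_forces_leave_positions(self, mini_tissue_factory):
        state, ep = mini_tissue_factory()
        before = state.pos.copy()
        wd.step(state, ep, wd.default_damping_params(), dt=0.01)
        assert np.allclose(state.pos, before, atol=1e-10)

    def test_spring_relaxation_matches_euler_closed_form(self):
        # two free nodes joined by a spring with r0 = 0 close symmetrically:
        # the gap obeys d_{n+1} = d_n (1 - 2 k dt / C) exactly under Euler
        k, x0, dt, C = 2.0, 1.0, 0.01, 1.0
        st, ep = _two_node_spring_rig(k, x0)
        dp = wd.default_damping_params()
        n = 50
        for _ in range(n):
            step(st, ep, dp, dt)
        expected = x0 * (1.0 - 2.0 * k * dt / C) ** n
        gap = st.pos[1, 0] - st.pos[0, 0]
        assert np.isclose(gap, expected, rtol=1e-12)

    def test_halving_dt_halves_one_step_displacement(self):
        st1, ep = _two_node_spring_rig(3.0, 1.5)
        st2 = st1.copy()
        dp = wd.default_damping_params()
        step(st1, ep, dp, dt=0.01)
        step(st2, ep, dp, dt=0.005)
        d1 = st1.pos[1, 0] - 1.5
        d2 = st2.pos[1, 0] - 1.5
        assert np.isclose(d1, 2 * d2, rtol=1e-12)

    def test_blow_up_reported_with_node(self, mini_tissue_factory):
        state, ep = mini_tissue_factory()
        state.pos[3] = np.nan
        sim = SimConfig(dt=0.004, max_steps=60, pair_refresh_interval=50,
                        output_interval=60)
        with pytest.raises(SimulationBlowUpError) as err:
            run(state, ep, wd.default_damping_params(), sim)
        assert err.value.node >= 0

    def test_stability_guard_names_offending_term(self, ep, dp):
        with pytest.raises(ValueError, match="E_"):
            check_stability(ep, dp, dt=1.0)


class TestDamping:
    def test_per_class_and_region_multipliers(self, mini_tissue_factory):
        state, _ = mini_tissue_factory()
        dp = wd.DampingParams(
            C_nuc=2.0, C_memb=3.0, C_ecm=4.0,
            ecm_region_multipliers={"ECMs": 1.0, "ECMbc": 1.0, "ECMc": 1000.0},
        )
        C = damping_vector(state, dp)
        assert np.all(C[state.node_class == NodeClass.NUCLEUS] == 2.0)
        assert np.all(C[state.node_class == NodeClass.MEMBRANE] == 3.0)
        ecmc = (state.node_class == NodeClass.ECM) & (state.region == Region.ECMC)
        ecms = (state.node_class == NodeClass.ECM) & (state.region == Region.ECMS)
        assert np.all(C[ecmc] == 4000.0)
        assert np.all(C[ecms] == 4.0)


class TestRefreshPairs:
    def test_parallel_chains_pair_with_horizontal_opposites(self, mini_tissue_factory):
        state, ep = mini_tissue_factory()
        refresh_pairs(state, ep)
        pairs = state.adhesion_pairs_lateral
        dy = np.abs(state.pos[pairs[:, 0], 1] - state.pos[pairs[:, 1], 1])
        assert np.median(dy) < 1e-9

    def test_one_partner_per_node(self, mini_tissue_factory):
        state, ep = mini_tissue_factory()
        refresh_pairs(state, ep)
        for pairs in (state.adhesion_pairs_basal, state.adhesion_pairs_apical):
            flat = pairs.ravel()
            assert len(flat) == len(np.unique(flat))

    def test_exclusion_pairs_symmetric_and_classified(self, jiggled_rig):
        state, ep = jiggled_rig
        pairs = {tuple(sorted(p)) for p in state.exclusion_pairs.tolist()}
        assert len(pairs) == len(state.exclusion_pairs)  # each pair once
        cls = state.node_class
        for i, j in state.exclusion_pairs:
            kinds = {int(cls[i]), int(cls[j])}
            if kinds == {NodeClass.NUCLEUS, NodeClass.MEMBRANE}:
                assert state.cell_id[i] == state.cell_id[j]
            elif kinds == {NodeClass.MEMBRANE}:
                assert state.cell_id[i] != state.cell_id[j]
            else:
                assert kinds == {NodeClass.MEMBRANE, NodeClass.ECM}

    def test_contractility_zone_tracks_nucleus_by_brute_force(self, mini_tissue_factory):
        state, ep = mini_tissue_factory()
        ep = ep.with_k_cont(6.0)
        refresh_pairs(state, ep)
        n_before = len(state.contractility_pairs)
        assert n_before > 0

        def brute_count(st):
            total = 0
            for ci in st.cells_of_kind("columnar"):
                cell = st.cells[ci]
                ring = cell.membrane_ring
                reg = st.region[ring]
                left = ring[reg == Region.LATERAL_LEFT][::-1]
                right = ring[reg == Region.LATERAL_RIGHT][1:]
                m = min(left.size, right.size)
                h_nuc = st.pos[cell.nucleus_nodes, 1].min()
                for a, b in zip(left[:m], right[:m]):
                    mid_y = (st.pos[a, 1] + st.pos[b, 1]) / 2
                    if mid_y < h_nuc - st.node_spacing:
                        total += 1
            return total

        assert n_before == brute_count(state)
        # move every nucleus apically by 5 μm: zone grows accordingly
        for cell in state.cells:
            state.pos[cell.nucleus_nodes, 1] += 5.0
        refresh_pairs(state, ep)
        assert len(state.contractility_pairs) == brute_count(state)
        assert len(state.contractility_pairs) > n_before


class TestRunProperties:
    def test_determinism_bitwise(self, mini_tissue_factory):
        state1, ep = mini_tissue_factory()
        state2, _ = mini_tissue_factory()
        dp = wd.default_damping_params()
        sim = SimConfig(dt=0.004, max_steps=400, output_interval=100,
                        convergence_window=10**9)
        t1 = run(state1, ep, dp, sim, ScenarioSpec(name="a", k_cont=6.0))
        t2 = run(state2, ep, dp, sim, ScenarioSpec(name="a", k_cont=6.0))
        assert np.array_equal(t1.final_state.pos, t2.final_state.pos)
        assert np.array_equal(t1.global_curvature, t2.global_curvature)

    def test_frame_invariance_under_rigid_motion(self, mini_tissue_factory):
        state1, ep = mini_tissue_factory()
        state2, _ = mini_tissue_factory()
        th = 0.5
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([7.0, -3.0])
        state2.pos = state2.pos @ Q.T + shift
        dp = wd.default_damping_params()
        sim = SimConfig(dt=0.004, max_steps=500, output_interval=250,
                        convergence_window=10**9)
        t1 = run(state1, ep, dp, sim, ScenarioSpec(name="a", k_cont=6.0))
        t2 = run(state2, ep, dp, sim, ScenarioSpec(name="a", k_cont=6.0))
        assert np.allclose(t2.final_state.pos, t1.final_state.pos @ Q.T + shift,
                           atol=1e-9)
        assert np.allclose(t1.global_curvature, t2.global_curvature, atol=1e-9)

    def test_convergence_detector_fires_on_constant_series(self, mini_tissue_factory):
        # a force-free flat tissue has constant (zero) curvature: the run
        # must converge as soon as one full window has been observed
        state, ep = mini_tissue_factory()
        dp = wd.default_damping_params()
        sim = SimConfig(dt=0.004, max_steps=2000, output_interval=50,
                        convergence_window=200, convergence_tol=0.01)
        traj = run(state, ep, dp, sim)
        assert traj.converged
        assert traj.steps_run <= 250

    def test_optional_noise_is_seeded_and_off_by_default(self, mini_tissue_factory):
        state1, ep = mini_tissue_factory()
        state2, _ = mini_tissue_factory()
        dp = wd.default_damping_params()
        noisy = SimConfig(dt=0.004, max_steps=100, output_interval=100,
                          convergence_window=10**9, noise_sd=0.01, noise_seed=5)
        t1 = run(state1, ep, dp, noisy)
        t2 = run(state2, ep, dp, noisy)
        assert np.array_equal(t1.final_state.pos, t2.final_state.pos)
        state3, _ = mini_tissue_factory()
        quiet = SimConfig(dt=0.004, max_steps=100, output_interval=100,
                          convergence_window=10**9)
        t3 = run(state3, ep, dp, quiet)
        assert not np.allclose(t1.final_state.pos, t3.final_state.pos)

    def test_event_beyond_horizon_rejected(self, mini_tissue_factory):
        from wingdisc.engine import SetKCont

        state, ep = mini_tissue_factory()
        sim = SimConfig(dt=0.004, max_steps=100)
        spec = ScenarioSpec(name="x", events=[(10_000.0, SetKCont(0.0))])
        with pytest.raises(ValueError, match="horizon"):
            run(state, ep, wd.default_damping_params(), sim, spec)

    def test_dt_refinement_consistency(self, mini_tissue_factory):
        # halving dt (with pair refreshes at matched simulation times)
        # changes the final curvature of a short reference run by < 1%
        state1, ep = mini_tissue_factory()
        state2, _ = mini_tissue_factory()
        dp = wd.default_damping_params()
        spec = ScenarioSpec(name="ref", k_cont=6.0)
        sim1 = SimConfig(dt=0.004, max_steps=2500, pair_refresh_interval=50,
                         output_interval=2500, convergence_window=10**9)
        sim2 = SimConfig(dt=0.002, max_steps=5000, pair_refresh_interval=100,
                         output_interval=5000, convergence_window=10**9)
        t1 = run(state1, ep, dp, sim1, spec)
        t2 = run(state2, ep, dp, sim2, spec)
        c1, c2 = t1.global_curvature[-1], t2.global_curvature[-1]
        assert abs(c1 - c2) / max(abs(c2), 1e-6) < 0.01
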