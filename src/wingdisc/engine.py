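"""Explicit-Euler integration of the overdamped node dynamics.

Each node class moves down the gradient of its own energy terms divided by
its drag coefficient:

    C_class dx/dt = F(x)          x <- x + dt F / C_class

with ``C_class`` one of C_nuc, C_memb, or C_ecm times the per-region ECM
multiplier.  The engine maintains the dynamic interaction pair lists
(adhesion re-matching, volume-exclusion neighbor lists, contractility
levels), applies scheduled perturbation events, records the shape-metric
time series, and stops when the global curvature has converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .forces import compute_total_forces
from .params import DampingParams, EnergyParams
from .quantify import cell_nuclear_positions, tissue_global_curvature
from .state import NodeClass, Region, TissueState

__all__ = [
    "SimConfig",
    "desk_sim_config",
    "Trajectory",
    "SimulationBlowUpError",
    "step",
    "refresh_pairs",
    "run",
    "damping_vector",
    "SetKCont",
    "MultiplyEcmDamping",
    "DeleteEcm",
    "DeleteApicalAdhesion",
]


@dataclass
class SimConfig:
    """Integration and bookkeeping settings.

    ``dt`` defaults to 0.002 AU; the desk-scale presets run at 0.005 AU,
    still far below the stability bound of the stiffest spring (the engine
    refuses any dt with k_max dt / C_min >= 2).  Convergence is declared
    when the relative change of global curvature over ``convergence_window``
    steps falls below ``convergence_tol`` (a floor keeps the relative test
    meaningful for flat tissues).
    """

    dt: float = 0.002
    max_steps: int = 100_000
    pair_refresh_interval: int = 50
    output_interval: int = 250
    convergence_window: int = 10_000
    convergence_tol: float = 0.01
    curvature_floor: float = 0.002   # μm^-1; flatness scale for relative tests
    store_snapshots: bool = False
    # optional isotropic positional noise (μm·AU^-1/2), for robustness tests
    # only: the model is deterministic by default
    noise_sd: float = 0.0
    noise_seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("max_steps", "pair_refresh_interval", "output_interval",
                     "convergence_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def desk_sim_config(**overrides) -> "SimConfig":
    """Integration settings for desk-scale (reduced-resolution) runs.

    dt = 0.005 AU sits at a 1.4x margin below the stability bound of the
    stiffest collective mode (the per-cell area penalty); runs stop at
    curvature convergence, typically well before the 70k-step ceiling.
    """
    cfg = SimConfig(
        dt=0.005,
        max_steps=70_000,
        output_interval=2_500,
        convergence_window=10_000,
        convergence_tol=0.01,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


class SimulationBlowUpError(RuntimeError):
    """Positions became non-finite (time step too large for the stiffness)."""

    def __init__(self, step_count: int, node: int):
        self.step_count = step_count
        self.node = node
        super().__init__(
            f"non-finite position at step {step_count} (worst node {node}); "
            "reduce dt or stiffnesses"
        )


# --- scenario events ------------------------------------------------------

@dataclass(frozen=True)
class SetKCont:
    """Set the basal actomyosin contractility level (nN/μm)."""

    value: float


@dataclass(frozen=True)
class MultiplyEcmDamping:
    """Scale the drag of one ECM region ('ECMs'|'ECMbc'|'ECMc')."""

    region: str
    factor: float


@dataclass(frozen=True)
class DeleteEcm:
    """Acutely remove the whole ECM chain and all cell-ECM adhesion."""


@dataclass(frozen=True)
class DeleteApicalAdhesion:
    """Remove the columnar-squamous interlayer adhesion (E_adhA)."""


@dataclass
class Trajectory:
    """Metric time series plus the final state of one run."""

    times: np.ndarray
    global_curvature: np.ndarray
    mean_nuclear_fraction: np.ndarray
    mean_height: np.ndarray
    final_state: TissueState
    converged: bool
    steps_run: int
    final_k_cont: float = 0.0  # contractility level in force at the end
    snapshots: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "global_curvature": self.global_curvature,
                "mean_nuclear_fraction": self.mean_nuclear_fraction,
                "mean_height": self.mean_height,
            }
        )


# --------------------------------------------------------------------------
# damping
# --------------------------------------------------------------------------

def damping_vector(state: TissueState, dp: DampingParams) -> np.ndarray:
    """Per-node drag coefficients (nN·AU/μm)."""
    C = np.empty(state.n_nodes)
    cls = state.node_class
    C[cls == NodeClass.NUCLEUS] = dp.C_nuc
    C[cls == NodeClass.MEMBRANE] = dp.C_memb
    ecm = cls == NodeClass.ECM
    C[ecm] = dp.C_ecm
    for name, mult in dp.ecm_region_multipliers.items():
        if mult != 1.0:
            code = Region.CODES[name]
            C[ecm & (state.region == code)] = dp.C_ecm * mult
    return C


def check_stability(ep: EnergyParams, dp: DampingParams, dt: float) -> None:
    """Refuse time steps beyond the explicit-Euler bound k dt / C >= 2."""
    terms = {
        "E_memb": ep.membrane.stiffness,
        "E_memb_bending": ep.membrane_bending_stiffness,
        "E_adhL": ep.lateral_adhesion.stiffness,
        "E_adhB": ep.basal_adhesion.stiffness,
        "E_adhA": ep.apical_interlayer_adhesion.stiffness,
        "E_cont": ep.contractility.stiffness,
        "E_ecm": ep.ecm.stiffness,
        "E_ecm_bending": ep.ecm_bending_stiffness,
    }
    c_min = dp.min_damping()
    for name, k in terms.items():
        if k * dt / c_min >= 2.0:
            raise ValueError(
                f"dt={dt} unstable for {name} (k={k} nN/μm, C_min={c_min}): "
                f"k·dt/C = {k * dt / c_min:.2f} >= 2"
            )


# --------------------------------------------------------------------------
# single step
# --------------------------------------------------------------------------

def step(
    state: TissueState,
    ep: EnergyParams,
    dp: DampingParams,
    dt: float,
    *,
    damping: np.ndarray | None = None,
) -> TissueState:
    """Advance the state by one explicit-Euler step, in place.

    ``x <- x + dt F / C`` per node; the per-node drag vector can be passed
    in to avoid recomputation inside tight loops.
    """
    C = damping if damping is not None else damping_vector(state, dp)
    F = compute_total_forces(state, ep)
    state.pos += (dt / C)[:, None] * F
    state.time += dt
    return state


# --------------------------------------------------------------------------
# pair maintenance
# --------------------------------------------------------------------------

def _mutual_nn_bipartite(pos, set_a, set_b, cutoff):
    """Mutually-nearest pairs (a, b) between two node sets within cutoff."""
    if set_a.size == 0 or set_b.size == 0:
        return np.empty((0, 2), dtype=np.intp)
    ta = cKDTree(pos[set_a])
    tb = cKDTree(pos[set_b])
    d_ab, nn_ab = tb.query(pos[set_a], k=1, distance_upper_bound=cutoff)
    d_ba, nn_ba = ta.query(pos[set_b], k=1, distance_upper_bound=cutoff)
    ia = np.flatnonzero(np.isfinite(d_ab))
    if ia.size == 0:
        return np.empty((0, 2), dtype=np.intp)
    jb = nn_ab[ia]
    mutual = nn_ba[jb] == ia
    ia, jb = ia[mutual], jb[mutual]
    return np.column_stack([set_a[ia], set_b[jb]])


def _sticky_rematch(
    pos, old_pairs, old_r0, candidate_sets, keep_cutoff, form_cutoff, default_r0
):
    """Persistent-bond re-matching of one adhesion type.

    Existing bonds survive as long as they remain within ``keep_cutoff``
    (adhesion receptors do not hop between partners); bonds stretched
    further detach.  Nodes left without a partner form new bonds by mutual
    nearest neighbor across each candidate interface, one partner per node
    — but only on contact, within the tighter ``form_cutoff``.  New bonds
    start at the default rest length; surviving bonds keep theirs.
    """
    if old_pairs.size:
        d = np.linalg.norm(pos[old_pairs[:, 0]] - pos[old_pairs[:, 1]], axis=1)
        alive = d <= keep_cutoff
        kept = old_pairs[alive]
        kept_r0 = old_r0[alive]
    else:
        kept = np.empty((0, 2), dtype=np.intp)
        kept_r0 = np.empty(0)
    bonded = set(kept[:, 0]) | set(kept[:, 1])
    new_parts = []
    for set_a, set_b in candidate_sets:
        free_a = set_a[~np.isin(set_a, list(bonded))] if bonded else set_a
        free_b = set_b[~np.isin(set_b, list(bonded))] if bonded else set_b
        p = _mutual_nn_bipartite(pos, free_a, free_b, form_cutoff)
        if p.size:
            new_parts.append(p)
    if new_parts:
        new = np.vstack(new_parts)
        pairs = np.vstack([kept, new])
        r0 = np.concatenate([kept_r0, np.full(len(new), float(default_r0))])
    else:
        pairs, r0 = kept, kept_r0
    return pairs, r0


def _match_cutoff(p):
    """Reach of an existing bond: its break distance; permanent bonds hold."""
    return p.break_distance if p.breakable else np.inf


def _form_cutoff(p):
    """Bond-formation range: receptors bind only near contact."""
    return 1.1 * p.rest_length if p.rest_length > 0 else 0.5


def refresh_pairs(state: TissueState, ep: EnergyParams) -> TissueState:
    """Rebuild all dynamic pair lists, in place.

    (a) adhesion pairs are persistent-bond re-matched: existing bonds
    survive while within the bond's reach, detached nodes re-pair by mutual
    nearest neighbor within cutoff (one partner per node) — laterally only
    across the fixed shared interfaces of neighboring cells, basally between
    ECM-adherent membrane nodes and the ECM chain, apically between the
    central columnar cells and the squamous layer;
    (b) the volume-exclusion neighbor list is rebuilt from a KD-tree with a
    0.3 μm skin so it stays valid between refreshes;
    (c) contractility pairs are re-selected as the laterally opposed
    membrane-node pairs of each columnar cell lying below the basal-most
    nucleus node minus one node spacing.
    """
    pos = state.pos
    cls = state.node_class
    reg = state.region

    # (a) adhesion re-matching.  Cadherin junctions are established once at
    # build across each shared cell-cell interface (mutual nearest neighbor,
    # one partner per node) and then kept: the junctional network is the
    # sheet's elastic shear memory, and its springs simply exert no force
    # beyond their break distance.  Integrin and interlayer bonds are
    # persistent with contact-limited re-formation (below).
    if state.adhesion_pairs_lateral.size == 0 and state.lateral_interfaces:
        lat_cut = _match_cutoff(ep.lateral_adhesion)
        lat_parts = [
            _mutual_nn_bipartite(pos, a, b, lat_cut)
            for a, b in state.lateral_interfaces
        ]
        lat_parts = [p for p in lat_parts if p.size]
        state.adhesion_pairs_lateral = (
            np.vstack(lat_parts) if lat_parts else np.empty((0, 2), dtype=np.intp)
        )
        state.lateral_r0 = np.full(
            len(state.adhesion_pairs_lateral), ep.lateral_adhesion.rest_length
        )

    if state.has_ecm:
        adherent = np.flatnonzero(state.ecm_adherent & (cls == NodeClass.MEMBRANE))
        ecm_nodes = np.flatnonzero(cls == NodeClass.ECM)
        state.adhesion_pairs_basal, state.basal_r0 = _sticky_rematch(
            pos, state.adhesion_pairs_basal, state.basal_r0,
            [(adherent, ecm_nodes)], _match_cutoff(ep.basal_adhesion),
            _form_cutoff(ep.basal_adhesion), ep.basal_adhesion.rest_length,
        )

    if (
        not state.apical_adhesion_disabled
        and state.squamous_apical_order.size
        and state.adhesion_zone_cells.size
    ):
        col_apical = [
            state.cells[int(ci)].membrane_ring[
                reg[state.cells[int(ci)].membrane_ring] == Region.APICAL
            ]
            for ci in state.adhesion_zone_cells
        ]
        col_apical = np.concatenate(col_apical)
        state.adhesion_pairs_apical, state.apical_r0 = _sticky_rematch(
            pos, state.adhesion_pairs_apical, state.apical_r0,
            [(col_apical, state.squamous_apical_order)],
            _match_cutoff(ep.apical_interlayer_adhesion),
            _form_cutoff(ep.apical_interlayer_adhesion),
            ep.apical_interlayer_adhesion.rest_length,
        )

    # (b) volume-exclusion neighbor list (0.3 μm skin).  E_v pairs:
    # nucleus-membrane within a cell, membrane-membrane of any two
    # membranes except ring-bonded neighbors (a cell's own opposite walls
    # repel, which is what restores cell width when contractility stops),
    # and membrane-ECM.
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=ep.volume_exclusion.cutoff + 0.3, output_type="ndarray")
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        ci, cj = state.cell_id[i], state.cell_id[j]
        cli, clj = cls[i], cls[j]
        nm_same = (
            ((cli == NodeClass.NUCLEUS) & (clj == NodeClass.MEMBRANE))
            | ((cli == NodeClass.MEMBRANE) & (clj == NodeClass.NUCLEUS))
        ) & (ci == cj)
        mm = (cli == NodeClass.MEMBRANE) & (clj == NodeClass.MEMBRANE)
        if mm.any() and state.membrane_bonds.size:
            n = state.n_nodes
            lo = np.minimum(pairs[:, 0], pairs[:, 1])
            hi = np.maximum(pairs[:, 0], pairs[:, 1])
            keys = lo * n + hi
            blo = np.minimum(state.membrane_bonds[:, 0], state.membrane_bonds[:, 1])
            bhi = np.maximum(state.membrane_bonds[:, 0], state.membrane_bonds[:, 1])
            bonded = np.isin(keys, blo * n + bhi)
            mm &= ~bonded
        me = ((cli == NodeClass.MEMBRANE) & (clj == NodeClass.ECM)) | (
            (cli == NodeClass.ECM) & (clj == NodeClass.MEMBRANE)
        )
        pairs = pairs[nm_same | mm | me]
    state.exclusion_pairs = pairs.astype(np.intp, copy=False)

    # (c) contractility pairs below the nucleus
    cont = []
    margin = state.node_spacing
    for ci in state.cells_of_kind("columnar"):
        cell = state.cells[ci]
        if cell.nucleus_nodes.size == 0:
            continue
        ring = cell.membrane_ring
        r = reg[ring]
        left = ring[r == Region.LATERAL_LEFT][::-1]   # basal -> apical
        right = ring[r == Region.LATERAL_RIGHT]       # basal -> apical
        # ring corners stagger the two arcs by one node; align by level
        right = right[1:]
        m = min(left.size, right.size)
        if m == 0:
            continue
        left, right = left[:m], right[:m]
        basal_mid = pos[ring[r == Region.BASAL]].mean(axis=0)
        apical_mid = pos[ring[r == Region.APICAL]].mean(axis=0)
        axis = apical_mid - basal_mid
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            continue
        axis /= nrm
        h_pair = ((pos[left] + pos[right]) / 2 - basal_mid) @ axis
        h_nuc = (pos[cell.nucleus_nodes] - basal_mid) @ axis
        sel = h_pair < h_nuc.min() - margin
        if sel.any():
            cont.append(np.column_stack([left[sel], right[sel]]))
    state.contractility_pairs = (
        np.vstack(cont) if cont else np.empty((0, 2), dtype=np.intp)
    )
    return state


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def _apply_action(action, state, ep, dp):
    """Apply one scheduled perturbation; returns possibly-new (ep, dp)."""
    if isinstance(action, SetKCont):
        ep = ep.with_k_cont(action.value)
    elif isinstance(action, MultiplyEcmDamping):
        mult = dict(dp.ecm_region_multipliers)
        mult[action.region] = mult.get(action.region, 1.0) * action.factor
        dp = DampingParams(dp.C_nuc, dp.C_memb, dp.C_ecm, mult)
    elif isinstance(action, DeleteEcm):
        state.delete_ecm()
    elif isinstance(action, DeleteApicalAdhesion):
        state.delete_apical_adhesion()
    else:
        raise TypeError(f"unknown scenario action {action!r}")
    return ep, dp


def run(
    state: TissueState,
    ep: EnergyParams,
    dp: DampingParams,
    sim: SimConfig,
    schedule=None,
) -> Trajectory:
    """Integrate until curvature convergence or ``max_steps``.

    ``schedule`` (optional) is a scenario specification carrying the initial
    contractility level ``k_cont`` and a list of ``(trigger_time, action)``
    events; events fire once when simulation time passes their trigger.
    The state is advanced in place; the trajectory holds the metric series.
    """
    sim.validate()
    ep = ep.with_k_cont(schedule.k_cont) if schedule is not None else ep
    events = []
    if schedule is not None:
        horizon = state.time + sim.max_steps * sim.dt
        for trig, action in schedule.events:
            if trig is None:
                raise ValueError(
                    "engine.run requires numeric trigger times; convergence-"
                    "triggered events are resolved by scenarios.run_scenario"
                )
            if trig > horizon:
                raise ValueError(
                    f"event at t={trig} lies beyond the run horizon {horizon}"
                )
            events.append([float(trig), action])
        events.sort(key=lambda e: e[0])
    check_stability(ep, dp, sim.dt)

    C = damping_vector(state, dp)
    rng = np.random.default_rng(sim.noise_seed) if sim.noise_sd > 0 else None
    times, curvs, fracs, heights = [], [], [], []
    snapshots = []
    window_samples = max(2, int(np.ceil(sim.convergence_window / sim.output_interval)))
    converged = False
    steps_done = 0

    def record():
        times.append(state.time)
        curvs.append(tissue_global_curvature(state))
        nps = cell_nuclear_positions(state)
        fracs.append(float(np.mean([m.fraction for m in nps])) if nps else np.nan)
        heights.append(float(np.mean([m.height for m in nps])) if nps else np.nan)
        if sim.store_snapshots:
            snapshots.append((state.time, state.pos.copy()))

    if not np.isfinite(state.pos).all():
        bad = int(np.flatnonzero(~np.isfinite(state.pos).all(axis=1))[0])
        raise SimulationBlowUpError(0, bad)
    refresh_pairs(state, ep)
    record()
    for n in range(1, sim.max_steps + 1):
        while events and state.time >= events[0][0] - 0.5 * sim.dt:
            _, action = events.pop(0)
            ep, dp = _apply_action(action, state, ep, dp)
            check_stability(ep, dp, sim.dt)
            refresh_pairs(state, ep)
            C = damping_vector(state, dp)
        step(state, ep, dp, sim.dt, damping=C)
        if rng is not None:
            state.pos += rng.normal(
                scale=sim.noise_sd * np.sqrt(sim.dt), size=state.pos.shape
            )
        steps_done = n
        if n % sim.pair_refresh_interval == 0:
            if not np.isfinite(state.pos).all():
                bad = int(np.flatnonzero(~np.isfinite(state.pos).all(axis=1))[0])
                raise SimulationBlowUpError(n, bad)
            refresh_pairs(state, ep)
        if n % sim.output_interval == 0:
            record()
            if len(curvs) >= window_samples and not events:
                recent = np.array(curvs[-window_samples:])
                scale = max(abs(recent[-1]), sim.curvature_floor)
                if (recent.max() - recent.min()) / scale < sim.convergence_tol:
                    converged = True
                    break

    if not np.isfinite(state.pos).all():
        bad = int(np.flatnonzero(~np.isfinite(state.pos).all(axis=1))[0])
        raise SimulationBlowUpError(steps_done, bad)

    return Trajectory(
        times=np.array(times),
        global_curvature=np.array(curvs),
        mean_nuclear_fraction=np.array(fracs),
        mean_height=np.array(heights),
        final_state=state,
        converged=converged,
        steps_run=steps_done,
        final_k_cont=ep.k_cont,
        snapshots=snapshots,
    )
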