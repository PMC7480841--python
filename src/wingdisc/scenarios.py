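"""The five in-silico experiments, as declarative schedules over the engine.

* baseline — no ECM prestrain, no contractility: a flat tissue stays flat;
* ecm_tension — passive ECM prestrain with the columnar-side ECM (ECMc)
  carrying 4-7x the tension of the squamous-side ECM (ECMs): mild bending;
* contractility — basal actomyosin contractility at 3/6/9 nN/μm, no
  prestrain: bending grows with the contractility level;
* maintenance — bend with high contractility, then switch contractility off
  while multiplying the ECMc drag by 10^3: the ECM "remembers" the shape;
* collagenase — bend, then acutely delete the ECM and switch contractility
  off: the margins curl toward the squamous layer (curvature sign inverts);
* dual — collagenase plus removal of the columnar-squamous interlayer
  adhesion: a gap opens between the two layers at the center.

Events with ``trigger_time=None`` fire when the generation phase has
converged; :func:`run_scenario` resolves them by running two phases of equal
duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .builder import PrestrainSpec, TissueConfig, apply_prestrain, build_tissue, reduced_config
from .engine import (
    DeleteApicalAdhesion,
    DeleteEcm,
    MultiplyEcmDamping,
    SetKCont,
    SimConfig,
    Trajectory,
    run,
)
from .params import (
    DampingParams,
    EnergyParams,
    default_damping_params,
    default_energy_params,
)
from .quantify import (
    point_polyline_distance,
    squamous_apical_polyline,
    tissue_global_curvature,
)
from .state import Region, TissueState

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "GapReport",
    "CONTRACTILITY_LEVELS",
    "scenario_baseline",
    "scenario_ecm_tension",
    "scenario_contractility",
    "scenario_maintenance",
    "scenario_collagenase",
    "scenario_dual_perturbation",
    "scenario_by_name",
    "detect_layer_gap",
    "run_scenario",
]

# low / medium / high basal actomyosin contractility (nN/μm)
CONTRACTILITY_LEVELS = {"low": 3.0, "medium": 6.0, "high": 9.0}

#: default squamous-side ECM tension (nN per spring) for the patterned-ECM
#: experiment; the columnar side carries ratio x this value
DEFAULT_F_ECMS = 0.25

#: standing tension of the squamous (peripodial) layer (nN per long-side
#: membrane bond), present in every scenario: it is the pull that inverts
#: the pouch through the marginal cells once the ECM is removed
DEFAULT_F_SQUAMOUS = 10.0


@dataclass
class ScenarioSpec:
    """Declarative schedule: prestrain, contractility, timed events."""

    name: str
    prestrain: PrestrainSpec = field(default_factory=PrestrainSpec)
    k_cont: float = 0.0
    # (trigger_time AU | None = at convergence, action)
    events: list = field(default_factory=list)

    def validate(self) -> None:
        last = -np.inf
        for trig, action in self.events:
            if trig is not None:
                if trig < last:
                    raise ValueError("event trigger times must be non-decreasing")
                last = trig
            if isinstance(action, MultiplyEcmDamping) and action.region not in (
                "ECMs", "ECMbc", "ECMc"
            ):
                raise ValueError(f"unknown ECM region {action.region!r}")


@dataclass
class GapReport:
    """Interlayer-gap readout over the central adhesion zone."""

    gap_present: bool
    gap_width: float            # μm beyond the adhesion rest separation
    location: tuple[int, int]   # columnar cell index range of the widest gap


@dataclass
class ScenarioResult:
    """Outcome of one scenario run (possibly two phases)."""

    spec: ScenarioSpec
    generation: Trajectory
    post: Trajectory | None
    final_state: TissueState
    switch_curvature: float | None
    final_curvature: float
    gap: GapReport | None


# --------------------------------------------------------------------------
# scenario factories
# --------------------------------------------------------------------------

def scenario_baseline() -> ScenarioSpec:
    """Flat control: no ECM prestrain, no contractility."""
    return ScenarioSpec(
        name="baseline",
        prestrain=PrestrainSpec(F_squamous=DEFAULT_F_SQUAMOUS),
    )


def scenario_ecm_tension(ratio: float, F_ECMs: float = DEFAULT_F_ECMS) -> ScenarioSpec:
    """Patterned passive ECM tension, ECMc carrying ``ratio`` x the ECMs level."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if ratio == 0 and F_ECMs == 0:
        return scenario_baseline()
    return ScenarioSpec(
        name=f"ecm_tension_x{ratio:g}",
        prestrain=PrestrainSpec(
            F_ECMs=F_ECMs, F_ECMc=ratio * F_ECMs,
            F_squamous=DEFAULT_F_SQUAMOUS,
        ),
    )


def scenario_contractility(level: str | float) -> ScenarioSpec:
    """Basal actomyosin contractility at a named or explicit level (nN/μm)."""
    k = CONTRACTILITY_LEVELS.get(level, None) if isinstance(level, str) else float(level)
    if k is None:
        raise ValueError(f"unknown contractility level {level!r}")
    if k < 0:
        raise ValueError("contractility level must be >= 0")
    if k == 0:
        return scenario_baseline()
    return ScenarioSpec(
        name=f"contractility_{k:g}",
        prestrain=PrestrainSpec(F_squamous=DEFAULT_F_SQUAMOUS),
        k_cont=k,
    )


def scenario_maintenance(
    damping_factor: float = 1e3, k_cont: float = CONTRACTILITY_LEVELS["high"]
) -> ScenarioSpec:
    """Bend at high contractility, then rely on a rigidified ECMc.

    At convergence the contractility is switched off and the ECMc drag is
    multiplied by three orders of magnitude; the curved ECM then cannot
    relax on the simulated horizon and holds the tissue shape.  Passing
    ``damping_factor=1`` gives the relaxation control.
    """
    return ScenarioSpec(
        name="maintenance" if damping_factor != 1 else "maintenance_control",
        prestrain=PrestrainSpec(F_squamous=DEFAULT_F_SQUAMOUS),
        k_cont=k_cont,
        events=[
            (None, SetKCont(0.0)),
            (None, MultiplyEcmDamping("ECMc", damping_factor)),
        ],
    )


def scenario_collagenase(k_cont: float = CONTRACTILITY_LEVELS["high"]) -> ScenarioSpec:
    """Bend, then acutely digest the ECM and stop contractility."""
    return ScenarioSpec(
        name="collagenase",
        prestrain=PrestrainSpec(F_squamous=DEFAULT_F_SQUAMOUS),
        k_cont=k_cont,
        events=[(None, DeleteEcm()), (None, SetKCont(0.0))],
    )


def scenario_dual_perturbation(
    k_cont: float = CONTRACTILITY_LEVELS["high"],
) -> ScenarioSpec:
    """Collagenase plus removal of the columnar-squamous adhesion."""
    return ScenarioSpec(
        name="dual",
        prestrain=PrestrainSpec(F_squamous=DEFAULT_F_SQUAMOUS),
        k_cont=k_cont,
        events=[
            (None, DeleteEcm()),
            (None, SetKCont(0.0)),
            (None, DeleteApicalAdhesion()),
        ],
    )


def scenario_by_name(name: str, **kwargs) -> ScenarioSpec:
    factories = {
        "baseline": scenario_baseline,
        "ecm_tension": scenario_ecm_tension,
        "contractility": scenario_contractility,
        "maintenance": scenario_maintenance,
        "collagenase": scenario_collagenase,
        "dual": scenario_dual_perturbation,
    }
    if name not in factories:
        raise ValueError(f"unknown scenario {name!r}")
    return factories[name](**kwargs)


# --------------------------------------------------------------------------
# gap detector
# --------------------------------------------------------------------------

def detect_layer_gap(state: TissueState, threshold: float | None = None,
                     rest_length: float = 1.0) -> GapReport:
    """Measure the apical separation between the two layers at the center.

    For each columnar cell of the central adhesion zone, the distance from
    its apical-arc midpoint to the squamous apical polyline is computed; a
    gap is reported when the largest such distance exceeds ``threshold``
    (default: twice the interlayer adhesion rest length).
    """
    if state.adhesion_zone_cells.size == 0:
        raise ValueError("state has no central adhesion zone")
    if state.squamous_apical_order.size == 0:
        raise ValueError("state has no squamous layer")
    if threshold is None:
        threshold = 2.0 * rest_length
    sq = squamous_apical_polyline(state)
    dists = []
    for ci in state.adhesion_zone_cells:
        ring = state.cells[ci].membrane_ring
        arc = ring[state.region[ring] == Region.APICAL]
        midpoint = state.pos[arc[len(arc) // 2]]
        dists.append(point_polyline_distance(midpoint, sq))
    dists = np.array(dists)
    above = dists > threshold
    if above.any():
        idx = np.flatnonzero(above)
        zone = state.adhesion_zone_cells
        location = (int(zone[idx[0]]), int(zone[idx[-1]]))
    else:
        k = int(np.argmax(dists))
        location = (int(state.adhesion_zone_cells[k]),) * 2
    return GapReport(
        gap_present=bool(above.any()),
        gap_width=float(max(0.0, dists.max() - rest_length)),
        location=location,
    )


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def continue_scenario(
    generation: Trajectory,
    spec: ScenarioSpec,
    ep: EnergyParams | None = None,
    dp: DampingParams | None = None,
    sim: SimConfig | None = None,
    duration: float | None = None,
) -> ScenarioResult:
    """Fire a scenario's convergence-triggered events on a finished run.

    The generation phase is left untouched (its final state is copied), so
    one bent tissue can seed several perturbation scenarios.  The post
    phase runs for ``duration`` AU (default: the generation duration) with
    convergence stopping disabled, so 'holds' and 'relaxes' are judged over
    matched horizons.
    """
    ep = ep if ep is not None else default_energy_params()
    dp = dp if dp is not None else default_damping_params()
    sim = sim if sim is not None else SimConfig()
    deferred = [action for trig, action in spec.events if trig is None]
    if not deferred:
        raise ValueError("spec has no convergence-triggered events")

    state = generation.final_state.copy()
    switch_curv = float(generation.global_curvature[-1])
    if duration is None:
        duration = float(generation.times[-1] - generation.times[0])
    post_steps = max(1, int(round(duration / sim.dt)))
    psim = replace(sim, max_steps=post_steps, convergence_tol=0.0)
    post_spec = ScenarioSpec(
        name=spec.name + "_post",
        k_cont=0.0
        if any(isinstance(a, SetKCont) for a in deferred)
        else generation.final_k_cont,
        events=[(state.time, a) for a in deferred],
    )
    post = run(state, ep, dp, psim, post_spec)
    final_state = post.final_state

    gap = None
    if final_state.squamous_apical_order.size and final_state.adhesion_zone_cells.size:
        gap = detect_layer_gap(
            final_state, rest_length=ep.apical_interlayer_adhesion.rest_length
        )
    return ScenarioResult(
        spec=spec,
        generation=generation,
        post=post,
        final_state=final_state,
        switch_curvature=switch_curv,
        final_curvature=float(post.global_curvature[-1]),
        gap=gap,
    )


def run_scenario(
    spec: ScenarioSpec,
    cfg: TissueConfig | None = None,
    ep: EnergyParams | None = None,
    dp: DampingParams | None = None,
    sim: SimConfig | None = None,
    generation: Trajectory | None = None,
) -> ScenarioResult:
    """Build the tissue, apply prestrain, and run the scenario end to end.

    Events with ``trigger_time=None`` fire after the generation phase has
    converged; the post-switch phase then runs for the same duration as the
    generation phase.  A precomputed ``generation`` trajectory (from a spec
    with the same prestrain and contractility) can be passed to reuse one
    bent tissue across several perturbation scenarios.
    """
    cfg = cfg if cfg is not None else reduced_config()
    ep = ep if ep is not None else default_energy_params()
    dp = dp if dp is not None else default_damping_params()
    sim = sim if sim is not None else SimConfig()
    spec.validate()

    deferred = [action for trig, action in spec.events if trig is None]
    timed = [(trig, action) for trig, action in spec.events if trig is not None]

    if generation is None:
        state = build_tissue(cfg, ep)
        ps = spec.prestrain
        if ps.F_ECMs or ps.F_ECMc or ps.F_ECMbc or ps.F_squamous:
            apply_prestrain(state, ps, ep)
        gen_spec = ScenarioSpec(spec.name, spec.prestrain, spec.k_cont, timed)
        generation = run(state, ep, dp, sim, gen_spec)

    if deferred:
        return continue_scenario(generation, spec, ep, dp, sim)

    final_state = generation.final_state
    gap = None
    if final_state.squamous_apical_order.size and final_state.adhesion_zone_cells.size:
        gap = detect_layer_gap(
            final_state, rest_length=ep.apical_interlayer_adhesion.rest_length
        )
    return ScenarioResult(
        spec=spec,
        generation=generation,
        post=None,
        final_state=final_state,
        switch_curvature=None,
        final_curvature=float(generation.global_curvature[-1]),
        gap=gap,
    )
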