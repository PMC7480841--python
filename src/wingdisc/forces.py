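"""Potential-energy terms and their forces.

The overdamped equations of motion move each node class down the gradient of
its own subset of the nine energy terms:

* nucleus nodes:   E_nuc + E_v
* membrane nodes:  E_memb + E_cont + E_v + E_vol + E_adhL + E_adhB + E_adhA
* ECM nodes:       E_ecm + E_v + E_adhB

All interactions are internal node-node pairs (or the per-cell area penalty,
whose gradient sums to zero over the ring), so the total force over the
system vanishes identically — there are no external fields.

``compute_total_forces`` is the single assembly point used by the
integrator; ``total_energy`` evaluates the matching scalar so forces can be
verified against finite differences.
"""

from __future__ import annotations

import numpy as np

from .params import EnergyParams, MorsePairParams, SpringParams
from .state import Cell, NodeClass, TissueState

__all__ = [
    "DegeneratePairError",
    "morse_force",
    "morse_energy",
    "spring_force",
    "spring_energy",
    "area_constraint_force",
    "compute_total_forces",
    "total_energy",
]

_TINY = 1e-12


class DegeneratePairError(ValueError):
    """Two interacting nodes coincide (zero separation)."""

    def __init__(self, i=None, j=None):
        self.node_ids = (i, j)
        msg = "zero separation between interacting nodes"
        if i is not None:
            msg += f" {i} and {j}"
        super().__init__(msg)


# --------------------------------------------------------------------------
# single-pair reference forms (also used vectorized on (n,) distance arrays)
# --------------------------------------------------------------------------

def _morse_dUdr(d, p: MorsePairParams):
    """dU/dr of U(r) = U0 e^(-r/xi0) - W0 e^(-r/gamma0), zero past cutoff."""
    d = np.asarray(d, dtype=float)
    dU = (
        -p.repulsion_amplitude / p.repulsion_scale * np.exp(-d / p.repulsion_scale)
        + p.attraction_amplitude / p.attraction_scale * np.exp(-d / p.attraction_scale)
    )
    return np.where(d < p.cutoff, dU, 0.0)


def morse_energy(d, p: MorsePairParams):
    """Morse pair energy, shifted to vanish continuously at the cutoff."""
    d = np.asarray(d, dtype=float)

    def U(r):
        return p.repulsion_amplitude * np.exp(-r / p.repulsion_scale) - (
            p.attraction_amplitude * np.exp(-r / p.attraction_scale)
        )

    return np.where(d < p.cutoff, U(d) - U(p.cutoff), 0.0)


def morse_force(r: np.ndarray, p: MorsePairParams) -> np.ndarray:
    """Force on the first node of a Morse pair with separation vector ``r``.

    ``r = x_first - x_second`` (μm); the force is ``-dU/dr * r_hat``:
    repulsive (along +r_hat) at short range, attractive near the attraction
    scale, identically zero at or beyond the cutoff.
    """
    r = np.asarray(r, dtype=float)
    d = float(np.linalg.norm(r))
    if d < _TINY:
        raise DegeneratePairError()
    return (-_morse_dUdr(d, p)) * (r / d)


def spring_energy(d, p: SpringParams):
    """Spring energy 1/2 k (d - r0)^2, frozen beyond the break distance."""
    d = np.asarray(d, dtype=float)
    stretch = d - p.rest_length
    e = 0.5 * p.stiffness * stretch**2
    if p.breakable:
        e_cap = 0.5 * p.stiffness * (p.break_distance - p.rest_length) ** 2
        e = np.where(d > p.break_distance, e_cap, e)
    return e


def spring_force(r: np.ndarray, p: SpringParams) -> np.ndarray:
    """Force on the first node of a spring with separation vector ``r``.

    Magnitude ``k (|r| - r0)`` directed to restore the rest length; zero
    beyond the break distance for breakable springs.  For a zero-rest-length
    spring the zero-separation force is the zero vector.
    """
    r = np.asarray(r, dtype=float)
    d = float(np.linalg.norm(r))
    if d < _TINY:
        if p.rest_length == 0.0:
            return np.zeros_like(r)
        raise DegeneratePairError()
    if p.breakable and d > p.break_distance:
        return np.zeros_like(r)
    return -p.stiffness * (d - p.rest_length) * (r / d)


# --------------------------------------------------------------------------
# area (2D volume) constraint
# --------------------------------------------------------------------------

def _polygon_self_intersects(poly: np.ndarray) -> bool:
    """O(n^2) segment-crossing test for small rings (validation only)."""
    n = len(poly)
    seg = [(poly[i], poly[(i + 1) % n]) for i in range(n)]

    def crosses(a, b, c, d):
        def orient(p, q, r):
            return np.sign((q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0]))

        return (
            orient(a, b, c) * orient(a, b, d) < 0
            and orient(c, d, a) * orient(c, d, b) < 0
        )

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if crosses(*seg[i], *seg[j]):
                return True
    return False


def area_constraint_force(
    cell: Cell, state: TissueState, k_vol: float, *, check: bool = True
) -> np.ndarray:
    """Forces of the quadratic area penalty on one cell's membrane ring.

    ``E_vol = 1/2 k_vol (A - A0)^2`` with ``A`` the signed shoelace area of
    the ring; returns a ``(n_ring, 2)`` array aligned with
    ``cell.membrane_ring``.  The gradient of the shoelace area sums to zero
    around the ring, so the penalty exerts no net force on the cell.
    """
    ring = cell.membrane_ring
    if ring.size < 3:
        raise ValueError("cell polygon needs at least 3 vertices")
    poly = state.pos[ring]
    nxt = np.roll(poly, -1, axis=0)
    prv = np.roll(poly, 1, axis=0)
    area = 0.5 * np.sum(poly[:, 0] * nxt[:, 1] - nxt[:, 0] * poly[:, 1])
    if check:
        if abs(area) < _TINY:
            raise ValueError("zero-area polygon in area constraint")
        if _polygon_self_intersects(poly):
            import warnings

            warnings.warn(
                "self-intersecting cell polygon: area sign may be locally wrong",
                RuntimeWarning,
                stacklevel=2,
            )
    grad = 0.5 * np.column_stack([nxt[:, 1] - prv[:, 1], prv[:, 0] - nxt[:, 0]])
    return -k_vol * (area - cell.target_area) * grad


# --------------------------------------------------------------------------
# vectorized assembly
# --------------------------------------------------------------------------

def _scatter(F: np.ndarray, i: np.ndarray, j: np.ndarray, f: np.ndarray) -> None:
    """Accumulate pair forces: +f on i, -f on j (Newton's third law)."""
    n = F.shape[0]
    F[:, 0] += np.bincount(i, weights=f[:, 0], minlength=n)
    F[:, 1] += np.bincount(i, weights=f[:, 1], minlength=n)
    F[:, 0] -= np.bincount(j, weights=f[:, 0], minlength=n)
    F[:, 1] -= np.bincount(j, weights=f[:, 1], minlength=n)


def _pair_geometry(pos, pairs, allow_zero: bool):
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = pos[i] - pos[j]
    d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
    if not allow_zero and d.size and d.min() < _TINY:
        k = int(np.argmin(d))
        raise DegeneratePairError(int(i[k]), int(j[k]))
    return i, j, dvec, d


def _add_spring_set(F, pos, pairs, k, r0, break_distance=None):
    if pairs.size == 0 or k == 0.0:
        return
    r0 = np.asarray(r0, dtype=float)
    allow_zero = bool(np.all(r0 == 0.0))
    i, j, dvec, d = _pair_geometry(pos, pairs, allow_zero)
    d_safe = np.where(d < _TINY, 1.0, d)
    mag = -k * (d - r0) / d_safe  # per-pair scalar multiplying dvec
    if break_distance is not None:
        mag = np.where(d > break_distance, 0.0, mag)
    _scatter(F, i, j, mag[:, None] * dvec)


def _add_morse_set(F, pos, pairs, p: MorsePairParams):
    if pairs.size == 0:
        return
    i, j, dvec, d = _pair_geometry(pos, pairs, allow_zero=False)
    mag = -_morse_dUdr(d, p) / d
    _scatter(F, i, j, mag[:, None] * dvec)


def compute_total_forces(state: TissueState, ep: EnergyParams) -> np.ndarray:
    """Assemble the total force on every node (nN).

    Each node class receives exactly the terms of its equation of motion;
    every pairwise interaction contributes equal and opposite forces, so the
    vector sum over all nodes is zero to round-off.
    """
    pos = state.pos
    F = np.zeros_like(pos)

    # Morse terms
    _add_morse_set(F, pos, state.nucleus_pairs, ep.nucleus)           # E_nuc
    _add_morse_set(F, pos, state.exclusion_pairs, ep.volume_exclusion)  # E_v

    # bonded springs; E_memb has a stretching part (nearest neighbors) and a
    # bending part (second neighbors at their as-built separations)
    _add_spring_set(F, pos, state.membrane_bonds, ep.membrane.stiffness,
                    state.membrane_r0)                                 # E_memb
    _add_spring_set(F, pos, state.membrane_bending_bonds,
                    ep.membrane_bending_stiffness, state.membrane_bending_r0)
    _add_spring_set(F, pos, state.ecm_bonds, ep.ecm.stiffness, state.ecm_r0)  # E_ecm
    _add_spring_set(F, pos, state.ecm_bending_bonds,
                    ep.ecm_bending_stiffness, state.ecm_bending_r0)

    # adhesion springs (breakable)
    _add_spring_set(F, pos, state.adhesion_pairs_lateral,
                    ep.lateral_adhesion.stiffness, state.lateral_r0,
                    ep.lateral_adhesion.break_distance
                    if ep.lateral_adhesion.breakable else None)        # E_adhL
    _add_spring_set(F, pos, state.adhesion_pairs_basal,
                    ep.basal_adhesion.stiffness, state.basal_r0,
                    ep.basal_adhesion.break_distance
                    if ep.basal_adhesion.breakable else None)          # E_adhB
    _add_spring_set(F, pos, state.adhesion_pairs_apical,
                    ep.apical_interlayer_adhesion.stiffness, state.apical_r0,
                    ep.apical_interlayer_adhesion.break_distance
                    if ep.apical_interlayer_adhesion.breakable else None)  # E_adhA

    # basal actomyosin contractility: zero-rest-length springs across the cell
    _add_spring_set(F, pos, state.contractility_pairs,
                    ep.contractility.stiffness,
                    np.full(len(state.contractility_pairs), ep.contractility.rest_length))  # E_cont

    # area (volume) conservation, vectorized over all rings at once
    k_vol = ep.area_constraint_stiffness
    if k_vol > 0.0 and state.cells:
        rs = state.ring_structure()
        nodes = rs["nodes"]
        p = pos[nodes]
        pn = pos[nodes[rs["next"]]]
        pp = pos[nodes[rs["prev"]]]
        cross = p[:, 0] * pn[:, 1] - pn[:, 0] * p[:, 1]
        areas = 0.5 * np.add.reduceat(cross, rs["offsets"])
        targets = np.array([c.target_area for c in state.cells])
        coeff = -k_vol * (areas - targets)  # per cell
        grad = 0.5 * np.column_stack([pn[:, 1] - pp[:, 1], pp[:, 0] - pn[:, 0]])
        f = coeff[rs["cell"]][:, None] * grad
        np.add.at(F, nodes, f)

    return F


def total_energy(state: TissueState, ep: EnergyParams) -> float:
    """Total potential energy matching :func:`compute_total_forces`."""
    pos = state.pos
    E = 0.0

    def pair_d(pairs):
        dvec = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        return np.sqrt(np.einsum("ij,ij->i", dvec, dvec))

    if state.nucleus_pairs.size:
        E += morse_energy(pair_d(state.nucleus_pairs), ep.nucleus).sum()
    if state.exclusion_pairs.size:
        E += morse_energy(pair_d(state.exclusion_pairs), ep.volume_exclusion).sum()

    def spring_sum(pairs, p: SpringParams, r0):
        if pairs.size == 0 or p.stiffness == 0.0:
            return 0.0
        d = pair_d(pairs)
        stretch = d - np.asarray(r0, dtype=float)
        e = 0.5 * p.stiffness * stretch**2
        if p.breakable:
            cap = 0.5 * p.stiffness * (p.break_distance - np.asarray(r0, dtype=float)) ** 2
            e = np.where(d > p.break_distance, cap, e)
        return e.sum()

    E += spring_sum(state.membrane_bonds, ep.membrane, state.membrane_r0)
    E += spring_sum(
        state.membrane_bending_bonds,
        SpringParams(stiffness=ep.membrane_bending_stiffness),
        state.membrane_bending_r0,
    )
    E += spring_sum(state.ecm_bonds, ep.ecm, state.ecm_r0)
    E += spring_sum(
        state.ecm_bending_bonds,
        SpringParams(stiffness=ep.ecm_bending_stiffness),
        state.ecm_bending_r0,
    )
    E += spring_sum(state.adhesion_pairs_lateral, ep.lateral_adhesion, state.lateral_r0)
    E += spring_sum(state.adhesion_pairs_basal, ep.basal_adhesion, state.basal_r0)
    E += spring_sum(state.adhesion_pairs_apical, ep.apical_interlayer_adhesion,
                    state.apical_r0)
    E += spring_sum(
        state.contractility_pairs,
        ep.contractility,
        np.full(len(state.contractility_pairs), ep.contractility.rest_length),
    )

    if ep.area_constraint_stiffness > 0.0 and state.cells:
        areas = state.cell_areas()
        targets = np.array([c.target_area for c in state.cells])
        E += 0.5 * ep.area_constraint_stiffness * np.sum((areas - targets) ** 2)
    return float(E)
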