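"""Shape metrics for wing-disc cross-sections.

Operates on point sets — surface polylines and nucleus centers — whether
they come from the simulator or from segmented images:

* global curvature: signed reciprocal circumradius of the circle through
  the two endpoints and the arc-length midpoint of a surface polyline
  (the circumcircle approach);
* local curvature profile: Menger curvature (4A / abc of the triangle
  through three points) evaluated over a sliding arc-length window;
* fractional apicobasal nuclear position L_B/(L_A+L_B), 0 at the basal
  surface and 1 at the apical surface, and cell height L_A + L_B;
* asymptotic plateau fit c(t) = c_inf - a exp(-t/tau) used to declare
  convergence of the curvature time series.

Sign convention (dome-positive): curvature is positive when the pouch bows
away from the squamous layer.  For a polyline ordered left to right with
the squamous layer on the +y side, that is a counter-clockwise turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SurfacePolyline",
    "NuclearPositionMetric",
    "MengerProfile",
    "ShapeMetrics",
    "circumcircle_curvature",
    "global_curvature",
    "menger_profile",
    "nuclear_position",
    "asymptotic_fit",
    "point_polyline_distance",
]


@dataclass
class SurfacePolyline:
    """Ordered 2D points tracing one epithelial surface."""

    points: np.ndarray
    surface_tag: str = "basal"  # 'apical' | 'basal'

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("polyline must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("polyline needs at least 3 points")
        if (np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0).any():
            raise ValueError("consecutive polyline points must be distinct")
        if self.surface_tag not in ("apical", "basal"):
            raise ValueError("surface_tag must be 'apical' or 'basal'")


@dataclass
class NuclearPositionMetric:
    """Apicobasal position of one nucleus between the two surfaces."""

    L_A: float        # distance nucleus center -> apical surface (μm)
    L_B: float        # distance nucleus center -> basal surface (μm)
    fraction: float   # L_B / (L_A + L_B): 0 basal, 1 apical
    height: float     # L_A + L_B (μm)
    clamped: bool = False  # center fell outside the slab and was clamped


@dataclass
class MengerProfile:
    """Local curvature at interior polyline points (window fitted)."""

    point_index: np.ndarray  # indices into the input polyline
    arc_length: np.ndarray   # arc-length coordinate of each point (μm)
    curvature: np.ndarray    # Menger curvature (μm^-1)


@dataclass
class ShapeMetrics:
    """Bundle of per-tissue shape statistics."""

    global_curvature: float
    local_profile: MengerProfile | None
    nuclear_fractions: np.ndarray
    heights: np.ndarray
    plateau_curvature: float | None = None
    fit_residual: float | None = None


# --------------------------------------------------------------------------
# curvature
# --------------------------------------------------------------------------

def circumcircle_curvature(p1, p2, p3) -> float:
    """Signed curvature 1/R of the circumcircle through three points.

    ``kappa = 4 * signed_area(p1,p2,p3) / (|p1p2| |p2p3| |p3p1|)``; the sign
    follows the triangle orientation (counter-clockwise positive).  Collinear
    points give 0; duplicate points are an error.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p1)
    b = np.linalg.norm(p3 - p2)
    c = np.linalg.norm(p1 - p3)
    if min(a, b, c) == 0.0:
        raise ValueError("circumcircle curvature needs three distinct points")
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    return float(2.0 * cross / (a * b * c))


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arc_length(points: np.ndarray, s: float) -> np.ndarray:
    cs = _arc_lengths(points)
    s = float(np.clip(s, 0.0, cs[-1]))
    k = int(np.searchsorted(cs, s, side="right") - 1)
    k = min(k, len(points) - 2)
    seg = cs[k + 1] - cs[k]
    t = 0.0 if seg == 0 else (s - cs[k]) / seg
    return points[k] + t * (points[k + 1] - points[k])


def global_curvature(
    surface: SurfacePolyline | np.ndarray, window: float | None = None
) -> float:
    """Signed circumcircle curvature of (first, arc-length midpoint, last).

    With the polyline ordered left to right and the squamous layer above,
    positive values are the wild-type dome (basal surface bowing away from
    the squamous layer).  Passing a ``window`` half-width (μm) switches to
    the window-averaged alternative: the mean Menger curvature over a
    sliding +-window along the polyline.
    """
    pts = surface.points if isinstance(surface, SurfacePolyline) else np.asarray(surface, float)
    if len(pts) < 3:
        raise ValueError("polyline needs at least 3 points")
    if window is not None:
        return float(menger_profile(pts, window).curvature.mean())
    mid = _point_at_arc_length(pts, 0.5 * _arc_lengths(pts)[-1])
    if np.allclose(mid, pts[0]) or np.allclose(mid, pts[-1]):
        return 0.0
    return circumcircle_curvature(pts[0], mid, pts[-1])


def menger_profile(
    surface: SurfacePolyline | np.ndarray, window_halfwidth: float
) -> MengerProfile:
    """Menger curvature at each interior point over a +-w arc-length window.

    At each point p with arc-length coordinate s such that both s - w and
    s + w lie on the polyline, the curvature of the circle through the
    (linearly interpolated) points at s - w, s, s + w is reported; endpoints
    where the window does not fit are omitted.
    """
    pts = surface.points if isinstance(surface, SurfacePolyline) else np.asarray(surface, float)
    cs = _arc_lengths(pts)
    total = cs[-1]
    w = float(window_halfwidth)
    if 2 * w > total:
        raise ValueError("polyline shorter than the Menger window")
    mean_spacing = total / (len(pts) - 1)
    if w < 2 * mean_spacing:
        raise ValueError("window halfwidth must be at least two point spacings")
    idx = np.flatnonzero((cs >= w) & (cs <= total - w))
    kappa = np.empty(idx.size)
    for out_i, i in enumerate(idx):
        p_minus = _point_at_arc_length(pts, cs[i] - w)
        p_plus = _point_at_arc_length(pts, cs[i] + w)
        kappa[out_i] = circumcircle_curvature(p_minus, pts[i], p_plus)
    return MengerProfile(point_index=idx, arc_length=cs[idx], curvature=kappa)


# --------------------------------------------------------------------------
# nuclear position
# --------------------------------------------------------------------------

def point_polyline_distance(point: np.ndarray, polyline: np.ndarray) -> float:
    """Minimum distance from a point to a piecewise-linear curve."""
    p = np.asarray(point, dtype=float)
    pts = np.asarray(polyline, dtype=float)
    if len(pts) == 1:
        return float(np.linalg.norm(p - pts[0]))
    a = pts[:-1]
    b = pts[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


def nuclear_position(
    apical: SurfacePolyline | np.ndarray,
    basal: SurfacePolyline | np.ndarray,
    center: np.ndarray,
) -> NuclearPositionMetric:
    """Fractional apicobasal position and height of one nucleus.

    ``L_A`` and ``L_B`` are the perpendicular (nearest-point) distances from
    the nucleus center to the apical and basal surfaces; the fraction
    ``L_B / (L_A + L_B)`` is 0 on the basal surface and 1 on the apical
    surface; the cell height is ``L_A + L_B``.
    """
    ap = apical.points if isinstance(apical, SurfacePolyline) else np.asarray(apical, float)
    ba = basal.points if isinstance(basal, SurfacePolyline) else np.asarray(basal, float)
    L_A = point_polyline_distance(center, ap)
    L_B = point_polyline_distance(center, ba)
    height = L_A + L_B
    if height <= 0.0:
        raise ValueError("degenerate cell: apical and basal surfaces coincide")
    fraction = L_B / height
    clamped = False
    if not 0.0 <= fraction <= 1.0:  # numerically impossible, kept for safety
        fraction = float(np.clip(fraction, 0.0, 1.0))
        clamped = True
    return NuclearPositionMetric(L_A, L_B, fraction, height, clamped)


# --------------------------------------------------------------------------
# tissue-level wrappers (simulation states)
# --------------------------------------------------------------------------

def pouch_basal_polyline(state) -> np.ndarray:
    """Basal surface of the columnar pouch, ordered left to right."""
    return state.pos[state.pouch_basal_order]


def pouch_apical_polyline(state) -> np.ndarray:
    return state.pos[state.pouch_apical_order]


def squamous_apical_polyline(state) -> np.ndarray:
    return state.pos[state.squamous_apical_order]


def tissue_global_curvature(state) -> float:
    """Dome-positive global curvature of the basal pouch surface.

    The experimental pipeline segments and quantifies the basal surface of
    the pouch; the same surface is used here.  The polyline order is fixed
    at build time (left to right, squamous layer on the +y side), so a
    counter-clockwise turn — the basal surface bowing away from the
    squamous layer, the wild-type dome — is positive.  The inverted
    profile, margins curling toward the squamous layer after ECM digestion,
    is negative.
    """
    return global_curvature(pouch_basal_polyline(state))


def cell_nuclear_positions(state) -> list[NuclearPositionMetric]:
    """Per-columnar-cell nuclear position against the cell's own surfaces.

    The nucleus center is the centroid of the cell's nucleus-node cluster;
    the apical and basal references are the cell's own membrane arcs.
    """
    from .state import Region

    out = []
    for ci in state.cells_of_kind("columnar"):
        cell = state.cells[ci]
        if cell.nucleus_nodes.size == 0:
            continue
        ring = cell.membrane_ring
        reg = state.region[ring]
        apical = state.pos[ring[reg == Region.APICAL]]
        basal = state.pos[ring[reg == Region.BASAL]]
        center = state.nucleus_centroid(ci)
        out.append(nuclear_position(apical, basal, center))
    return out


def tissue_shape_metrics(state, menger_window: float | None = 5.0) -> ShapeMetrics:
    """Global curvature, local profile, and per-cell nuclear statistics."""
    basal = pouch_basal_polyline(state)
    profile = None
    if menger_window is not None:
        try:
            profile = menger_profile(basal, menger_window)
        except ValueError:
            profile = None
    nps = cell_nuclear_positions(state)
    return ShapeMetrics(
        global_curvature=global_curvature(basal),
        local_profile=profile,
        nuclear_fractions=np.array([m.fraction for m in nps]),
        heights=np.array([m.height for m in nps]),
    )


# --------------------------------------------------------------------------
# convergence fit
# --------------------------------------------------------------------------

def asymptotic_fit(times, curvatures):
    """Least-squares fit of c(t) = c_inf - a exp(-t / tau).

    Returns ``(c_inf, tau, residual)`` with the residual being the RMS
    misfit normalized by the larger of |c_inf| and the series range.  A fit
    that fails to converge is flagged with residual = inf.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(curvatures, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 samples")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")

    span = float(c.max() - c.min())
    scale = max(abs(c[-1]), span, 1e-12)
    if span == 0.0:  # constant series: exact plateau
        return float(c[-1]), float(t[-1] - t[0]), 0.0

    t0 = t[0]

    def model(p, tt):
        c_inf, a, log_tau = p
        return c_inf - a * np.exp(-(tt - t0) / np.exp(log_tau))

    p0 = np.array([c[-1], c[-1] - c[0], np.log(max((t[-1] - t0) / 3.0, 1e-6))])
    try:
        sol = least_squares(lambda p: model(p, t) - c, p0, max_nfev=2000)
    except Exception:
        return float(c[-1]), float("nan"), float("inf")
    if not sol.success:
        return float(c[-1]), float("nan"), float("inf")
    c_inf, _a, log_tau = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return float(c_inf), float(np.exp(log_tau)), rms / scale
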