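"""Construction of the initial flat wing-disc cross-section.

The built tissue matches the calibrated geometry: a row of tall columnar
pouch cells, marginal boundary cells closing each side, a squamous
(peripodial) layer above the pouch with the lumen between the two apical
surfaces, and a three-region ECM chain (ECMs over the squamous layer, ECMbc
around the margins, ECMc under the pouch) wrapping the entire basal
perimeter.  Nuclei of columnar cells start apically biased.

Every bonded spring (membrane rings, ECM chain, adhesion pairs) is
initialized exactly at its rest length and every Morse pair beyond its
cutoff, so the construct is force-free at t = 0; ECM prestrain is then
applied by shortening ECM rest lengths (:func:`apply_prestrain`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import EnergyParams, default_energy_params
from .state import Cell, NodeClass, Region, TissueState

__all__ = [
    "TissueConfig",
    "PrestrainSpec",
    "build_tissue",
    "apply_prestrain",
    "make_arc_fixture",
    "full_config",
    "reduced_config",
    "mini_config",
]


@dataclass
class TissueConfig:
    """Geometry of the initial cross-section (lengths in μm).

    ``columnar_width`` is the lattice pitch of the pouch; the cell polygon is
    inset by half the ``lateral_gap`` on each side so that neighboring
    membranes sit one adhesion rest length apart.  ``squamous_width`` is
    nominal: the squamous layer tiles the pouch span exactly, so the actual
    width is ``n_columnar*columnar_width / n_squamous``.
    """

    n_columnar: int = 65
    columnar_width: float = 2.5
    columnar_height: float = 25.0
    n_squamous: int = 10
    squamous_width: float = 16.0
    squamous_height: float = 4.0
    n_boundary_per_side: int = 2
    membrane_node_spacing: float = 0.5
    nucleus_nodes_per_cell: int = 10
    initial_nuclear_fraction: float = 0.65
    ecm_node_spacing: float = 0.5
    rng_seed: int = 0
    # inter-membrane spacings (equal to the adhesion rest lengths)
    lateral_gap: float = 0.8
    lumen_gap: float = 1.0
    ecm_gap: float = 0.8
    # fraction of central columnar cells tied to the squamous layer (E_adhA)
    adhesion_zone_fraction: float = 0.2
    # extra material length of the squamous-side ECM, stored as waves: the
    # basement membrane is loose around the peripodium but taut around the
    # pouch, so the ECMs run is built sinusoidal with this fractional slack
    # while ECMbc and ECMc are straight and taut-length
    ecms_slack_fraction: float = 0.15
    ecms_wave_length: float = 5.0  # μm per wave of the loose ECMs

    def validate(self) -> None:
        if min(self.n_columnar, self.n_squamous, self.n_boundary_per_side,
               self.nucleus_nodes_per_cell) < 1:
            raise ValueError("all counts must be >= 1")
        for name in ("columnar_width", "columnar_height", "squamous_width",
                     "squamous_height", "membrane_node_spacing",
                     "ecm_node_spacing", "lateral_gap", "lumen_gap", "ecm_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.initial_nuclear_fraction < 1.0:
            raise ValueError("initial_nuclear_fraction must be in (0, 1)")
        if not 0.0 < self.adhesion_zone_fraction <= 1.0:
            raise ValueError("adhesion_zone_fraction must be in (0, 1]")


def full_config(**overrides) -> TissueConfig:
    """Full calibrated geometry: 65 columnar cells of 2.5 x 25 μm."""
    return replace(TissueConfig(), **overrides)


def reduced_config(**overrides) -> TissueConfig:
    """Reduced-resolution preset for desk-scale runs.

    17 columnar cells at 1.25 μm node spacing; the squamous layer keeps its
    nominal cell width by tiling the narrower pouch with 3 cells.
    """
    cfg = TissueConfig(
        n_columnar=17,
        n_squamous=3,
        membrane_node_spacing=1.25,
        ecm_node_spacing=1.25,
    )
    return replace(cfg, **overrides)


def mini_config(**overrides) -> TissueConfig:
    """Very small rig for fast tests and the sensitivity screen."""
    cfg = TissueConfig(
        n_columnar=9,
        n_squamous=2,
        membrane_node_spacing=1.25,
        ecm_node_spacing=1.25,
        nucleus_nodes_per_cell=6,
        n_boundary_per_side=1,
    )
    return replace(cfg, **overrides)


@dataclass
class PrestrainSpec:
    """Per-spring tension (nN) carried by each ECM region at t = 0.

    ``F_squamous`` is the standing tension of the squamous (peripodial)
    layer itself, carried by the long-side membrane bonds of squamous
    cells.  It models the taut peripodial membrane whose pull on the
    margins is what inverts the pouch once the ECM is digested.
    """

    F_ECMs: float = 0.0
    F_ECMc: float = 0.0
    F_ECMbc: float | None = None  # defaults to F_ECMs
    F_squamous: float = 0.0

    def __post_init__(self) -> None:
        if self.F_ECMbc is None:
            self.F_ECMbc = self.F_ECMs
        if min(self.F_ECMs, self.F_ECMc, self.F_ECMbc, self.F_squamous) < 0:
            raise ValueError("prestrain tensions must be >= 0")

    def tension(self, region_code: int) -> float:
        return {
            Region.ECMS: self.F_ECMs,
            Region.ECMBC: self.F_ECMbc,
            Region.ECMC: self.F_ECMc,
        }[region_code]


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _rect_ring(xl, xr, yb, yt, spacing):
    """CCW rectangle ring starting at the bottom-left corner.

    Returns (points, side_codes) with side codes 0=bottom, 1=right, 2=top,
    3=left; each corner belongs to the side it starts.
    """
    nx = max(2, round((xr - xl) / spacing))
    ny = max(2, round((yt - yb) / spacing))
    xs = np.linspace(xl, xr, nx + 1)
    ys = np.linspace(yb, yt, ny + 1)
    pts, side = [], []
    for x in xs[:-1]:
        pts.append((x, yb)); side.append(0)
    for y in ys[:-1]:
        pts.append((xr, y)); side.append(1)
    for x in xs[:0:-1]:
        pts.append((x, yt)); side.append(2)
    for y in ys[:0:-1]:
        pts.append((xl, y)); side.append(3)
    return np.array(pts), np.array(side)


def _resample_polyline(vertices, spacing):
    """Points along a piecewise-linear path, landing on every vertex."""
    pts = [np.asarray(vertices[0], dtype=float)]
    for a, b in zip(vertices[:-1], vertices[1:]):
        a, b = np.asarray(a, float), np.asarray(b, float)
        seg = np.linalg.norm(b - a)
        n = max(1, round(seg / spacing))
        for k in range(1, n + 1):
            pts.append(a + (b - a) * k / n)
    return np.array(pts)


def _wavy_segment(a, b, spacing, slack_fraction, wave_length):
    """Sinusoidal polyline from a to b carrying extra material length.

    The wave amplitude is solved so the arc length exceeds the chord by
    ``slack_fraction``; a slack segment built this way is force-free (all
    bonds at rest) yet can lengthen by unbending its waves, which is how a
    loose basement membrane behaves.  ``slack_fraction=0`` gives a straight
    segment.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    chord = np.linalg.norm(b - a)
    if slack_fraction <= 0.0 or chord == 0.0:
        return _resample_polyline([a, b], spacing)
    n_waves = max(1, round(chord / wave_length))
    t_hat = (b - a) / chord
    n_hat = np.array([-t_hat[1], t_hat[0]])

    def wave(amp, s):
        # swings outward only, with both ends exactly on the chord
        return amp * (1.0 - np.cos(2 * np.pi * n_waves * s / chord))

    def length_factor(amp):
        s = np.linspace(0.0, chord, 2001)
        y = wave(amp, s)
        return np.sum(np.hypot(np.diff(s), np.diff(y))) / chord

    lo, hi = 0.0, chord
    target = 1.0 + slack_fraction
    for _ in range(60):
        mid = (lo + hi) / 2
        if length_factor(mid) < target:
            lo = mid
        else:
            hi = mid
    amp = (lo + hi) / 2
    # sample densely along the wave, then resample to the node spacing
    s = np.linspace(0.0, chord, 4001)
    pts = a + s[:, None] * t_hat + wave(amp, s)[:, None] * n_hat
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n_nodes = max(2, round(arc[-1] / spacing) + 1)
    targets = np.linspace(0.0, arc[-1], n_nodes)
    out = np.column_stack([
        np.interp(targets, arc, pts[:, 0]),
        np.interp(targets, arc, pts[:, 1]),
    ])
    return out


def morse_equilibrium_distance(p) -> float:
    """Separation where the Morse force vanishes (closed form)."""
    return math.log(
        (p.repulsion_amplitude * p.attraction_scale)
        / (p.attraction_amplitude * p.repulsion_scale)
    ) / (1.0 / p.repulsion_scale - 1.0 / p.attraction_scale)


def _nucleus_cluster(center, m, spacing):
    """m nucleus nodes in a vertical column with the given spacing.

    Columnar-cell nuclei are elongated along the apicobasal axis; a single
    column whose adjacent nodes sit exactly at the Morse equilibrium of
    E_nuc (non-adjacent pairs beyond its cutoff) is force-free at build and
    its centroid lies exactly at ``center``, making the initial fractional
    position exact.
    """
    cx, cy = center
    ys = cy + (np.arange(m) - (m - 1) / 2) * spacing
    return np.column_stack([np.full(m, cx), ys])


# --------------------------------------------------------------------------
# build
# --------------------------------------------------------------------------

def build_tissue(cfg: TissueConfig, ep: EnergyParams | None = None) -> TissueState:
    """Construct the flat cross-section described by ``cfg``.

    The returned state is force-free under ``ep`` (all bonded springs at
    rest, all Morse pairs beyond cutoff, all cell areas at target) and has
    zero global curvature.
    """
    cfg.validate()
    ep = ep if ep is not None else default_energy_params()

    w = cfg.columnar_width
    H = cfg.columnar_height
    g = cfg.lateral_gap
    lumen = cfg.lumen_gap
    hs = cfg.squamous_height
    pouch_w = cfg.n_columnar * w
    nb = cfg.n_boundary_per_side
    y_sq_b, y_sq_t = H + lumen, H + lumen + hs  # squamous bottom/top

    pos_list: list[np.ndarray] = []
    cls_list: list[np.ndarray] = []
    cell_list: list[np.ndarray] = []
    reg_list: list[np.ndarray] = []
    adh_list: list[np.ndarray] = []
    cells: list[Cell] = []
    next_id = 0

    def add_nodes(pts, cls, cell, reg, adherent):
        nonlocal next_id
        n = len(pts)
        pos_list.append(np.asarray(pts, float))
        cls_list.append(np.full(n, cls, dtype=np.int8))
        cell_list.append(np.full(n, cell, dtype=np.int32))
        reg_list.append(np.asarray(reg, dtype=np.int8))
        adh_list.append(np.asarray(adherent, dtype=bool))
        ids = np.arange(next_id, next_id + n)
        next_id += n
        return ids

    def add_cell(kind, xl, xr, yb, yt, *, flip_ab, adherent_sides, nucleus_frac=None):
        """Add one rectangular cell; flip_ab swaps apical/basal tags."""
        cid = len(cells)
        pts, side = _rect_ring(xl, xr, yb, yt, cfg.membrane_node_spacing)
        if flip_ab:  # squamous: apical faces down (lumen), basal faces up
            tag_map = {0: Region.APICAL, 2: Region.BASAL}
        else:
            tag_map = {0: Region.BASAL, 2: Region.APICAL}
        tag_map.update({1: Region.LATERAL_RIGHT, 3: Region.LATERAL_LEFT})
        regs = np.array([tag_map[s] for s in side])
        adherent = np.isin(side, adherent_sides)
        ring_ids = add_nodes(pts, NodeClass.MEMBRANE, cid, regs, adherent)

        nuc_ids = np.empty(0, dtype=np.intp)
        if nucleus_frac is not None:
            spacing = morse_equilibrium_distance(ep.nucleus)
            center = ((xl + xr) / 2, yb + nucleus_frac * (yt - yb))
            npts = _nucleus_cluster(center, cfg.nucleus_nodes_per_cell, spacing)
            nuc_ids = add_nodes(
                npts,
                NodeClass.NUCLEUS,
                cid,
                np.full(len(npts), Region.NONE),
                np.zeros(len(npts), bool),
            )
        area = (xr - xl) * (yt - yb)
        cells.append(Cell(kind, ring_ids, nuc_ids, area))
        return cid

    # columnar pouch: lattice pitch w, polygons inset by g/2
    columnar_ids = []
    for i in range(cfg.n_columnar):
        x0 = i * w
        columnar_ids.append(
            add_cell(
                "columnar", x0 + g / 2, x0 + w - g / 2, 0.0, H,
                flip_ab=False, adherent_sides=(0,),
                nucleus_frac=cfg.initial_nuclear_fraction,
            )
        )

    # marginal boundary cells spanning both layers (y = 0 .. squamous top)
    for s in range(nb):  # left side, outermost first
        x0 = -(nb - s) * w
        add_cell("boundary", x0 + g / 2, x0 + w - g / 2, 0.0, y_sq_t,
                 flip_ab=False, adherent_sides=(0, 2, 3) if s == 0 else (0, 2))
    for s in range(nb):  # right side
        x0 = pouch_w + s * w
        add_cell("boundary", x0 + g / 2, x0 + w - g / 2, 0.0, y_sq_t,
                 flip_ab=False,
                 adherent_sides=(0, 1, 2) if s == nb - 1 else (0, 2))

    # squamous layer tiling the pouch span, apical surface facing the lumen
    ws = pouch_w / cfg.n_squamous
    squamous_ids = []
    for i in range(cfg.n_squamous):
        x0 = i * ws
        squamous_ids.append(
            add_cell("squamous", x0 + g / 2, x0 + ws - g / 2, y_sq_b, y_sq_t,
                     flip_ab=True, adherent_sides=(2,))
        )

    # ECM chain: ECMs over the squamous layer, down around the margins
    # (ECMbc), under the pouch (ECMc), and back up the far margin (ECMbc)
    d = cfg.ecm_gap
    x_l = -nb * w + g / 2 - d
    x_r = pouch_w + nb * w - g / 2 + d
    y_t = y_sq_t + d
    y_b = -d
    top = _wavy_segment(
        (x_l, y_t), (x_r, y_t), cfg.ecm_node_spacing,
        cfg.ecms_slack_fraction, cfg.ecms_wave_length,
    )
    right = _resample_polyline([(x_r, y_t), (x_r, y_b)], cfg.ecm_node_spacing)[1:]
    bottom = _resample_polyline([(x_r, y_b), (x_l, y_b)], cfg.ecm_node_spacing)[1:]
    left = _resample_polyline([(x_l, y_b), (x_l, y_t)], cfg.ecm_node_spacing)[1:-1]
    chain_pts = np.vstack([top, right, bottom, left])
    chain_reg = np.concatenate([
        np.full(len(top), Region.ECMS),
        np.full(len(right), Region.ECMBC),
        np.full(len(bottom), Region.ECMBC),  # refined below for the pouch span
        np.full(len(left), Region.ECMBC),
    ])
    # bottom nodes under the columnar span are ECMc
    under_pouch = (
        (np.abs(chain_pts[:, 1] - y_b) < 1e-9)
        & (chain_pts[:, 0] > 0.0 - 1e-9)
        & (chain_pts[:, 0] < pouch_w + 1e-9)
    )
    chain_reg[under_pouch] = Region.ECMC
    ecm_ids = add_nodes(
        chain_pts, NodeClass.ECM, -1, chain_reg, np.zeros(len(chain_pts), bool)
    )

    pos = np.vstack(pos_list)
    state = TissueState(
        pos=pos,
        node_class=np.concatenate(cls_list),
        cell_id=np.concatenate(cell_list),
        region=np.concatenate(reg_list),
        cells=cells,
        ecm_chain=np.asarray(ecm_ids, dtype=np.intp),
        ecm_adherent=np.concatenate(adh_list),
        node_spacing=cfg.membrane_node_spacing,
    )

    # bonded springs at rest: membrane rings and the ECM chain
    mb, mr0, mb2, mr0_2 = [], [], [], []
    for cell in cells:
        ring = cell.membrane_ring
        nxt = np.roll(ring, -1)
        mb.append(np.column_stack([ring, nxt]))
        mr0.append(np.linalg.norm(pos[nxt] - pos[ring], axis=1))
        # second-neighbor springs encode the ring's resting angles
        nxt2 = np.roll(ring, -2)
        mb2.append(np.column_stack([ring, nxt2]))
        mr0_2.append(np.linalg.norm(pos[nxt2] - pos[ring], axis=1))
    state.membrane_bonds = np.vstack(mb)
    state.membrane_r0 = np.concatenate(mr0)
    state.membrane_bending_bonds = np.vstack(mb2)
    state.membrane_bending_r0 = np.concatenate(mr0_2)
    eb = np.column_stack([ecm_ids[:-1], ecm_ids[1:]])
    state.ecm_bonds = eb
    state.ecm_r0 = np.linalg.norm(pos[eb[:, 1]] - pos[eb[:, 0]], axis=1)
    # rod-like straightness springs along straight chain runs only: second-
    # and fourth-neighbor bonds suppress crumpling and short-wavelength
    # serpentines while the global single-arc mode stays essentially free;
    # corners and the loose wavy ECMs remain unsprung hinges
    eb2, eb2_r0 = [], []
    ids = np.asarray(ecm_ids)
    seg = pos[ids[1:]] - pos[ids[:-1]]
    seg_u = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    straight = np.einsum("ij,ij->i", seg_u[:-1], seg_u[1:]) > np.cos(np.deg2rad(15.0))
    for offset in (2, 4):
        for k in range(len(ids) - offset):
            if straight[k:k + offset - 1].all():
                eb2.append((ids[k], ids[k + offset]))
                eb2_r0.append(float(np.linalg.norm(pos[ids[k + offset]] - pos[ids[k]])))
    state.ecm_bending_bonds = (
        np.array(eb2, dtype=np.intp) if eb2 else np.empty((0, 2), dtype=np.intp)
    )
    state.ecm_bending_r0 = np.array(eb2_r0)

    # nucleus cohesion: all pairs within each cell's cluster
    npairs = []
    for cell in cells:
        nn = cell.nucleus_nodes
        if nn.size >= 2:
            ii, jj = np.triu_indices(nn.size, k=1)
            npairs.append(np.column_stack([nn[ii], nn[jj]]))
    state.nucleus_pairs = (
        np.vstack(npairs) if npairs else np.empty((0, 2), dtype=np.intp)
    )

    # central adhesion zone: the central fraction of columnar cells
    n_zone = max(1, round(cfg.adhesion_zone_fraction * cfg.n_columnar))
    mid = cfg.n_columnar // 2
    lo = max(0, mid - n_zone // 2)
    state.adhesion_zone_cells = np.asarray(
        columnar_ids[lo:lo + n_zone], dtype=np.intp
    )

    # ordered surface polylines (topological order, stable under motion)
    def arc_nodes(cell_ids, region_code, reverse_per_cell=False):
        out = []
        for cid in cell_ids:
            ring = cells[cid].membrane_ring
            sel = ring[state.region[ring] == region_code]
            out.append(sel[::-1] if reverse_per_cell else sel)
        return np.concatenate(out)

    state.pouch_basal_order = arc_nodes(columnar_ids, Region.BASAL)
    # apical arcs run right-to-left in ring order; flip for left-to-right
    state.pouch_apical_order = arc_nodes(columnar_ids, Region.APICAL, True)
    state.squamous_apical_order = arc_nodes(squamous_ids, Region.APICAL)

    # fixed shared interfaces between neighboring cells: cadherin junctions
    # are matched only across these walls, never across the tissue
    def wall(cid, region_code):
        ring = cells[cid].membrane_ring
        return ring[state.region[ring] == region_code]

    n_col = cfg.n_columnar
    left_b = list(range(n_col, n_col + nb))              # outermost -> innermost
    right_b = list(range(n_col + nb, n_col + 2 * nb))    # innermost -> outermost
    interfaces: list[tuple[np.ndarray, np.ndarray]] = []

    def link(cid_a, cid_b):
        interfaces.append((wall(cid_a, Region.LATERAL_RIGHT),
                           wall(cid_b, Region.LATERAL_LEFT)))

    for i in range(n_col - 1):
        link(columnar_ids[i], columnar_ids[i + 1])
    for s in range(nb - 1):
        link(left_b[s], left_b[s + 1])
        link(right_b[s + 1], right_b[s])
    link(left_b[-1], columnar_ids[0])        # inner-left boundary | pouch
    link(columnar_ids[-1], right_b[0])       # pouch | inner-right boundary
    link(left_b[-1], squamous_ids[0])        # inner-left boundary | squamous
    link(squamous_ids[-1], right_b[0])       # squamous | inner-right boundary
    for i in range(cfg.n_squamous - 1):
        link(squamous_ids[i], squamous_ids[i + 1])
    state.lateral_interfaces = interfaces

    # dynamic pairs: match adhesion/contractility/exclusion, then set every
    # adhesion rest length to the as-built distance (zero initial force)
    from .engine import refresh_pairs

    refresh_pairs(state, ep)
    for pairs_attr, r0_attr in (
        ("adhesion_pairs_lateral", "lateral_r0"),
        ("adhesion_pairs_basal", "basal_r0"),
        ("adhesion_pairs_apical", "apical_r0"),
    ):
        pairs = getattr(state, pairs_attr)
        if pairs.size:
            d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
            setattr(state, r0_attr, d)

    _check_no_overlap(state)
    state.validate_topology()
    return state


def _check_no_overlap(state: TissueState) -> None:
    """Reject constructions whose cell rectangles overlap."""
    boxes = []
    for i in range(len(state.cells)):
        poly = state.cell_polygon(i)
        boxes.append((poly[:, 0].min(), poly[:, 0].max(),
                      poly[:, 1].min(), poly[:, 1].max()))
    for a in range(len(boxes)):
        for b in range(a + 1, len(boxes)):
            xl = max(boxes[a][0], boxes[b][0])
            xr = min(boxes[a][1], boxes[b][1])
            yb = max(boxes[a][2], boxes[b][2])
            yt = min(boxes[a][3], boxes[b][3])
            if xl < xr - 1e-9 and yb < yt - 1e-9:
                raise ValueError(f"constructed cells {a} and {b} overlap")


def apply_prestrain(
    state: TissueState, spec: PrestrainSpec, ep: EnergyParams
) -> TissueState:
    """Load the ECM chain with region-wise tension, in place.

    Each chain spring in region R has its rest length shortened to
    ``r0 = r_init - F_R / k_ecm`` so that it carries tension exactly ``F_R``
    at the as-built geometry (tension is encoded as rest-length offset).
    """
    if not state.has_ecm:
        raise ValueError("state has no ECM chain")
    k = ep.ecm.stiffness
    if k <= 0:
        raise ValueError("ECM stiffness must be positive to carry prestrain")
    # a chain spring takes the region of its more interior endpoint: ECMc
    # wins over ECMbc so the pouch span is fully loaded
    reg_i = state.region[state.ecm_bonds[:, 0]]
    reg_j = state.region[state.ecm_bonds[:, 1]]
    for bond_idx in range(len(state.ecm_bonds)):
        region = int(max(reg_i[bond_idx], reg_j[bond_idx]))
        F = spec.tension(region)
        if F == 0.0:
            continue
        shortening = F / k
        if shortening >= state.ecm_r0[bond_idx]:
            raise ValueError(
                f"prestrain {F} nN exceeds what spring {bond_idx} can carry "
                f"(rest length {state.ecm_r0[bond_idx]:.3f} μm, k={k})"
            )
        state.ecm_r0[bond_idx] -= shortening

    if spec.F_squamous > 0.0:
        k_m = ep.membrane.stiffness
        if k_m <= 0:
            raise ValueError("membrane stiffness must be positive for squamous tension")
        squamous = set(state.cells_of_kind("squamous"))
        i, j = state.membrane_bonds[:, 0], state.membrane_bonds[:, 1]
        long_side = np.isin(state.region[i], (Region.APICAL, Region.BASAL)) & (
            state.region[i] == state.region[j]
        )
        target = long_side & np.isin(state.cell_id[i], list(squamous))
        shortening = spec.F_squamous / k_m
        if np.any(state.membrane_r0[target] <= shortening):
            raise ValueError("F_squamous exceeds what the membrane bonds can carry")
        state.membrane_r0[target] -= shortening
    return state


def make_arc_fixture(
    radius: float,
    span_angle: float = math.pi / 2,
    n_points: int = 100,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Analytic circular-arc polyline with known curvature (test fixture).

    Returns ``(points, true_curvature)``; ``radius=np.inf`` produces a
    straight segment with curvature 0.  Isotropic Gaussian noise of sd
    ``noise_sd`` is added when requested.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    if not np.isinf(radius) and radius <= 0:
        raise ValueError("radius must be positive (or inf for a line)")
    if np.isinf(radius):
        xs = np.linspace(0.0, 10.0 * max(1, n_points // 10), n_points)
        pts = np.column_stack([xs, np.zeros_like(xs)])
        kappa = 0.0
    else:
        theta = np.linspace(-span_angle / 2, span_angle / 2, n_points)
        pts = radius * np.column_stack([np.sin(theta), -np.cos(theta)])
        kappa = 1.0 / radius
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    return pts, kappa
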