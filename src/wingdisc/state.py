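"""Array-backed tissue state for the subcellular-element model.

The state of the cross-section is a set of typed nodes (nucleus, membrane,
ECM) with positions in the plane, grouped into cells, plus the bonded
topology (membrane rings, ECM chain) and the dynamic interaction pair lists
(adhesion, contractility, volume exclusion).  Everything the force kernel
touches is stored as flat NumPy arrays so a time step is a handful of
vectorized operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NodeClass", "Region", "Cell", "TissueState"]


class NodeClass:
    """Integer codes for the three node types."""

    NUCLEUS = 0
    MEMBRANE = 1
    ECM = 2

    NAMES = {NUCLEUS: "nucleus", MEMBRANE: "membrane", ECM: "ecm"}
    CODES = {v: k for k, v in NAMES.items()}


class Region:
    """Integer codes for membrane arcs and ECM chain regions."""

    NONE = -1
    APICAL = 0
    BASAL = 1
    LATERAL_LEFT = 2
    LATERAL_RIGHT = 3
    ECMS = 4   # ECM over the squamous layer
    ECMBC = 5  # ECM around the marginal boundary cells
    ECMC = 6   # ECM under the columnar pouch

    NAMES = {
        NONE: "none",
        APICAL: "apical",
        BASAL: "basal",
        LATERAL_LEFT: "lateral_left",
        LATERAL_RIGHT: "lateral_right",
        ECMS: "ECMs",
        ECMBC: "ECMbc",
        ECMC: "ECMc",
    }
    CODES = {v: k for k, v in NAMES.items()}
    ECM_REGIONS = (ECMS, ECMBC, ECMC)


@dataclass
class Cell:
    """One cell: ordered membrane ring, nucleus node cluster, target area.

    ``membrane_ring`` is a simple closed polygon traversed counter-clockwise,
    so its shoelace area is positive.  ``target_area`` is the conserved 2D
    "volume" of the cytoplasm.  Squamous and boundary cells may have an empty
    nucleus cluster (only columnar nuclei are modeled and quantified).
    """

    kind: str  # 'columnar' | 'boundary' | 'squamous'
    membrane_ring: np.ndarray  # (n,) node ids, CCW order
    nucleus_nodes: np.ndarray  # (m,) node ids (may be empty)
    target_area: float

    def __post_init__(self) -> None:
        self.membrane_ring = np.asarray(self.membrane_ring, dtype=np.intp)
        self.nucleus_nodes = np.asarray(self.nucleus_nodes, dtype=np.intp)
        if self.kind not in ("columnar", "boundary", "squamous"):
            raise ValueError(f"unknown cell kind {self.kind!r}")


def _empty_pairs() -> np.ndarray:
    return np.empty((0, 2), dtype=np.intp)


@dataclass
class TissueState:
    """Positions plus typed topology of all nodes of the cross-section."""

    pos: np.ndarray                 # (N, 2) float64, μm
    node_class: np.ndarray          # (N,) int8, NodeClass codes
    cell_id: np.ndarray             # (N,) int32, -1 for ECM nodes
    region: np.ndarray              # (N,) int8, Region codes
    cells: list[Cell]
    ecm_chain: np.ndarray           # ordered ECM node ids, open polyline
    # membrane nodes eligible for integrin (cell-ECM) adhesion matching
    ecm_adherent: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    # typical bonded node spacing (μm); sets the contractility-zone margin
    node_spacing: float = 0.5
    # bonded springs (never re-matched)
    membrane_bonds: np.ndarray = field(default_factory=_empty_pairs)
    membrane_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    # second-neighbor cortex springs (bending stiffness of each ring)
    membrane_bending_bonds: np.ndarray = field(default_factory=_empty_pairs)
    membrane_bending_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    ecm_bonds: np.ndarray = field(default_factory=_empty_pairs)
    ecm_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    # second-neighbor chain springs along straight ECM runs (rod behavior)
    ecm_bending_bonds: np.ndarray = field(default_factory=_empty_pairs)
    ecm_bending_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    # dynamic adhesion / contractility pairs with per-pair rest lengths
    adhesion_pairs_lateral: np.ndarray = field(default_factory=_empty_pairs)
    lateral_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    adhesion_pairs_basal: np.ndarray = field(default_factory=_empty_pairs)
    basal_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    adhesion_pairs_apical: np.ndarray = field(default_factory=_empty_pairs)
    apical_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    contractility_pairs: np.ndarray = field(default_factory=_empty_pairs)
    # volume-exclusion neighbor list (rebuilt by refresh_pairs)
    exclusion_pairs: np.ndarray = field(default_factory=_empty_pairs)
    # nucleus-cohesion pairs (static all-pairs within each cell's cluster)
    nucleus_pairs: np.ndarray = field(default_factory=_empty_pairs)
    time: float = 0.0
    # ordered columnar basal / apical membrane node ids (set by the builder;
    # topological order is stable under deformation)
    pouch_basal_order: np.ndarray = field(default_factory=lambda: np.empty(0, np.intp))
    pouch_apical_order: np.ndarray = field(default_factory=lambda: np.empty(0, np.intp))
    squamous_apical_order: np.ndarray = field(default_factory=lambda: np.empty(0, np.intp))
    # columnar cell ids connected to the squamous layer by E_adhA
    adhesion_zone_cells: np.ndarray = field(default_factory=lambda: np.empty(0, np.intp))
    # fixed cell-adjacency wall pairs for lateral adhesion matching:
    # list of (nodes_a, nodes_b) membrane-node id arrays, one per shared
    # interface between neighboring cells (junctions do not hop interfaces)
    lateral_interfaces: list = field(default_factory=list)
    # set when the interlayer adhesion machinery has been abolished
    apical_adhesion_disabled: bool = False
    # cached concatenated-ring structure for the vectorized area force
    _ring_cache: dict | None = field(default=None, repr=False)

    # -- basic views -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.pos.shape[0]

    def nodes_of_class(self, cls: int) -> np.ndarray:
        return np.flatnonzero(self.node_class == cls)

    @property
    def has_ecm(self) -> bool:
        return self.ecm_chain.size > 0

    def cells_of_kind(self, kind: str) -> list[int]:
        return [i for i, c in enumerate(self.cells) if c.kind == kind]

    # -- ring structure ----------------------------------------------------

    def ring_structure(self) -> dict:
        """Concatenated membrane-ring arrays for the vectorized area term.

        Returns node ids, the concat-index of each vertex's ring successor
        and predecessor, per-vertex cell index, and reduceat offsets.
        """
        if self._ring_cache is None:
            nodes, nxt, prv, cell_idx, offsets = [], [], [], [], []
            base = 0
            for ci, cell in enumerate(self.cells):
                ring = cell.membrane_ring
                n = ring.size
                idx = np.arange(n)
                nodes.append(ring)
                nxt.append(base + (idx + 1) % n)
                prv.append(base + (idx - 1) % n)
                cell_idx.append(np.full(n, ci, dtype=np.intp))
                offsets.append(base)
                base += n
            self._ring_cache = {
                "nodes": np.concatenate(nodes),
                "next": np.concatenate(nxt),
                "prev": np.concatenate(prv),
                "cell": np.concatenate(cell_idx),
                "offsets": np.array(offsets, dtype=np.intp),
            }
        return self._ring_cache

    def cell_areas(self) -> np.ndarray:
        """Signed shoelace area of every cell's membrane ring (μm²)."""
        rs = self.ring_structure()
        p = self.pos[rs["nodes"]]
        pn = self.pos[rs["nodes"][rs["next"]]]
        cross = p[:, 0] * pn[:, 1] - pn[:, 0] * p[:, 1]
        return 0.5 * np.add.reduceat(cross, rs["offsets"])

    def cell_polygon(self, cell_index: int) -> np.ndarray:
        return self.pos[self.cells[cell_index].membrane_ring]

    def nucleus_centroid(self, cell_index: int) -> np.ndarray:
        nn = self.cells[cell_index].nucleus_nodes
        if nn.size == 0:
            raise ValueError(f"cell {cell_index} has no nucleus nodes")
        return self.pos[nn].mean(axis=0)

    # -- copying / editing -------------------------------------------------

    def copy(self) -> "TissueState":
        return TissueState(
            pos=self.pos.copy(),
            node_class=self.node_class.copy(),
            cell_id=self.cell_id.copy(),
            region=self.region.copy(),
            cells=[
                Cell(c.kind, c.membrane_ring.copy(), c.nucleus_nodes.copy(), c.target_area)
                for c in self.cells
            ],
            ecm_chain=self.ecm_chain.copy(),
            ecm_adherent=self.ecm_adherent.copy(),
            node_spacing=self.node_spacing,
            membrane_bonds=self.membrane_bonds.copy(),
            membrane_r0=self.membrane_r0.copy(),
            membrane_bending_bonds=self.membrane_bending_bonds.copy(),
            membrane_bending_r0=self.membrane_bending_r0.copy(),
            ecm_bonds=self.ecm_bonds.copy(),
            ecm_r0=self.ecm_r0.copy(),
            ecm_bending_bonds=self.ecm_bending_bonds.copy(),
            ecm_bending_r0=self.ecm_bending_r0.copy(),
            adhesion_pairs_lateral=self.adhesion_pairs_lateral.copy(),
            lateral_r0=self.lateral_r0.copy(),
            adhesion_pairs_basal=self.adhesion_pairs_basal.copy(),
            basal_r0=self.basal_r0.copy(),
            adhesion_pairs_apical=self.adhesion_pairs_apical.copy(),
            apical_r0=self.apical_r0.copy(),
            contractility_pairs=self.contractility_pairs.copy(),
            exclusion_pairs=self.exclusion_pairs.copy(),
            nucleus_pairs=self.nucleus_pairs.copy(),
            time=self.time,
            pouch_basal_order=self.pouch_basal_order.copy(),
            pouch_apical_order=self.pouch_apical_order.copy(),
            squamous_apical_order=self.squamous_apical_order.copy(),
            adhesion_zone_cells=self.adhesion_zone_cells.copy(),
            lateral_interfaces=[(a.copy(), b.copy()) for a, b in self.lateral_interfaces],
            apical_adhesion_disabled=self.apical_adhesion_disabled,
        )

    def delete_ecm(self) -> None:
        """Remove every ECM node and all bonds/pairs touching it, in place.

        Models acute collagenase digestion of the basement membrane.  Node
        ids are compacted; all topology arrays are remapped.
        """
        keep = self.node_class != NodeClass.ECM
        if keep.all():
            return
        old_ids = np.flatnonzero(keep)
        remap = np.full(self.n_nodes, -1, dtype=np.intp)
        remap[old_ids] = np.arange(old_ids.size)

        self.pos = self.pos[keep]
        self.node_class = self.node_class[keep]
        self.cell_id = self.cell_id[keep]
        self.region = self.region[keep]
        self.ecm_adherent = self.ecm_adherent[keep]
        for cell in self.cells:
            cell.membrane_ring = remap[cell.membrane_ring]
            cell.nucleus_nodes = remap[cell.nucleus_nodes]
        self.ecm_chain = np.empty(0, dtype=np.intp)
        self.ecm_bonds = _empty_pairs()
        self.ecm_r0 = np.empty(0)
        self.ecm_bending_bonds = _empty_pairs()
        self.ecm_bending_r0 = np.empty(0)
        self.adhesion_pairs_basal = _empty_pairs()
        self.basal_r0 = np.empty(0)
        self.membrane_bonds = remap[self.membrane_bonds]
        self.membrane_bending_bonds = remap[self.membrane_bending_bonds]

        def _remap_pairs(pairs: np.ndarray, *r0s: np.ndarray):
            if pairs.size == 0:
                return (pairs, *r0s)
            ok = keep[pairs[:, 0]] & keep[pairs[:, 1]]
            return (remap[pairs[ok]], *(r0[ok] for r0 in r0s))

        self.adhesion_pairs_lateral, self.lateral_r0 = _remap_pairs(
            self.adhesion_pairs_lateral, self.lateral_r0
        )
        self.adhesion_pairs_apical, self.apical_r0 = _remap_pairs(
            self.adhesion_pairs_apical, self.apical_r0
        )
        (self.contractility_pairs,) = _remap_pairs(self.contractility_pairs)
        (self.exclusion_pairs,) = _remap_pairs(self.exclusion_pairs)
        (self.nucleus_pairs,) = _remap_pairs(self.nucleus_pairs)
        self.pouch_basal_order = remap[self.pouch_basal_order]
        self.pouch_apical_order = remap[self.pouch_apical_order]
        self.squamous_apical_order = remap[self.squamous_apical_order]
        self.lateral_interfaces = [
            (remap[a], remap[b]) for a, b in self.lateral_interfaces
        ]
        self._ring_cache = None

    def delete_apical_adhesion(self) -> None:
        """Remove all columnar-squamous interlayer adhesion (E_adhA).

        Also disables re-formation: the perturbation abolishes the adhesion
        machinery, not just the current bonds.
        """
        self.adhesion_pairs_apical = _empty_pairs()
        self.apical_r0 = np.empty(0)
        self.apical_adhesion_disabled = True

    # -- validation --------------------------------------------------------

    def validate_topology(self) -> None:
        """Check the structural invariants of the node/cell data model."""
        n = self.n_nodes
        for name in ("membrane_bonds", "ecm_bonds", "adhesion_pairs_lateral",
                     "adhesion_pairs_basal", "adhesion_pairs_apical",
                     "contractility_pairs", "nucleus_pairs"):
            pairs = getattr(self, name)
            if pairs.size and (pairs.min() < 0 or pairs.max() >= n):
                raise ValueError(f"{name} references nonexistent nodes")
        # membership: every membrane/nucleus node in exactly one cell
        owner = np.full(n, -1, dtype=np.int64)
        for ci, cell in enumerate(self.cells):
            for ids in (cell.membrane_ring, cell.nucleus_nodes):
                if ids.size and (owner[ids] != -1).any():
                    raise ValueError("node assigned to more than one cell")
                owner[ids] = ci
            if cell.target_area <= 0:
                raise ValueError("cell target_area must be positive")
        cls = self.node_class
        if (owner[cls == NodeClass.MEMBRANE] < 0).any():
            raise ValueError("membrane node belongs to no cell")
        if (owner[cls == NodeClass.NUCLEUS] < 0).any():
            raise ValueError("nucleus node belongs to no cell")
        if (owner[cls == NodeClass.ECM] != -1).any():
            raise ValueError("ECM nodes must not belong to a cell")
        # pair class constraints
        if self.adhesion_pairs_basal.size:
            i, j = self.adhesion_pairs_basal.T
            if not ((cls[i] == NodeClass.MEMBRANE) & (cls[j] == NodeClass.ECM)).all():
                raise ValueError("basal adhesion pairs must be membrane-ECM")
        if self.adhesion_pairs_lateral.size:
            i, j = self.adhesion_pairs_lateral.T
            same = self.cell_id[i] == self.cell_id[j]
            if not ((cls[i] == NodeClass.MEMBRANE) & (cls[j] == NodeClass.MEMBRANE)).all():
                raise ValueError("lateral adhesion pairs must be membrane-membrane")
            if same.any():
                raise ValueError("lateral adhesion pairs must join distinct cells")
        if self.contractility_pairs.size:
            i, j = self.contractility_pairs.T
            if (self.cell_id[i] != self.cell_id[j]).any():
                raise ValueError("contractility pairs must be within one cell")
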