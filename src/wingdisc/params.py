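"""Energy and damping parameters of the subcellular-element model.

Every interaction in the model is one of nine potential-energy terms:

====== ==================== ==============================================
term   type                 physical representation
====== ==================== ==============================================
E_v    Morse                volume exclusion between node types
E_nuc  Morse                cohesion / size of the nucleus node cluster
E_adhL spring               E-cadherin cell-cell adhesion (lateral)
E_adhB spring               integrin cell-ECM adhesion (basal)
E_adhA spring               columnar-squamous interlayer adhesion (apical)
E_cont spring               basal actomyosin contractility (k_cont)
E_memb spring               membrane cortex stiffness (bonded ring)
E_ecm  spring               extracellular-matrix stiffness (bonded chain)
E_vol  quadratic area       cytoplasm volume (2D: area) conservation
====== ==================== ==============================================

Units: lengths in μm, forces in nN, stiffnesses in nN/μm, the area-penalty
stiffness in nN/μm^3, time in arbitrary units (AU).  Damping coefficients
(nN·AU/μm) absorb the time scale.

Defaults below are the package's calibration of the model: they are chosen
so that the calibrated tissue reproduces the measured wing-disc phenotype
(apically biased nuclei near 70 %, bending driven by basal contractility at
3–9 nN/μm, ECM-tension-only bending mild in comparison).  All of them can be
overridden from a YAML parameter file (:func:`load_params`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, TextIO

import yaml

__all__ = [
    "MorsePairParams",
    "SpringParams",
    "EnergyParams",
    "DampingParams",
    "default_energy_params",
    "default_damping_params",
    "load_params",
    "dump_params",
]


@dataclass
class MorsePairParams:
    """Two-exponential Morse pair potential.

    ``U(r) = U0 exp(-r/xi0) - W0 exp(-r/gamma0)``, hard cutoff beyond
    ``cutoff``.  Short-range repulsion (scale ``xi0``) plus longer-range
    attraction (scale ``gamma0``).
    """

    repulsion_amplitude: float  # U0, nN
    repulsion_scale: float      # xi0, μm
    attraction_amplitude: float  # W0, nN
    attraction_scale: float     # gamma0, μm
    cutoff: float               # μm

    def validate(self) -> None:
        if not (self.repulsion_amplitude > 0 and self.attraction_amplitude > 0):
            raise ValueError("Morse amplitudes must be strictly positive")
        if not (self.repulsion_scale > 0 and self.attraction_scale > 0):
            raise ValueError("Morse length scales must be strictly positive")
        if not self.repulsion_scale < self.attraction_scale:
            raise ValueError(
                "Morse repulsion scale must be shorter than attraction scale "
                f"(got xi0={self.repulsion_scale}, gamma0={self.attraction_scale})"
            )
        if not self.cutoff >= self.attraction_scale:
            raise ValueError("Morse cutoff must be >= attraction scale")


@dataclass
class SpringParams:
    """Linear spring ``E = 1/2 k (|r| - r0)^2``, optionally breakable.

    A breakable spring exerts no force beyond ``break_distance`` (adhesion
    bonds can detach); permanent bonds (membrane ring, ECM chain) never break.
    """

    stiffness: float           # k, nN/μm
    rest_length: float = 0.0   # r0, μm
    breakable: bool = False
    break_distance: float | None = None  # μm, required if breakable

    def validate(self) -> None:
        if self.stiffness < 0:
            raise ValueError("spring stiffness must be >= 0")
        if self.rest_length < 0:
            raise ValueError("spring rest length must be >= 0")
        if self.breakable and (
            self.break_distance is None or self.break_distance <= 0
        ):
            raise ValueError("breakable spring needs a positive break_distance")


@dataclass
class EnergyParams:
    """Coefficients of all nine energy terms."""

    volume_exclusion: MorsePairParams   # E_v
    nucleus: MorsePairParams            # E_nuc
    membrane: SpringParams              # E_memb, nearest-neighbor cortex bonds
    # E_memb bending part: second-neighbor springs along each membrane ring
    # at their as-built rest lengths.  They give the cortex angular
    # stiffness, i.e. the cell's elastic memory of its resting shape;
    # without them a sheet of cells shears freely and any bent configuration
    # is a zero-energy ground state.
    membrane_bending_stiffness: float   # nN/μm
    lateral_adhesion: SpringParams      # E_adhL
    basal_adhesion: SpringParams        # E_adhB
    apical_interlayer_adhesion: SpringParams  # E_adhA
    contractility: SpringParams         # E_cont, stiffness = k_cont, r0 = 0
    ecm: SpringParams                   # E_ecm, nearest-neighbor chain bonds
    # E_ecm bending part: second-neighbor springs along straight chain runs.
    # The taut basement membrane behaves like a rod: inextensible, resistant
    # to short-wavelength crumpling, yet free to bend at tissue scale (and
    # free to hinge at corners and to unfold the loose wavy ECMs, which
    # carry no second-neighbor springs).
    ecm_bending_stiffness: float        # nN/μm
    area_constraint_stiffness: float    # k_vol, nN/μm^3 (E_vol)

    def validate(self) -> None:
        self.volume_exclusion.validate()
        self.nucleus.validate()
        for sp in (
            self.membrane,
            self.lateral_adhesion,
            self.basal_adhesion,
            self.apical_interlayer_adhesion,
            self.contractility,
            self.ecm,
        ):
            sp.validate()
        if self.area_constraint_stiffness < 0:
            raise ValueError("area constraint stiffness must be >= 0")
        if self.membrane_bending_stiffness < 0:
            raise ValueError("membrane bending stiffness must be >= 0")
        if self.ecm_bending_stiffness < 0:
            raise ValueError("ECM bending stiffness must be >= 0")

    @property
    def k_cont(self) -> float:
        """Basal actomyosin contractility level (nN/μm)."""
        return self.contractility.stiffness

    def with_k_cont(self, k_cont: float) -> "EnergyParams":
        return replace(self, contractility=replace(self.contractility, stiffness=k_cont))

    def max_spring_stiffness(self) -> float:
        return max(
            self.membrane.stiffness,
            self.membrane_bending_stiffness,
            self.lateral_adhesion.stiffness,
            self.basal_adhesion.stiffness,
            self.apical_interlayer_adhesion.stiffness,
            self.contractility.stiffness,
            self.ecm.stiffness,
            self.ecm_bending_stiffness,
        )


@dataclass
class DampingParams:
    """Per-node-class drag coefficients of the overdamped equations.

    ``ecm_region_multipliers`` scales the ECM drag per region (the shape-
    maintenance scenario multiplies the ECMc drag by 10^3).
    """

    C_nuc: float = 1.0   # nN·AU/μm
    C_memb: float = 1.0
    C_ecm: float = 1.0
    ecm_region_multipliers: dict[str, float] = field(
        default_factory=lambda: {"ECMs": 1.0, "ECMbc": 1.0, "ECMc": 1.0}
    )

    def validate(self) -> None:
        if not (self.C_nuc > 0 and self.C_memb > 0 and self.C_ecm > 0):
            raise ValueError("damping coefficients must be strictly positive")
        for region, m in self.ecm_region_multipliers.items():
            if region not in ("ECMs", "ECMbc", "ECMc"):
                raise ValueError(f"unknown ECM region {region!r}")
            if m <= 0:
                raise ValueError("ECM damping multipliers must be strictly positive")

    def min_damping(self) -> float:
        return min(self.C_nuc, self.C_memb, self.C_ecm)


def default_energy_params() -> EnergyParams:
    """Calibrated defaults (see docs/methods.md for the rationale)."""
    return EnergyParams(
        # Pure-exclusion regime: equilibrium distance of the pair lies beyond
        # the cutoff, so the term is repulsive over its whole active range.
        volume_exclusion=MorsePairParams(
            repulsion_amplitude=2.0,
            repulsion_scale=0.2,
            attraction_amplitude=0.1,
            attraction_scale=0.45,
            cutoff=0.7,
        ),
        # Equilibrium spacing ~0.8 μm; adjacent cluster nodes sit exactly at
        # equilibrium and diagonals beyond the cutoff, so a freshly built
        # nucleus is force-free.
        nucleus=MorsePairParams(
            repulsion_amplitude=2.0,
            repulsion_scale=0.3,
            attraction_amplitude=1.0,
            attraction_scale=0.8,
            cutoff=1.0,
        ),
        membrane=SpringParams(stiffness=10.0, rest_length=0.0),  # r0 set per bond
        membrane_bending_stiffness=30.0,
        # E-cadherin junctions between neighboring cells persist through the
        # basal pinching of the contractility scenarios; they are what keeps
        # a cell's width loss from collapsing the whole lateral gap
        lateral_adhesion=SpringParams(
            stiffness=15.0, rest_length=0.8, breakable=True, break_distance=4.0
        ),
        # integrin anchorage of the basal surface to the basement membrane is
        # firm (high integrin intensity under the pouch): the bond survives
        # every deformation short of ECM digestion.  A detachable bond lets
        # the basal feet ratchet along the chain, irreversibly narrowing the
        # pouch base instead of bending the ECM with it.
        basal_adhesion=SpringParams(stiffness=30.0, rest_length=0.8),
        apical_interlayer_adhesion=SpringParams(
            stiffness=15.0, rest_length=1.0, breakable=True, break_distance=3.0
        ),
        contractility=SpringParams(stiffness=0.0, rest_length=0.0),
        ecm=SpringParams(stiffness=20.0, rest_length=0.0),  # r0 set per bond
        ecm_bending_stiffness=40.0,
        area_constraint_stiffness=4.0,
    )


def default_damping_params() -> DampingParams:
    return DampingParams()


# --- YAML parameter files -------------------------------------------------

_MORSE_KEYS = {
    "repulsion_amplitude",
    "repulsion_scale",
    "attraction_amplitude",
    "attraction_scale",
    "cutoff",
}
_SPRING_KEYS = {"stiffness", "rest_length", "breakable", "break_distance"}

_ENERGY_BLOCKS = {
    "E_v": ("volume_exclusion", "morse"),
    "E_nuc": ("nucleus", "morse"),
    "E_memb": ("membrane", "spring"),
    "E_adhL": ("lateral_adhesion", "spring"),
    "E_adhB": ("basal_adhesion", "spring"),
    "E_adhA": ("apical_interlayer_adhesion", "spring"),
    "E_cont": ("contractility", "spring"),
    "E_ecm": ("ecm", "spring"),
}


def _update_block(obj: Any, block: dict, allowed: set[str], name: str) -> None:
    for key, value in block.items():
        if key not in allowed:
            raise ValueError(f"unknown key {key!r} in parameter block {name!r}")
        setattr(obj, key, value)


def load_params(source: str | TextIO) -> tuple[EnergyParams, DampingParams]:
    """Read energy/damping parameters from a YAML file.

    The file holds one block per energy term (``E_v``, ``E_nuc``, ``E_memb``,
    ``E_adhL``, ``E_adhB``, ``E_adhA``, ``E_cont``, ``E_ecm``, ``E_vol``) and
    one ``damping`` block (``C_nuc``, ``C_memb``, ``C_ECM``, optional
    ``ecm_region_multipliers``).  Omitted blocks keep their calibrated
    defaults; unknown blocks or keys are rejected.
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValueError("parameter file must contain a mapping at top level")

    ep = default_energy_params()
    dp = default_damping_params()
    for block_name, block in raw.items():
        if block_name in _ENERGY_BLOCKS:
            attr, kind = _ENERGY_BLOCKS[block_name]
            allowed = _MORSE_KEYS if kind == "morse" else _SPRING_KEYS
            block = dict(block)
            if block_name == "E_memb" and "bending_stiffness" in block:
                ep.membrane_bending_stiffness = block.pop("bending_stiffness")
            if block_name == "E_ecm" and "bending_stiffness" in block:
                ep.ecm_bending_stiffness = block.pop("bending_stiffness")
            _update_block(getattr(ep, attr), block, allowed, block_name)
        elif block_name == "E_vol":
            block = dict(block)
            if set(block) - {"stiffness"}:
                raise ValueError(
                    f"unknown key in parameter block 'E_vol': {set(block) - {'stiffness'}}"
                )
            ep.area_constraint_stiffness = block["stiffness"]
        elif block_name == "damping":
            block = dict(block)
            mapping = {"C_nuc": "C_nuc", "C_memb": "C_memb", "C_ECM": "C_ecm"}
            for key, value in block.items():
                if key in mapping:
                    setattr(dp, mapping[key], value)
                elif key == "ecm_region_multipliers":
                    dp.ecm_region_multipliers.update(value)
                else:
                    raise ValueError(f"unknown key {key!r} in parameter block 'damping'")
        else:
            raise ValueError(f"unknown parameter block {block_name!r}")
    ep.validate()
    dp.validate()
    return ep, dp


def dump_params(ep: EnergyParams, dp: DampingParams) -> str:
    """Serialize parameters to the YAML block format of :func:`load_params`."""
    doc: dict[str, Any] = {}
    for block_name, (attr, kind) in _ENERGY_BLOCKS.items():
        obj = getattr(ep, attr)
        keys = _MORSE_KEYS if kind == "morse" else _SPRING_KEYS
        doc[block_name] = {k: getattr(obj, k) for k in sorted(keys)}
    doc["E_memb"]["bending_stiffness"] = ep.membrane_bending_stiffness
    doc["E_ecm"]["bending_stiffness"] = ep.ecm_bending_stiffness
    doc["E_vol"] = {"stiffness": ep.area_constraint_stiffness}
    doc["damping"] = {
        "C_nuc": dp.C_nuc,
        "C_memb": dp.C_memb,
        "C_ECM": dp.C_ecm,
        "ecm_region_multipliers": dict(dp.ecm_region_multipliers),
    }
    return yaml.safe_dump(doc, sort_keys=True)
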