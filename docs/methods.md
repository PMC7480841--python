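# Methods

## The model

`wingdisc` simulates a cross-section of the *Drosophila* wing imaginal disc
along its anterior-posterior axis with a subcellular-element (SCE) model.
Three node types — nucleus, membrane, and ECM nodes — move by overdamped
("Langevin without noise") dynamics,

    C_nuc  dx_nuc/dt  = −∇(E_nuc + E_v)
    C_memb dx_memb/dt = −∇(E_memb + E_cont + E_v + E_vol + E_adhL + E_adhB + E_adhA)
    C_ecm  dx_ecm/dt  = −∇(E_ecm + E_v + E_adhB)

integrated with the explicit Euler method.  The nine potential-energy terms
are:

| term   | type   | represents                                     |
|--------|--------|------------------------------------------------|
| E_v    | Morse  | volume exclusion between node types             |
| E_nuc  | Morse  | cohesion/size of the nucleus node cluster       |
| E_adhL | spring | E-cadherin cell-cell adhesion                   |
| E_adhB | spring | integrin cell-ECM adhesion                      |
| E_adhA | spring | columnar-squamous interlayer adhesion           |
| E_cont | spring | basal actomyosin contractility (k_cont)         |
| E_memb | spring | membrane/cortex stiffness                       |
| E_ecm  | spring | ECM (collagen) stiffness                        |
| E_vol  | area   | conservation of cytoplasmic volume (2D: area)   |

The Morse form is the two-exponential SCE pair potential
`U(r) = U0 e^(−r/ξ0) − W0 e^(−r/γ0)` with a hard cutoff.  Units are μm, nN,
nN/μm, and arbitrary time units (AU); the damping coefficients (all 1.0
nN·AU/μm by default) absorb the time scale, so AU here are not comparable
with any other implementation's AU.

## Tissue architecture

The built tissue matches the calibrated cross-section geometry: 65 columnar
pouch cells of 2.5 × 25 μm (lattice pitch × height), 10 squamous
(peripodial) cells above the pouch with the lumen between the two apical
surfaces, 2 marginal boundary cells per side spanning both layers, and an
open ECM chain wrapping the entire basal perimeter in three regions — ECMs
over the squamous layer, ECMbc around the margins, ECMc under the pouch.
Each columnar cell carries a 10-node nucleus cluster whose centroid starts
at fractional height 0.65 (apically biased).  Cell polygons are inset by
half of an 0.8 μm inter-membrane gap so every adhesion bond is exactly at
rest; all Morse pairs start beyond cutoff and every cell is at its target
area, so the construct is force-free to < 1e−8 nN and exactly flat.

Structural choices that the energy table does not fix, and why:

* **Elongated nuclei.**  The nucleus cluster is a single vertical column
  with adjacent nodes exactly at the E_nuc Morse equilibrium (~0.8 μm) and
  non-adjacent pairs beyond its cutoff.  Columnar-cell nuclei are
  apicobasally elongated, and this is the only force-free arrangement that
  fits a 1.7 μm cell interior.
* **Cortical shape memory.**  E_memb has a stretching part (nearest-neighbor
  ring springs) and a bending part (second-neighbor springs at their
  as-built separations).  Without angular stiffness a sheet of cells shears
  freely and *any* bent configuration is a zero-energy ground state; with
  it, cells elastically remember their resting shape, which is what lets a
  perturbed tissue relax.
* **Taut vs loose basement membrane.**  The ECMc and ECMbc runs are built
  straight and carry second- and fourth-neighbor "rod" springs on straight
  stretches, so the taut basement membrane around the pouch is inextensible
  and resists short-wavelength crumpling while remaining free to arc at
  tissue scale (chain corners are unsprung hinges).  The ECMs run over the
  peripodium is loose: it is built as a force-free sinusoid carrying 15%
  extra material length, reflecting the observed slack basement membrane on
  that side.
* **Firm integrin anchorage.**  E_adhB bonds are permanent.  A detachable
  basal bond lets the feet ratchet along the chain under contraction,
  irreversibly narrowing the pouch base instead of bending the ECM with the
  tissue.  E_adhL and E_adhA remain breakable (forces vanish beyond their
  break distances, 4.0 and 3.0 μm); E_adhL junctions are established once
  per shared cell-cell interface, E_adhA bonds re-form only on contact.
* **Standing peripodial tension.**  `PrestrainSpec.F_squamous` loads the
  squamous layer's long-side membrane bonds with a standing tension
  (default 10 nN), present in every scenario: the squamous layer pulls on
  the margins, which is the force that acts against the generated dome once
  the ECM is removed.

## The bending mechanism

Basal actomyosin contractility is modeled as zero-rest-length springs
joining the laterally opposed membrane nodes of each columnar cell below
its basal-most nucleus node (minus one node spacing); the pair set is
re-selected as the nucleus moves.  Contraction pinches the cell below the
nucleus; volume exclusion pushes the nucleus apically; and, because the
basal surface is glued to the inextensible ECMc, the demanded shortening of
the basal line can only be met by bending it: the basal surface sags into a
dome bowing away from the squamous layer while the margins are drawn
inward and upward.  Passive ECM prestrain (rest-length offsets of chain
springs, `r0 = r_init − F/k_ecm`) bends the tissue only weakly by
comparison.  Shape maintenance works through the same backbone: multiplying
the ECMc drag by 10³ freezes the chain that carries the dome, so switching
contractility off leaves the curvature almost unchanged, while the
no-multiplier control relaxes.

## Quantification

* Global curvature: signed circumcircle curvature `4A/(abc)` of the triple
  (first point, arc-length midpoint, last point) of a surface polyline.
  The tissue-level readout uses the basal pouch surface, the surface the
  experimental pipeline segments.  Sign convention: polylines are ordered
  left to right with the squamous layer on the +y side; positive =
  basal surface bowing away from the squamous layer (the wild-type dome),
  negative = the inverted profile.
* Local curvature: Menger curvature (identical quantity, three-point form)
  over a sliding ±w arc-length window, default w = 5 μm, linear
  interpolation along the polyline, endpoints omitted where the window does
  not fit.
* Nuclear position: `L_A`/`L_B` are nearest-point distances from the
  nucleus centroid to the cell's apical/basal surfaces; fraction =
  `L_B/(L_A+L_B)` (0 basal, 1 apical); height = `L_A+L_B`.
* Convergence: least-squares fit of `c(t) = c_∞ − a·e^(−t/τ)` to the
  curvature series; the engine stops when the relative change over a
  10 000-step window falls below 1% (with a 0.002 μm⁻¹ flatness floor so
  the relative test is meaningful for flat tissues).

## Parameters

Energy coefficients are not printed in the source material; the defaults
here are this package's calibration, chosen once so that the model
reproduces the headline phenotype — apically biased nuclei near 70%,
bending monotone in k_cont over 3–9 nN/μm, mild bending from ECM tension
alone, and ECM-damping-based shape maintenance:

| parameter | default | role |
|---|---|---|
| E_v: U0, ξ0, W0, γ0, cutoff | 2, 0.2, 0.1, 0.45, 0.7 | short-range exclusion (repulsive over its whole range) |
| E_nuc: U0, ξ0, W0, γ0, cutoff | 2, 0.3, 1, 0.8, 1.0 | nucleus cohesion, equilibrium ≈ 0.80 μm |
| k_memb / bending | 10 / 30 nN/μm | cortex stretching / angular stiffness |
| k_adhL | 15 nN/μm (rest 0.8, break 4.0) | cell-cell junctions |
| k_adhB | 30 nN/μm (rest 0.8, permanent) | integrin anchorage |
| k_adhA | 15 nN/μm (rest 1.0, break 3.0) | interlayer adhesion (central 20% of the pouch) |
| k_ecm / bending | 20 / 40 nN/μm | chain stretching / rod straightness |
| k_vol | 4 nN/μm³ | per-cell area error stays < 1% in all scenarios |
| C_nuc, C_memb, C_ecm | 1.0 | damping (time scale) |
| F_squamous | 10 nN | standing peripodial tension |
| F_ECMs (patterned-tension runs) | 0.25 nN | squamous-side prestrain; ECMc carries ratio × this |

Numerical settings: the explicit-Euler step must satisfy `k·dt/C < 2` for
every spring (the engine refuses otherwise).  The stiffest collective mode
is the area penalty (λ ≈ k_vol × perimeter × spacing); the desk-scale
presets use dt = 0.005 AU, a ≈1.4× margin below that bound.  Interaction
pair lists are refreshed every 50 steps with a 0.3 μm KD-tree skin.

## Problem sizes

All shipped presets are desk-scale reductions of the full 65-cell geometry
(the package's own choice of resolution):

* `full_config()` — 65 columnar cells, 0.5 μm node spacing (≈ 13 000
  nodes); faithful geometry, hours per scenario.
* `reduced_config()` — 17 columnar cells, 1.25 μm spacing (≈ 1 350 nodes);
  used for the calibration target and the scenario suite; a
  high-contractility run to convergence takes a few minutes on one core.
* `mini_config()` — 9 columnar cells (≈ 700 nodes); used by the
  sensitivity screen and fast tests.

The LHS/PRCC screen runs 30–60 mini-resolution simulations over ≥ 6
parameter ranges (k_cont 0–9 nN/μm, prestrain levels, adhesion/membrane/ECM
stiffnesses ±50%) on a fixed short horizon; PRCC uses rank-residual
correlation with bootstrap percentile intervals (B = 500 by default).

## What the model does and does not show

Passing tests demonstrate the mechanical mechanism — contractility-graded
dome formation with apical nuclear bias, ECM-prestrain encoding, ECM-drag
shape memory — inside this idealized 2D cross-section: rectangle-built
cells, no cell division or growth, no lumen fluid pressure, no thermal
noise, no dissipative shear friction, and a rigid-rod basement membrane.
They do not show anything about pixel-level image segmentation or about
3D/out-of-plane mechanics.

Known limitations at the shipped resolution:

* The patterned-ECM-tension scenario produces essentially no bending at
  this scale (curvature < 0.001 μm⁻¹ for ECMc/ECMs ratios 4–7): the taut
  bottom chain stays straight under tension and the margin-rotation
  threshold is never reached.  This reproduces the strongest form of the
  finding that ECM tension alone cannot bend the tissue, but the graded
  mild response of the full-scale system is below this resolution.
* Mean columnar cell height settles ≈ 10% below its resting value at every
  contractility level rather than increasing with the level; the cells
  near the margins shorten as the margins rotate inward, outweighing the
  elongation of the central cells.
* The post-collagenase relaxation is incomplete: after acute ECM deletion
  the dome decays by ~30–40% and then locks in a jammed, margin-crushed
  configuration; the full sign inversion of the curvature (and hence the
  wide central interlayer gap of the dual perturbation) does not emerge in
  this athermal, desk-scale calibration.  The drivers and obstacles are
  analyzed in the acceptance notes; briefly, the standing squamous tension
  attainable in this architecture is below the buckling threshold of the
  relaxed sheet, and the missing lumen-pressure coupling (explicitly out of
  scope) removes the main channel by which the two layers communicate at
  the center.
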