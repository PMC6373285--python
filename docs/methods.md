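# Methods

This note records the models implemented in `headfsi`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
surrogates do and do not establish about real head models.

## 1. The two CSF treatments

The cerebrospinal fluid layer between pia and dura is represented two ways,
selected by `mode`:

**Sliding (Lagrangian elastic fluid).** Pressure integrates the rate law
`Ṗ = −K ε̇ᵢᵢ` with bulk modulus `K = 2.19 GPa`; shear modulus is zero, but a
tensor-viscosity deviatoric stress `σᵛ = VC·ΔL·a·ρ·ε̇′` is applied, with
`VC = 0.3` (inside the recommended 0.1–0.5 damping band), `ΔL` the
characteristic element length (cube root of element volume for non-cubic
elements; the cell width in 1D), `a = √(K/ρ)` the bulk sound speed and `ρ`
the density. `VC` is numerical damping; its stress nevertheless acts on the
physics like a viscosity of magnitude `VC·ΔL·a·ρ` (~670 Pa·s at 1.5 mm
cells), which is the crux of the model comparison. The mesh is Lagrangian:
no advection phase, and the interface contact is compression-only with free
separation (a sliding-only contact transmits no tension radially — the
contract is stated nowhere authoritatively, so compression-only was chosen
as the reading consistent with "permits sliding").

**FSI (ALE Mie–Grüneisen fluid).** Pressure follows the Mie–Grüneisen
equation of state with the standard water constants `C = 1482.9 m/s`,
`S₁ = 2.1057`, `S₂ = −0.1744`, `S₃ = 0.010085`, `γ₀ = 1.2`, volume
correction `a = 0`, on the compression measure `μ = ρ/ρ₀ − 1`. The printed
Hugoniot form omits the internal-energy term of the full Grüneisen EOS; the
implementation adds the conventional `(γ₀ + a·μ)·E` term (energy per unit
reference volume) behind an `energy_term` switch, default on, because the
solver tracks internal energy and the named EOS conventionally includes it;
with `E = 0` the bare expression is recovered exactly. Tension is floored
at the cut-off pressure `p_cut = −22 MPa` (degassed-water cavitation
strength), applied as a hard floor after EOS evaluation, not as element
erosion. Deviatoric stress is Newtonian, `σᵛ = γ·ε̇′`, with
`γ = 0.001 Pa·s`. CSF density is not separately documented; `ρ₀ = 1000
kg/m³` (water-like) is the default, configurable.

The analytic contrast between the treatments is
`effective_viscosity_ratio = VC·ΔL·a·ρ/γ ≈ 4.4×10⁵` at `ΔL = 1 mm`
defaults — the mechanism behind the orders-of-magnitude CSF shear-stress
difference and the different brain–skull mobility the two models predict.

## 2. The hydrocode

`column.FluidColumn` is a one-dimensional staggered-grid explicit solver
(velocities on nodes, thermodynamic state in cells) advanced by the classic
two-phase operator split:

1. *Lagrangian phase.* Cell strain rates from nodal velocities; pressure
   from the mode's EOS; standard artificial bulk viscosity on compression
   (linear + quadratic, coefficients 0.06 and 1.5 — common explicit-code
   defaults, config-exposed); deviatoric stress from the mode's viscosity
   law with the uniaxial-strain deviator `ε̇′ₓₓ = ⅔ε̇`; central-difference
   velocity/position update; internal energy updated from the stress power
   on the fluid fraction of each cell.
2. *Advection phase* (FSI mode only). Node positions return to the
   reference grid, which rides rigidly with the prescribed skull wall
   (`mesh_relaxation = 1`; values below 1 blend in a mass-weighted
   neighbour smoothing of the Lagrangian positions). Signed per-face
   transport volumes remap fluid volume, mass and internal energy
   conservatively with the donor-cell (first-order upwind) or van Leer
   (MUSCL with monotonized-central limiting) scheme — van Leer by default,
   as the more accurate of the pair. Nodal momentum remaps on the
   half-index-shifted dual grid.

Cells carry two materials, CSF and void. Void cells have no mass and no
stress; they exist so the fluid surface can migrate. Cells whose fluid
content falls below thresholds (10⁻⁶ of a reference cell's mass or volume,
or volume fraction below 0.05) are treated as pressure-free surface slabs:
their density estimate `m/V_f` is dominated by remap round-off, and the
load path runs through the full cells and the coupling force. Their mass
still advects and conserves. Surface nodes carry an inertia floor of 0.1
reference-cell masses (small-cell stabilization). Boundary faces are
exactly closed: the reference grid is anchored at the wall node, and a free
fluid surface at the far end makes that end node track the material. These
choices are what achieves machine-precision mass conservation and an exact
momentum ledger (the solver books wall tractions, coupling forces,
constraint impulses at prescribed nodes, and momentum absorbed by the
inertia floor).

**Coupling.** Penetration of the brain surface node into the
fluid-occupied region (wall position + total fluid thickness) produces a
penalty force `F = k·d` with `k = penalty_factor · K_bulk / ΔL` per unit
face area and `penalty_factor = 0.1`; equal and opposite forces act on the
structure and on the last massive fluid node. The stiffness scaling is a
declared choice (the reference solver's rule is not documented). FSI mode
transmits tension and compression (coupled interface); sliding mode is
compression-only.

**Timestep.** `cfl × min(cell width / sound speed)` over fluid cells
(`cfl = 0.5`), with the tensor-viscosity diffusion limit
`width/(2·VC·a)` for the elastic fluid, the brain rod's acoustic and
viscous limits, and a penalty-frequency limit `1/√(k/m_ref)`.

## 3. Surrogate experiments

The 3D head geometry is unavailable, so two canonical 1D surrogates carry
the physics; this is the central scale reduction of the package.

**Radial column** (`experiment: radial_column`): skull wall | CSF gap
(3 mm, two element layers — the mesh-converged default, refinable) | brain
rod (60 mm, 12 elements) | CSF gap | skull wall. In FSI mode each gap adds
2 mm of void mesh beyond the initial fluid so CSF can be transported toward
regions initially occupied by the brain. Both walls move rigidly with the
doubly integrated translational pulse. Exercises: EOS, coup/contrecoup
pressure pattern (the trailing wall drives into the lagging brain:
compression on the impact side, transient tension opposite, floored at
`p_cut`), cut-off, multi-material advection, penalty coupling. The brain
rod is a lumped-mass Kelvin–Voigt solid with modulus 2.19 GPa (bulk-like,
since the radial direction loads the brain volumetrically), viscosity
500 Pa·s, density 1040 kg/m³.

**Shear gap** (`experiment: shear_gap`): skull plate | CSF layer (3 mm,
two layers) | brain block, in the tangential direction. Tangential momentum
diffuses across the gap with the mode's effective viscosity (`γ` for FSI,
`VC·Δy·a·ρ` for sliding), no-slip at both faces. The brain block is a
rigid lumped mass (`ρ_b × 0.1 m` per unit area) restrained by an elastic
tether to the skull — a stand-in for falx/tentorium/neck restraint —
with default natural frequency 50 Hz (mid-range of reported brain–skull
resonances) and damping ratio 0.05; both configurable. The skull plate's
tangential velocity is the integrated rotational-acceleration pulse times
an effective head radius (0.06 m). This experiment maps "cortical relative
motion" onto the plate–block relative displacement and is the carrier of
the ASDH comparison. A `bottom: fixed` / constant `wall_velocity` variant
provides the Couette verification benchmark. Bridging veins ride the block
and plate kinematically (strain gauges); an optional linear spring
stiffness can feed forces back, default off.

## 4. Bridging veins and rupture

The 11 parasagittal vein pairs carry their measured rest lengths
(8.8–19.9 mm) and angles from the mid-sagittal line (44–103°). Under a
tangential relative displacement `d` (taken along the mid-sagittal
direction), a vein at angle `θ` sees an axial component `d·cosθ` and a
transverse component `d·sinθ`; engineering strain is the end-to-end length
change over rest length, floored at zero (slack veins buckle; rupture
concerns tension only). Thresholds: ultimate strain 0.5 ± 0.16, lowest
observed rupture strain 0.36. The mean ± SD range [0.34, 0.66] overlaps the
lowest-observed value; the implementation flags a vein (possible ASDH) at
peak strain ≥ 0.36 — the operative comparison — and categorises
below-lowest / within-range / above-range with boundaries 0.36 and 0.66,
keeping the 0.34 lower edge in the reported range.

## 5. CORA rating

Components are computed on 0–1 and scaled to 0–10. Curves are linearly
resampled onto the finer of the two grids over the evaluation window (no
interpolation scheme is canonical; linear is the declared choice). The
corridor uses inner/outer half-widths `a₀·Y`/`b₀·Y` of the reference peak
`Y` with transition exponent `k_c`; phase scans integer-sample shifts
within `max_shift_fraction` of the window (ties toward zero shift), scoring
linearly between `d_min·T` and `d_max·T`; shape is the clipped normalised
cross-correlation at the aligned position to the power `k_V`; size is the
ratio of trapezoidal ∫x² areas to the power `k_G`; B is the weighted mean
(equal weights by default — the one combination rule that is fixed).
Defaults `a₀ = 0.05`, `b₀ = 0.5`, `k_c = 2`, `k_V = k_G = 1`,
`d_min = 0.01`, `d_max = 0.12`, `max_shift_fraction = 0.2` follow common
published practice and are all exposed. Classification bins are
Unacceptable [0, 2.6), Marginal [2.6, 4.5), Fair [4.5, 6.5), Good
[6.5, 8.6), Excellent [8.6, 10]; the published table's overlapping
Fair/Good bins are treated as a typo and repaired at 6.5. Channel and case
aggregation is the unweighted mean; display rounding is half-even to two
decimals. The published per-case rating rows shipped in
`reference_tables.py` do not always equal the mean of their printed
components (unstated weighting); they are stored as printed, and only
quantities derivable from them (averages, improvements, classifications)
are recomputed.

## 6. Synthetic data

Loading pulses are haversine (or triangular) with exact peak placement;
the ASDH reconstruction case uses 450 g translational (g = 9.81 m/s²
exactly) and 26.2 krad/s² rotational peaks with a 10 ms default duration —
a typical head-impact timescale; the recorded curves exist only as figures
and were not digitized, so no figure-derived numbers appear anywhere.
Perturbation fixtures apply time shift, amplitude scaling and seeded
i.i.d. Gaussian noise (the simplest null model for rating-robustness
checks) with analytically known effects on each CORA component. All
generators are pure functions of (spec, seed).

What the surrogates do **not** establish: absolute magnitudes. The shear
gap has no curvature, no distributed brain compliance in shear, no
anatomical vein placement; its relative displacements (and hence BV
strains) depend on the chosen tether stiffness and effective radius.
Directional and ratio claims — fluid CSF admits more brain–skull motion
than tensor-viscosity CSF, sliding-mode shear stress exceeds FSI-mode by
the effective viscosity ratio, flagged-vs-unflagged rupture assessments —
are robust to those choices; peak millimetre values are not, and are never
compared against 3D-model results.

## 7. Verification

`benchmarks.py` holds the problems with closed-form references: acoustic
pulse transit across a 200-cell, 1 m water column (measured speed within
0.3% of `√(K/ρ)`; the EOS intercept `C` and `√(K/ρ)` themselves agree to
0.2%); square-wave advection (van Leer L1 error ≈ ⅓ of donor-cell, total
variation non-increasing, no new extrema, conservation to round-off);
steady Couette wall stress (`γV/h` to machine precision, since the discrete
steady state is exact). Problem sizes (200 cells, 10⁴-step conservation
runs, 100-pair oracle scans) are chosen so the whole verification suite
runs in well under a minute on one core while still resolving the physics
each check targets.

## 8. Known limitations

* One-dimensional surrogates only; no 2D/3D ALE, no skull deformability,
  no ventricles, no anatomical scaling.
* The energy-term convention of the reference solver's EOS runs is
  undocumented; both behaviours are provided, default on.
* Donor-based volume-fraction transport smears the fluid surface over a
  few cells; the surface position (cumulative fluid volume) remains
  conservative and well-defined.
* The momentum remap reconstructs velocities from remapped momenta with a
  nodal-mass floor at the surface; the absorbed difference is booked in the
  impulse ledger rather than eliminated.
* Bridging veins default to kinematic gauges; force feedback to the brain
  block is available but off, matching the spring-as-strain-sensor reading
  of the source model.
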