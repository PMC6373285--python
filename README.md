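# headfsi

Desk-scale tools for studying how the **brain–skull interface** is modelled
in finite element head models — specifically, what changes when the
cerebrospinal fluid (CSF) layer between brain and skull is treated as an
actual fluid instead of a Lagrangian solid.

## The problem

Finite element head models predict traumatic brain injury from impact
kinematics, and their predictions hinge on the brain–skull interface. Most
models represent the CSF with Lagrangian solid elements: an "elastic fluid"
with pressure rate `Ṗ = −K ε̇ᵢᵢ` (bulk modulus `K` = 2.19 GPa) and a
deviatoric stress `σᵛᵢⱼ = VC·ΔL·a·ρ·ε̇′ᵢⱼ`, whose *tensor viscosity*
coefficient `VC` is numerical damping, not physics. An alternative treats
the CSF on an arbitrary Lagrangian–Eulerian (ALE) multi-material mesh as a
true fluid: a Mie–Grüneisen equation of state with the standard water
constants (`C` = 1482.9 m/s, `S₁` = 2.1057, `S₂` = −0.1744,
`S₃` = 0.010085, `γ₀` = 1.2), Newtonian viscosity `σᵛᵢⱼ = γ ε̇′ᵢⱼ` with
`γ` = 0.001 Pa·s, a tensile cut-off pressure of −22 MPa standing in for
cavitation, and penalty-based fluid–structure coupling to the Lagrangian
brain.

At equal deviatoric strain rate the two laws differ by the effective
viscosity ratio `VC·ΔL·a·ρ/γ` — more than five orders of magnitude at
millimetre element sizes. That contrast controls how freely the brain
slides inside the skull, and therefore the bridging-vein (BV) strains that
drive acute subdural haematoma (ASDH) prediction: a parasagittal bridging
vein stretched past the lowest observed rupture strain (0.36, within the
ultimate range 0.5 ± 0.16) marks a plausible ASDH.

This package implements both CSF treatments and everything needed to
compare them:

* a one-dimensional explicit **multi-material ALE hydrocode**
  (Lagrangian phase + donor-cell/van Leer advection remap, void material,
  penalty coupling, artificial bulk viscosity) with two canonical surrogate
  experiments — a radial skull–CSF–brain–CSF–skull column and a tangential
  CSF shear gap;
* the **CORA biofidelity rating** (corridor C1, cross-correlation shape V,
  size G, phase P, overall B on 0–10 with the five-level classification),
  plus per-case and cross-case aggregation;
* the **bridging-vein catalogue** (11 parasagittal pairs with measured
  lengths and angles), strain evaluation and rupture-risk assessment;
* **synthetic inputs**: impact pulses at the documented ASDH-case peaks
  (450 g translational, 26.2 krad/s² rotational), perturbed rating fixtures
  and runnable geometries;
* an end-to-end **comparison pipeline** and a `headfsi` CLI.

## Worked example

Rate a perturbed copy of a 450 g haversine pulse against the original:

```python
from headfsi import (CoraConfig, rate_pair, classify_biofidelity,
                     make_pulse, PulseSpec, perturb_curve, PerturbationSpec)

ref = make_pulse(PulseSpec("haversine", peak=4414.5, duration=0.01), 1e-4)
test = perturb_curve(ref, PerturbationSpec(time_shift=0.0006,
                                           amplitude_scale=1.3,
                                           noise_sd=150.0, seed=42))
rc = rate_pair(ref, test)
print(f"V={rc.V:.2f}  G={rc.G:.2f}  P={rc.P:.2f}  C1={rc.C1:.2f}  B={rc.B:.2f}")
print("classification:", classify_biofidelity(rc.B))
```

```
V=10.00  G=5.91  P=5.45  C1=5.49  B=6.71
classification: Good
```

The amplitude scaling hits the size score G, the 0.6 ms delay hits the
phase score P, the noise erodes the corridor score C1 — while the shape
score V stays at 10 because correlation is scale-invariant.

Run the surrogate ASDH comparison (identical loading, both CSF treatments):

```python
from headfsi import run_comparison

report = run_comparison({"experiment": "shear_gap", "seed": 1})
f, s = report.peaks["fsi"], report.peaks["sliding"]
print(f"peak brain-skull relative displacement: "
      f"FSI {f['relative_displacement']*1e3:.2f} mm, "
      f"sliding {s['relative_displacement']*1e3:.2f} mm")
print(f"peak CSF shear stress: FSI {f['csf_shear']:.1f} Pa, "
      f"sliding {s['csf_shear']:.3g} Pa")
for mode in ("fsi", "sliding"):
    a = report.rupture[mode]
    print(f"{mode}: max BV strain {a.max_strain:.2f}, "
          f"possible ASDH: {a.any_flagged}")
```

```
peak brain-skull relative displacement: FSI 19.64 mm, sliding 3.09 mm
peak CSF shear stress: FSI 18.0 Pa, sliding 1.49e+05 Pa
fsi: max BV strain 2.03, possible ASDH: True
sliding: max BV strain 0.28, possible ASDH: False
```

The fluid CSF lets the brain slide (large relative motion, injurious BV
strain, ASDH flagged); the tensor-viscosity CSF locks brain to skull
through shear stresses three-plus orders of magnitude larger, and predicts
no rupture under the same injurious loading. The same stages are available
from the shell: `headfsi simulate|cora|bv-risk|synth|compare|report`
(see `headfsi --help`).

## Layout

```
src/headfsi/
  signals.py       uniformly sampled time histories, CSV I/O, alignment
  cora.py          corridor/cross-correlation ratings, aggregation, classes
  materials.py     elastic-fluid and Mie-Gruneisen CSF laws
  advection.py     donor-cell and van Leer conservative remaps
  column.py        staggered-grid ALE fluid column, brain rod, coupling
  simulate.py      radial-column and shear-gap experiments
  benchmarks.py    acoustic / advection / Couette verification drivers
  veins.py         bridging-vein catalogue, strain, rupture assessment
  synthetic.py     pulses, perturbation fixtures, geometry presets
  pipeline.py      two-mode comparison and reporting
  cli.py           `headfsi` command line
docs/methods.md    model assumptions, parameters, numerical choices
```
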