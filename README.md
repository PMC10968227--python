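# aneufsi

Fluid–structure interaction of an idealized sidewall intracranial aneurysm:
a self-contained Python framework for asking how much the rigid-wall
assumption distorts the haemodynamic indicators used in aneurysm rupture-risk
research.

Intracranial aneurysms are pathological bulges of cerebral arteries.  Most
computational studies of their haemodynamics treat the vessel wall as rigid,
yet rigid-wall CFD is known to overestimate wall shear stress, and aneurysm
wall pulsation is now directly observable in vivo.  `aneufsi` implements a
reproducible benchmark for this question: a curved parent vessel (half-torus
tube, 4 mm diameter, inlet and outlet on the plane y = 0) carrying a
spherical aneurysm bulge (centre at y = 10 mm) with a 0.25 mm hyperelastic
wall, driven by a calibrated internal-carotid-like pulse, solved either as
pure CFD (rigid walls) or as strongly coupled FSI (compliant walls), and
reduced to the standard metrics.

The numerical core, written on numpy/scipy:

- **Flow** — incompressible Navier–Stokes in an arbitrary
  Lagrangian–Eulerian frame, equal-order P1–P1 tetrahedral elements with
  residual-based variational-multiscale stabilization (SUPG/PSPG +
  grad-div), BDF2 time stepping, Picard-linearized convection
  `((v − v_m)·∇)v`, parabolic inlet, resistance outlet
  `P = P0 + Rd·Q_out` (P0 = −3.7 kPa, Rd = 1.31 kPa·s/mL) with the flux
  feedback assembled implicitly in the velocity unknowns.
- **Wall** — isochoric neo-Hookean solid with a Simo–Taylor volumetric law
  (`U(J) = κ/4 (J²−1) − κ/2 ln J`, `dev σ = μ J^{-5/3} dev[FFᵀ]`), mixed
  displacement–pressure P1 elements, BDF2 inertia, Newton with complex-step
  element Jacobians; bulge tissue (E = 0.75 MPa) ten times softer than the
  parent artery, ν = 0.45.
- **Coupling** — partitioned Dirichlet-to-Neumann fixed point with Aitken
  Δ² dynamic relaxation (ω₀ = 0.1, tolerance 1e-5 mm on the node-scaled
  residual), linear displacement predictor, mesh motion by an
  inverse-squared-distance diffusion extension.
- **Metrics** — wall shear vector `τ = σ_f n − (n·σ_f n) n`, TAWSS, OSI,
  bulge-averaged WSS (y > 8 mm), swirl rate (upward flow through the plane
  y = 10 mm), bulge volume variation vs the diastolic state, peak-to-peak
  delays.
- **Meshing & I/O** — parametric implicit-surface meshing of the benchmark
  with a graded near-wall layer, wall shells extruded conformally from the
  fluid interface, structured tube/box/spherical-shell fixtures, Gmsh MSH
  4.1 round-trip and VTU/PVD export.

## A worked example

```
python examples/waveform_and_outlet.py
```

prints

```
cycle-mean flow   : 4.000000 mL/s   (target 4.0)
peak flow         : 6.520 mL/s
peak Reynolds     : 519      (parent vessel)
Womersley number  : 2.80
outlet pressure   : 2.1 .. 36.3 mmHg
```

i.e. the synthetic pulse is calibrated exactly to the 4 mL/s mean flow of
the internal carotid artery, reaches the physiological pulsatility regime
(Re ≈ 520, Wo = 2.8), and keeps the outlet pressure inside the intended
0–40 mmHg corridor.  The other examples mesh the benchmark geometry
(`examples/mesh_case_r.py`), verify the flow solver against the Poiseuille
and Womersley closed forms (`examples/flow_verification.py`), and run the
full rigid-vs-compliant comparison (`examples/rigid_vs_compliant.py`,
about fifteen minutes on one core), which at the desk resolution prints

```
peak bulge WSS        : rigid 1.818 Pa, compliant 1.813 Pa (drop 0.2%)
swirl delay vs inflow : rigid 30 ms, compliant 15 ms
outlet-pressure lag   : 3 ms (compliant)
max wall displacement : 0.162 mm
peak volume variation : 8.5%
```

— the qualitative signature of wall compliance in this geometry: the
compliant wall lowers the peak bulge-averaged WSS, lets the aneurysmal
swirl develop earlier, and delays the outlet-pressure peak behind the
inflow peak, while the bulge itself pulsates visibly (0.16 mm, 8.5% of its
volume).  The desk profile is deliberately coarse; the orderings, not the
magnitudes, are the reproducible content at this resolution.

A thin CLI wraps the same library:

```
aneufsi mesh --profile desk          # case-R fluid + solid meshes (MSH 4.1)
aneufsi run --mode rigid             # one case end to end
aneufsi verify poiseuille inflation  # oracle checks
aneufsi compare                      # rigid vs compliant report
```

The coarse `desk` profile (default) runs everything on a workstation; the
`full` profile reproduces the published resolution (≈1 M fluid elements,
1 ms steps, 1.8 s) and is meant for cluster-scale studies.  See
`docs/methods.md` for models, parameters and numerical choices.

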