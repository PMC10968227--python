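# Methods

`aneufsi` simulates pulsatile blood flow in an idealized sidewall
intracranial aneurysm with either rigid or compliant arterial walls, and
post-processes the flow into the haemodynamic indicators used for rupture-risk
research (WSS, TAWSS, OSI, swirl intensity, bulge volume variation).  This
note records the models, the discretizations, the parameter choices and the
numerical safeguards, and states explicitly what the desk-scale test battery
does and does not demonstrate.

## Benchmark geometry (case R)

The parent vessel is a torus tube of major radius `R_t = 7 mm` and lumen
radius `a = 2 mm` (4 mm inlet diameter); the upper half of the torus forms a
U-shaped vessel whose inlet and outlet discs both lie in the plane `y = 0`.
A spherical bulge of radius `3 mm` is centred at `(0, 10, 0) mm`, 3 mm above
the vessel apex, and the sharp neck intersection is smoothed with a blend of
width `0.5 mm`.  The arterial wall is a constant-thickness shell
(`0.25 mm`), split at the plane `y = 8 mm` into a bulge region and a parent
artery region with different stiffnesses.  The torus major radius, bulge
radius and fillet width are figure-derived: the benchmark's published prose
fixes only the inlet diameter, wall thickness, bulge-centre height and cut
plane, so these three are exposed as configuration with defaults chosen to
be geometrically consistent with the published drawings (a proper sidewall
neck, dome top at `y = 13 mm`).

The lumen is described implicitly: signed distance to the torus tube and to
the sphere, combined by a polynomial smooth-minimum whose blend width plays
the role of the neck fillet.  A rolling-ball fillet on a CAD kernel would
give the same C1 neck; the implicit blend is exact enough for meshing and
keeps the geometry fully parametric in ~40 lines.

### Meshing

*Fluid.*  Surface points are seeded parametrically (rings along the vessel,
a Fibonacci lattice on the sphere), projected onto the implicit surface,
and supplemented by inward offset shells following a geometric
boundary-layer progression (first layer `t1`, growth `alpha`, stopped at the
first layer whose cumulative depth reaches the prescribed total — the
printed triple (0.02 mm, 1.2, 0.3 mm) has no exact integer solution, so the
progression is cut at ~8 layers / 0.33 mm at full resolution).  A jittered
interior lattice at the core size completes the point set; Delaunay
tetrahedralization followed by an inside-test on cell centroids yields the
lumen mesh, with boundary faces tagged inlet / outlet (on `y = 0`) and
interface.  Deterministic tangential and depth jitter on the structured
point families breaks the cospherical degeneracies that would otherwise
produce sliver cells.  Around the neck fillet the target spacing is blended
down to `min(0.5 r_fillet, 0.45 h)` inside a band of width ~2.5 `r_fillet`:
the concave crease is the one feature the nominal sizing cannot represent,
and leaving it unresolved produces pinched boundary triangles whose extruded
wall shell self-intersects.  A post-pass additionally deletes the rare
"pinch" cells that leave a boundary edge shared by more than two faces, so
the lumen boundary is guaranteed manifold before the wall is extruded.

*Solid.*  The wall mesh is extruded from the fluid interface triangulation
along the implicit-surface normals in `solid_layers` equal layers; prisms are
split into tetrahedra with the min-vertex diagonal rule, which is conforming
across neighbouring prisms.  Fluid and solid interface triangulations are
therefore vertex-identical by construction, so interface data transfer needs
no interpolation.  Cells above `y = 8 mm` are tagged bulge-wall.

Two sizing profiles exist.  The **full** profile reproduces the published
sizing (core 0.17 mm, boundary layer 0.02/1.2/0.3 mm, 6 wall layers of
0.042 mm; on the order of a million fluid elements) and is intended for
cluster-scale runs.  The **desk** profile (core 1.05 mm, a single near-wall
shell at 0.39 mm, one wall layer of the full 0.25 mm thickness; ~13k fluid
and ~5k solid tetrahedra) runs the identical physics at workstation cost and
is what the test battery and the ordering checks use.  The desk near-wall
shell is deliberately thick: a compliant run moves the wall by a few tenths
of a millimetre, and near-wall cells much thinner than that excursion invert
under the mesh motion — boundary-layer resolution at desk scale is traded
for robustness of the moving mesh.

## Boundary conditions

The inlet carries a parabolic profile `v = V(t) (1 - (r/a)^2) e_y`.  `V(t)`
is a synthetic internal-carotid-like pulse — two periodic Gaussian bumps
(systolic peak near 15% of the cycle, dicrotic bump near 42%) on a diastolic
baseline — normalized to unit mean and rescaled so the peak-to-mean ratio is
exactly 1.63.  The amplitude calibration `scale = 2 Q_mean / A` is exact for
a parabolic profile; with the 4 mL/s target it gives a peak Reynolds number
of ~519 and a Womersley number of 2.80 in the parent vessel.  A 0.2 s linear
ramp precedes the periodic pulse.  The shape ships as data (samples plus
periodic linear interpolation), so a digitized measured waveform can replace
it via CSV.

The outlet applies the resistance condition `P = P0 + Rd Q_out`
(`P0 = -3.7 kPa`, `Rd = 1.31 kPa s/mL`) as a uniform weak normal traction
`-P n`.  The flux feedback `Rd Q_out(v)` is assembled *implicitly*: `Q_out`
is a linear functional `w·v` of the discrete velocity, so the term enters the
system matrix as a symmetric positive semi-definite rank-one block on the
outlet dofs.  This matters for the coupled case: evaluated explicitly (from
the BDF2-extrapolated velocity), the resistance forms a feedback loop with
the wall compliance whose *converged-in-time* map is period-2 unstable — each
coupled step converges, yet the states double every two steps once the
resistance activates.  With the calibrated pulse the outlet pressure
traverses 2–36 mmHg, inside the intended 0–40 mmHg corridor.  During the
start-up ramp the outlet traction is multiplied by the same linear ramp
factor and switched off while the model still predicts suction: applied
literally from `t = 0`, the offset `P0` would put a -3.7 kPa step suction on
the undeformed wall, which is a numerical artefact of cold-starting rather
than part of the cycle (the metric window starts only after the ramp).

Solid nodes on the plane `y = 0` are clamped; the exterior wall surface is
traction free.  Fluid density 1000 kg/m^3 and solid density 1000 kg/m^3 are
configuration defaults (the benchmark states them only graphically; 1000 is
also the only standard value consistent with Wo = 2.8 at the stated radius,
period and viscosity).

## Fluid solver

Incompressible Navier–Stokes in ALE form, P1-P1 tetrahedral elements with
residual-based stabilization (SUPG/PSPG plus grad-div), BDF2 in time with a
BDF1 first step, Picard linearization of the convective term `(v - vm) . grad v`.
Stabilization parameters (quasi-static subscales, one-point element
quadrature for the stabilization terms):

    tau_M = ( 2 rho/dt + 4 mu/h^2 + 2 rho |u| / h )^-1,
    tau_C = mu + rho |u| h / 2,

with `h` the equal-volume regular-tet edge length.  The transient term is
retained in `tau_M`.  Linear systems are solved with a sparse direct
factorization (the meshes used here are small enough that SuperLU with
COLAMD ordering beats any preconditioned iteration we tried).  Successive
flow solves reuse the previous factorization through an exact
defect-correction loop (`x <- x + LU^-1 (b - A x)` iterated to a 1e-9
relative residual, refactorizing whenever the iteration stops contracting):
between coupling subiterations the matrix changes only through micron-scale
mesh motion, while a factorization costs roughly fifty triangular solves.
Element scatter patterns are precomputed once per mesh, so repeated assembly
reduces to a weighted bincount.

Picard iterates to a relative velocity-increment tolerance of 1e-6 (max 20)
by default; the desk-profile case runs instead use a single semi-implicit
sweep per solve, with the convection velocity extrapolated from the two
previous time levels (`2 v^n - v^{n-1}`) — the standard choice for pulsatile
haemodynamics at small time steps, and what keeps a 500-step coupled run in
minutes.  The convergence test carries an RMS-velocity floor of 1e-9 m/s so
that a quiescent (round-off level) field counts as converged.

Boundary tractions are evaluated two ways for two different consumers.  The
fluid load handed to the solid uses the variational (residual-based) nodal
forces — the momentum-row residual of the assembled pre-Dirichlet system —
which are the exact momentum fluxes of the discrete scheme and guarantee a
discretely balanced force transfer.  The wall-*shear* metric, however,
cannot use them: the variational flux includes the stabilization's
contribution, and the grad-div term carries an effective viscosity
`tau_C ~ mu + rho |u| h / 2` that exceeds the physical `mu` by orders of
magnitude at these cell sizes.  On an axial tube the P1 interpolant is
exactly divergence-free and the pollution vanishes (which is why the
Poiseuille verification is clean), but on the curved vessel the nonzero
element-wise divergence turns into spurious tangential forces tens of times
the few-Pa physical shear.  WSS is therefore sampled from the
volume-averaged element viscous stress, `mu (grad v + grad v^T) n`,
projected tangentially — first-order accurate (it underestimates a resolved
boundary layer by O(h/a)) but physically clean, and verified against the
Poiseuille closed form.

### Mesh motion

Interface displacement is extended into the lumen by solving
`div(gamma grad d) = 0` per component with `gamma = 1 / max(dist, floor)^2`,
`dist` the distance to the interface evaluated once on the reference mesh
(floored at the first boundary-layer thickness to avoid a singular
coefficient).  Two practical amendments: `gamma` is additionally multiplied
by an inverse-quality factor `clip((0.4/q)^2, 1, 1e6)` (`q` = equal-volume
edge over longest edge) so the few flat cells a Delaunay boundary produces
deform rigidly instead of inverting, and the operator is factorized once
since it lives on the reference configuration.  The mesh velocity uses the
same BDF stencil as the flow, `vm = (a0 d + a1 d^n + a2 d^{n-1}) / dt`, so
the discrete interface velocity matches the displacement history exactly.

## Solid solver

The wall is an isochoric neo-Hookean material with a Simo–Taylor volumetric
law,

    U(J) = k/4 (J^2 - 1) - k/2 ln J,   W = mu/2 (tr[Cbar] - 3),
    ps = U'(J) = k/2 (J - 1/J),        dev[sigma] = mu J^{-5/3} dev[F F^T],

solved in total-Lagrangian mixed (u, ps) form on P1 tetrahedra: ps is an
independent vertex field tied to the dilatation through the nonlinear law
(the linear pressure–dilatation relation is its consistent linearization),
stabilized by an element Laplacian of ps scaled by `0.25 h^2 / (2 mu)`.
One printed form of the volumetric stress, `k/2 (J + 1/J)`, is inconsistent
with `U'(J)` and with a stress-free reference state; the package uses
`k/2 (J - 1/J)`.  Moduli derive from `E` and `nu = 0.45` per region:
bulge `E = 0.75 MPa`, parent artery ten times stiffer — the calibration that
produces bulge volume pulsation in the range reported in vivo.  Density
1000 kg/m^3; no structural damping and no pre-stress (the diastolic pressure
level is lowered instead, which is what the resistance outlet's negative
offset accomplishes).

Inertia uses the same BDF2/BDF1 stencils as the flow, applied twice
(velocity from displacement history, acceleration from velocity history).
Newton element Jacobians are assembled by vectorized complex-step
differentiation of the element residual — exact to round-off, immune to
step-size tuning, and cheap because the residual is closed-form per element
(P1 kinematics make `F` element-constant, so the 4-point pressure quadrature
collapses to the element mean).  The analytic material tangent `dS/dC` is
exposed separately and verified against finite differences.  The Newton loop
is a modified Newton: the factorized Jacobian is reused across iterations
(and subsequent calls) while the residual keeps contracting, and refreshed
whenever progress degrades; a backtracking line search keeps `det F > 0` and
the residual decreasing, which is what lets the solver survive the violent
transient loads a partitioned coupling can hand it.

## Coupling

Classic Dirichlet-to-Neumann partitioning, iterated to a fixed point within
every time step: predict the solid displacement (linear extrapolation of the
two previous converged levels), move the fluid mesh, solve the fluid with
the interface mesh velocity as Dirichlet data, hand the (sign-flipped)
consistent interface nodal forces to the solid as its Neumann load, solve
the solid, and form the residual `r = u_new - u_pred` over all solid nodes.
Convergence is declared when `||r||_2 / N_nodes < tol` in millimetres.  This
norm divides by the node count, not its square root, so its physical meaning
scales with `1/sqrt(N)`: the library default `tol = 1e-5 mm` corresponds to
a sub-micron RMS interface mismatch at production node counts, and the desk
case profile uses `tol = 1e-4 mm`, which at its ~1.6k solid nodes is the
*same* few-micron RMS mismatch (about 1/1000 of the wall motion) rather than
a looser test.  The relaxation factor follows the Aitken recursion seeded
with `omega0 = 0.1` for the first two sub-increments.  Conforming interfaces plus nodal-force transfer make
the dynamic continuity exact by construction; kinematic continuity holds at
convergence through the shared BDF stencil.

Three safeguards, all inactive at a converged fixed point: the Aitken factor
is clamped in magnitude to `[1e-4, 2]` with its sign preserved (strongly
added-mass-coupled cases legitimately need factors of order 0.005, and
occasionally negative ones — a positive-floor clamp at 0.01 stalls them); a
trust region caps the largest nodal move of one relax update at 0.05 mm; and
if a transient load excursion makes the solid momentarily non-solvable, the
prediction is pulled halfway back towards the last converged level and the
sub-increment repeated.  A fourth, case-level lever: the aneurysm case caps
the Aitken factor at 0.08 (and seeds with 0.05).  A fixed-relaxation probe
measured the interface map's stiffest-mode amplification at about -17 at
desk scale, so factors much above ~0.1 diverge; with the full clamp the
Aitken recursion entered exact limit cycles around that threshold, and the
cap — plus a bisection that halves the factor whenever the residual fails to
contract over two sub-increments — restores monotone convergence.  On the
slender elastic-tube pressure-wave fixture (density ratio 1, the classic
added-mass stress test) the scheme needs 10–20 sub-increments per step.

## Haemodynamic metrics

All metrics use only samples inside the metric window (one full cardiac
period after the flow is developed).  The wall shear vector is the
tangential traction; TAWSS its time-averaged magnitude (trapezoid); OSI the
standard normalized reversal measure, defined as 0 where the shear vanishes
identically.  The bulge-averaged WSS is the vertex-area-weighted mean of
`|tau|` over the surface above `y = 8 mm`.  The swirl rate integrates the
*positive part* of `v_y` over the plane `y = 10 mm` through the bulge —
inside a closed recirculation the net flux nearly cancels and could not
measure the swirl's intensity; the net-flux variant sits behind a flag.
Plane integrals slice the tetrahedra exactly (marching-tets polygons,
linear-exact clipping against `v_y = 0`).  The bulge volume above the cut
plane is evaluated by the divergence theorem on the clipped interface
surface (`int (y - y_cut) n_y dA`; the cap contributes nothing), relative to
the diastolic reference, taken at the instant of minimum inflow within the
window.  Peak-to-peak delays use parabolic sub-sample refinement.
"Maximum displacement" is the pointwise maximum over surface and time.

## Desk-scale protocol and what it shows

The published protocol (1 ms steps, 1.8 s of physical time, metrics on the
second cycle, million-element meshes) is available as the `full` profile but
is a cluster-scale computation.  The shipped desk protocol runs case R at
the coarse sizing above with `dt = 4 ms` (200 steps per cycle), simulating
1.0 s and measuring on the first full post-ramp cycle `[0.2, 1.0] s`; this
keeps a complete rigid-plus-compliant comparison around fifteen minutes on
one core.  Peak delays are recovered with sub-sample accuracy by quadratic
interpolation around the discrete peak, so the ordering metrics remain
meaningful at this step size.  At this
resolution the quantitative values of WSS, delays and volume variation
carry O(1) discretization error and the first-cycle window retains some
start-up transient; what the desk battery therefore demonstrates is the
*sign pattern* of the compliance effects — compliant peak bulge WSS below
rigid, compliant swirl developing earlier than rigid, outlet-pressure peak
lagging the inflow peak — together with machine-precision or percent-level
agreement of every solver component against independent closed forms
(Poiseuille, Womersley, Laplace shell, Aitken secant identity, rigid-limit
equivalence, OSI limit cases, spherical-cap volumes).

The synthetic benchmark also idealizes away features of real aneurysm data:
Newtonian rheology, a symmetric parent vessel and inlet profile, a single
outlet, uniform wall thickness, isotropic tissue, no pre-stress and no
perianeurysmal contact.  Passing the battery validates the numerical
machinery and the direction of compliance effects in this controlled
setting, not patient-specific accuracy.

## Known limitations

- The Delaunay-based mesher produces a small fraction (~0.1%) of flat
  near-boundary cells; the quality-stiffened mesh motion tolerates them, but
  mesh-independence studies should use the full profile or an external mesh
  imported via MSH.
- The desk profile's single semi-implicit convection sweep is first-order in
  the convective linearization; verification fixtures always iterate Picard.
- Restart/checkpoint plumbing is not implemented; runs are cheap enough at
  desk scale to re-execute from the embedded configuration.
- The Turek flag-behind-cylinder benchmark harness is not included; the
  elastic-tube pressure wave covers the added-mass regime instead.
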