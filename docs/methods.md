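# Methods

`skinslide` simulates a weight-bearing bony-prominence region — a thin skin
layer bonded to much softer subcutaneous tissue — sliding frictionally over
a hospital-mattress block during patient repositioning, and quantifies the
internal and interface stresses that are associated with superficial
pressure-ulcer risk. This note records the model, its numerical treatment,
and the choices made where the design was genuinely open.

## Model

**Geometry.** The region of interest is a two-layer tissue strip (skin
2 mm, subcutis 15 mm, length 60 mm) whose lower surface follows a circular
arc of radius `prominence_radius` — the contour of the underlying bone —
apex down, initially just touching a 400 × 50 mm mattress block. The bone
itself is not meshed: its rigidity enters through the boundary condition on
the tissue's top edge. The skin is the outermost (mattress-facing) 2 mm
stratum across the full strip length; skin and subcutis are tied by literal
node sharing (a conforming mesh), the simplest exact bonded interface.

**Materials.** All components are isotropic linear elastic in plane stress
(out-of-plane thickness 1 mm; plane-stress results in stress units do not
depend on this choice). Defaults: skin E = 15.2/50/100 kPa (the swept
parameter, spanning compliant young skin to stiff aged or diabetic skin),
ν = 0.49; subcutis E = 2 kPa, ν = 0.48; mattress E = 10 kPa, ν = 0.3.
Densities are carried on the material records but unused — the analysis is
quasi-static and body weight enters through the applied pressure. A
plane-strain material variant exists for laterally-confined cross-section
studies but is not used by any default, test, or reported result.

**Loading.** Two phases over t ∈ [0, 10] s. Phase 1 (t ≤ 1 s): the
weight-bearing pressure ramps to 130 kPa on the tissue top edge while that
edge is held at zero displacement. Phase 2: the top edge — a rigid driver
standing in for the bony prominence — translates linearly to 100 mm of
lateral slide and 10 mm of downward immersion, carrying the (follower)
pressure with it. The edge is displacement-controlled throughout: because
every degree of freedom of the driven edge is prescribed, the pressure
there alters edge reactions but not tissue deformation. This is a
deliberate design choice: with a 2 kPa subcutis, a force-controlled 130 kPa
settle has no meaningful linear-elastic equilibrium (nominal strain 65),
whereas the displacement-driven protocol realizes the stated repositioning
kinematics exactly. The mattress is fixed on its sides and bottom,
representing the unmodeled mattress continuation.

**Contact and friction.** Node-to-segment contact between the skin's outer
boundary (slave) and the mattress top edge (master), evaluated on the
current configuration every Newton iteration so arbitrarily large sliding
is supported. Normal contact is a linear penalty p = k_n·max(0, −gap);
friction is regularized Coulomb: an elastic tangential predictor
τ_trial = τ_committed − k_t·Δslip followed by a return map onto |τ| ≤ μp.
Slip is measured as the change of the closest-point coordinate along the
master polyline *in the master's reference arc-length metric*, so
stretching of the deformed master surface does not register as sliding.
Master normals are averaged at vertices and interpolated along segments,
making the gap function continuous across segment junctions of the
deformed (kinked) surface.

## Numerics

**Elements.** 4-node isoparametric quadrilaterals, 2 × 2 Gauss quadrature,
stresses reported at centroids. The element response is linear
(engineering strain); the contact kinematics are the only geometric
nonlinearity. The irregular-patch test is reproduced to machine precision.

**Incremental solution.** 10 increments for phase 1, 90 for phase 2
(uniform Δt). Each increment is solved by Newton iteration with an energy
convergence criterion — the work of the correction on the residual,
relative to the increment's first iteration, below 1e-10 — with a relative
residual-norm fallback at 1e-8. "Effectively zero" tolerances that still
terminate. Each linearized system is solved by sparse LU.

**Globalization.** Frictional penalty contact on layers this soft is
genuinely hard for Newton's method, and three safeguards are layered:

1. *Frozen-geometry phases.* If plain Newton stalls, the projection
   geometry (segment, ξ, normal) is frozen, making the residual piecewise
   affine, and a semismooth phase polishes the state before geometry is
   refreshed.
2. *Uzawa fallback.* If the coupled iteration still cycles (typical for
   symmetric Poisson spreading under settle, where slip directions sit on
   a knife edge), the increment is re-solved as a sequence of convex
   fixed-friction-bound (Tresca) problems with an Armijo line search on
   the incremental potential, the bound updated from the converged normal
   pressures (g ← μp) until self-consistent.
3. *Time-step bisection.* An increment that still fails is split
   recursively (up to 2^6 sub-steps).

The slip-state tangent keeps the unsymmetric μ·k_n (t ⊗ n) coupling term:
with a 2 kPa subcutis the friction-to-gap feedback gain exceeds one and a
symmetrized tangent diverges. A slip-direction chatter detector assigns a
stick-type tangent (forces untouched) to nodes whose slip direction flips
between iterations. A force-loaded body whose whole interface slips has a
singular tangential rigid-body mode; an optional small slip-stabilization
term in the tangent handles that configuration (off by default — the
repositioning problem is displacement-driven and does not need it).

**Penalty stiffness.** Default k_n = k_t = 25 × the softest contacting
modulus per mm (250 kPa/mm for the tissue-mattress pair). At this
problem's few-kPa contact pressures this keeps penetration at ~1e-2 mm,
well below the admissible 2% of skin thickness, which is verified after
every run; if the bound is ever exceeded the penalties are raised and the
run repeated. Stiffer penalties buy nothing physically and degrade the
Newton iteration (the penalty noise against the faceted master surface
also scales with k_n, which is why the Hertz benchmark uses a softer
penalty still). Elastic slip at the friction limit is ≤ ~0.02 mm,
negligible against the 100 mm travel.

**Mesh density.** The structured generator derives divisions from
per-layer element-count targets. The reference density (8515/24300/20000
targets — 20 elements through the skin, 60 through the subcutis, so the
apex midline column holds exactly 20 + 60 elements) resolves the skin's
surface stress boundary layer but makes a single simulation an hour-scale
computation; the production density used throughout the tests and the
acceptance script is 1/16 of it (~3350 elements), which keeps a full sweep
tractable. `mesh_convergence_study` implements the successive-refinement
protocol (working mesh accepted when the maximal effective stress changes
by < 2% between two successively refined meshes, evaluated at the highest
COF): at reduced densities it honestly reports *not converged* for the
midline skin maximum — that quantity samples the element row nearest the
contact surface and keeps growing as the surface layer is refined, which
is exactly why the reference density is as fine as it is. The subcutaneous
and interface maxima are far less density-sensitive. Quantitatively, the
production-density skin maxima should be read with a O(10–30%)
discretization reserve; the reference-density mode remains available via
the density targets.

**Prominence radius.** The bone-contour radius is not derivable from the
anatomy alone; it was calibrated once against the reference simulation
(COF 0.2, skin 15.2 kPa) and frozen at 60 mm — a shallow
ischial-tuberosity-scale contour — for every run, test, and reported
number. The calibration moves the midline skin stress by ~15% across
plausible radii and the interface tractions by almost nothing.

## Post-processing

Internal tissue loading is the plane-stress von Mises stress
√(σxx² − σxxσyy + σyy² + 3τxy²), extracted on the midline element column
through the prominence apex; whole-field per-layer maxima are logged as
diagnostics (`field_max_*`), and are substantially higher than the midline
maxima because the strongest concentration sits at the contact edges.
Interface quantities come from the contact tractions (primary) with the
adjacent-element τxy available in the profiles: the interface effective
stress combines pressure and shear as √(p² + 3τ²), the only von Mises
invariant constructible from exactly those two tractions. Each simulation
reduces to its final-time maxima (skin, subcutis, interface shear,
interface effective), the row type of the 12-run sweep table; maxima are
taken at the last time step, where loads peak.

## Known limitations

- The materials are linear elastic while the subcutis reaches strains well
  above 50% under the imposed immersion; real adipose tissue stiffens
  strongly there. In this plane-stress linear regime the imposed 10 mm
  immersion is largely absorbed by subcutis flattening (~4–5 mm) rather
  than mattress indentation, which caps peak contact pressure near
  1–3 kPa. Consequently the subcutaneous and compliant-skin internal
  maxima are quantitatively trustworthy, while interface shear levels are
  best read as trends in COF and skin stiffness rather than absolute
  values. Viscoelasticity, hyperelastic stiffening, and repositioning
  velocity are out of scope.
- 2D cross-section with unit thickness; no 3D anatomy, no sheets or
  clothing, no microclimate thermodynamics.
- Quasi-static: no inertia; densities unused.
- The penalty treatment admits ~1e-2 mm interpenetration and a tiny
  elastic stick slip, both bounded and checked.
- Fully force-controlled floating bodies in gross slip need the optional
  slip-stabilization term; the repositioning protocol never hits this.
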