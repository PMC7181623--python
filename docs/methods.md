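# Methods

`osseoimpact` models impact damage to the bone surrounding a dental
implant with two connected components: a one-dimensional stress-wave
analysis of Split Hopkinson Pressure Bar (SHPB) tests that supplies
dynamic yield strengths of bone, and an explicit elastodynamic finite
element simulation of a rigid ball striking the implant, in which bone
elements whose von Mises stress reaches those yield strengths are
deleted ("ineffective units").

## SHPB stress-wave analysis

A specimen of length `l_s` and cross-section `A_s` is sandwiched
between steel pressure bars (Young's modulus `E`, density `rho`,
cross-section `A_b`, wave speed `C0 = sqrt(E/rho)`; defaults 209 GPa,
7830 kg/m³, Ø20 mm, giving `C0 ≈ 5166 m/s`).  From the incident,
reflected and transmitted bar strains `ε_I, ε_R, ε_T` the specimen
histories follow one-dimensional wave theory:

    σ_s(t)  =  E (A_b / A_s) ε_T(t)
    ε_s(t)  = -(2 C0 / l_s) ∫₀ᵗ ε_R dτ
    ε̇_s(t) = -(2 C0 / l_s) ε_R(t)

Internally compression is positive; records with raw gauge polarity are
flipped on ingest.  Integration is cumulative trapezoidal on the
(required) uniform time grid, which makes the strain-rate/strain pair
exactly consistent under the shared scheme.

The forward generator (`synthesize_waves`) produces gauge records for
an elastic–perfectly-plastic specimen under the standard assumption of
quasi-static specimen equilibrium: a trapezoidal incident pulse of
amplitude `v/(2 C0)` (striker speed `v ≈ 10 m/s`, 10% rise/fall) drives
a per-sample fixed-point solve of `σ(ε_s) A_s = E A_b ε_T` with
`ε̇_s = (2 C0/l_s)(ε_I − ε_T)`, iterated to 1e-10; `ε_R = ε_T − ε_I`,
so the force-equilibrium residual `ε_I + ε_R − ε_T` vanishes by
construction and is exposed as a diagnostic for external records.
Specimen geometries follow the dynamic tests: cortical 6 × 3 × 8 mm
loaded along the 8 mm axis; cancellous 5 × 6 × 6 mm.  The cancellous
load axis is not named in the source protocol; the 5 mm dimension is
taken as the loading axis (`l_s = 5 mm`, `A_s = 36 mm²`).  Resulting
specimen strain rates are ~1.2–2.0 × 10³ s⁻¹.

Yield extraction defaults to the plateau method: the initial modulus is
fit on the early loading leg, and the yield stress is the mean stress
over the samples (up to peak strain) where the tangent modulus has
dropped below 10% of it.  A 0.2%-offset method is available; a curve
that never leaves the linear regime returns an explicit no-yield
result.  For elastic–perfectly-plastic specimens the round trip
(synthesize → reconstruct → extract) recovers the input yield to
machine precision; the 1% test tolerance covers less idealised inputs.

## Materials

Per-region isotropic elasticity with abrupt failure.  Dynamic yield
defaults are the measured values for rabbit femur at ~10³ s⁻¹:
cortical 180 MPa, cancellous 8.9 MPa; the implant never fails.  Elastic
constants are literature-typical continuum values and are flagged
"assumed" in every run report (cortical E = 15 GPa, ν = 0.3,
ρ = 1900 kg/m³; cancellous E = 0.5 GPa, ν = 0.3, ρ = 500 kg/m³;
CP-titanium implant E = 110 GPa, ν = 0.33, ρ = 4500 kg/m³).  All values
are overridable from a YAML config with unit-suffixed keys; the
resolved library is echoed as JSON in every run report.

## Synthetic geometry

The micro-CT reconstruction chain is replaced by a parametric model: a
rectangular bone block (default 12 × 12 × 16 mm) on a structured grid
(default 1 mm), each hexahedral cell split into six tetrahedra sharing
the cell diagonal.  The split is conformal by construction, so the
implant–bone interface is a shared-node (perfectly bonded) interface —
the tie-constraint idealisation of complete osseointegration.  A
cylindrical implant (Ø4 × 8 mm) enters through the top face and crosses
a 1.5 mm cortical shell labelled on all outer surfaces; the rest is
cancellous, by centroid predicates.  The implant carries an exposed
head (default 2 mm above the bone surface): the experimental loading
struck the implant head above the bone, and a flush-top model cannot be
hit laterally at all; `implant_protrusion=0` restores a flush implant.
The default mesh has 13,968 elements — deliberately desk-scale;
image-based microstructural reconstructions of such systems run to
~3 × 10⁵ elements.

Cancellous bone is a homogeneous effective continuum (the dynamic yield
data are apparent-level).  `apply_trabecular_porosity` optionally
removes a seeded random fraction of cancellous elements as a stochastic
stand-in for unresolved trabecular architecture; it is off by default.
What the generator does *not* emulate: real trabecular microstructure,
implant threads, bone anisotropy, marrow, and the far-field anatomy
beyond the block — consequences are discussed under Limitations.

## Explicit dynamics

Small-strain elastodynamics on constant-strain tetrahedra with a
row-sum lumped mass matrix and central-difference (velocity-Verlet)
integration.  Stresses are linear-elastic Hooke; the patch test is
exact for affine fields.  The stable step is
`cfl_factor × min_e(h_e / c_d,e)` with `h_e` the minimum tet altitude
and `c_d = sqrt((λ+2μ)/ρ)`; `cfl_factor` defaults to 0.5 for headroom
with contact, and the run loop additionally respects the penalty-spring
bound `cfl × 2 sqrt(m_node/k)` on the contact patch.

Linear bulk viscosity is on by default (`b1 = 0.06`, the conventional
explicit-dynamics value): each element contributes a damping pressure
`b1 ρ c_d h_e tr(ε̇)`.  It enters the force assembly only — failure is
evaluated on the elastic stress — and its dissipation is carried in the
energy ledger.  Without it the fixed-face block is an undamped
resonator: reverberating waves keep deleting elements indefinitely and
the ineffective count never becomes a well-posed observable.  With it,
the deletion transient plateaus within ~0.4 ms of impact.

The impactor is a rigid sphere (Ø15 mm, 15 g — a steel ball) with
frictionless penalty contact against the exposed implant-head nodes:
nodes penetrating the sphere receive `k·g` along the sphere-surface
normal, with the exact opposite resultant on the sphere.  The default
penalty stiffness is 5× the stiffest adjacent nodal stiffness estimate
(implant modulus × grid spacing ⇒ k = 5.5 × 10⁸ N/m at defaults),
keeping penetrations at micrometre scale without dragging the global
time step below the CFL limit.  The 2 mm initial gap is crossed by
analytically advanced free flight (pure kinematics), which the stepped
time budget `t_end` does not charge.

The single-hit rule ("the ball is removed immediately after contact")
is implemented as permanent deactivation at the first *sustained*
separation — the gap must stay open for a 2 µs dwell *and* the sphere
must no longer be advancing along its approach direction.  The dwell
filters sub-microsecond contact chatter from nodal ringing; the
advance test prevents a spurious end-of-impact when the light implant
briefly outruns the ball after its apex support crushes (the ball
would physically recontact immediately).

Failure: after each step, every active cortical or cancellous element
whose von Mises stress has reached its region's yield strength (≥,
ties delete) is deactivated — stiffness removed, mass retained, event
logged with time and stress; implant elements are exempt and deletion
is irreversible.  Deleted elements' stored strain energy is moved to a
damage-dissipation account so the ledger (kinetic + strain + penalty +
impactor kinetic + deletion + viscous) stays conserved; on an undamaged
run the drift is below 1% of peak kinetic energy.

Runs stop at `t_end` or, after a completed impact, at
`max(5 × contact duration, 1 ms)` past release.  The floor exists
because contact lasts only ~20–30 µs while the delayed stress-wave
damage phase lasts several hundred µs, and a window proportional to
contact duration would truncate faster impacts harder.

## Load matrix, probes, convergence

Conditions combine impact speeds 4.0 / 5.1 / 6.3 m/s with directions
0° / 45° / 90° measured from the implant long axis (0° = axial).  The
speeds correspond to drop heights via free fall: √(2·g·0.8) → 4.0 and
√(2·g·2.0) → 6.3 m/s at printed precision; the 1.5 m case does not
match free fall (≈5.4 m/s) and the stated 5.1 m/s is taken as given.
The sphere centre is placed on the ray through the implant-axis entry
point along the approach direction, at the exact distance where its
surface clears the nearest head node by the 2 mm gap; velocity is the
condition speed along that ray.

Probes sample the von Mises stress of the element nearest a fixed
material point at every snapshot: "cortical neck" sits half a grid
spacing outside the implant radius at mid-shell depth; "cancellous
apex" sits on the axis 1 mm below the implant bottom.  A probe whose
element is deleted is truncated at the deletion time and flagged.  Both
locations are package choices and are configurable.

The convergence study repeats one condition over non-increasing grid
spacings and declares convergence at the first level whose peak probed
von Mises stress changes by <5% against the next finer level.

## Numerical and design choices

- Compression-positive sign convention throughout the SHPB module.
- 0-based indices; SI units internally; reports in the units stated.
- The equilibrium fixed point is a strong contraction (factor ~1e-4 at
  the default configurations); 200-iteration cap with a diagnostic
  error.
- The hot loop is a fused per-element kernel (numba-compiled when
  available, serial and therefore bit-deterministic; a plain numpy
  reference implementation backs it and is cross-checked in the tests).
- Determinism: identical config + seed give bit-identical reports;
  randomness exists only in the optional trabecular porosity, which
  requires a seed.

## Limitations

- The homogeneous continuum cancellous region pairs solid-continuum
  wave impedance with the apparent-level 8.9 MPa yield.  Under any of
  the studied impacts this saturates the peri-implant interface (most
  interface elements delete in every condition) and the implant
  debonds — a harsher damage regime than a microstructural model, in
  which element-level strength is tissue-level and apparent weakness
  emerges from architecture.  Ordinal comparisons of *total*
  ineffective counts across conditions are therefore fragile at desk
  scale: in the default configuration the total is not monotone in
  impact speed (faster impacts crush an apex cushion whose removal
  shields deeper bone and caps energy transfer), and the oblique 45°
  case ranks second (within 3%) rather than first by total count, even
  though its cortical sub-count is the largest, consistent with the
  bending mechanism.  The probe-timing observable (cortical stress
  peaks early; sub-apical cancellous stress peaks later and its damage
  continues after unloading) is robust.
- Small-strain kinematics; adequate because failure truncates elements
  before large strains accumulate, but post-debond implant motion is
  rigid-body translation through voided elements, not contact-resolved
  penetration.
- Deleted elements leave true voids (no densification/recontact of
  crushed material).
- No implant threads, no friction, no strain-rate-dependent moduli, no
  fatigue or progressive damage.
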