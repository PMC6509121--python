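# Methods

This note records the models implemented by `cartimech`, their
assumptions, the defaults and the places where the design was genuinely
open.

## Relaxometry

Magnitude signals are fitted per pixel with trust-region reflective least
squares (`scipy.optimize.least_squares`), with tight termination
tolerances (1e-14) so noise-free round trips recover generating
parameters to better than 1e-6 relative.  Initial guesses come from a
log-linearized decay for T1ρ/T2/T2\* and from the null-point heuristic
TI_min/ln 2 for inversion-recovery T1.  The T1 model is the magnitude
form |A[1 − 2e^{−TI/T1} + e^{−TR/T1}]|; the offset B is fitted for the T2
model only (background noise floor of the multi-spin-echo readout) and
fixed at zero elsewhere.

Assumptions and QC:

* additive Gaussian noise on magnitudes — no Rician correction in the
  fitter.  The phantom generator can inject true Rician noise; a seeded
  Monte-Carlo test characterizes the resulting positive bias of recovered
  decay times at low SNR rather than asserting a fixed number.
* echoes with TE > 60 ms are excluded for T2 and T2\* (both, since the
  acquisition rationale applies equally); exclusion is implemented by
  dropping the points, which is equivalent to zero-weighting them.
* boundary pixels are excluded by one-pixel 4-connected erosion of the
  mask (partial-volume guard), radius configurable; if erosion would
  empty the mask it is skipped with a warning so degenerate masks remain
  usable.
* fit quality is the adjusted coefficient of determination
  1 − (1−R²)(n−1)/(n−p−1); no hard cutoff is applied by default, an
  optional threshold masks poor pixels.  Optimizer failures are flagged
  with a −inf quality sentinel instead of raising, so one bad pixel
  cannot abort a map.

Default timing grids (ms): T1 inversion times 150/300/500/800/1000/1500
at TR 3000; T1ρ spin-lock 0–40 in steps of 10; T2 echoes n·8.38 for
n = 1–12 (the cutoff keeps n ≤ 7); T2\* echoes 3.9 + n·9.6 for n = 1–14.

## Composition

Depth is normalized per mask column: the first masked pixel of each
column is the articular surface (z = 0), the last the osteochondral
interface (z = 1); pixels are pooled into 20 depth bins (configurable).
The idealized depth-dependent mean composition used to anchor the
calibrations is shipped as an implementation default — fluid
0.85 → 0.70 and collagen 0.10 → 0.25 from surface to bone, both
quadratic in z, proteoglycan the remainder — and can be overridden by a
user table; the published source of this idealization is a figure, not a
formula, so only the qualitative shape (fluid decreasing, collagen
increasing) should be regarded as fixed.

The calibration Tx(φ) = a·e^{bφ} + c is fitted by least squares with a
log-linear initializer; its inverse φ(Tx) = ln((Tx−c)/a)/b is continuously
extended by constants outside the relaxation-time bounds of definition,
making it total, continuous and monotone (property-tested against a
bisection oracle).  Constant relaxation times leave b unidentifiable and
raise a calibration error.

The rational depth representation
φ̃(z) = (αz³ + βz² + γz + δ)/(εz + κ) shares a scale between numerator
and denominator; the gauge κ = 1 makes the coefficients identifiable, and
multiplying through by the denominator turns the fit into a linear least
squares.  If the optimum places a denominator root inside [0, 1] the fit
is repeated with ε bounded away from −1 (warning issued).  Evaluations
are clipped to [0, 1] since the quantity is a volume fraction.

Weighted combination and closure: Φ_ξ(z) = Σ_x w_Tx^ξ φ̃_ξ^Tx(z), with
each constituent's four weights summing to one (tolerance 1e-8); the
proteoglycan fraction is the saturation remainder and must stay at least
Δtol = 1e-6 everywhere, otherwise construction fails naming the offending
depth.  No direct proteoglycan calibration exists — it is defined by
closure, mirroring how the fluid and collagen fractions are the
qMRI-informed quantities.

## Constitutive model

The tissue is a biphasic mixture restricted to the relaxed
(time-independent) configuration: fluid flux, permeability and the
chemo-mechanical potential term are out of scope by construction.  All
phases are intrinsically incompressible, so volume loss equals fluid
loss, and the admissible volume ratio is bounded below by the compaction
point J → Φ_s = 1 − Φ_f, where the osmotic multiplier diverges.

The energy is the ground truth and the Cauchy stress is its exact
derivative, assembled as σ = J⁻¹ F S Fᵀ with
S = 2J^{−2/3}[S̄ − ⅓(S̄:C̄)C̄⁻¹] − πJC⁻¹ (so the osmotic Cauchy
contribution is the pure pressure −πI).  A central-difference oracle
verifies energy–stress consistency to 1e-5 relative on 100 seeded random
states, and objectivity σ(QF) = Qσ(F)Qᵀ holds to machine precision.

Two deliberate choices resolve ambiguities in the published closed
forms:

* **Dispersion-weighted tension invariant.**  The fibril tension
  invariant is Ī4ᵢ = tr(C̄ L̃ᵢ) with the generalized structure tensor
  L̃ᵢ = (w/3)I + (1−w)mᵢ⊗mᵢ — the Gasser–Ogden–Holzapfel convention —
  rather than the unweighted mᵢ⊗mᵢ.  With the unweighted tensor the
  energy gradient at the reference configuration is
  Φ_co·k1·w·dev(Σᵢ mᵢ⊗mᵢ) ≠ 0 for the arcade at any inclination off the
  magic angle, i.e. the reference would not be stress free and the w = 1
  limit would not be isotropic.  The weighted invariant makes S̄(I)
  exactly isotropic (Σᵢ[f′(1)L̃ᵢ + g′(1)(I−L̃ᵢ)] = nI), which the
  deviatoric projection annihilates; together with π(1) = 0 the reference
  is stress free for every admissible composition, dispersion and
  parameter set.  The published closed-form fibril stress attaches f′ to
  the weighted tensor too, which corroborates this reading.  The
  unweighted invariant remains available via
  `invariants(..., weighted_i4=False)`.
* **Published stress as an alternate path.**  The printed closed-form
  S̄ = Φ_co Σᵢ k1[(f′−g′)L̃ᵢ + g′K̄ᵢI] + Φ_pg a0 I evaluates
  ∂K̄/∂C̄ at the reference only (it drops the C̄-dependent terms
  K̄C̄⁻¹ − det(C̄)C̄⁻¹L̃C̄⁻¹).  Both paths are implemented
  (`cauchy_stress(..., method="energy" | "printed")`); they coincide at
  F = I and diverge under load, and a test asserts exactly that rather
  than silently preferring one.

Other conventions: the fibril sum runs over a single family count
(default 8); the single dispersion weight w is shared by all families;
the exponential tension term is evaluated for all Ī4ᵢ with no
tension-only switch (the K̄ term carries the compressive tube-contraction
response); the fibril contribution is dropped below Φ_co = 1e-8 because
the stress scales with Φ_co while the energy constant 1/k̃2 would
overflow; exponents are clipped at ±500 to avoid overflow during
optimizer excursions.  The arcade inclination profile is linear,
θ(z) = 90°·z, and configurable.

Default global parameters: k1 = 0.6 MPa, k2 = 50, k3 = 25, a0 = 0.35 MPa,
a1 = 5, w = 0.3; weights (T1, T1ρ, T2, T2\*) = (0.41, 0.42, 0.16, 0.01)
for fluid and (0.31, 0.12, 0.11, 0.46) for collagen.

A scale observation the acceptance script makes quantitative: under
these defaults and the idealized composition the forward model yields
≈ 2.3 MPa nominal stress and ≈ 31 MPa tangent stiffness at 15 % strain,
driven almost entirely by the osmotic exponent 2·Φ_f·a1 ≈ 7.5, whereas
the bundled cohort table reports a measured mean stiffness of
1.53 ± 0.68 MPa.  The defaults and the idealized composition therefore
describe a much stiffer tissue than the measured cohort mean; the
package treats the parameter set and the measured table as independent
inputs and does not attempt to reconcile them.

## Column solver

The confined test is idealized as a series column: N uniform-thickness
layers (default 20), zero lateral strain (F = diag(1,1,λ) per layer, so
J = λ and nominal and Cauchy axial stresses coincide), rigid piston and
wall.  Equilibrium demands a depth-uniform axial stress and
thickness-weighted strains summing to the applied strain.  Layer
compositions are exact averages of the field's piecewise-linear
interpolant; architectures are evaluated at layer midpoints.

The solver is a damped Newton iteration on (λ₁…λ_N, s) with an
analytically reduced linear solve (the Jacobian is diagonal-plus-rank-one)
and a vectorized closed-form stress kernel: under the diagonal confined
deformation all equiangular families of a layer share the same
invariants, so the family sum collapses to a multiplier.  The kernel is
cross-checked against the full tensor evaluation to machine precision.
Convergence tolerance is 1e-11 MPa on the stress residual (the strain
constraint is linear and satisfied exactly); warm starts propagate along
the loading protocol.  On the rare non-convergence the solver falls back
to nested bracketed root finding.  Tests compare two-layer solutions
against an independent nested-bisection oracle to 1e-8.

The loading protocol defaults to twenty 1 % steps to 20 % total strain;
the 1 %/min ramp rate is metadata because only relaxed states are
modelled (tare preload and thickness determination are likewise not
simulated; measured curves are assumed re-zeroed at the tare state).
Stiffness at ε = 15 % defaults to the tangent modulus (central-difference
slope interpolated from adjacent protocol points); the secant σ(ε₀)/ε₀
is available behind a flag since the published quantity does not state
its definition.

## Inverse identification

All samples are fitted simultaneously with one shared parameter set.
Residuals are normalized per sample by ‖y‖ so stiff samples do not
dominate (the published account does not specify the error metric).  The
optimizer is trust-region reflective least squares with bounds; the
weight normalization Σ_x w_Tx^ξ = 1 holds by construction through
elimination of one weight per row (the largest-weight modality), with
negative excursions clipped, renormalized and penalized.  Forward-model
failures under a candidate (compaction, saturation, solver) contribute a
large penalty residual instead of raising, and are logged.  Multi-start
(default 3 seeded restarts, best-of) guards against local minima at
moderate cost; the published workflow used an unspecified constrained
optimizer, so this is a package choice.

Identifiability: k1 and the collagen weight row are partially
confounded (both scale the fibril stress through Φ_co), as are a0 and
the fluid row through the osmotic exponent.  `parameter_sweep` exposes
1-D objective profiles as a diagnostic.  The bundled recovery study uses
three synthetic samples whose per-modality depth profiles carry
independent smooth perturbations — the inter-modality contrast is what
makes the weight rows identifiable.

## Phantoms

Synthetic stacks are forward-simulated from depth-graded truth
relaxation profiles (defaults, surface → bone: T1 900 → 600 ms,
T1ρ 60 → 35 ms, T2 80 → 45 ms, T2\* 45 → 25 ms, spanning the bundled
cohort's per-sample means) on the default timing grids, with Gaussian or
two-channel-Gaussian (Rician) magnitude noise; all generators are
deterministic under a fixed seed, and a seed is mandatory whenever noise
is on.  Mechanical samples perturb the idealized composition profiles
per modality with quadratic perturbations pinned to zero at z = 1 (where
the saturation margin is smallest), combine them with the default weight
set, and simulate the default protocol under the default material
constants; measurement noise is multiplicative (2 % in the recovery
study).  Default geometry: 64×64 pixels with depth along rows, 4.2 mm
sample thickness, 12 layers for generated samples.

What the phantoms do not emulate: partial-volume effects, B0/B1
inhomogeneity, magic-angle effects, inter-contrast misregistration, and
any systematic mismatch between the idealized composition profiles and
real tissue.  Passing recovery tests therefore demonstrates correctness
and identifiability of the pipeline under its own model assumptions, not
accuracy on scanner data.

## Problem sizes and numerical defaults

Test and script problem sizes are chosen to exercise every code path at
comfortable cost: phantom frames 10–16 px in tests, 12 layers for
generated samples, 20 layers for forward studies (20- vs 80-layer curves
differ by < 0.01 %), three samples × two to five replicate seeds in
recovery studies.  Tolerances: saturation closure 1e-10, Δtol 1e-6,
equilibrium stress residual 1e-11 MPa, weight normalization 1e-8,
compaction guard 1e-9.

## Known limitations

* Equilibrium only: no poroelastic transients, permeability or
  viscoelasticity; ramp-and-hold histories are not simulated.
* The series-column idealization omits lateral wall friction and any 3-D
  end effects of the physical test.
* The idealized composition profiles and the exponential
  calibration anchors are modelling choices, not measurements; absolute
  composition values inherit their uncertainty.
* The global parameter set is a point estimate; beyond 1-D sweeps no
  uncertainty quantification is provided.
* DICOM and scanner-specific formats are out of scope (NIfTI/TIFF only).
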