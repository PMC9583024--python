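# Methods

## Scope and model

`axonve` treats the axonal cytoskeletal core as a linear viscoelastic,
orthotropic composite: unidirectional microtubules (MT) on a triangular
lattice in the transverse plane, cross-linked by Tau protein, in an
axoplasmic matrix.  Direction 3 is the MT axis.  Nine independent Prony
relaxation functions (C11, C12, C13, C22, C23, C33, C44, C55, C66 in Voigt
arrangement) close the constitutive law through the Boltzmann hereditary
integral.  Strains are small; the shear components use the *engineering*
shear convention (γ = face displacement / box dimension), which matches how
the displacement-controlled shear load cases are normalized.  Initial
strain is fixed at zero; histories with nonzero initial strain are
rejected.

## Constituent materials

**Tau.**  Literature values characterize Tau as a Kelvin–Voigt solid
(E = 5 MPa, retardation time 0.35 s, hence viscosity 1.75 MPa·s).
Relaxation-type solvers need a General Maxwell form, so a
standard-linear-solid is matched to the Kelvin–Voigt creep response with the
equilibrium spring pinned to E and the branch dashpot to μ; the branch
stiffness is m·E.  The creep discrepancy (maximum absolute difference over
t ∈ [0, 5 τ_ret] at 500 log-spaced points, normalized by the asymptotic
strain) decreases monotonically with m, so "best" has no interior optimum;
the conventional multiplier m = 100 is exposed as a default rather than
re-derived.  It gives a branch relaxation time μ/(100 E) = 3.5 ms.
Young's→shear conversion uses the correspondence principle; with a
time-constant Poisson's ratio (0.33) the transform-domain relation
collapses to term-wise division by 2(1+ν), preserving all relaxation times.
A symbolic-transform oracle in the tests confirms the collapse.

**Matrix.**  Compressible neo-Hookean with G = E/(2(1+ν)),
K = E/(3(1−2ν)), d = 2/K from E = 1.47 kPa, ν = 0.33.  The strain-energy
function itself belongs to the solver and is out of scope.

**Tau bulk relaxation** (needed only by the synthetic generator's
parameterization, not by any reported quantity) is assumed to share the
shear time constants, scaled by E/(3(1−2ν)).

## RVE geometry and volume fractions

The unit cell is the rectangular cell of the triangular lattice: two MTs
(corner + centre), box a1 = p, a2 = √3·p, a3 = 2L with pitch
p = d_MT + 2 R_O.  `d_MT` is interpreted as the transverse *wall-to-wall*
spacing: the observed drop of the MT fraction from 0.185 to 0.094 when d_MT
goes 20 → 38 nm matches the (45/63)² inverse-pitch-squared scaling exactly,
which an axial-gap reading would not produce.

Each MT carries one axial discontinuity of gap_MT = 20 nm per 500 nm
half-span, placed uniformly at random (seeded) within the central 80% of
that half-span.  The resulting axial coverage 0.96 turns the cross-sectional
wall fraction 0.1921 into a volume fraction 0.1844.  Gap *placement* affects
only the exported geometry, never the volume fractions.

Tau cross-links are flat-capped cylinders of radius R_tau and length d_MT
(surface to surface), normal to the MT axis, three per MT per axial
station (six unique bonds per two-MT cell; each bond shared by two MTs of
the hexagonal coordination).  Stations are spaced d_tau apart within the
central 80% window of the RVE length — the same central window that carries
the MT discontinuities — giving 20 stations for the base geometry.  This
window convention is the package's choice where the exact CAD convention is
unknowable; it reproduces the reference Tau fractions of all four geometry
presets within 10% (0.0344/0.0774/0.0688/0.0333 against
0.036/0.085/0.071/0.036), whereas full-length station placement
overestimates them by ~19%.  A quasi-Monte-Carlo voxelization oracle in the
tests confirms the closed-form counting against the explicit segment
geometry to 0.5%.

## Relaxation test and stress evaluation

The characterization protocol is a trapezoidal strain history: ramp to the
plateau strain ε* over (t0, t1], hold to t2, unload to t3, recover to t4,
with defaults 0/3/12/15/40 ms and ε* = δ/a for a 3 nm face displacement.
Six displacement-controlled load cases drive ε1, ε2, ε3, γ23, γ13, γ12 in
turn; case 1 identifies C11, case 2 C12 and C22, case 3 C13, C23 and C33,
and cases 4/5/6 the shear diagonals, using the transverse stress components
of the same run for the off-diagonal functions.

Stress evaluation integrates the exponential kernel *exactly* over each
linear strain segment, eliminating time-step sensitivity; the four-phase
closed form is the same mathematics specialized to the trapezoid and
evaluated with non-positive exponents only (overflow-safe for any relaxation
time the optimizer explores).  A plain trapezoidal quadrature of the
hereditary integral (step 1 µs) is kept *outside* the library as the
independent oracle in the tests and the acceptance script.

## Prony regression

`PronyRelaxationModel` fits {C0, h1..hn, τ1..τn} (n = 2 by default; n = 1
supported) to a volume-averaged stress history by weighted least squares.
Numerical choices:

* **Constraints.**  C0 and τk are log-parameterized (positivity), hk carries
  [0, 1] box bounds, and Σhk ≤ 1 a smooth quadratic penalty, so a damped
  least-squares step remains applicable throughout.  Outputs are projected
  so the thermodynamic constraints hold exactly.
* **Weights.**  σ_SD is not identifiable from the synthetic data; unit
  weights by default, overridable per point.
* **Initialization.**  C0 from the stress/strain ratio at t1, h = (0.3,
  0.6), τ = (t1, t2 − t1); five seeded multi-starts jitter this guess to
  escape the near-degeneracy when two relaxation times approach each other.
  A user-supplied guess violating the constraints is projected into the
  feasible set with a warning.
* **Jacobian.**  Analytic, exploiting that the response is linear in C0 and
  in each hk for fixed τ.
* **Polish.**  Optima with Σhk = 1 sit on the penalty kink where the
  bounded solver stalls; an unconstrained damped (Levenberg–Marquardt)
  refinement from the best multi-start is accepted only when it stays
  feasible and lowers χ².  This resolves nearly coincident relaxation-time
  pairs (e.g. 4.63/4.64 ms) from noiseless data.
* **Tie-break.**  Branches are reported sorted by ascending τ; comparisons
  against reference coefficient sets are made modulo branch relabelling,
  since the Prony series is invariant under branch exchange.
* **Non-convergence** is flagged on the results object, not raised.

Coefficients across repeated observations are summarized as mean ±
standard error (sample standard deviation over √N; absent for N = 1).  The
reference summary mixes observations from different geometries into one
mean ± SE; the package reproduces that summary shape but the heterogeneity
should be kept in mind.  Confidence intervals from the fit Hessian are
deliberately not produced.

## Synthetic generator

The generator stands in for a finite-element solve.  It produces, per load
case, element-wise stress/strain histories on a shared grid (default step
0.05 ms over the 40 ms protocol) whose volume-weighted mean equals the
exact forward-model response: element noise (relative Gaussian, seeded) is
projected to zero volume-weighted sum, so averaging tests and regression
tests are decoupled by construction.  Element volumes are a seeded
Dirichlet partition of the box volume.  It does **not** emulate spatially
correlated stress fields, mesh geometry, stress concentrations at the MT
discontinuities, or the stiffening of a nonlinear large-strain solve —
so passing round-trip tests demonstrate the correctness of the averaging
and regression machinery, not fidelity to any particular solver's field
output.

For the damage stage the generator emits micro-strain histories under a
constant axial strain-rate ramp: MT strain follows the volume-averaged
strain one-to-one, while the Tau population-mean maximum principal strain
is amplified by a concentration factor.  The default 5.48 is a documented
*calibration* (40% Tau failure strain / 7.3% axon failure strain), not a
derivation; it stands in for the micro-field amplification a solver would
produce, where the highest Tau strains occur near MT ends.

## Effective transverse modulus

The transverse cross-section is layered: optional myelin sheath (fraction
1 − g² of the sheath disc, modulus 3·K_ms·(1 − 2ν_ms)), a 10 nm
actin–spectrin membrane, a 200 nm soft inner region, and the cytoskeletal
core using the short-term transverse modulus C11,0 as its stiffness.  The
effective modulus is the harmonic (Reuss, series) mean [Σ α_p/E_p]⁻¹ — the
formula is read as the inverse rule of mixture by its own naming, and
because an inverted plain sum would carry wrong units.  When myelinated,
the inner fractions are renormalized by g² so all fractions sum to one.
The inner-region fraction at which the curve crosses an experimental
target modulus is solved by bisection and *reported*, not asserted: the
crossing depends on the exact core/membrane stiffnesses used for the
reference curve, which are not recoverable.

## Damage evaluation

Failure criteria: Tau at 40% maximum principal strain, MT at 50% axial
strain.  The earliest criterion crossing (linear interpolation between
samples, default micro-field sampling 0.01 ms) sets the failure time;
axon failure strain is rate · t_fail and failure stress the closed-form
ramp response of C33 at t_fail.  Ramps are capped at 12% axon strain; if
no criterion is crossed within the cap, the result reports no failing
component.  Because the micro-field model is a pure scaling of the applied
ramp, the failure *strain* is rate-independent while the failure *stress*
grows with rate (less relaxation time) — the qualitative signature of
viscoelastic stiffening.

**Limitation.**  Failure stresses from the homogenized linear Prony model
are much lower than what a nonlinear large-strain solve with explicit stiff
MT fibres produces; the module therefore reports linear-model stresses and
additionally accepts user-supplied micro-stress/strain series (e.g.
exported solver data) for direct criterion evaluation.

## Problem sizes and determinism

Default problem sizes: 801-point histories per load case, 5 multi-starts
per fit, 50 random models for the closed-form/oracle comparison, 30 ground
truths for the recovery study, 2¹⁹ Sobol points for the geometry oracle.
All randomness — noise, element partitions, gap placement, multi-start
jitter, random model draws — flows from explicit integer seeds; equal
configurations reproduce byte-identical outputs.

## Known limitations

* No frequency-domain (storage/loss) outputs, no temperature dependence,
  no tensor rotation of the orthotropic matrix, no large-strain
  constitutive law for Tau.
* No meshing or contact resolution in the geometry; MTs are straight,
  Tau cylinders may touch MT walls only at their flat ends.
* No Tau–MT interfacial strength or phosphorylation-driven detachment;
  perfect bonding is implicit in the linear model.
* The Tau volume-fraction convention (station window, surface-to-surface
  length) reproduces the reference fractions to ~10%, reflecting genuine
  ambiguity in the reference geometry's CAD conventions.
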