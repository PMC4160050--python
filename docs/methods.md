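# Methods

`ligknee` compares two ways of representing knee ligaments inside one
quasi-static tibiofemoral model: **anatomic fiber bundles** with an
anisotropic hyperelastic (Holzapfel–Gasser–Ogden, HGO) material, and
**simplified uniaxial trusses** with a tension-only quadratic-toe/linear
law.  Everything else — geometry, contact, muscle loads, load cases — is
held identical, so kinematic differences between the two model variants are
attributable to the ligament representation alone.  This note records the
models, the defaults and why, what the synthetic data do and do not emulate,
and the numerical choices.

## 1. Constitutive model

Ligament tissue is modeled as an incompressible fiber-reinforced solid with
strain-energy density

    psi = c/2 (I1bar - 3)  +  sum_i  k1/(2 k2) [ exp(k2 E_i^2) - 1 ],
    E_i = kappa_i (I1bar - 3) + (1 - 3 kappa_i)(I4bar_i - 1),

where `I1bar = tr(Cbar)` and `I4bar_i = a0_i . Cbar a0_i` are isochoric
invariants, `a0_i` the mean fiber direction, and `kappa in [0, 1/3]` the
fiber-dispersion parameter (0 = perfectly aligned, 1/3 = isotropic).  `E_i`
is algebraically identical to the usual `kappa I1 + (1-3 kappa) I4 - 1`; the
increment form is used so it vanishes *exactly* (in floating point) in the
reference state.  Collagen supports tension only: a family contributes while
`E_i > 0` (default; C1-continuous at the switch because energy and stress
are quadratic/linear in `E` there).  The alternative switch `I4bar > 1` is
available per material (`recruitment="i4"`); the two differ only for
strongly dispersed families transverse to the stretch.

Incompressibility is an input contract (`det F = 1` within 1e-9), not a
penalty.  The Cauchy stress is

    sigma = -p I + dev( Fbar Sbar Fbar^T ),
    Sbar  = c I + sum_i 2 k1 E_i exp(k2 E_i^2) H_i,
    H_i   = kappa_i I + (1 - 3 kappa_i) a0_i (x) a0_i,

with `p` the constraint pressure.  For uniaxial tension,
`F = diag(lam, lam^-1/2, lam^-1/2)` and `p` is eliminated from the
traction-free out-of-plane face (`sigma33 = 0`; for fibers in the
load/transverse plane this is the plane-stress condition, and for fibers on
the load axis `sigma22 = sigma33` so both lateral faces are free).  The
analytic stress is verified against central finite differences of the
energy to 1e-6 relative over random incompressible deformations.

Units: MPa, mm, N, N·mm; degrees at public interfaces, radians internally.

## 2. Calibration

Coefficients are identified from uniaxial engineering-strain/stress curves
by bounded trust-region least squares on `uniaxial_stress(1 + strain)`,
with bounds `c > 0, k1 >= 0, k2 > 0, 0 <= kappa <= 1/3`.  Two-family
(cruciate) fits share `c, k1, k2, kappa` and fit a symmetric bundle
half-angle `theta in [0, 45] deg` — one uniaxial curve cannot separate
per-bundle coefficients.  Because exponential models are multi-modal, a
5-restart seeded multi-start wraps the solver; the lowest residual wins
(ties to the lowest `k2`), and a result worse than the initial guess is
never accepted (returned with `converged=False`).  A flat-residual probe
(double `k2`, cost unchanged) flags `k2` non-identifiability, e.g. on
neo-Hookean data.

**Identifiability caveat.**  Noise-free generate-and-refit recovers all
coefficients to better than 1%.  Under realistic multiplicative noise the
(k1, k2, kappa) triplet is *sloppy*: a Cramér–Rao analysis at 2% noise
gives best-case relative standard deviations near or above 100% for k1/k2
and worse for kappa, for any strain range and point count a tensile test
plausibly provides.  Fitted coefficient values from noisy curves are
therefore reported as a set reproducing the curve, not as individually
meaningful parameters.  The fitted *response* is stable.

**Presets.**  ACL and PCL carry two symmetric fiber families (bundle
half-angles 12 and 15 deg), MCL (superficial) one family, and the LCL
copies the MCL, matching the modeled bundle structure of the source study.
The numeric coefficients (e.g. MCL: c 1.44 MPa, k1 4.0 MPa, k2 60,
kappa 0.02) are plausible defaults shaped to published cruciate/MCL tensile
behavior (tens of MPa at ~10% strain); the study itself prints no fitted
values, so these are explicitly *not* paper numbers.

## 3. Uniaxial truss law

The simplified representation uses the canonical tension-only ligament
spring: zero force when slack, `f = k eps^2 / (4 eps_l)` in the toe region
`0 < eps <= 2 eps_l`, and `f = k (eps - eps_l)` beyond — C1-continuous and
non-decreasing.  Default constants are Blankevoort-style single-bundle
values (ACL 10000 N, PCL 18000 N, MCL 4000 N, LCL 2000 N total per
ligament, `eps_l = 0.03`), split equally over the trusses (3 per ligament
by default).  These are deliberately *not* refit to the HGO response: the
study's question is precisely how the common simplified law, with its
customary constants, changes joint kinematics.

## 4. Joint coordinate system

Rotations are reported in the clinical three-axis convention: femoral
medial–lateral axis e1 (flexion), tibial long axis e3 (internal/external
rotation), floating axis e2 = e3 × e1 (ab/adduction, valgus positive).
With body frames x = anterior, y = proximal, z = medial–lateral this is the
intrinsic z–x–y Euler sequence; the decomposition is singular at
|abduction| = 90 deg and raises rather than extrapolating.  Translations
are the clinical projections `t . e_i` on the (non-orthogonal) JCS axes;
composition inverts those projections exactly, so compose/decompose
round-trips to 1e-9 deg.  All sign conventions are the package's own — the
source figures' conventions are unrecoverable — and the synthetic corridors
use the same conventions, so comparisons are internally consistent.

## 5. Reduced-order knee model

This is an explicit desk-scale surrogate, *not* a finite-element model:
rigid femur and tibia, two femoral condyle spheres (radius 21 mm, centers
±22 mm on the flexion axis) in penalty contact (2000 N/mm) with a tibial
plateau plane, ligaments as line elements, and two resultant muscle cables.
What it preserves from the full-model methodology is the comparison design:
identical attachments and loads for both ligament representations, the four
load cases, and corridor-based validation.  What it gives up: articular
surface geometry, menisci, cartilage deformation, finite-sliding contact,
the patellofemoral joint, and non-uniform strain *within* a ligament cross
section beyond the sampled fiber lines.

Key model elements and the reasoning behind them:

- **Fiber bundles.**  Each anatomic ligament is n (default 10) parallel
  fiber lines sampled center-out over elliptical attachment footprints
  (sunflower pattern), equal area split, with slack lengths set at full
  extension through per-ligament reference strains (ACL +4%, PCL −2%,
  MCL +3%, LCL +2% — Blankevoort-style pre-strains; PCL slack in
  extension).  Fiber tension is `max(sigma11(lam), 0) × reference area`,
  and the fiber potential is the consistent integral `A L0 ∫ sigma dlam`
  (Gauss–Legendre, 12 points), so the solver's energy gradient reproduces
  exactly these tensions.
- **Plateau slope.**  The tibial plateau plane has an 11 deg posterior
  slope (upper range reported for young female athletes, the source
  subject's population).  Because the plane's distance from any point on
  the flexion axis is rotation-invariant, condyle contact is preserved
  through the flexion arc; under internal rotation the lateral condyle
  rides onto lower (more posterior) surface, reproducing the medial-pivot
  coupling of internal rotation into valgus.
- **Corner restraints.**  Posterior capsule bundles (medial, lateral,
  oblique), an anterolateral structure (ALS) and a posterior oblique
  ligament (POL) are tension-only trusses present in *both*
  representations (the study substitutes only the four main ligaments).
  The ALS (slack at reference, engaging at ~1% rotation strain) is the
  dominant internal-rotation restraint; POL and the oblique capsule are
  taut near extension and release with flexion, which — together with the
  pre-strained, obliquely oriented ACL — produces the screw-home internal
  rotation over early flexion against the small internal bias of the
  medially offset hamstrings.
- **Muscles.**  Quadriceps (400 N) and hamstrings (200 N) act as
  constant-tension cables from tibia-fixed attachments to femur-fixed via
  points (patellar and proximal-posterior anchors) that follow the
  prescribed flexion; the cable potential is tension × length, so lines of
  action realign with joint motion instead of carrying a frozen direction.
  The full model's 13 muscle trusses are reduced to these two resultants.
- **Load cases.**  The registry holds exactly four: abduction moment ramp
  0→50 N·m at 25 deg flexion; the same ramp plus constant 20 N·m internal
  torque; the unloaded 0–90 deg flexion sweep; and 15 N·m internal torque
  over the sweep — all with muscle loads on, 50 steps by default, moments
  in N·mm internally (N·m × 1000 at interfaces).

The default geometry was designed (once, then frozen) so that the surrogate
exhibits the documented qualitative behaviors of the knee under these
loads: monotone valgus under the abduction ramp (~6 deg at 50 N·m),
internal-rotation/valgus coupling (the combined case's valgus never below
the pure case's), the screw-home rise of internal rotation over 0–20 deg
flexion, and degree-scale divergence between the two ligament
representations.  Each geometric choice above names the mechanism it
implements; none is a fitted quantity.

**Equilibrium.**  Flexion is prescribed; the remaining five DOF (valgus,
internal rotation, three translations) minimize total potential energy
(ligament + truss + contact penalty − applied-moment and muscle work).
Applied abduction/internal moments are conjugate to the JCS angles.  The
solver is BFGS on batched central-difference gradients followed by a damped
Newton polish (finite-difference Hessian, eigenvalue-shifted), warm-started
along ramps, iteration cap 200.  The first point of a loaded case ramps the
constant loads up in sub-steps to stay in the basin.  Convergence demands a
*normalized* residual below 1e-6: the max generalized-force component
divided by the gross internal load (applied moments plus 50 mm × the sum of
element tensions, contact forces and muscle magnitudes) — an absolute
1e-6 N·mm is below floating-point noise for energies of order 1e4 N·mm.
Reported solutions carry their residual; non-convergence raises with the
failing step identified.

## 6. Synthetic data: what a green test establishes

The study's raw inputs (digitized tensile curves, CT/MRI geometry, a
19-specimen cadaveric corridor) are not available, so generators stand in:

- `synth_tensile_curve` — the HGO closed form plus i.i.d. Gaussian noise,
  clipped at zero.  Emulates the smooth toe-then-stiffening character of
  ligament tensile data; does not emulate strain-rate effects, hysteresis,
  failure, or grip artifacts.
- `default_geometry` — the frozen fixture above.  Literature-plausible, but
  a *single* synthetic knee; no claim of subject-specific accuracy.
- `synth_specimen_corridor` — 19 perturbed anatomic models per case
  (material coefficients ×lognormal cv 4%, attachments ±0.5 mm, reference
  strains ±0.003), solved individually; the corridor is the pointwise mean
  ± t(0.975, n−1) × sd, i.e. a 95% *specimen-population* band.  A
  mean-CI band (sd/√n ≈ 0.5 deg wide) is deliberately not used: the source
  reports predictions with RMSE above 2 deg as lying inside its corridors,
  which is only arithmetically possible for degrees-wide specimen bands.

Because the corridor is generated from the anatomic model family, the
anatomic representation is the better match *by construction*.  A green
comparison therefore establishes that the machinery (simulation, metrics,
report) reproduces the study's qualitative pattern under its stated design
— higher r, lower RMSE and full containment for the anatomic model, the
uniaxial model outside the bands — not that either representation is
closer to real cadaveric kinematics.

Default seed 20130501; every stochastic operation takes an explicit seed
and is bit-reproducible.

## 7. Numerical choices and degenerate inputs

- Fiber/truss engagement at exactly zero strain contributes zero force and
  energy; switches are closed (≤) on the slack side.
- The fiber stress exponent `k2 E^2` is clamped at 350 inside the
  vectorized uniaxial path only, to keep exploratory solver steps finite;
  the clamp is unreachable below ~100% fiber strain.
- Corridor membership uses a 1e-9 band tolerance for float-edge points;
  curves are resampled to the corridor abscissa by linear interpolation
  before metrics, and r/RMSE are computed against the corridor mean.
- Coincident element endpoints, singular poses, non-volume-preserving
  deformation gradients, missing config blocks and double uniaxial
  substitution raise typed errors (`ligknee.errors`).
- Multi-start ties in calibration break to the lowest `k2`; the fit is
  fully deterministic given the data and the initial guess.

## 8. Known limitations

- Sphere-on-plane contact has no congruency: axial-rotation restraint
  comes entirely from soft tissue, so absolute rotation magnitudes at
  15–20 N·m sit at the upper end of cadaveric ranges.
- Fiber tension uses Cauchy stress × reference area (a model definition,
  consistent with its energy); a nominal-stress definition would differ by
  the factor lam (≤ ~15% at physiologic strains).
- The two-family cruciate calibration constrains both families to shared
  coefficients; per-bundle differences are not identifiable from one curve
  and not modeled.
- Noisy-data coefficient recovery is limited by genuine model sloppiness
  (Section 2); only the response, not the coefficient vector, should be
  interpreted.
- Quantitative agreement with the source study's r/RMSE values is out of
  scope: those numbers depend on its cadaveric corridors and full FE
  model, neither of which is available.
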