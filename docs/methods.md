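# Methods

`protonrem` is a desk-scale, fully deterministic re-implementation of a
margin-reduction workflow for pencil-beam-scanning (PBS) proton therapy of
mediastinal targets.  Clinical planning systems, Monte Carlo dose engines and
deformable image registration are replaced by small, analytically known
components so that every stage of the chain — robust optimization, dose
mimicking, 3D and 4D robustness evaluation, risk modelling, paired
statistics — can be tested against closed forms and brute-force oracles.
This note records the models, their parameters, and the design choices made
where the design was genuinely open.

## Synthetic 4D thorax phantom

The phantom is a voxelized thorax-like geometry on an axis-aligned grid
(default 3 mm isotropic; the cohort study uses 48³ voxels ≈ 14 cm cube, unit
tests 32³): an elliptical body, two low-density lungs (relative stopping
power 0.26), a heart (1.05) caudal-posterior of a mediastinal CTV, left and
right breasts (0.95), thyroid and esophagus.  Structure masks are pairwise
disjoint; the CTV has rasterization priority so the heart mask excludes
target voxels, which keeps mean-heart-dose a pure spill-over quantity.

**Breathing.**  Motion is a single smooth spatial envelope times a
sinusoidal phase factor over 10 phases,

    u(x, p) = a(x) · d̂ · s_p,      s_p = (1 − cos 2π(p − p_ref)/10) / 2,

with the end-of-exhale reference fixed at phase index 5 (s_5 = 0, peak
inhale at phase 0).  The direction d̂ is predominantly cranio-caudal with an
anterior–posterior component (0, 0.35, 0.94); the envelope `a(x)` is an
anisotropic Gaussian (σ = 14, 14, 16 mm) centred 16 mm caudal of the CTV,
rescaled so the realized point-max displacement over the CTV equals the
configured value exactly.  Requested point-max values of 5–20 mm then
produce CTV mean motions of roughly 0.5–10 mm, spanning the magnitudes
typical of mediastinal targets.  The envelope/offset combination keeps the
deformation Jacobian below 1, so the forward map x ↦ x + u is a
diffeomorphism.

**Field convention.**  Each phase stores `dvf_to_reference` on the
*reference* grid, pointing reference → phase (the fixed-image = reference
convention of deformable registration).  Phase images are built by
resampling the reference through the numerically inverted map (fixed-point
iteration to < 0.01 voxel; the round-trip error is well below the 0.1-voxel
contract).  Dose accumulation therefore warps with the analytically known
field — registration error is zero by construction, which is intentional:
the pipeline under test is the evaluation logic, not a registration
algorithm.

**Internal target volume.**  The ITV is the union of the per-phase CTV
masks on the common scanner grid — the envelope a clinician would contour.
With zero motion it equals the CTV exactly; under a rigid k-voxel
translation it is the CTV dilated along the motion axis.

**Average anatomy.**  The planning anatomy is the equal-weight per-voxel
mean of the phases, each first warped to the reference through its field.

**Weekly variation.**  Each of the 8 weekly snapshots composes the
breathing model with a smooth random systematic displacement (Gaussian
noise, smoothed at σ = 5 voxels, normalized to a maximum magnitude drawn
from U(0.5, 1) × 2 mm).  An optional multiplicative density drift is off by
default.  Weekly snapshots reuse the planning phantom's phase inverses as
warm starts, and their phase fields point from the *planning* reference so
longitudinal accumulation needs no field composition.

Not emulated (and hence not validated by passing tests): Hounsfield
calibration and realistic tissue heterogeneity, cardiac motion, baseline
drift and irregular breathing, contour uncertainty, and registration error.
Conclusions about real patients require all of these.

## Dose engine

Each spot deposits

    D(x) = w · G(ℓ₁ − p₁) · G(ℓ₂ − p₂) · B(WEPL(x) · ρ, R) · RBE,

with an isotropic lateral Gaussian `G` (per-spot σ, truncated at 3σ) in
beam-frame coordinates (ℓ₁, ℓ₂), and a Bragg-curve surrogate in
water-equivalent depth:

    B(d, R) = 0.25 + 0.75 (d/R)³            for d ≤ R,
    B(d, R) = normalized Gaussian falloff   for R < d < R + 3σ_f,  else 0,

with distal falloff σ_f = 3 mm (exact zero at R + 9 mm; the truncated tail
is shifted so the curve is continuous).  The peak-to-entrance ratio is 4,
the unique maximum sits exactly at the nominal range.  RBE is a constant
factor 1.1; plan weights are calibrated so a plan's grid is the total-course
dose in Gy(RBE).

WEPL is the cumulative density integral along the beam axis (midpoint
rule), computed by resampling the density onto a beam-aligned grid; for
axis-aligned beams the computation is exact.  Beams are coplanar (gantry
about the longitudinal axis, 0° anterior), matching the anterior/posterior
arrangements used clinically for mediastinal fields, and letting one lateral
spot axis coincide with z.

Scenario semantics: a rigid setup shift δ moves the lateral spot pattern by
the in-plane components of δ, while the WEPL of an anatomy voxel is
invariant under rigid translation — so the along-axis component of a shift
leaves the dose unchanged, as it (to first order) does for real protons.
On a uniform medium the dose field is exactly translation-equivariant for
lateral shifts, which the tests exploit as an oracle.  A "range"
uncertainty of ±3 % is a density scale ρ ∈ {0.97, 1.03} multiplying the
WEPL integrand.  Dose is scored only in material voxels (density > 0):
vacuum absorbs no energy.

No Monte Carlo noise is simulated (the clinical 1 % statistical uncertainty
would only blur the oracle tests), and there is no nuclear halo, scattering
heterogeneity correction, or variable RBE.

## Scenario sets and per-fraction errors

* optimization: {no shift, ±setup·ê_x, ±ê_y, ±ê_z} × density {1−r, 1, 1+r}
  = 21 scenarios;
* evaluation: 6 axis shifts plus 8 body-diagonal shifts (normalized to the
  setup-uncertainty sphere; a `component` convention is available) ×
  density {1−r, 1+r} = 28 scenarios;
* per-fraction: each of the (default 14) scenarios draws one systematic
  setup vector plus independent per-fraction random vectors, isotropic
  zero-mean Gaussians.  The stated 2 mm total residual setup magnitude is
  split van Herk style (M = 2.5Σ + 0.7σ with Σ = σ), giving component SDs
  of 2/3.2 = 0.625 mm.  Systematic range levels {−3, 0, +3} % are assigned
  5/4/5 across the 14 scenarios.

Enumeration order is deterministic (nominal first, axes x, y, z with
negative before positive, diagonals in sign-lexicographic order, density
innermost) so scenario indices are stable across runs.

## Robust optimization

Spot positions tile the target: lateral grid at 1σ spacing over the
beam's-eye-view projection of the target dilated by the setup margin, energy
layers spanning the target's WEPL extent padded by the range-uncertainty
excursion plus the distal falloff.  The study configuration uses σ = 7 mm
spots (a realistic width for shallow mediastinal fields treated through a
range shifter) and 10 mm layer spacing, which keeps desk-scale plans at
600–800 spots.

The objective is a weighted sum of dimensionless terms (quadratic residuals
are expressed in % of prescription, mean doses as fractions of
prescription, so behaviour is independent of the 19.8 vs 30 Gy(RBE)
course):

* a **worst-case target term**: one-sided quadratic underdose below
  1.02 × Rx evaluated on the *voxel-wise minimum* dose across the 21
  optimization scenarios (each voxel's residual attributed to the scenario
  realizing its minimum), plus a mild hot-spot penalty above 1.07 × Rx on
  the voxel-wise maximum, weight 10;
* **OOI mean-dose terms** on the nominal scenario, weight 1 per organ and
  0.15 for the body (conformity pressure).

The 2 % overcoverage margin mirrors clinical prescription practice: the
voxel-wise minimum distribution is less favorable than any single scenario,
so single-scenario coverage must land above the >95 %/98 % gate.  The
voxel-wise worst-case composite was chosen over selecting one
lowest-coverage scenario per iteration because it optimizes exactly the
quantity the gate evaluates and gives a stable first-order descent
direction (single-scenario minimax subgradients stall when two scenarios
tie).  The lowest-D98 scenario is still identified and reported with the
result.

The solver is projected gradient descent with Armijo backtracking
(objective trace monotone non-increasing by construction, weights
non-negative, iteration cap 200–300, relative tolerance 1e-6).  Influence
matrices are built sparsely and row-restricted to the voxels each term
touches.  After optimization a minimum-MU deliverability filter drops spots
below 10⁻³ of the largest weight.

## Dose mimicking

Plans at reduced setup uncertainty are regenerated from the reference plan
by minimizing (i) a one-sided quadratic penalty for OOI voxel doses
exceeding the reference nominal dose (weight 20 × the organ weight),
(ii) the one-sided worst-case underdose below prescription over the
*reduced* scenario set, and (iii) the same OOI mean-dose terms as the
planner, acting as an active sparing pressure.  Term (iii) is what converts
the freed robustness margin into organ sparing: with only (i) and (ii) the
reference weights would already be optimal and nothing would change.  The
reference's nominal-scenario dose is mimicked (a voxel-wise-minimum
reference would double-count robustness); optimization starts from the
reference weights.  Mimicking at a setup uncertainty not smaller than the
reference's is rejected.

## 3D robustness evaluation (3DREM)

All 28 evaluation-scenario doses are computed on the planning (average)
anatomy, aggregated voxel-wise into the minimum distribution, and the
clinical gate applied to the target (the ITV): D98 > 95 % of prescription
and V95 > 98 %, both strict, evaluated on exact voxel-sample DVHs with the
floor convention for D-at-volume (no interpolation — conservative for
coverage).  OOI metrics (mean doses; lung V5 and breast V4, thresholds read
as 5 %/4 % of the prescription dose) are taken on the nominal dose and
reported in both % of structure volume and cm³, since either unit appears
in clinical summaries.  The degenerate setting `su = 0` evaluates the
nominal scenario only.

## 4D robustness evaluation (4DREM)

Eight fractions × 14 scenarios.  Delivery timing is simulated — 10 ms per
spot event, 1 s energy-layer switch, 5 s beam switch — values chosen once
as representative PBS timing; with ~50 spots per layer one painting takes
~0.5 s, a fraction of the 4.5 s breathing cycle, so five-layer repainting
genuinely averages over phases.  Each spot event is assigned the phase
`floor(((t/T + φ₀) mod 1) · 10)`; the starting phase φ₀ is drawn uniformly
per (fraction, scenario).  Fraction f uses weekly anatomy f (1:1).  Spot
doses are computed per phase on the weekly anatomy under the fraction's
setup/range perturbation, warped to the planning reference through the
known fields, summed, averaged over fractions with equal weights, and
scaled by n_clinical/n_simulated to a course total.  Voxel-wise mean and
minimum over the 14 scenario courses give the expected and worst-case
delivered dose; coverage is gated on the reference-phase CTV of the
voxel-wise minimum (same thresholds as planning), OOI metrics on the
voxel-wise mean.

In the static limit (zero motion, zero errors, unchanged weekly anatomy)
the accumulated course reproduces the 3D static dose to relative L∞ below
1e-6 — the cross-module consistency anchor between the two evaluation
paths.

## Outcomes and statistics

Lifetime acute-coronary-event risk follows the linear relative-risk form
NTCP = baseline × (1 + c · MHD), with the per-Gy excess coefficient
c = 0.074/Gy(RBE) by default and the individual's baseline lifetime risk
supplied as input (the baseline already encodes age — floored at 40 years,
the model's validation boundary — sex and cardiac risk factors).
Population-specific recalibrations are configuration, not code.  ΔNTCP is
photon-minus-proton risk; model-based selection passes at ΔNTCP ≥ 2
percentage points (boundary included).

The Wilcoxon signed-rank test is implemented exactly for up to 25 non-zero
differences by a subset-sum dynamic program over doubled ranks (zero
differences dropped, ties get average ranks; two-sided
p = min(1, 2·min(CDF, SF))), with a tie- and continuity-corrected normal
approximation beyond.  Fewer than 5 non-zero differences trigger a warning
but still return the exact value.  Bonferroni thresholds keep the unrounded
α/m internally and display it rounded to three decimals (0.05/3 → 0.017).
Cohort values are reported as median (range), even-sized samples using the
mean of the middle two.

## Study conditions

The cohort driver runs 10 synthetic patients on 48³ grids: course
schedules (15 × 2.0 or 11 × 1.8 Gy(RBE)) and per-patient point-max target
motion (5–20 mm) follow the emulated case mix, with CTV size/position
jittered per patient; baseline ACE risks are drawn from U(6, 14) % and
synthetic photon comparator MHDs from the proton reference MHD plus
U(2.5, 7) Gy(RBE).  Per patient: robust plan at 5 mm, mimicked plans at 4
and 3 mm, 3DREM at each plan's own setup uncertainty, and 4DREM under one
identical comprehensive error realization for all three plans (the 4D
comparison is between plans, not error draws).  All randomness derives from
the single study seed; reruns are bit-reproducible.  These problem sizes
(48³ voxels, ~700 spots, 8 × 14 fraction-scenarios) are the package's
desk-scale operating point — large enough for the spatial trends to be
meaningful, small enough to run a full cohort in minutes.

## Known limitations

* The Bragg and lateral models are shape surrogates; absolute dose levels
  are internally consistent, not benchmarked against measured depth-dose
  data.
* Axial setup-shift invariance is exact here but only approximate in
  reality (inhomogeneity boundaries move).
* The phantom's organ topology is fixed; only sizes, positions and motion
  vary across the synthetic cohort.
* The ACE model is linear in MHD with a configurable slope; no nonlinear
  or dose-volume cardiac endpoints are modelled.
* Statistical behaviour is demonstrated on n = 10 paired synthetic
  patients; the Wilcoxon exact machinery is general, the cohort is not.
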