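# Methods

This note records the models, conventions, numerical choices and known
limitations behind `facesym`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## 1. Head frame and plane construction

3D photographs carry no bony landmarks, so the Frankfort horizontal (FH)
orientation is realized through a soft-tissue surrogate: the plane through
the **left and right tragion** and the **midpoint of the two exocanthia**.
The head frame is anchored at the tragion midpoint with

* `axis_transverse` — unit vector from right to left tragion (+x toward the
  subject's left),
* `axis_vertical` — the FH normal orthogonalized against the transverse
  axis, oriented upward,
* `axis_anterior` — completing the right-handed triad, pointing out of the
  face.

The **coronal plane** is spanned by the transverse and vertical axes
through the tragion midpoint. The **midsagittal plane** passes through
sellion and subnasale and is perpendicular to the coronal plane; its normal
is therefore ∝ `axis_anterior × (Sn − Se)`, signed to point toward the
subject's left. Both constructions are exactly covariant under rigid motion
of the inputs (verified to 1e-6). Users with an externally defined frame
(e.g. from a scanner's own orientation) can supply it via
`AsymmetryConfig.frame`, bypassing the surrogate.

## 2. Mirror-superimposition registration

The mirrored surface must be registered back onto the original by a
best-fit rigid motion before distances are measured. Choices, and why:

* **Correspondence: closest point on the target surface** (exact
  point-to-triangle projection), not nearest vertex. Nearest-vertex
  matching plateaus at the mesh sampling resolution: in instrumented runs a
  5° rotation stopped ~4° short of recovery because every vertex snapped to
  a fixed partner. Surface correspondence removes the plateau.
* **Initialization: landmark Procrustes.** The reflected landmark set with
  left/right tags swapped is paired with the original landmarks (midline
  points map to themselves); the Kabsch solution of those ≤ 6 pairs starts
  the iteration near the optimum.
* **Two phases, trimmed second.** Classical untrimmed ICP converges
  globally but is biased by the very asymmetry being measured: a localized
  unilateral deformation drags the optimum by roughly
  Σ(residuals)/surface-area (~0.03 mm for a 0.9 cm³ bump on this fixture),
  which, spread over the measured regions, inflated volumes by ~25% in
  untrimmed runs. The refinement phase therefore excludes the
  `icp_trim_fraction` (default 0.1) of source points with the largest
  residuals. Trimming cannot be used from a cold start — the excluded
  large-residual pairs are exactly the ones carrying the global alignment
  signal — and the excluded set is **frozen** once after the global phase:
  re-trimming every iteration makes the iteration cycle near the cut
  instead of converging. Setting the fraction to 0 recovers classical ICP.
* **Convergence: maximum point motion of the incremental step** below
  `tol`, not RMS change. The step criterion has a true fixed point and is
  insensitive to membership churn. Defaults: `tol = 1e-5` mm for the
  generic routine, `1e-4` mm inside the asymmetry pipeline; `max_iter =
  500` per phase. Point-to-point ICP contracts linearly (rate ≈ 0.97 per
  iteration on these smooth surfaces), and the slow modes are tangential
  sliding, which does not perturb surface-to-surface distances — a 1e-4 mm
  step tolerance leaves the normal-direction alignment bias around 2·10⁻⁴
  mm, two orders of magnitude below scanner-level noise (~0.1 mm).
  Non-convergence sets a flag on the result, never raises.

## 3. Regions and volumetric integration

Cut levels are taken along `axis_vertical`: the mean level of the two
exocanthia, the mean level of the two cheilia, and the menton level (means
keep the cuts symmetric and deterministic for asymmetric landmark pairs).
Faces are assigned by centroid: **midface** between cheilion and
exocanthion levels, **lower face** between menton and cheilion levels,
everything else **outside**. The **nasal exclusion** relabels faces inside
a head-frame-aligned box: laterally the alare span ± 5 mm (configurable),
vertically subnasale level → exocanthion level, unbounded anteriorly. The
supraorbital region needs no separate handling; the exocanthion cut already
removes it.

The volumetric difference integrates |closest-point distance| from
original-face centroids to the aligned mirror, weighted by face area
(one-sided integration over the original surface; the half-sum two-sided
variant is available as `two_sided_integration`). The whole-face value is
defined as midface + lower face, exactly additive by construction. Under
this convention a unilateral hemispherical bump of radius r measures
≈ 2·(2/3)πr³: the bump side contributes its height integral over the
curved surface (πr³) and the mirror-bump side the crater integral (πr³/3).
Acceptance checks recover the r = 6 mm bump within 5% at ≥ 20k faces with
< 2% change on refinement, and verify additivity, the symmetric-face null
(< 1e-6 cm³), rigid invariance (< 0.5%), and strict monotonicity in the
injected chin-shift magnitude. cm³ values are rounded (2 decimals) only in
the CLI/report layer.

## 4. PA-cephalometric conventions

* Midline: CG–ANS by default; CG–U1 available (`convention="cg_u1"`). The
  two coincide for a symmetric dentition; the choice is recorded in the
  output metadata because maxillary asymmetry moves U1 and can mask
  midfacial discrepancies.
* Component distances are unsigned; the five side differences are signed
  a − b (so, e.g., a longer contralateral mandibular body gives a negative
  Go–Me diff). The midline–U1 distance is signed positive toward the
  deviated side, identified by the side of Me relative to the midline
  (falling back to the side of Go(a) when Me lies on it).
* FP and FP′ are treated as infinite lines for perpendicular distances.
* Angles are acute, unsigned, in [0°, 90°].
* Film-plane millimetres are taken at face value; no magnification
  correction is applied.

All 28 formulas are checked against an independent second implementation
on randomized fixtures (1e-9), under rigid motions (1e-9), and for the
symmetry null.

## 5. Statistics

* Pearson r via the standard product-moment estimator; two-sided p from
  t = r√((n−2)/(1−r²)) with n−2 df; R² = r². Cohen's R² classes with
  lower-inclusive boundaries: very weak < 0.02 ≤ weak < 0.13 ≤ moderate
  < 0.26 ≤ substantial. No multiple-testing correction by default (the
  28 × 3 screen is exploratory); Benjamini–Hochberg is available.
* Dahlberg TEM = √(Σd²/2n); reliability R = 1 − TEM²/σ² with σ² the
  sample variance of the pooled measurements.
* ICC(A,1): single-measure, absolute-agreement, two-way model, from the
  ANOVA mean squares (McGraw–Wong form); all-identical tables return 1 by
  convention. Landis–Koch labels: < 0 poor, ≤ 0.20 slight, ≤ 0.40 fair,
  ≤ 0.60 moderate, ≤ 0.80 substantial, else almost perfect. Cross-checked
  against pingouin and a hand ANOVA.
* Exact correlation power: the critical value on the r scale comes from
  the null t distribution; power integrates the exact non-null sampling
  density of r (hypergeometric-series form, evaluated in log space with
  `scipy.special.hyp2f1`) by adaptive quadrature (tolerance 1e-6). The
  smallest n with power ≥ target is found by forward search. For
  ρ = 0.50, α = 0.05 two-tailed, power 0.80 this gives n = 29 (Fisher-z:
  30); a 50 000-replicate Monte-Carlo oracle agrees within sampling error.

## 6. Synthetic data: what it emulates, and what it does not

**Faces.** The generator builds the front of an ellipsoid-like dome
(half-width 70 mm, half-height 85 mm, peak depth 80 mm) with a Gaussian
nasal ridge, landmarks placed analytically on the surface, and a default
resolution of 40 000 triangles (≈ 1 mm spacing, mimicking clinical
stereophotogrammetry). Grid x-coordinates are stored antisymmetrically and
the depth field is even in x, so the undeformed mesh is mirror-symmetric to
machine precision — the pipeline's null is exactly testable. Deformations:

* `bump` — hemispherical outward displacement, radius r mm; one-sided
  displaced volume (2/3)πr³ exactly (returned as ground truth).
* `lateral_shift` — transverse displacement with a C¹ quartic window of
  radius 25 mm; nominal planar displaced volume s·π·25²/3.

Sites (chin, cheeks, jaw angles) may not overlap. What the generator does
**not** emulate: scanner noise and holes, hair/eyebrow artifacts, skin
texture, facial expression, and realistic anatomical shape variation.
Passing tests therefore demonstrate correctness of the measurement chain,
not clinical robustness to acquisition artifacts.

**PA landmark sets.** A symmetric schematic frontal skull at clinically
plausible scale; menton offset and occlusal/gonial/jugale cants map exactly
onto midline–Me, ∠Ocl, ∠Fmp, ∠J; optional Gaussian jitter models tracing
error.

**Cohorts.** Multivariate normal, calibrated to the reference descriptive
statistics (means/SDs of all 28 measurements and the three regional
volumes) and to the published R² map. Volumes come first with correlation
matrix Σ_v; each measurement attaches as m = b′f + e with b = Σ_v⁻¹ρ,
ρ = sign·√R², making measurements conditionally independent given the
volumes while reproducing every measurement↔volume correlation exactly.
Σ_v defaults to the additivity-implied correlations of the volume SDs
(whole = mid + lower gives cov(mid, lower) from the three variances),
shrunk 5% toward the identity because the exact additivity matrix is
singular — notably, the reference descriptives themselves are not exactly
additive (11.32 ≠ 1.90 + 7.99), so Σ_v is a modelling choice, documented
and configurable. Published tables report only R², not signs, so all signs
default to positive. Rows whose implied explained variance would exceed 1
are scaled back with a warning (none at defaults). Volumes are *not*
clipped at zero by default: the reference analysis models the data as
normal, and clipping (which would affect ~27% of midface draws) attenuates
the calibrated correlations; `clip_volumes_at_zero=True` is available when
non-negativity matters more than calibration.

**Repeated measures.** Two sessions = truth + independent N(0, TEM²)
errors, so the expected Dahlberg TEM equals the prescribed value.

## 7. Study orchestration

`run_study` in `mesh` mode draws a per-subject skeletal menton deviation
|N(4.26, 3.43²)| mm that drives both the 3D chin shift and the PA menton
offset (plus an independent cheek bump U(0, 5) mm and landmark jitter of
0.5 mm), measures every subject through both pipelines, and reports
Table-style descriptives (mean, t-based 95% CI with n−1 df, SD, min, max)
and the R²/effect-class matrix. `cohort` mode samples the calibrated
multivariate cohort directly. Reports round to 3 decimals; all inner
computation is full precision; reruns with the same seed are byte
identical. Tests run the mesh mode at reduced size (a few subjects, 2 000
faces); the defaults (33 subjects, 40 000 faces) are the intended
study-scale configuration.

## 8. Known limitations

* The asymmetry score is undirected: it cannot distinguish anteroposterior
  from transverse discrepancies.
* The commercial mirroring software used in clinical practice documents
  neither its best-fit objective nor its integration sides; absolute
  volumes from this package can differ from it by a method-dependent
  offset. The additive whole = mid + lower convention here is one such
  difference.
* The FH surrogate (tragia + exocanthion midpoint) is a convention;
  supplying a different frame shifts the region cuts.
* Cohort calibration reproduces first and second moments and the published
  effect-size map, not the unpublished full correlation structure among
  measurements.
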