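# Methods

## The model

`hipshape` implements the standard statistical shape modelling (SSM)
pipeline for 2D hip morphology, together with the epidemiological
analysis layer that relates shape to radiographic hip osteoarthritis
(RHOA) and hip pain.

A hip is represented by an ordered configuration of P = 58 landmark
points placed on the bone edges of a DXA projection: the acetabular
"eyebrow" and rim (with one medial and two lateral key points), the
femoral head, the superior and inferior femoral neck, both trochanters
and the upper shaft. Point indices are anatomical: index k marks the
same locus on every image. Left hips are reflected into the right-hip
frame before any modelling; the alignment itself never reflects, so
anatomical chirality is preserved.

**Alignment.** Generalized Procrustes analysis (GPA) removes
translation, rotation and scale. In 2D the ordinary (pairwise) problem
has an exact closed form in complex notation: for centred shape z and
reference w, the optimal rotation-plus-scale is the complex scalar
⟨z, w⟩/⟨z, z⟩. The generalized fit iterates pairwise alignment to the
current mean, mean recomputation, re-centring and renormalization of
the mean to unit centroid size, until the root-mean-square change of
the mean falls below `tol = 1e-8` (cap `max_iter = 100`; synthetic
cohorts converge in 3–5 iterations). Because scaling is removed, size
is not a model variable. The converged mean is unique only up to a
global rotation, so the frame is canonicalized by rotating the mean
until its first landmark lies at zero angle from the centroid; this
makes results independent of input order and of any global similarity
transform applied to the raw data. The monotone quantity across
iterations is the sum of squared full-Procrustes distances to the
iterate mean (the raw coordinate sum-of-squares is not comparable
across iterations because of the unit-size renormalization).

**Shape modes.** PCA of the aligned coordinate vectors (covariance
matrix, via SVD of the centred data) yields the point-distribution
model: mean shape, orthonormal eigenvector "modes", eigenvalues, and
per-mode variance fractions taken against the full covariance trace.
An individual's raw projection on a mode is standardized by the
training cohort's per-mode mean and SD, so scores are in cohort SD
units (training scores have mean 0, SD 1 per mode by construction).
Shapes are reconstructed as mean + Σ (de-standardized score) ×
eigenvector; the ±2 SD reconstructions are what the mode-shape figures
draw (dashed = +2 SD, solid = −2 SD). Similarity alignment removes
four degrees of freedom from the 2P coordinates, so at most
min(n−1, 2P−4) modes may be requested; the association battery uses
the top 10 by variance. Eigenvector signs out of an eigendecomposition
are arbitrary and odds ratios flip with them, so each mode is oriented
so that its largest-magnitude loading is positive (ties broken by
lowest index). Tangent-space projection before PCA is deliberately not
performed (a toggle was considered and rejected: the classic
point-distribution-model recipe runs PCA directly on aligned
coordinates, and at the shape variation levels involved here the two
differ negligibly).

**Quality control.** Mode scores beyond ±4 SD flag an image for manual
review (they usually indicate landmark placement errors); flagged
images are reported, not auto-excluded, with an optional
`drop_flagged` switch. Operator accuracy on a shared training set is
the median, pooled over all (image, point) pairs, of the distance
between an operator's point and the all-operator average point —
including the scored operator's own placement in the average, which
matters: a leave-one-out average would inflate the metric. A median of
≤ 3 pixels is acceptable. The pooled median (rather than a per-image
median of medians) is a documented reading of "median point-to-point
difference".

## Outcomes

Radiographs are scored for joint space narrowing (JSN; medial,
lateral, concentric, 0–4), osteophytes at four sites (0–3),
subchondral sclerosis, cysts and femoral head deformity (0–3). The
Croft aggregate is: 0 no features; 1 osteophytosis only; 2 JSN only;
3 two of {osteophytosis, JSN, sclerosis, cysts}; 4 three of those
four; 5 grade-4 criteria plus head deformity — with "presence" meaning
any site/region at grade ≥ 1. RHOA is Croft ≥ 2 (primary) or ≥ 3
(sensitivity). One corner case deserves note: a film showing only
sclerosis or only cysts matches none of grades 1–5 and is graded 0,
consistent with the requirement that radiographic OA involve
osteophytes or JSN; whether such films were ever graded ≥ 3 in the
original reading protocols is unknowable from the aggregate
definition. The mapping is monotone non-decreasing in every component
grade, and the severe definition is nested in the moderate one.

Pain outcomes: binary pain on internal rotation; a 0–4 walking-pain
score dichotomized at ≥ 1; and the WOMAC composite (pain + stiffness +
function) on 0–20. Printed percentages round half-up to one decimal.

## Association analysis

Each of the top-10 modes (SD units) is a continuous exposure. Binary
outcomes use maximum-likelihood logistic regression; WOMAC uses
proportional-odds (ordinal logistic) regression with a common odds
ratio across thresholds. Results are OR per SD with Wald 95% CIs
exp(β̂ ± 1.96·SE) and two-sided Wald p-values (the Wald construction is
a documented default; the CI method behind published symmetric-on-log
intervals is rarely stated). Adjusted models add age, height, weight
and race, the latter indicator-coded against the "white" reference
(largest category). Missingness is handled complete-case per outcome,
and `n_used` is reported per cell. With ten modes as independent
exposures the Bonferroni threshold is 0.05/10 = 0.005.

Numerical details: Newton's method occasionally stalls on
near-separated tables (rare outcomes in small cohorts); the fitter
falls back to BFGS and accepts a solution when the gradient is below
1e-4, raising a `SeparationError` otherwise (and whenever |β̂| > 20,
the signature of an unbounded likelihood). The WOMAC tail is sparse,
so ordinal levels are merged downward from the top until every
modelled category holds ≥ 5 observations (configurable). The
proportional-odds assumption is asserted, not tested. A two-level
ordinal outcome reproduces the logistic fit to ~1e-6, which is used as
a cross-model consistency check. Per-cell model failures in the
battery are recorded in an `error` column rather than aborting the
run.

## The synthetic cohort generator

No landmark-level hip shape dataset is publicly deposited, so the
pipeline is exercised on synthetic cohorts whose defaults emulate an
elderly-male cohort of the kind the analysis targets: n = 4,100,
age ~ N(72.8, 5.5²) years, height ~ N(174.4, 7²) cm, weight ~
N(83.6, 13²) kg, race mix 90.7% white / 3.3% Asian / 3.2% African
American / 2.8% other; target prevalences RHOA 7.1%, pain on
examination 11.4%, pain on walking 20.2%; WOMAC right-skewed with
mean 0.9 (72% zeros with a geometric tail, ratio 0.689, giving
SD ≈ 2).

**Shapes.** A deterministic 58-point right-hip template is drawn from
parametric arcs and lines (head circle radius 22 px, concentric
acetabular arc, neck saddle, trochanteric bumps). Shape variation is
planted as four deformation fields: *pincer-like* (lateral acetabular
rim displaced laterally and inferiorly over the femoral head,
extending coverage), *cam-like* (radial bone apposition at the
superior head–neck junction), and two nuisance fields
(lesser-trochanter size; linearized neck-shaft-angle rotation). Before
Gram–Schmidt orthonormalization the fields are projected onto the
orthogonal complement of the four similarity-tangent directions
(translations, scaling, rotation) at the template — only that
component of a field survives Procrustes alignment, so planting the
projected fields is what makes the planted subspace exactly
recoverable by the shape model. Loadings are Gaussian with SDs
(3.0, 2.0, 1.5, 1.0) px; isotropic landmark noise has SD 0.2 px
(modest digitization error, ≤ 20% of the smallest planted mode SD so
the four-mode structure stays identifiable at n = 1000); each image
then receives a random similarity transform (rotation ±0.15 rad,
log-scale ±0.1, translation ±25 px). All randomness derives from one
seed through named `SeedSequence` children, so stages are
independently reproducible.

**Outcomes.** Planting inverts the analysis models and operates on
*true* loadings standardized by their own cohort SD (not on fitted
scores), keeping the ground truth model-free. RHOA case status is
Bernoulli with logit = α + log(1.23)·z_pincer + log(1.37)·z_cam +
small age/weight terms; α is calibrated numerically (Brent's method)
so the expected prevalence equals the target, and a realized miss of
more than 2 percentage points at n ≥ 4000 raises a calibration error.
The planted per-SD effects echo the magnitudes reported for
pincer-positive and cam-associated modes in cohort studies of this
design (1.23; 1.37 ≈ 1/0.73). Cases then receive component grades
constructed to reach a target Croft grade drawn from a mix
(grade 2 : 3 : 4 : 5 = 0.654 : 0.20 : 0.10 : 0.046, matching the
moderate/severe split 289 vs 100), with site/region mixes weighted so
lateral acetabular osteophytes and medial JSN dominate, as in the
target feature table; non-cases receive at most osteophytes
(Croft ≤ 1), or occasionally sclerosis alone. By construction every
case carries osteophytes or JSN. Binary pains follow their own
calibrated logistic models (cam effects log(1.19) and log(1.14));
walking pain and WOMAC are drawn from proportional-odds models whose
thresholds are shifted to hit P(≥1) = 0.202 and mean 0.9 respectively.

**What the generator does not emulate.** Real DXA landmarking noise is
spatially correlated and operator-dependent, not isotropic; real shape
variation has dozens of modes with a smoothly decaying spectrum rather
than four planted fields plus white noise; radiographic grades are
generated *from* case status rather than from anatomy, so
feature-level associations are inherited from the RHOA model rather
than biologically distinct; and the planted fields are geometric
idealizations labelled by construction — no alpha-angle or
centre-edge-angle calibration is attempted. Passing tests therefore
demonstrate the correctness and statistical calibration of the
machinery, not clinical validity on real images.

## Problem sizes in the shipped checks

The test suite and the acceptance script choose sizes that make
sampling error small relative to the tolerances they assert: subspace
recovery at n = 1000 (principal angles < 5°, mode SDs within 10%);
logistic effect recovery over 200 replicates of n = 4000 (mean β̂
within 3 Monte-Carlo SEs); ordinal null calibration over 300 permuted
replicates of n = 1000 (Kolmogorov–Smirnov at the 1% level);
prevalence calibration at n = 10,000; the end-to-end demo at n = 500,
run twice to confirm bit-identical outputs under a fixed seed. The
full-size acceptance run uses n = 4,100.

## Known limitations

- 2D similarity shapes only; no 3D, no missing-landmark handling, no
  robust/weighted Procrustes.
- The GPA mean is a local optimum of a non-convex problem; with
  anatomically plausible variation the iteration is far inside the
  basin of attraction, but pathological shape sets could converge
  elsewhere.
- Mode interpretation (which fitted mode "is" cam or pincer) is done
  in the generator's frame by correlating fitted scores with true
  loadings; on real data that labelling step is a human judgement and
  is out of scope.
- Ordinal regression relies on the proportional-odds assumption
  without a blocking diagnostic.
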