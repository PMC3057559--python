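# Methods

This note documents the statistical models, the synthetic-data calibration,
and the numerical and design choices behind `sasangface`.

## Landmark scheme and metric definitions

The package operates on 20 manually placed 2-D facial points: P1–P14 plus
six "primed" eyebrow points P9p–P14p directly above the periocular points.
Coordinates follow the image convention (x rightward, y downward), so
"vertical" distances are absolute y differences; all other distances are
Euclidean. The published point scheme is given only as a figure, so the
point semantics used here (P1 forehead/P2 chin midline, P3/P4 cheekbones,
P5/P6 gonion, P7/P8 the fWHR height endpoints, P9–P12 outer/inner eye
corners, P13/P14 pupils) are this package's documented convention; the
reading is fixed by the point budget and by the lower-face definition
referencing the pupils, and it is encoded in one place
(`landmarks.POINT_SEMANTICS`).

Two definitional choices matter:

* **Eye size** is read as (d(P9,P10) − d(P11,P12))/2 — the mean width of a
  single eye when P9/P10 are outer and P11/P12 inner corners. The literal
  alternative reading "outer span minus half the inner span" yields values
  near 60 mm, far from the published 28–33 mm scale; the chosen reading
  reproduces that scale.
* **PAR** uses the closed five-edge cycle P3→P5→P2→P6→P4→P3 (the published
  wording lists P3 twice, implying closure) and the absolute shoelace area,
  so vertex orientation never flips the sign. Self-intersecting polygons
  and zero areas are rejected with diagnostics.

All metric computation is done in millimetres. Pixel-unit landmark tables
require an explicit mm-per-pixel scale, because the study reports eye size
and eyebrow height in mm but never states its own scale factor.

Test–retest reliability is summarised as the per-metric coefficient of
variation, 100·SD/mean across repeated landmarkings (sample SD), reported
as the min–max range over subjects — the form in which the study reports
its own operator reliability (0.4–5.53%).

## Group comparison

Differences across the three constitutional types are assessed per
sex × age stratum with one-way ANOVA, followed by Duncan's multiple range
test. For a span of p adjacent ordered means the critical range is
q(α_p; p, df)·√(MSE/n_h) with the protection level α_p = 1 − (1−α)^(p−1)
and n_h the harmonic mean of the group sizes (the study's groups are
unbalanced and its software convention is unstated; harmonic-mean n is the
common convention and is documented as ours). A range is non-significant
only together with every containing range, and groups inside a
non-significant range share a letter. Letters descend a, b, c with the
means. Default α = 0.05, matching the study's starring convention.

The studentized-range quantile comes from scipy's numerical integration of
the distribution (no closed form exists) and is memoized; the test suite
pins it against published q-tables at two decimals. Two consequences of
Duncan's construction are worth noting because they bound what simulations
can show: under the null, all three groups share a single letter with
probability exactly 1 − α₃ ≈ 0.90 (not higher), and Duncan's critical
ranges never exceed Tukey's HSD, so Duncan never merges a pair that Tukey
separates.

## Correlation comparison

Pooled BMI–metric associations use the Pearson correlation with the
t-distribution p-value (n−2 df). Two independent correlations (r₁,n₁),
(r₂,n₂) are compared on the Fisher-z scale, z = atanh(r), with variance
1/(n−3) and a **two-sided** normal p-value: the two-sided convention
reproduces every recomputable published comparison p-value at two decimals,
while a one-sided reading does not. Stars follow .05/.01/.001.

One published cell (female WHR, young-vs-old comparison) prints 2.43, which
equals the z statistic of that comparison rather than its p-value
(≈ 0.015) — an apparent typesetting error; the package reports the p-value
and that cell is not used as a reference value anywhere.

## TE classification

TE vs non-TE is modelled by binary logistic regression. Fitting is
Newton/IRLS with step halving, declared converged when the log-likelihood
changes by less than 1e-10; Wald standard errors come from the inverse
observed information. Perfect separation (classes split by a hyperplane,
diverging coefficients) is detected and either raised or flagged; a small
ridge penalty (1e-4) is available as a stabilised fallback and is used
automatically only for leave-one-out folds that separate. The in-package
IRLS is cross-checked against statsmodels' `Logit` in the test suite; it
exists because model averaging and leave-one-out validation need thousands
of small refits.

Model uncertainty is handled by exhaustive BIC-based Bayesian model
averaging over all 2⁸ subsets of the eight candidate predictors (BMI plus
the seven metrics): BIC = −2·loglik + k·ln n with k counting the
intercept, weights w_m ∝ exp(−BIC_m/2) under a uniform model prior (the
study names the approach and BIC but no prior), per-predictor inclusion
probabilities, and the argmin-BIC ("most parsimonious") model. Subsets
that fail to converge are excluded with a warning and the weights
renormalised.

Discrimination is the c statistic — the ROC area estimated by the
rank-based Mann–Whitney statistic with ties counted one half, verified
against a brute-force pairwise oracle and scikit-learn. Internal validation
is leave-one-out cross-validation at a 0.5 probability threshold (the study
says only "cross-validation"; leave-one-out at 0.5 is our documented
reading). Odds ratios are reported per the study's comparison units
(1 for BMI, eye size, eyebrow height; SD-like units 0.002, 0.14, 0.05,
0.02, 0.06 for PAR, WHR, CJWR, LF/FH, FW/LFH).

The four published predictive equations use the sign convention
P(TE) = 1/(1+e^x); they are stored and evaluated exactly as printed, and
internal fits expose the conversion (x = −η) explicitly. Two published
quantities attached to these equations do not self-verify and are therefore
not used as reference values: the per-0.05-CJWR fold changes
(0.37/0.56/0.3/0.46) are inconsistent with exp(−0.05·b_CJWR) of the printed
equations (likely posterior-averaged rather than single-model
coefficients), and the F20s per-unit-BMI fold prints 1.58 while
exp(0.4617) = 1.5868 rounds to 1.59.

## Synthetic cohort generator

The generator emulates the study's sampling design, not its photographs.

**Metric level.** Each (stratum, type) group draws (BMI, 7 metrics) from a
multivariate normal with the published group means and SDs and the
published group sizes (e.g. 96/57/77 for young men). Normality per type is
consistent with the study's mean-(SD) reporting and ANOVA analysis. Only
*pooled* BMI–metric correlations are published, so the within-type
correlation ρ_w is assumed equal across the three types (the minimal
sufficient assumption) and is **calibrated** from the mixture moment
identity

    r_pooled · σ_tot(B) · σ_tot(M) = cov_between + ρ_w · Σ_g n_g σ_gB σ_gM / N,

where the between-group moments come from size-weighted group means and
σ²_tot = σ²_within + σ²_between. The within-covariance term uses the
size-weighted mean of per-group SD *products* — exactly the pooled
covariance a common per-group correlation produces — so the generated
pooled correlation converges to the target (an RMS-based approximation
would bias it by several thousandths when group SDs differ). Targets
outside the attainable range (|ρ_w| ≥ 1) raise a calibration error.
Metric–metric within-type correlations are unpublished and default to
zero (configurable); if the assembled correlation matrix is not positive
definite it is repaired to the nearest PD matrix by eigenvalue clipping,
with a warning.

Heights are drawn independently per group and weight is derived as
BMI·height², because BMI is the analysis variable and the published female
BMI means are not consistent with the published weight/height means (e.g.
58.6 kg at 161.6 cm implies 22.4 kg/m² against a printed 19.35); matching
the printed BMI distributions exactly is the convention adopted here, at
the cost of female weight means that differ from the printed weight rows.
Similarly, the published male-sixties pooled n (219) exceeds the sum of its
printed group sizes (218); the generator uses the group sizes, while
Fisher comparisons against published (r, n) pairs use the pairs as printed.

**Geometry level.** For each synthetic subject a full 20-point landmark
set is constructed whose metric vector equals the sampled targets. The
construction is closed-form in a canonical frame (midline x = 0, pupil
line y = 0): the four ratio metrics fix the lower-face polygon's shape,
a single uniform scaling of the polygon hits PAR (PAR scales as 1/s while
ratios are invariant), and the eye, pupil, brow and fWHR points are placed
directly from the mm-valued targets. Degrees of freedom the metrics do not
constrain — pupil separation, inner eye span, cheek/jaw vertical positions,
brow line — are inherited from a template face. The shipped template is
synthetic: it is itself constructed from the published young-male TE mean
metrics with default shape constants, and the construction is verified
against the metric computation to 1e-9 relative (infeasible targets, e.g.
a negative eye size, raise an error naming the metric).

**What the generator does not emulate.** Real faces have correlated
metrics beyond the BMI channel, non-Gaussian and bounded measurements,
landmarking error, and age/sex covariance structure that printed summary
tables cannot identify. Passing simulation-recovery tests therefore shows
that the pipeline recovers the *generative model's* truth under the study's
printed first and second moments — not that it would reproduce the study's
subject-level results, which would require the original cohort.

## Problem sizes used in validation

The validation suite runs at the study's own scale: classifier-recovery
experiments use the published young-male stratum (n = 230 per replicate)
averaged over 200 seeds (100 for leave-one-out), model-selection
consistency uses 100 replicates of n = 230 with two true predictors and
six noise metrics, calibration checks sample ~10⁵ subjects per stratum,
and geometry round-trips verify 100 random target vectors to 1e-6
relative. The selection-consistency experiment generates labels from a
logistic model in BMI and CJWR at one e-fold of odds per pooled SD each —
a canonical detectable-signal choice; note that with six noise candidates
the probability that no noise predictor beats the BIC penalty is
(1 − P(χ²₁ > ln 230))⁶ ≈ 0.89, which bounds how often exact support
recovery can be expected at this sample size.

## Known limitations

* The landmark semantics are a documented convention, not a reproduction of
  the original figure; metric values on real photographs depend on placing
  the points per `landmarks.POINT_SEMANTICS`.
* Duncan lettering on unbalanced real data may differ marginally from the
  study's (unstated) software convention for unequal n.
* The geometry generator produces bilaterally symmetric canonical faces;
  it is intended for pipeline validation, not for synthesising realistic
  facial variation.
* No multiple-testing correction is applied anywhere, matching the study's
  analysis plan.
* The three-type problem is deliberately out of scope: only the TE vs
  non-TE binary classifier is modelled, as in the study.
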