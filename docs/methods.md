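# Methods

This note documents the statistical models and numerical conventions behind
`ovatriage`: what the synthetic cohort generator simulates, how the
analysis machinery is defined, and which design choices were genuinely open.

## 1. Case scoring

Image predictions are probability vectors over ten histological categories
in a fixed order (five benign, then five malignant). The image-level risk
of malignancy is the summed malignant mass; the case-level malignancy score
is the unweighted arithmetic mean over the case's images (grayscale and
Doppler images are not distinguished, and no image is excluded). A case is
classified malignant when its score *strictly* exceeds the cut-off; a score
exactly at the cut-off is benign. The default cut-off is 0.5. Probability
vectors must be non-negative and sum to 1 within 1e-6.

## 2. Diagnostic metrics

All metrics are case-level functions of the 2×2 confusion matrix with
malignant as the positive class. Conventions for degenerate inputs:

- proportions with an empty denominator are explicit missing values, never
  silently 0;
- DOR is `+inf` when `fp·fn = 0` with `tp·tn > 0`; an optional
  Haldane–Anscombe 0.5 correction (all four cells) is available but off by
  default;
- MCC is 0 when any marginal vanishes;
- Cohen's κ uses marginal-product chance agreement;
- Jeffreys intervals are equal-tailed Beta(x+½, n−x+½) quantiles with the
  boundary conventions lower = 0 at x = 0 and upper = 1 at x = n;
- AUC is the Mann–Whitney concordance probability (ties count ½), computed
  from midranks; it equals the trapezoidal area under the empirical ROC
  exactly;
- percentages are reported to two decimals.

`reconstruct_confusion` inverts printed sensitivity/specificity
percentages into integer counts by nearest-integer rounding of
`sens·n_pos` and `spec·n_neg`; an exact .5 product is reported as an
ambiguity rather than resolved silently.

## 3. Synthetic cohort generator

The generator's defaults encode the study conditions the analyses assume;
they are fixed once, not tuned per experiment.

**Cases.** 19 centers × 140 cases (2,660 total). Histological categories
are drawn i.i.d. from the test-data composition (40.8% malignant); the
small "rare benign" group is folded into "other common benign", since the
specific remapping of rare diagnoses onto the five benign classes is
clinical information the generator cannot reproduce. A configurable
fraction of cases (default 0) is conservatively managed; such cases are
generated benign-only, matching follow-up-based reference labels. Image
counts are `1 + NegBin(r = 2.4, mean = 3.85)`, whose quartiles are exactly
(3, 4, 6). Ages are normal (benign mean 45, malignant mean 58, s.d. 14,
clipped to 18–90); exam years uniform 2006–2021; ultrasound systems
categorical with GE at 91.8%.

**Latent difficulty.** Every case carries a scalar difficulty
`d ~ N(0, 1)`, larger = harder, shared by all examiners *and* the AI. This
single shared factor is the simplest mechanism that produces the error
correlations a real review exhibits (examiners err on the same cases, and
the AI's hard cases overlap with the examiners'); it also drives the
confidence ratings.

**Examiner panel.** 33 experts and 33 non-experts. Latent
(sensitivity, specificity) pairs are `expit` of a bivariate normal on the
logit scale. Tier means are the pooled single-examiner operating points
(expert 82.40%/82.67%, non-expert 78.71%/77.27%); the between-examiner
s.d. (0.40 logit) and sens–spec correlation (−0.3) are not identified by
pooled operating points and were set once to values typical of reader
studies — heterogeneity wide enough that inverse-workload pooling and the
bivariate random-effects summary are non-trivial, correlation negative as
the threshold trade-off implies. Each examiner has a lognormal review
propensity (s.d. 0.5) so workloads vary.

**Correctness link.** For an examiner with latent operating point `p`
(sensitivity on malignant cases, specificity on benign) the probability of
a correct call on a case of difficulty `d` is

    P(correct | d) = c · Φ(θ − k·d),    θ = √(1+k²) · Φ⁻¹(p / c)

with ceiling `c = 0.99` (accuracy on the easiest conceivable case) and
difficulty weight `k = 1`. Because `E_{d~N(0,1)}[Φ(θ − k d)] =
Φ(θ/√(1+k²))`, the intercept is available in closed form and each
examiner's *marginal* sensitivity and specificity equal their latent values
exactly — the basis of the parameter-recovery tests.

**Confidence.** The examiner perceives `u = d + ε`, `ε ~ N(0, 0.5²)`, and
reports *certain* if `u < 0.3`, *probable* if `0.3 ≤ u < 1.2`, *uncertain*
otherwise. Thresholds act on the signed perceived difficulty: since the
correct-call probability is decreasing in `d` and `u` is positively
correlated with `d`, accuracy is monotone decreasing from certain to
uncertain, as observed in real reviews. (Thresholding |d| instead would
label the easiest cases "uncertain" and invert the ordering.)

**Review design.** Panel sizes per case are rounded normals clipped to
[7, 13] experts (mean 10) and [6, 12] non-experts (mean 9), reproducing the
review minimums and medians. Examiners from the case's own center are
excluded; among eligible examiners the panel is drawn without replacement
with probability proportional to propensity (Gumbel top-k keys, i.e.
Efraimidis–Spirakis weighted sampling). A center whose external examiner
pool cannot satisfy the minimum is an infeasibility error.

**AI predictions.** A case-level latent signal

    z = ±(μ − a·d) + √(1−a²)·η,   η ~ N(0,1)

(sign + for malignant) has class-conditional law `z | class ~ N(±μ, 1)`
regardless of `a`, while the difficulty loading `a = 0.6` ties AI errors to
examiner errors. Each image observes `z_i = z + σ·ξ_i` (σ = 0.3); the
image-level malignant mass is the exact posterior
`P(malignant | z_i)` under `z_i | class ~ N(±μ, 1+σ²)` with the cohort's
class prior, so the **calibrated** mode is calibrated by construction
(Jensen smoothing from the image mean leaves the decile curve within ~0.015
of the identity at n = 20,000). `μ = 1.2` gives case-level AUC ≈ 0.95.
**Overconfident**/**underconfident** modes multiply/divide the posterior
log-odds by a temperature (default 2). The malignant mass is spread over
the five malignant categories (benign mass likewise) by a Dirichlet draw
(concentration 0.5) boosted at the case's true category (+8), so vectors
sum to 1 exactly and the top category usually matches the truth.

**What the generator does not emulate.** Real image content and any
image-quality covariates; center-specific case-mix differences (centers are
exchangeable); secular drift over exam years; examiner learning or fatigue;
non-ignorable missingness in the review design. Consequently, passing
tests demonstrate the correctness and calibration of the *analysis
machinery* under a plausible data-generating process, not the clinical
performance of any particular model.

## 4. Reader comparison

**Pairing.** The unit of the AI-vs-examiner comparison is the examiner:
each of the 66 examiners contributes one (examiner metric, AI metric) pair
computed on exactly the case set that examiner assessed. Per-case pairing
is deliberately not offered.

**Wilcoxon signed-rank.** Zero differences are discarded (all-zero input:
p = 1). For n ≤ 25 after zero removal the two-sided p-value is exact:
midranks are doubled to integers and the null distribution of W⁺ is built
by generating-function convolution over all 2ⁿ sign assignments (scipy's
exact method does not admit ties, hence the in-package implementation,
cross-checked against full enumeration and against scipy on tie-free
data). Beyond n = 25 the tie-corrected normal approximation with
continuity correction is used.

**Inverse-workload pooling.** Pooled tier-level operating points draw, per
replicate, one examiner per case with probability ∝ 1/workload
(equalising examiner representation), compute the metric suite on the
selected calls, and report the replicate mean with (2.5, 97.5) percentile
CIs (default 2,000 replicates). Whether a pooled figure should be a
replicate mean or a single draw is not determined by the design; the
replicate mean is the default as the lower-variance choice.

**Bootstrap.** The resampling unit everywhere is the case, unstratified.
ROC confidence bands hold the pointwise 2.5th/97.5th percentiles of
bootstrap sensitivities, linearly interpolated onto a 1,001-point
specificity grid; degenerate single-class resamples are redrawn and
counted.

**Matched cut-offs.** Among cut-offs whose constrained coordinate
(sensitivity or specificity) is at least the target, the one closest to the
target is taken, ties broken toward the higher unconstrained coordinate;
candidates are 0 and the distinct scores, which exhaust all achievable
operating points under the strict-inequality decision rule.

**Bivariate random-effects summary.** Per-examiner (Se, Sp) are
logit-transformed (0.5 added to the cells of a zero margin) with
delta-method within-examiner variances `1/x + 1/(n−x)`. The
between-examiner covariance is method-of-moments: the sample covariance of
the logits minus the mean within-examiner variance on the diagonal, floored
at 0 and clipped to remain positive semi-definite. The mean's sampling
covariance is the sample covariance divided by the number of examiners; the
95% confidence ellipse follows from its χ²(2) quantile. Method of moments
was chosen over full ML because it is deterministic, closed-form and
directly testable by parameter recovery (mean bias < 1 percentage point at
33 examiners × 600 cases); full ML (e.g. a Reitsma-type GLMM) is a noted
extension, not a default.

**Calibration.** Ten equal-frequency bins by default (constant scores
collapse to one bin); the summary error is the count-weighted mean absolute
deviation between mean predicted risk and observed malignancy proportion.
Smoothed calibration curves are deliberately not the default.

## 5. Triage simulation

Rules (binary calls; confidence ∈ {certain, probable, uncertain}):

- *current practice*: a non-expert assesses; refer iff the call is
  malignant or the confidence is uncertain; the expert's call is final.
  Referral uses the call itself, not a confidence-weighted probability.
- *AI-assisted (non-)expert*: AI and the initial examiner assess; on
  agreement the shared call is final (1 examination), otherwise an expert
  arbitrates (2 examinations). In the expert-initial arm the arbiter must
  be a *different* expert; arbiter draws that collide with the initial
  examiner are rejected and redrawn, which is equivalent to renormalising
  the weights without the initial examiner.
- *single expert / single non-expert / AI alone*: one examination, no
  referral. The AI is not counted as a human resource, so the floor is the
  one acquiring examination.

Per replicate (default 1,000), initial and arbitration examiners are drawn
per case among that case's assessors with inverse-workload weights.
Human resources satisfy `HR = 1 + referral fraction` identically on every
replicate. Point estimates are replicate means with percentile CIs;
replicate 0's per-case decisions are exported. The expert-initial variant
of current practice is implemented but excluded from the default report.

## 6. Pipeline and reproducibility

All randomness flows from one master seed through named integer substreams
(`SeedSequence([seed, stage_id])`), so each stage is independently
reproducible and inserting a stage never perturbs another stage's stream.
Two runs with the same config and seed produce byte-identical JSON/CSV
outputs. CSV dialect is fixed (UTF-8, header, "." decimal). Input
validation distinguishes hard errors (schema violations, orphan case ids,
probability rows off by > 1e-6, conservative cases labelled malignant)
from warnings.

## 7. Problem sizes used in the shipped checks

The test suite and acceptance script scale simulations to what the
analyses need rather than to the original study: generator composition and
calibration checks use 10,000–20,000 cases; parameter-recovery checks use
five centers × 300–400 cases (≥ 10,000 assessments); bootstrap coverage
uses 500 outer replications × 500 cases × 500 resamples; bivariate
recovery uses 200 panels of 33 examiners with ~600 cases each; triage
Monte-Carlo-vs-enumeration uses 12-case toys with 3 examiners per tier; the
acceptance script's synthetic run uses the full 2,660-case default cohort
with 300–400 replicates for pooled and triage estimates.

## 8. Known limitations

- The bivariate summary is method-of-moments, not (restricted) ML; with
  very few examiners the floored between-covariance can be degenerate.
- The generator's examiner heterogeneity magnitudes are calibrated only to
  pooled tier operating points; individual-examiner spread is an
  assumption, not an estimate.
- Calibration of the *case* score inherits a small Jensen smoothing from
  image averaging; it is well within the tested tolerance but not exactly
  the image-level posterior.
- Undefined subgroup metrics are flagged and excluded, not imputed; pooled
  replicate summaries drop non-finite replicate values (e.g. infinite DOR).
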