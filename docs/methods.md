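# Methods

## The measurement problem

Two "methods" measure the same quantity on each athlete: direct
gas-exchange V̇O₂max during the final 4-minute all-out stage of an
incremental rowing step test, and a linear prediction from lean body
mass (LBM) and the distance covered in that stage. The package treats
the prediction equation as a candidate replacement method and asks the
standard method-comparison questions: how strongly the two agree in
rank/consistency (ICC), how large a single measurement's typical error
is (SEM), how large the disagreement on an individual athlete can
plausibly be (Bland–Altman limits, repeatability coefficient), and
whether the two produce the same distribution at all (Kolmogorov–
Smirnov).

## Prediction equations

The frozen equations are exact linear forms, one per sex:

* boys: V̇O₂max (mL·min⁻¹) = −2310.815 + 40.991·LBM + 3.365·distance
* girls: V̇O₂max (mL·min⁻¹) = −572.696 + 41.182·LBM + 1.707·distance

Evaluation is intercept + Σ coefficient·value with no hidden transforms;
coefficients are stored and reported in natural units (mL·min⁻¹ per kg,
per m). Refitting uses ordinary least squares; stepwise selection is
forward entry of the candidate with the smallest partial-F p-value below
`alpha_enter` (default 0.05) followed by backward elimination of any
included predictor with p above `alpha_remove` (default 0.10), iterated
to stability — the conventional SPSS-style "probability of F" stepwise.
Ties in entry p-values are broken by the documented candidate order
(lean body mass first), making selection deterministic. A model revisited
by the enter/remove cycle terminates the loop. The overall model F and
its degrees of freedom are reported from the fit itself; note that
published F values for equations of this family are not always
consistent with the printed n and r², so no attempt is made to match any
particular printed F.

## Agreement statistics

All statistics operate on aligned series, with the sign convention fixed
once as diff = predicted − measured.

* **ICC.** Single-measure consistency ICC of the two-way mixed model
  (methods fixed, subjects random), computed from the subjects × methods
  ANOVA without interaction: ICC = (MS_rows − MS_err)/(MS_rows +
  (k−1)·MS_err) with k = 2. A constant offset between methods is
  absorbed by the method effect and does not reduce this ICC. The 95% CI
  comes from F-distribution bounds on F = MS_rows/MS_err with
  (n−1, (n−1)(k−1)) degrees of freedom. Zero between-subject variance is
  an error: with indistinguishable subjects there is no reliability to
  estimate.
* **SEM** = SD·√(1 − ICC), where SD is the SD of all 2n values pooled
  across both methods (the "grand" SD). This is the input convention
  that reproduces published SEM values from their printed grand SDs and
  ICCs.
* **CV%** = √(MS_err)/grand mean × 100, taking the error mean square
  from the same two-way ANOVA as the ICC.
* **Bland–Altman.** Limits of agreement = mean diff ± 1.96·SD_diff (the
  z multiplier, not a t quantile — the choice that reproduces published
  limit widths exactly); width = 2·1.96·SD_diff; repeatability
  coefficient RC = 1.96·√(2·SD²_diff), so RC/width ≡ √2/2 identically.
  The standard error of the limits defaults to the large-sample form
  SD_diff·√(3/n); a legacy variant √3·SD_diff/(n−1) sits behind a flag
  because published "SEL" values in this literature are not reproducible
  under any standard formula. Each limit's CI is limit ± 1.96·SEL.
* **K-S test.** D is the maximum absolute ECDF difference. For samples
  of at most 10 values each the p-value is exact, by enumeration of all
  C(n₁+n₂, n₁) label assignments of the pooled values (ties handled by
  evaluating only at distinct-value boundaries); otherwise the
  asymptotic Kolmogorov distribution is used with effective
  n = n₁n₂/(n₁+n₂).

## Matched hold-out allocation

Validation subgroups of size k (default 13) are drawn uniformly without
replacement and accepted as soon as every matching variable (default
lean body mass and fat %) shows p > α (default 0.05) in a two-sided
Welch test of subgroup vs remainder. Welch is the default because
nothing guarantees equal variances in a 13-vs-106 comparison; a
pooled-variance flag exists. Both-samples-zero-variance comparisons are
degenerate and resolve to p = 1 (equal means) or p = 0 (unequal). The
loop is capped (default 10 000 draws) and on exhaustion reports the best
draw's p-values. On a homogeneous cohort the first-draw acceptance
probability is ≈ (1−α) per independent matching variable, i.e. ≈ 0.90
for two — the loop nearly always accepts within a few draws. Note that
even a strongly bimodal matching variable does not force rejection:
mixed draws inflate the within-group variance, and the test remains
approximately null-calibrated under exchangeable splitting; rejection
loops that never terminate require an unattainable α, not merely a
heterogeneous cohort.

## Synthetic cohorts

The generator emulates per-sex cohorts of elite adolescent rowers. Body
mass, lean body mass, 4-min distance and mean power are jointly Gaussian
with a Markov-chain correlation structure along body mass — LBM —
distance — power; edge correlations default to 0.9 (mass–LBM), 0.5
(LBM–distance) and 0.9 (distance–power), and non-adjacent correlations
are path products, which keeps the matrix positive semi-definite for any
edge values. Coupling body mass to lean mass is deliberate: with
independent draws the physical constraint LBM < body mass would reject
~15% of male rows and visibly shrink the lean-mass SD, whereas at 0.9
the rejection rate is negligible and all marginal moments are recovered
to sampling error. Remaining fields (age, height, fat %, stroke rate,
maximum heart rate) are independent Gaussians; they exist largely to
exercise stepwise selection with uninformative candidates. Rows
violating physical ranges are rejected and resampled, so marginals are
very mildly truncated Gaussians.

Default moments are the published per-sex development-cohort
descriptives (e.g. boys: LBM 57.04 ± 10.23 kg, distance 1175.78 ±
102.12 m). Measured V̇O₂max is the sex's frozen equation evaluated on
the draw plus Gaussian noise. The noise SD defaults to "calibrate-to-
r2": σe = SD(linear predictor)·√((1−R²)/R²) with targets R² = 0.715
(boys) and 0.769 (girls), so the generative population R² equals the
published squared multiple correlation. Because fat % is drawn with its
own published moments, it is not arithmetically consistent with the
drawn body and lean masses; the cohort reader, by the documented
precedence rule, keeps a supplied lean mass and only logs a summary
warning on disagreement.

What the generator does **not** emulate: measurement error in the
predictors, non-Gaussian tails, age/maturation structure linking
anthropometrics, sex-mixed training groups, and any longitudinal or
training-response behaviour. Passing tests therefore demonstrate that
the pipeline's statistics behave correctly under the model the analysis
itself assumes (joint normality, linear signal, homoscedastic noise),
not that the equations are valid in new real populations.

## Determinism and numerics

Every stochastic stage takes a seed; the study runner derives named
substreams (generation, allocation, per sex) from one top-level seed via
`numpy` seed sequences, so stages can be re-run in isolation and a full
run is byte-reproducible (report rendering embeds no timestamps).
Sample SDs use the n−1 denominator throughout, matching the descriptive
mean ± SD convention. OLS goes through statsmodels; rank-deficient
designs are refused with the collinear columns named rather than
silently pseudo-inverted. Cohort CSVs are written with shortest-repr
floats, so write → read round-trips are exact.

## Problem sizes

The test suite works at the study's own scales (pools of 119/96,
development cohorts of 106/83, hold-outs of 13) plus larger cohorts
(10⁴–10⁵) where convergence of moments or of the calibrated R² is the
property under test; stochastic recovery checks use 50 seeded
replicates. The acceptance script uses 20 noise-free points per sex —
parameter recovery from noise-free data is exact at any n above the
design rank, so nothing is gained by more.

## Known limitations

* The stepwise procedure inherits the usual caveats of F-to-enter
  selection (biased in-sample r², no post-selection inference); it is
  implemented because it is the procedure this workflow prescribes, not
  because it is the best modern practice.
* The SEL/CI-of-limits block implements two defensible formulas, but no
  published values exist against which to validate either; treat those
  outputs as indicative.
* The exact K-S option enumerates all label assignments and is
  restricted to n₁, n₂ ≤ 10 (≈ 1.8×10⁵ assignments at 10 + 10).
* Consistency ICC, by construction, ignores fixed bias; a systematically
  biased equation can still score ICC ≈ 1. That is why the Bland–Altman
  block and the mean difference are always reported alongside.
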