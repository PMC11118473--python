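# Methods

This note records the statistical conventions, numerical choices and open
design decisions of the package, and what its synthetic-data tests do and do
not demonstrate about real data.

## Ground truth and labels

The ground truth is a continuous functional readout: enzymatic activity of
each variant protein as a percentage of wild type (%WT). The binary
pathogenicity label is derived as z = I(y < t) with t = 13 %WT by default.
The inequality is **strict**: a variant measured at exactly 13 %WT is benign.
Both the threshold and the strictness are configurable
(`assign_class_labels(..., inclusive=True)` moves the boundary case to the
pathogenic side). Records without a measured activity carry no label and can
never sit in the evaluation set.

The evaluation set is derived from the curated set by removing variants whose
ClinVar clinical significance is one of the six definitive categories
(Pathogenic, Likely pathogenic, Pathogenic/Likely pathogenic, Benign, Likely
benign, Benign/Likely benign) *and* whose review status does not mention
conflicting interpretations. Matching is exact string membership after
whitespace trimming for the significance field, and a case-insensitive
substring test ("conflicting interpretations") for the review field. Variants
absent from ClinVar and variants present as VUS are treated identically —
both are retained — because the two cannot be distinguished from the input
table alone.

## Score normalization

All classification metrics use the **low-score-pathogenic** convention: a
variant is called positive at threshold t when its predicted activity is
≤ t. Submitted scores are first mean-imputed (missing entries replaced by the
arithmetic mean of the non-missing scores; by default the mean is taken over
evaluation-set variants only, configurable to the full curated set — the
population being evaluated is the population the imputed value should
represent). Imputation always precedes normalization.

Orientation is decided by computing the AUC of the raw scores under the
activity convention, on evaluation-set labels only:

* AUC ≥ 0.5 → ŷ = 100·r (direct; preserves Pearson, τ and AUC exactly);
* AUC < 0.5 → ŷ = 100·(1 − r) (flip; negates the correlations, maps AUC to
  1 − AUC).

Fundamental features get min-max normalization onto exactly [0, 100], on the
negated scores when their orientation AUC is below 0.5. No transform clamps:
raw scores outside [0, 1] pass through the flip unclamped, because the
transforms must stay strictly monotone and clamping would manufacture ties.
A prediction set records which transform was applied and refuses to be
normalized twice.

## Metrics

* **Pearson r** and **R²** follow their standard definitions;
  R² = 1 − SS_res/SS_tot can be negative and is reported but never ranked,
  since it requires a calibrated predictor rather than a well-ordered one.
* **Kendall τ** is the plain pairwise sign statistic
  Σ_{i<j} sign((y_i−y_j)(ŷ_i−ŷ_j)) / (n(n−1)/2): tied pairs contribute zero
  to the numerator and remain in the denominator (τ-a). This deliberately
  differs from the τ-b default of standard libraries, which rescales for
  ties; the suite cross-checks against an O(n²) double loop.
* **ROC** is built tie-aware: thresholds are the sorted distinct prediction
  values; a group of tied scores contributes a single vertex, so mixed-class
  ties appear as diagonal segments; (0, 0) is prepended. **AUC** is computed
  two ways — exhaustive-equivalent pair counting
  (P(ŷ_p < ŷ_b) + ½ P(ŷ_p = ŷ_b), via sorted searches) and the trapezoidal
  area under the ROC polyline — and the two are asserted equal to 1e-10
  on every call.
* **Truncated AUC** integrates the ROC over FPR ∈ [0, 0.2] with linear
  interpolation of TPR at the right boundary when no vertex lies there, and
  divides by 0.2. A perfect predictor scores 1; the all-tied (diagonal)
  predictor scores 0.1 (= ½·0.2²/0.2).
* Undefined metrics (zero variance, single-class input) raise typed errors
  rather than returning NaN, so rank aggregation can never silently ingest
  an undefined value.

## Bootstrap, intervals and the win test

Uncertainty comes from B = 1000 with-replacement resamples of the evaluation
set (resample size = evaluation size). One index stream per replicate is
generated from the seed and **shared by every metric and every predictor**,
making per-replicate differences paired. Replicates on which a metric is
undefined (e.g. a single-class resample) are recorded as undefined and
excluded from interval computation; with 73/219 positives this is vanishingly
rare but must not crash.

Percentile intervals use the 5th and 95th bootstrap percentiles with the
**Hyndman–Fan type-6 (Weibull) plotting position** (position q·(n+1) in the
sorted sample, linear interpolation between order statistics); the Gaussian
summary is 1.96 × the bootstrap sample standard deviation (ddof = 1).

The pairwise comparison "A beats B on metric m" counts the replicates where
A's estimate **strictly** exceeds B's — ties and undefined replicates count
against A, the conservative choice — and computes the exact upper tail
P(Binomial(B, ½) ≥ wins) with arbitrary-precision integers (a single
correctly rounded division, so the reported double is exact down to
underflow), plus a log10 tail via gammaln/logsumexp for magnitudes far below
double range. A model compared against itself scores 0 wins and p = 1.

## Ranking

Leaderboards rank on four metrics — Pearson r, Kendall τ, AUC, truncated
AUC — all larger-is-better after normalization (the orientation heuristic
guarantees AUC ≥ 0.5 in practice). Tied metric values receive mean ranks; the
final ordering is by the arithmetic mean of exactly the four ranks, with ties
broken by higher Pearson and then name so output is deterministic. Teams
fielding several models are first collapsed to their best model by the same
rule within the team; submitted models, public tools and fundamental features
are always ranked as three separate groups.

## Difficult-variant mining

For an index pathogenic variant and one predictor, the per-variant FPR is the
fraction of benign variants predicted **strictly** below it on the normalized
%WT scale, i.e. scored more pathogenic; prediction ties do not count toward
the rate. The per-variant FNR of a benign variant is symmetric (pathogenic
variants predicted strictly above it). Strictness is the only reading
consistent with describing the same quantity both as "scored lower" and
"scored higher by the method" depending on which side is the reference.
Rates use normalized predictions so they are comparable across predictors of
different orientations, and are computed over *all* variants with measured
activity, not only the evaluation subset; pool membership (AUC strictly
greater than 0.8) is, in contrast, decided on the evaluation set.

Per class side the package reports each variant's minimum and average rate
across the pool, their gap, the predictors attaining the minimum, and the
fraction of co-class variants with a more extreme activity (lower for
pathogenic, higher for benign). Top-10 lists by minimum rate, average rate
and gap are produced with boundary ties broken toward the more extreme
measured activity, then by identifier; the union list is their set union.

## Synthetic data generator

The generator emulates the statistical structure the assessment assumes, not
any particular protein's biology:

* **Activity**: a two-component scaled-Beta mixture. Pathogenic activities
  are Beta(0.8, 4) scaled onto [activity_min, 13) — right-skewed with mass
  near zero, as expected for loss-of-function variants with a residual-
  activity tail; benign activities are Beta(1.2, 2.5) scaled onto
  [13, activity_max] — broad with mass toward the lower end. Defaults are the
  study conditions: 73 pathogenic / 146 benign, range (−0.016, 161.17). The
  Beta shapes are a pragmatic choice for bounded bimodal data and are exposed
  in the spec.
* **Scores**: Gaussian noise added to standardized activity *ranks* by
  default (value-space noise optional), with the amplitude calibrated by
  bounded root finding so the realized Pearson correlation with activity
  equals the target. Rank-space noise keeps the calibration stable under the
  heavy-tailed activity scale, at the price of a noise-free ceiling of about
  r ≈ 0.97 (the rank–value correlation of the mixture); targets above it
  raise a calibration error, and near-perfect predictors should use
  value-space noise. Activity-oriented predictors are then mapped affinely
  onto the submission scale (0 = no activity, 1 ≈ wild type); probability-
  oriented predictors pass through a decreasing logistic into (0, 1), which
  anti-correlates them with activity so the orientation heuristic must fire.
  Missingness is completely at random at the configured rate.
* **Calibration modes**: `"sample"` (default) makes the realized sample
  correlation hit the target exactly — right for fixtures with known
  effect sizes. `"population"` calibrates on a large reference population
  (default 20001 draws) from the same mixture and maps the sample through the
  population's rank scale, so the *population* correlation equals the target
  and the sample estimate fluctuates with sampling noise — the correct regime
  for confidence-interval coverage studies, where sample-exact calibration
  would make coverage trivially near-total.
* The default predictor roster mirrors the correlation levels, orientations
  and missingness patterns observed across submitted models, public tools and
  fundamental features in a community challenge of this design (best
  submissions near r ≈ 0.58–0.59, best public tool r ≈ 0.61
  probability-oriented, a conservation-like feature at r ≈ 0.33, one
  submission with 5% missing scores).

What passing synthetic tests shows: the pipeline recovers known orderings
(three predictors at target r 0.8/0.6/0.4 rank correctly in ≥ 95% of seeded
replicates), flips every probability-oriented predictor with real signal, and
produces percentile intervals with approximately nominal (≈ 90%) coverage of
a known population correlation. What it does not show: robustness to
assay-specific error structure, to informative missingness, to predictor
score distributions unlike monotone-transform-plus-noise, or to ClinVar
annotation dynamics — synthetic datasets are born as evaluation sets and the
ClinVar filter is exercised only on hand-written micro-fixtures.

## Problem sizes and determinism

The shipped test suite runs the full pipeline at the study-condition sizes
(n = 219) with reduced bootstrap depths where only point estimates matter
(ranks are bootstrap-free) and B = 400 over 200 repetitions for the coverage
study; `scripts/acceptance.py` uses the full B = 1000. Every random draw in
the package flows from an explicit integer seed through NumPy
`SeedSequence` spawning, and the end-to-end pipeline is bit-reproducible for
a fixed seed (verified byte-for-byte on the emitted report files).

## Known limitations

* The curated-versus-evaluation imputation scope and the percentile
  definition are choices the original study design leaves open; both are
  documented above and configurable where it matters.
* The exact composition of the difficult-variant predictor pool (team
  representatives vs all submissions vs public tools) is a configuration
  input rather than a fixed rule.
* Per-variant identifiers are protein-level substitutions only; there is no
  genomic-coordinate or VCF handling, and no live ClinVar querying —
  annotations must arrive in the input table.
* Likelihood-ratio and posterior-probability evidence-strength metrics used
  in some clinical frameworks are out of scope.
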