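# vepeval

Benchmarking variant-effect predictors against continuous **percent-wild-type
(%WT) enzymatic activity** measurements.

Computational predictors of missense-variant effect are increasingly used to
triage variants of uncertain significance (VUS), but their scores arrive in
incompatible conventions: some predict residual activity (high score = benign),
others a probability of pathogenicity (high score = damaging), and fundamental
biological features (conservation, solvent accessibility, ...) live on arbitrary
scales. `vepeval` implements a complete, reproducible evaluation pipeline for
scoring such predictors against a functional assay readout, of the kind used in
community assessment challenges for enzymes such as arylsulfatase A, where
loss-of-function variants cause a recessive lysosomal storage disorder and a
variant is called **pathogenic when its measured activity y < 13 %WT**
(z = I(y < 13)).

The pipeline provides:

* **data model** — curated variant tables (TSV/CSV) with measured activity,
  optional ClinVar annotation, evaluation-set derivation (variants with a
  definitive ClinVar classification — P/LP/B/LB without conflicting
  interpretations — are removed; VUS are kept) and strict-threshold labeling;
* **normalization** — mean imputation of missing scores, then an
  AUC-based orientation heuristic: scores are evaluated as activity predictions
  (low = pathogenic, calls made at ŷ ≤ t); if the resulting AUC is below 0.5
  the scores are interpreted as pathogenicity probabilities and mapped
  ŷ = 100·(1 − r), otherwise ŷ = 100·r; features get min-max onto [0, 100],
  negated when anti-oriented;
* **metrics** — R², Pearson r, Kendall τ as the plain pairwise sign statistic
  (τ-a: tied pairs stay in the n(n−1)/2 denominator), tie-aware ROC under the
  ≤ t convention, AUC = P(ŷ_pathogenic < ŷ_benign) + ½·P(tie) (pair counting
  and trapezoid area, asserted equal), and truncated AUC — the area over
  FPR ∈ [0, 0.2] divided by 0.2, emphasizing the clinically relevant
  low-false-positive regime;
* **assessment** — B = 1000 paired bootstrap (one resample-index stream shared
  by all predictors), 5th–95th percentile and 1.96·sd confidence intervals, a
  one-sided exact binomial win test for paired predictor comparison, per-team
  representative selection, and average-rank leaderboards over
  {r, τ, AUC, tAUC}, ranked separately for submitted models, public tools and
  fundamental features;
* **difficult-variant mining** — per-variant FPR (for an index pathogenic
  variant: the fraction of benign variants scored more pathogenic than it) and
  FNR (symmetric for benign variants) across a pool of predictors with
  AUC > 0.8, summarized into difficult-for-all / difficult-on-average / gap
  top-10 lists and their union;
* **synthetic data** — a seeded generator producing the bimodal activity
  distribution (73 pathogenic / 146 benign by default, range −0.016…161.17),
  predictor scores calibrated to a target Pearson correlation in either
  orientation, and missing-at-random dropout, so the entire pipeline is
  testable without any download.

## Worked example

```python
import vepeval as vp

spec = vp.SimulationSpec(
    predictors=(
        vp.PredictorSpec("rf_meta", 0.58, team="alpha", category="submitted"),
        vp.PredictorSpec("deep_plm", 0.61, category="public",
                         orientation="pathogenicity_probability"),
        vp.PredictorSpec("conservation", 0.33, category="feature"),
    ),
    seed=20221115,
)
dataset = vp.generate_activity(spec)          # 219 variants, 73 pathogenic
for ps in vp.generate_predictions(spec, dataset):
    out = vp.normalize_predictions(ps, dataset)
    ps = out.prediction_set
    mask = dataset.evaluation_mask
    y, yhat = dataset.activities[mask], ps.normalized_scores[mask]
    z = dataset.labels[mask].astype(int)
    print(f"{ps.predictor_name:>12}  transform={out.transform_used:<14}"
          f" r={vp.pearson(y, yhat).value:.3f}"
          f" tau={vp.kendall_tau(y, yhat).value:.3f}"
          f" AUC={vp.auc(yhat, z).value:.3f}"
          f" tAUC={vp.truncated_auc(yhat, z).value:.3f}")
```

prints

```
     rf_meta  transform=direct         r=0.580 tau=0.424 AUC=0.788 tAUC=0.353
    deep_plm  transform=flip           r=0.610 tau=0.460 AUC=0.835 tAUC=0.514
conservation  transform=minmax         r=0.330 tau=0.223 AUC=0.676 tAUC=0.278
```

`rf_meta` submits activity-like scores, so the direct transform keeps its
correlation at the generator's target (0.58). `deep_plm` submits pathogenicity
probabilities: its raw scores anti-correlate with activity, the orientation
AUC falls below 0.5 and the flip transform restores the intended orientation
(r = 0.61 after flipping). The conservation feature is min-max scaled and, as
a single raw biological quantity, separates classes far more weakly
(AUC 0.68). The truncated AUC shows the same ordering but discriminates more
sharply in the low-FPR region that matters for clinical use.

The same flow is available from a shell — `vepeval simulate`, `normalize`,
`evaluate`, `compare`, `difficult` and `report` (full pipeline from a YAML
config to a leaderboard/CI/pairwise/difficult-variant report bundle plus a
JSON run manifest).

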