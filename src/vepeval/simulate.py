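"""Synthetic activity measurements and predictor scores for end-to-end testing.

The generator emulates the statistical structure the assessment assumes:

* a bimodal %WT activity distribution straddling the pathogenicity threshold,
  with exact class counts (73 pathogenic / 146 benign by default, activity
  spanning roughly -0.016 to 161.17).  Components are scaled Beta
  distributions — right-skewed near zero on the pathogenic side, broad on the
  benign side.  The shapes are a pragmatic choice for bounded bimodal data,
  not a claim about any real activity distribution.
* predictor scores correlated with activity at a configurable Pearson level.
  Noise is added on standardized activity ranks by default (value-space noise
  is available); the noise amplitude is calibrated by root finding so the
  realized correlation hits the target despite the heavy-tailed activity
  scale.  With ``calibration="population"`` the amplitude is calibrated on a
  large reference population instead, so the *population* correlation equals
  the target and the sample correlation fluctuates around it — that is the
  right regime for studying confidence-interval coverage.
* either score orientation: ``"activity"`` scores are an increasing map of
  the noisy signal onto the submission scale (0 = no activity, 1 = wild
  type), while ``"pathogenicity_probability"`` scores pass through a
  decreasing logistic into (0, 1), which makes the downstream orientation
  heuristic flip them.
* missing-completely-at-random score dropout at a configurable rate.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import rankdata

from .datasets import (
    PredictionSet,
    VariantDataset,
    VariantRecord,
    assign_class_labels,
    write_prediction_table,
    write_variant_table,
)
from .errors import SimulationError

_AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_ACTIVITY_RANGE = (-0.016, 161.17)


@dataclass(frozen=True)
class PredictorSpec:
    """One synthetic predictor: correlation target, orientation, dropout."""

    name: str
    target_pearson: float = 0.6
    team: str = ""
    category: str = "submitted"
    orientation: str = "activity"  # activity | pathogenicity_probability
    missing_rate: float = 0.0
    noise_model: str = "rank"  # rank | value
    calibration: str = "sample"  # sample | population


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    n_pathogenic: int = 73
    n_benign: int = 146
    threshold: float = 13.0
    activity_range: tuple[float, float] = DEFAULT_ACTIVITY_RANGE
    predictors: tuple[PredictorSpec, ...] = ()
    seed: int = 0
    pathogenic_beta: tuple[float, float] = (0.8, 4.0)
    benign_beta: tuple[float, float] = (1.2, 2.5)
    population_size: int = 20001

    def __post_init__(self) -> None:
        lo, hi = self.activity_range
        if not lo < self.threshold < hi:
            raise SimulationError(
                f"threshold {self.threshold} outside activity range ({lo}, {hi})"
            )
        if self.n_pathogenic < 1 or self.n_benign < 1:
            raise SimulationError("class counts must be >= 1")
        for p in self.predictors:
            if not -1.0 < p.target_pearson < 1.0:
                raise SimulationError(f"{p.name}: target_pearson must be in (-1, 1)")
            if not 0.0 <= p.missing_rate < 1.0:
                raise SimulationError(f"{p.name}: missing_rate must be in [0, 1)")
            if p.orientation not in ("activity", "pathogenicity_probability"):
                raise SimulationError(f"{p.name}: unknown orientation {p.orientation!r}")
            if p.noise_model not in ("rank", "value"):
                raise SimulationError(f"{p.name}: unknown noise model {p.noise_model!r}")
            if p.calibration not in ("sample", "population"):
                raise SimulationError(f"{p.name}: unknown calibration {p.calibration!r}")


def _rng_for(spec: SimulationSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=key))


def _draw_activities(
    rng: np.random.Generator, spec: SimulationSpec, n_path: int, n_benign: int
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = spec.activity_range
    thr = spec.threshold
    a, b = spec.pathogenic_beta
    path = lo + (thr - lo) * rng.beta(a, b, size=n_path)
    path = np.minimum(path, np.nextafter(thr, -np.inf))  # strictly below threshold
    a, b = spec.benign_beta
    ben = thr + (hi - thr) * rng.beta(a, b, size=n_benign)
    return path, ben


def generate_activity(spec: SimulationSpec) -> VariantDataset:
    """A labeled evaluation dataset with exact per-class counts."""
    rng = _rng_for(spec, 0)
    path, ben = _draw_activities(rng, spec, spec.n_pathogenic, spec.n_benign)
    values = np.concatenate([path, ben])
    order = rng.permutation(len(values))
    values = values[order]
    records = []
    for i, v in enumerate(values):
        ref, alt = rng.choice(list(_AA), size=2, replace=False)
        records.append(
            VariantRecord(
                variant_id=f"p.{ref}{i + 1}{alt}",
                activity=float(v),
                in_evaluation_set=True,
            )
        )
    ds = VariantDataset(tuple(records), threshold=spec.threshold, role="evaluation")
    return assign_class_labels(ds, spec.threshold)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise SimulationError("degenerate constant signal")
    return (x - x.mean()) / sd


def _calibrate_lambda(
    base: np.ndarray, eps: np.ndarray, x: np.ndarray, target: float, name: str
) -> float:
    """Noise amplitude such that corr(base + lam*eps, x) == target."""

    def realized(lam: float) -> float:
        s = base + lam * eps
        return float(np.corrcoef(s, x)[0, 1])

    r0 = realized(0.0)
    if target > r0 + 1e-9:
        raise SimulationError(
            f"{name}: target Pearson {target} unachievable (noise-free maximum {r0:.4f})"
        )
    if abs(target - r0) <= 1e-9:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(60):  # bounded doubling search for a bracketing amplitude
        if realized(hi) < target:
            break
        hi *= 2.0
    else:
        raise SimulationError(f"{name}: noise calibration failed to bracket the target")
    return float(brentq(lambda lam: realized(lam) - target, lo, hi, xtol=1e-10))


def _uniformized_positions(values: np.ndarray, reference_sorted: np.ndarray) -> np.ndarray:
    """Map values to (0,1) by their position in a sorted reference, zero-mean/unit-var."""
    q = (np.searchsorted(reference_sorted, values, side="right") + 0.5) / (
        len(reference_sorted) + 1
    )
    return (q - 0.5) * np.sqrt(12.0)


def generate_predictions(
    spec: SimulationSpec, dataset: VariantDataset
) -> list[PredictionSet]:
    """Synthetic score sets for every predictor in the spec, aligned to *dataset*."""
    x = dataset.activities
    n = len(x)
    out = []
    for k, pspec in enumerate(spec.predictors):
        rng = _rng_for(spec, 1, k)
        eps = rng.standard_normal(n)
        if pspec.calibration == "sample":
            base = (
                _standardize(rankdata(x)) if pspec.noise_model == "rank" else _standardize(x)
            )
            lam = _calibrate_lambda(base, eps, x, pspec.target_pearson, pspec.name)
            signal = base + lam * eps
        else:
            # calibrate against a large reference population from the same mixture
            p_frac = spec.n_pathogenic / (spec.n_pathogenic + spec.n_benign)
            n_pop = spec.population_size
            n_path_pop = int(round(p_frac * n_pop))
            pop_path, pop_ben = _draw_activities(rng, spec, n_path_pop, n_pop - n_path_pop)
            x_pop = np.concatenate([pop_path, pop_ben])
            x_pop_sorted = np.sort(x_pop)
            if pspec.noise_model == "rank":
                base_pop = _uniformized_positions(x_pop, x_pop_sorted)
                base = _uniformized_positions(x, x_pop_sorted)
            else:
                mu, sd = x_pop.mean(), x_pop.std()
                base_pop = (x_pop - mu) / sd
                base = (x - mu) / sd
            eps_pop = rng.standard_normal(n_pop)
            lam = _calibrate_lambda(
                base_pop, eps_pop, x_pop, pspec.target_pearson, pspec.name
            )
            signal = base + lam * eps

        if pspec.orientation == "activity":
            # increasing affine map onto the submission scale (1 ~ wild type)
            span = signal.max() - signal.min()
            hi = spec.activity_range[1] / 100.0
            scores = hi * (signal - signal.min()) / span
        else:
            scores = expit(-1.5 * _standardize(signal))

        if pspec.missing_rate > 0.0:
            scores = scores.copy()
            scores[rng.random(n) < pspec.missing_rate] = np.nan

        out.append(
            PredictionSet(
                predictor_name=pspec.name,
                raw_scores=scores,
                team=pspec.team,
                category=pspec.category,
            )
        )
    return out


def default_predictors() -> tuple[PredictorSpec, ...]:
    """A roster emulating the mix seen in a community challenge.

    Correlation targets mirror the levels observed for real submissions,
    public tools and fundamental features; one public tool is
    probability-oriented (so the flip heuristic must fire) and one submission
    has missing scores.
    """
    return (
        PredictorSpec("team1_rf", 0.576, team="team1", category="submitted"),
        PredictorSpec("team1_knn", 0.45, team="team1", category="submitted"),
        PredictorSpec("team2_ensemble", 0.594, team="team2", category="submitted"),
        PredictorSpec(
            "team3_svm", 0.50, team="team3", category="submitted", missing_rate=0.05
        ),
        PredictorSpec(
            "public_deep",
            0.614,
            category="public",
            orientation="pathogenicity_probability",
        ),
        PredictorSpec(
            "public_meta",
            0.55,
            category="public",
            orientation="pathogenicity_probability",
        ),
        PredictorSpec("conservation_feature", 0.33, category="feature"),
    )


def default_simulation_spec(seed: int = 0) -> SimulationSpec:
    return SimulationSpec(predictors=default_predictors(), seed=seed)


def write_fixture_bundle(spec: SimulationSpec, out_dir: str | Path) -> dict:
    """Write a complete assessment fixture: variant table, one submission file
    per predictor, a ready-to-run config and a manifest.

    Re-running with the same spec produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "submissions").mkdir(exist_ok=True)
    dataset = generate_activity(spec)
    predictions = generate_predictions(spec, dataset)
    write_variant_table(dataset, out / "variants.tsv")

    realized = {}
    x = dataset.activities
    submissions = []
    for ps, pspec in zip(predictions, spec.predictors):
        path = out / "submissions" / f"{ps.predictor_name}.tsv"
        write_prediction_table(ps, dataset, path, which="raw")
        present = ~np.isnan(ps.raw_scores)
        realized[ps.predictor_name] = float(
            np.corrcoef(ps.raw_scores[present], x[present])[0, 1]
        )
        submissions.append(
            {
                "path": str(path),
                "name": ps.predictor_name,
                "team": ps.team,
                "category": ps.category,
            }
        )

    config = {
        "variant_table": str(out / "variants.tsv"),
        "submissions": submissions,
        "threshold": spec.threshold,
        "bootstrap": {"B": 1000, "seed": spec.seed},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    manifest = {
        "seed": spec.seed,
        "n_pathogenic": spec.n_pathogenic,
        "n_benign": spec.n_benign,
        "threshold": spec.threshold,
        "activity_range": list(spec.activity_range),
        "realized_pearson": realized,
        "predictors": [
            {
                "name": p.name,
                "team": p.team,
                "category": p.category,
                "target_pearson": p.target_pearson,
                "orientation": p.orientation,
                "missing_rate": p.missing_rate,
            }
            for p in spec.predictors
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
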