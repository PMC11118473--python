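"""Mapping heterogeneous predictor outputs onto the %WT-activity scale.

Submissions arrive in two incompatible orientations: activity-like scores
(large = functional = benign) and pathogenicity-probability-like scores
(large = damaging).  The two are anti-correlated, so evaluating them with a
single convention requires reconciliation.  The arbiter is an AUC heuristic:
the raw scores are scored *as if* they predicted activity (low score =
pathogenic); an AUC below 0.5 reveals a probability-oriented predictor, whose
scores are then flipped as ``100 * (1 - r)``.  Otherwise scores are rescaled
as ``100 * r`` (submissions use a 0..1-ish scale where 1 means wild-type
activity).  The direct transform leaves Pearson, Kendall tau and AUC exactly
unchanged; the flip negates the correlations and maps AUC to 1 - AUC.

Fundamental features (conservation scores, solvent accessibility, ...) live
on arbitrary scales and instead get a min-max transform onto [0, 100],
negated first when the same AUC heuristic says the feature tracks
pathogenicity rather than activity.  No clamping is ever applied: clamping
would create artificial ties and all transforms must stay strictly monotone.

Missing scores are imputed with the mean of the non-missing scores *before*
any transform, by default over the evaluation-set variants only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import PredictionSet, VariantDataset
from .errors import NormalizationError, UndefinedMetricError
from .metrics import _auc_pairs, _validate_classes


@dataclass(frozen=True)
class NormalizationOutcome:
    """A normalized prediction set plus the heuristic's decision variable."""

    prediction_set: PredictionSet
    orientation_auc: float
    transform_used: str


def impute_missing(scores: np.ndarray, scope_mask: np.ndarray | None = None) -> np.ndarray:
    """Replace missing entries by the mean of non-missing scores.

    ``scope_mask`` restricts which entries contribute to the mean (e.g. the
    evaluation subset) — every missing entry is filled regardless of scope.
    Non-missing entries are returned unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    present = ~np.isnan(scores)
    in_scope = present if scope_mask is None else (present & np.asarray(scope_mask, bool))
    if not in_scope.any():
        raise NormalizationError("all scores missing: cannot impute")
    filled = scores.copy()
    filled[~present] = scores[in_scope].mean()
    return filled


def _orientation_auc(
    scores: np.ndarray, dataset: VariantDataset, evaluation_only: bool
) -> float:
    """AUC of raw scores read as activity predictions (low = pathogenic)."""
    mask = dataset.evaluation_mask if evaluation_only else dataset.labeled_mask
    if not mask.any():
        raise UndefinedMetricError("dataset carries no class labels")
    yhat, z = _validate_classes(scores[mask], dataset.labels[mask])
    return _auc_pairs(yhat, z)


def _check_ready(prediction_set: PredictionSet) -> np.ndarray:
    if prediction_set.transform_used is not None:
        raise NormalizationError(
            f"{prediction_set.predictor_name}: already normalized "
            f"({prediction_set.transform_used})"
        )
    scores = np.asarray(prediction_set.raw_scores, dtype=float)
    if np.isnan(scores).any():
        raise NormalizationError(
            f"{prediction_set.predictor_name}: impute missing scores before normalizing"
        )
    return scores


def orient_and_scale(
    prediction_set: PredictionSet,
    dataset: VariantDataset,
    *,
    evaluation_only: bool = True,
) -> NormalizationOutcome:
    """Rescale submitted scores to the %WT scale, flipping probability-oriented ones.

    If the orientation AUC is below 0.5 the scores are interpreted as
    pathogenicity probabilities and mapped as ``100 * (1 - r)``; otherwise
    (including exactly 0.5) as ``100 * r``.
    """
    r = _check_ready(prediction_set)
    a = _orientation_auc(r, dataset, evaluation_only)
    if a < 0.5:
        yhat = 100.0 * (1.0 - r)
        transform = "flip"
    else:
        yhat = 100.0 * r
        transform = "direct"
    out = replace(
        prediction_set,
        normalized_scores=yhat,
        orientation_flipped=transform == "flip",
        transform_used=transform,
        orientation_auc=a,
    )
    return NormalizationOutcome(out, orientation_auc=a, transform_used=transform)


def minmax_feature_transform(
    prediction_set: PredictionSet,
    dataset: VariantDataset,
    *,
    evaluation_only: bool = True,
) -> NormalizationOutcome:
    """Min-max map a fundamental feature onto exactly [0, 100].

    Features whose orientation AUC is below 0.5 are negated before the
    min-max step so that, after the transform, low values mean pathogenic for
    every feature alike.
    """
    r = _check_ready(prediction_set)
    lo, hi = float(r.min()), float(r.max())
    if hi == lo:
        raise NormalizationError(
            f"{prediction_set.predictor_name}: constant feature, min-max undefined"
        )
    a = _orientation_auc(r, dataset, evaluation_only)
    if a >= 0.5:
        yhat = 100.0 * (r - lo) / (hi - lo)
        transform = "minmax"
    else:
        yhat = 100.0 * (hi - r) / (hi - lo)
        transform = "minmax_negated"
    out = replace(
        prediction_set,
        normalized_scores=yhat,
        orientation_flipped=transform == "minmax_negated",
        transform_used=transform,
        orientation_auc=a,
    )
    return NormalizationOutcome(out, orientation_auc=a, transform_used=transform)


def normalize_predictions(
    prediction_set: PredictionSet,
    dataset: VariantDataset,
    *,
    impute_scope: str = "evaluation",
    evaluation_only: bool = True,
) -> NormalizationOutcome:
    """Impute then normalize one prediction set according to its category.

    ``impute_scope`` selects which variants feed the imputation mean:
    ``"evaluation"`` (default) or ``"all"``.
    """
    if impute_scope not in ("evaluation", "all"):
        raise NormalizationError(f"unknown impute scope {impute_scope!r}")
    scope = dataset.evaluation_mask if impute_scope == "evaluation" else None
    imputed = replace(
        prediction_set, raw_scores=impute_missing(prediction_set.raw_scores, scope)
    )
    if prediction_set.category == "feature":
        outcome = minmax_feature_transform(imputed, dataset, evaluation_only=evaluation_only)
    else:
        outcome = orient_and_scale(imputed, dataset, evaluation_only=evaluation_only)
    # keep the submission as read; only normalized_scores are derived
    outcome.prediction_set.raw_scores = np.asarray(prediction_set.raw_scores, dtype=float)
    return outcome
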