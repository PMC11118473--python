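"""Mining the hardest-to-predict pathogenic and benign variants.

For an index pathogenic variant and one predictor, the per-variant false
positive rate (FPR) is the fraction of benign variants that the predictor
scores *more pathogenic* than the index variant (strictly lower normalized
%WT): it is the false-positive cost of drawing the decision threshold exactly
at that variant.  Symmetrically, the per-variant false negative rate (FNR) of
a benign variant is the fraction of pathogenic variants scored strictly less
pathogenic (higher normalized %WT) than it.

Rates are computed for every predictor in a pool of well-performing models
(evaluation AUC strictly above 0.8 by default) and summarized per variant by
their minimum, average, and the average-minus-minimum gap.  Three top-10
lists follow per class side — highest minimum rate ("difficult for all"),
highest average rate ("difficult on average") and largest gap — plus their
union.  The analysis runs over all variants with a measured activity, not
only the evaluation subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import PredictionSet, VariantDataset
from .errors import IntegrityError, PoolError, VepevalError

DEFAULT_POOL_AUC = 0.8
DEFAULT_TOP_K = 10

_RATE_TOL = 1e-12


class ClassSideError(VepevalError):
    """The variant is not on the class side the rate is defined for."""


@dataclass(frozen=True)
class VariantDifficulty:
    """Per-variant difficulty summary across the predictor pool."""

    variant_id: str
    class_side: str  # pathogenic | benign
    activity: float
    per_predictor_rate: dict[str, float]
    min_rate: float
    avg_rate: float
    gap: float
    attaining_predictors: tuple[str, ...]
    #: fraction of co-class variants with a more extreme measured activity
    #: (lower for pathogenic, higher for benign) — the parenthetical statistic
    #: reported next to each listed variant.
    coclass_more_extreme: float


@dataclass(frozen=True)
class DifficultySide:
    side: str
    variants: tuple[VariantDifficulty, ...]
    difficult_for_all: tuple[str, ...]
    difficult_on_average: tuple[str, ...]
    gap_list: tuple[str, ...]
    union_list: tuple[str, ...]

    def table(self) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            rows.append(
                {
                    "variant": v.variant_id,
                    "activity": v.activity,
                    "coclass_more_extreme": v.coclass_more_extreme,
                    "min_rate": v.min_rate,
                    "avg_rate": v.avg_rate,
                    "gap": v.gap,
                    "difficult_for_all": int(v.variant_id in self.difficult_for_all),
                    "difficult_on_average": int(v.variant_id in self.difficult_on_average),
                    "gap_list": int(v.variant_id in self.gap_list),
                    "attaining_predictors": ";".join(v.attaining_predictors),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DifficultyReport:
    pool: tuple[str, ...]
    pathogenic: DifficultySide
    benign: DifficultySide


def _scores_for(prediction_set: PredictionSet) -> np.ndarray:
    if prediction_set.normalized_scores is None:
        raise IntegrityError(
            f"{prediction_set.predictor_name}: rates require normalized predictions"
        )
    return prediction_set.normalized_scores


def variant_fpr(
    variant_id: str, prediction_set: PredictionSet, dataset: VariantDataset
) -> float:
    """FPR of one pathogenic variant under one predictor.

    Fraction of benign variants predicted strictly below (more pathogenic
    than) the index variant; prediction ties do not count.
    """
    scores = _scores_for(prediction_set)
    idx = dataset.index_of()[variant_id]
    labels = dataset.labels
    if labels[idx] != 1.0:
        raise ClassSideError(f"{variant_id} is not pathogenic")
    benign = scores[labels == 0.0]
    return float(np.mean(benign < scores[idx]))


def variant_fnr(
    variant_id: str, prediction_set: PredictionSet, dataset: VariantDataset
) -> float:
    """FNR of one benign variant: fraction of pathogenic variants predicted
    strictly above (less pathogenic than) it."""
    scores = _scores_for(prediction_set)
    idx = dataset.index_of()[variant_id]
    labels = dataset.labels
    if labels[idx] != 0.0:
        raise ClassSideError(f"{variant_id} is not benign")
    pathogenic = scores[labels == 1.0]
    return float(np.mean(pathogenic > scores[idx]))


def select_predictor_pool(reports, auc_threshold: float = DEFAULT_POOL_AUC) -> list[str]:
    """Predictors whose evaluation-set AUC strictly exceeds the threshold."""
    candidates = {r.predictor_name: r.point_estimates["auc"] for r in reports}
    pool = [name for name, a in candidates.items() if a > auc_threshold]
    if not pool:
        raise PoolError(
            f"no predictor with AUC > {auc_threshold}; candidates: "
            + ", ".join(f"{k}={v:.3f}" for k, v in sorted(candidates.items()))
        )
    return pool


def _side_summary(
    dataset: VariantDataset,
    pool: list[PredictionSet],
    side: str,
    top_k: int,
) -> DifficultySide:
    labels = dataset.labels
    labeled = dataset.labeled_mask
    target = 1.0 if side == "pathogenic" else 0.0
    own = labeled & (labels == target)
    other = labeled & (labels == (1.0 - target))
    own_idx = np.flatnonzero(own)
    acts = dataset.activities

    # rate matrix: variants x predictors, via one sort of the opposite class
    names = [ps.predictor_name for ps in pool]
    rates = np.empty((len(own_idx), len(pool)))
    for j, ps in enumerate(pool):
        scores = _scores_for(ps)
        opp_sorted = np.sort(scores[other])
        n_opp = len(opp_sorted)
        s = scores[own_idx]
        if side == "pathogenic":
            # benign strictly below the index variant's prediction
            counts = np.searchsorted(opp_sorted, s, side="left")
        else:
            # pathogenic strictly above
            counts = n_opp - np.searchsorted(opp_sorted, s, side="right")
        rates[:, j] = counts / n_opp

    own_acts = acts[own_idx]
    n_co = len(own_idx)
    variants = []
    for i, di in enumerate(own_idx):
        row = rates[i]
        mn, avg = float(row.min()), float(row.mean())
        attain = tuple(
            sorted(name for name, v in zip(names, row) if v <= mn + _RATE_TOL)
        )
        if side == "pathogenic":
            extreme = float(np.mean(own_acts < own_acts[i]))
        else:
            extreme = float(np.mean(own_acts > own_acts[i]))
        variants.append(
            VariantDifficulty(
                variant_id=dataset.records[di].variant_id,
                class_side=side,
                activity=float(acts[di]),
                per_predictor_rate=dict(zip(names, row.tolist())),
                min_rate=mn,
                avg_rate=avg,
                gap=avg - mn,
                attaining_predictors=attain,
                coclass_more_extreme=extreme,
            )
        )

    def top(key) -> tuple[str, ...]:
        # ties at the boundary break toward the more extreme measured activity
        extremeness = (
            (lambda v: v.activity) if side == "pathogenic" else (lambda v: -v.activity)
        )
        ordered = sorted(
            variants, key=lambda v: (-key(v), extremeness(v), v.variant_id)
        )
        return tuple(v.variant_id for v in ordered[: min(top_k, len(ordered))])

    for_all = top(lambda v: v.min_rate)
    on_avg = top(lambda v: v.avg_rate)
    gaps = top(lambda v: v.gap)
    union = tuple(sorted(set(for_all) | set(on_avg) | set(gaps)))
    return DifficultySide(
        side=side,
        variants=tuple(variants),
        difficult_for_all=for_all,
        difficult_on_average=on_avg,
        gap_list=gaps,
        union_list=union,
    )


def difficult_lists(
    dataset: VariantDataset,
    pool_predictions: list[PredictionSet],
    top_k: int = DEFAULT_TOP_K,
) -> DifficultyReport:
    """Difficulty report over all labeled variants, both class sides.

    ``dataset`` should be the full curated dataset (all variants with
    measured activity participate, not just the evaluation subset).
    """
    if not pool_predictions:
        raise PoolError("empty predictor pool")
    return DifficultyReport(
        pool=tuple(ps.predictor_name for ps in pool_predictions),
        pathogenic=_side_summary(dataset, pool_predictions, "pathogenic", top_k),
        benign=_side_summary(dataset, pool_predictions, "benign", top_k),
    )
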