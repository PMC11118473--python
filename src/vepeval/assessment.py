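"""Bootstrap uncertainty, paired significance testing and rank aggregation.

Uncertainty is quantified by resampling the evaluation set with replacement
(B = 1000 by default) and re-evaluating every metric on each replicate.
One index stream per replicate is shared by *all* predictors, which makes
the per-replicate metric differences paired: the one-sided significance test
for "predictor A beats predictor B on metric m" counts the replicates where
A's estimate strictly exceeds B's (ties and undefined replicates count
against A) and refers the count to an exact Binomial(B, 1/2) upper tail.

Confidence intervals are the 5th/95th bootstrap percentiles (Weibull /
Hyndman-Fan type-6 plotting positions) or, as a Gaussian summary,
1.96 x the bootstrap standard deviation.

Leaderboards rank predictors on four metrics — Pearson r, Kendall tau, AUC,
truncated AUC, all larger-is-better after normalization — with mean ranks on
ties, and order by the average of the four ranks.  Teams fielding several
models are collapsed to their best-ranking model first, and submitted models,
public tools and fundamental features are always ranked as separate groups.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

from . import __version__ as _pkg_version
from .datasets import (
    PredictionSet,
    VariantDataset,
    derive_evaluation_set,
    read_prediction_table,
    read_variant_table,
)
from .difficult import DifficultyReport, difficult_lists, select_predictor_pool
from .errors import (
    ConfidenceIntervalError,
    PairingError,
    ParameterError,
    StageError,
    UndefinedMetricError,
)
from .metrics import ALL_METRICS, RANKING_METRICS, compute_metric
from .normalization import normalize_predictions

#: Arbitrary but fixed default seed, recorded in every run manifest.
DEFAULT_SEED = 20221115

DEFAULT_B = 1000


@dataclass(frozen=True)
class BootstrapDistribution:
    """Replicate values of one metric; NaN marks replicates where it was undefined."""

    metric_name: str
    estimates: np.ndarray
    seed: int
    n: int

    @property
    def B(self) -> int:
        return len(self.estimates)

    @property
    def defined(self) -> np.ndarray:
        return self.estimates[~np.isnan(self.estimates)]

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.estimates).sum())


@dataclass(frozen=True)
class PairwiseComparison:
    predictor_a: str
    predictor_b: str
    metric_name: str
    wins_a: int
    B: int
    p_value: float
    log10_p_value: float


@dataclass
class MetricReport:
    """Point estimates, bootstrap intervals and (once ranked) per-metric ranks."""

    predictor_name: str
    team: str
    category: str
    point_estimates: dict[str, float]
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    gaussian_half_width: dict[str, float] = field(default_factory=dict)
    per_metric_rank: dict[str, float] = field(default_factory=dict)
    average_rank: float | None = None
    n: int = 0


def bootstrap_indices(n: int, B: int, seed: int) -> np.ndarray:
    """The shared (B, n) with-replacement index stream for a given seed."""
    if B < 1:
        raise ParameterError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(B, n))


def bootstrap_metrics(
    dataset: VariantDataset,
    prediction_set: PredictionSet,
    B: int = DEFAULT_B,
    seed: int = DEFAULT_SEED,
    metrics: Sequence[str] = ALL_METRICS,
    indices: np.ndarray | None = None,
) -> dict[str, BootstrapDistribution]:
    """Bootstrap every requested metric on the evaluation subset.

    Replicates where a metric is undefined (e.g. a single-class resample) are
    recorded as NaN and excluded from interval computation downstream.
    """
    if prediction_set.normalized_scores is None:
        raise ParameterError("normalize predictions before bootstrapping")
    mask = dataset.evaluation_mask
    y = dataset.activities[mask]
    yhat = prediction_set.normalized_scores[mask]
    z = dataset.labels[mask].astype(int)
    n = len(y)
    idx = bootstrap_indices(n, B, seed) if indices is None else np.asarray(indices)
    out = {m: np.empty(len(idx)) for m in metrics}
    for b, row in enumerate(idx):
        yb, hb, zb = y[row], yhat[row], z[row]
        for m in metrics:
            try:
                out[m][b] = compute_metric(m, yb, hb, zb)
            except UndefinedMetricError:
                out[m][b] = np.nan
    return {
        m: BootstrapDistribution(metric_name=m, estimates=out[m], seed=seed, n=n)
        for m in metrics
    }


def percentile_ci(
    distribution: BootstrapDistribution, lower: float = 5.0, upper: float = 95.0
) -> tuple[float, float]:
    """Bootstrap percentile interval (type-6 / Weibull plotting positions)."""
    d = distribution.defined
    if len(d) < 2:
        raise ConfidenceIntervalError(
            f"{distribution.metric_name}: need >= 2 defined estimates, have {len(d)}"
        )
    lo, hi = np.percentile(d, [lower, upper], method="weibull")
    return float(lo), float(hi)


def gaussian_ci(distribution: BootstrapDistribution) -> float:
    """Half-width of the Gaussian 95% interval: 1.96 x bootstrap sample sd."""
    d = distribution.defined
    if len(d) < 2:
        raise ConfidenceIntervalError(
            f"{distribution.metric_name}: need >= 2 defined estimates, have {len(d)}"
        )
    return 1.96 * float(np.std(d, ddof=1))


def exact_binomial_tail(wins: int, B: int) -> float:
    """P(Binomial(B, 1/2) >= wins), exactly.

    Computed with arbitrary-precision integers and one correctly rounded
    division, so the result is the nearest double to the true tail (0.0 when
    the tail underflows doubles entirely).
    """
    if not 0 <= wins <= B:
        raise ParameterError(f"wins must be in [0, {B}], got {wins}")
    numerator = sum(math.comb(B, k) for k in range(wins, B + 1))
    return numerator / (1 << B)


def log10_binomial_tail(wins: int, B: int) -> float:
    """log10 of P(Binomial(B, 1/2) >= wins), stable far below double underflow."""
    if not 0 <= wins <= B:
        raise ParameterError(f"wins must be in [0, {B}], got {wins}")
    k = np.arange(wins, B + 1)
    log_terms = gammaln(B + 1) - gammaln(k + 1) - gammaln(B - k + 1)
    return float((logsumexp(log_terms) - B * math.log(2.0)) / math.log(10.0))


def pairwise_win_test(
    a: BootstrapDistribution,
    b: BootstrapDistribution,
    predictor_a: str = "A",
    predictor_b: str = "B",
) -> PairwiseComparison:
    """One-sided paired-bootstrap sign test: does A beat B more often than chance?

    A "win" is a replicate where A's estimate strictly exceeds B's; ties and
    undefined replicates are not wins.  The p-value is the exact upper tail
    of Binomial(B, 1/2) at the win count.
    """
    if (a.seed, a.B, a.n, a.metric_name) != (b.seed, b.B, b.n, b.metric_name):
        raise PairingError(
            "distributions are not paired: seed/B/n/metric must match "
            f"({a.metric_name}: seed {a.seed} vs {b.seed}, B {a.B} vs {b.B})"
        )
    both = ~np.isnan(a.estimates) & ~np.isnan(b.estimates)
    wins = int(np.sum(a.estimates[both] > b.estimates[both]))
    return PairwiseComparison(
        predictor_a=predictor_a,
        predictor_b=predictor_b,
        metric_name=a.metric_name,
        wins_a=wins,
        B=a.B,
        p_value=exact_binomial_tail(wins, a.B),
        log10_p_value=log10_binomial_tail(wins, a.B),
    )


def compute_metric_report(
    dataset: VariantDataset,
    prediction_set: PredictionSet,
    B: int = DEFAULT_B,
    seed: int = DEFAULT_SEED,
    indices: np.ndarray | None = None,
) -> tuple[MetricReport, dict[str, BootstrapDistribution]]:
    """Point estimates on the evaluation subset plus bootstrap intervals."""
    mask = dataset.evaluation_mask
    y = dataset.activities[mask]
    yhat = prediction_set.normalized_scores[mask]
    z = dataset.labels[mask].astype(int)
    points = {m: compute_metric(m, y, yhat, z) for m in ALL_METRICS}
    dists = bootstrap_metrics(dataset, prediction_set, B=B, seed=seed, indices=indices)
    report = MetricReport(
        predictor_name=prediction_set.predictor_name,
        team=prediction_set.team,
        category=prediction_set.category,
        point_estimates=points,
        n=int(mask.sum()),
    )
    for m, dist in dists.items():
        lo, hi = percentile_ci(dist)
        report.ci_low[m] = lo
        report.ci_high[m] = hi
        report.gaussian_half_width[m] = gaussian_ci(dist)
    return report, dists


def _ranked_copy(reports: Sequence[MetricReport]) -> list[MetricReport]:
    ranked = [
        replace_report(r) for r in reports
    ]
    for m in RANKING_METRICS:
        values = np.array([r.point_estimates[m] for r in ranked])
        ranks = rankdata(-values, method="average")
        for r, rk in zip(ranked, ranks):
            r.per_metric_rank[m] = float(rk)
    for r in ranked:
        r.average_rank = float(np.mean([r.per_metric_rank[m] for m in RANKING_METRICS]))
    ranked.sort(
        key=lambda r: (r.average_rank, -r.point_estimates["pearson"], r.predictor_name)
    )
    return ranked


def replace_report(r: MetricReport) -> MetricReport:
    return MetricReport(
        predictor_name=r.predictor_name,
        team=r.team,
        category=r.category,
        point_estimates=dict(r.point_estimates),
        ci_low=dict(r.ci_low),
        ci_high=dict(r.ci_high),
        gaussian_half_width=dict(r.gaussian_half_width),
        per_metric_rank={},
        average_rank=None,
        n=r.n,
    )


def rank_models(
    reports: Sequence[MetricReport], group: str | None = None
) -> list[MetricReport]:
    """Rank one group on the four metrics; rank 1 = best, mean ranks on ties.

    Returns fresh reports sorted by ascending average rank (ties broken by
    higher Pearson, then name).  Ranking is always within a single group —
    pass ``group`` to filter by category.
    """
    pool = [r for r in reports if group is None or r.category == group]
    if not pool:
        raise ParameterError(f"no reports to rank in group {group!r}")
    return _ranked_copy(pool)


def select_team_representative(
    reports: Sequence[MetricReport], team: str | None = None
) -> MetricReport:
    """The team's best model by the within-team four-metric average rank."""
    pool = [r for r in reports if team is None or r.team == team]
    if not pool:
        raise ParameterError(f"no reports for team {team!r}")
    return _ranked_copy(pool)[0]


# ---------------------------------------------------------------------------
# end-to-end orchestration


@dataclass
class SubmissionSpec:
    path: str
    name: str
    team: str = ""
    category: str = "submitted"


@dataclass
class AssessmentConfig:
    """Everything run_full_assessment needs, loadable from YAML/JSON."""

    variant_table: str
    submissions: list[SubmissionSpec]
    threshold: float = 13.0
    inclusive_threshold: bool = False
    evaluation_mode: str = "auto"  # auto | flag | clinvar | all
    B: int = DEFAULT_B
    seed: int = DEFAULT_SEED
    impute_scope: str = "evaluation"
    pool_auc_threshold: float = 0.8
    difficult_top_k: int = 10
    pool: list[str] | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "AssessmentConfig":
        raw = dict(raw)
        subs = [SubmissionSpec(**s) for s in raw.pop("submissions")]
        boot = raw.pop("bootstrap", None)
        if boot:
            raw.setdefault("B", boot.get("B", DEFAULT_B))
            raw.setdefault("seed", boot.get("seed", DEFAULT_SEED))
        return cls(submissions=subs, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssessmentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class AssessmentResult:
    curated: VariantDataset
    evaluation: VariantDataset
    prediction_sets: list[PredictionSet]
    reports: list[MetricReport]
    leaderboards: dict[str, list[MetricReport]]
    pairwise: list[PairwiseComparison]
    difficulty: DifficultyReport | None
    manifest: dict


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_full_assessment(
    config: AssessmentConfig, out_dir: str | Path | None = None
) -> AssessmentResult:
    """The whole pipeline: read -> evaluation set -> normalize -> metrics ->
    bootstrap -> representatives -> group-wise ranking -> pairwise tests ->
    difficult-variant mining, with optional TSV/JSON report output."""
    with _stage("read"):
        curated = read_variant_table(
            config.variant_table,
            threshold=config.threshold,
            inclusive=config.inclusive_threshold,
        )

    with _stage("evaluation-set"):
        mode = config.evaluation_mode
        if mode == "auto":
            has_flags = not all(r.in_evaluation_set for r in curated.records)
            has_clinvar = any(r.clinvar_significance for r in curated.records)
            mode = "flag" if has_flags else ("clinvar" if has_clinvar else "all")
        if mode == "flag":
            evaluation = curated.subset(
                np.array([r.in_evaluation_set for r in curated.records]),
                role="evaluation",
            )
        elif mode == "clinvar":
            evaluation = derive_evaluation_set(curated)
        elif mode == "all":
            evaluation = curated.subset(np.ones(curated.n, bool), role="evaluation")
        else:
            raise ParameterError(f"unknown evaluation mode {config.evaluation_mode!r}")
        eval_ids = set(evaluation.variant_ids)
        flags = np.array([vid in eval_ids for vid in curated.variant_ids])
        curated = VariantDataset(
            tuple(
                replace(r, in_evaluation_set=bool(f))
                for r, f in zip(curated.records, flags)
            ),
            threshold=curated.threshold,
            role="curated",
        )

    with _stage("normalize"):
        prediction_sets = []
        for sub in config.submissions:
            ps = read_prediction_table(
                sub.path, curated, sub.name, team=sub.team, category=sub.category
            )
            outcome = normalize_predictions(
                ps, curated, impute_scope=config.impute_scope
            )
            prediction_sets.append(outcome.prediction_set)

    with _stage("metrics-bootstrap"):
        n_eval = int(curated.evaluation_mask.sum())
        idx = bootstrap_indices(n_eval, config.B, config.seed)
        reports = []
        dists: dict[str, dict[str, BootstrapDistribution]] = {}
        for ps in prediction_sets:
            rep, d = compute_metric_report(
                curated, ps, B=config.B, seed=config.seed, indices=idx
            )
            reports.append(rep)
            dists[ps.predictor_name] = d

    with _stage("ranking"):
        leaderboards: dict[str, list[MetricReport]] = {}
        submitted = [r for r in reports if r.category == "submitted"]
        if submitted:
            representatives = [
                select_team_representative(submitted, team)
                for team in sorted({r.team for r in submitted})
            ]
            leaderboards["submitted"] = rank_models(representatives)
        for group in ("public", "feature"):
            members = [r for r in reports if r.category == group]
            if members:
                leaderboards[group] = rank_models(members)

    with _stage("pairwise"):
        pairwise: list[PairwiseComparison] = []
        for group, board in leaderboards.items():
            names = [r.predictor_name for r in board]
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    for m in RANKING_METRICS:
                        pairwise.append(
                            pairwise_win_test(
                                dists[names[i]][m], dists[names[j]][m],
                                names[i], names[j],
                            )
                        )
        # the headline cross-group comparison: best public tool vs best submission
        if "public" in leaderboards and "submitted" in leaderboards:
            a = leaderboards["public"][0].predictor_name
            b = leaderboards["submitted"][0].predictor_name
            for m in RANKING_METRICS:
                pairwise.append(pairwise_win_test(dists[a][m], dists[b][m], a, b))

    with _stage("difficult-variants"):
        difficulty = None
        if config.pool is not None:
            pool_names = list(config.pool)
        else:
            try:
                pool_names = select_predictor_pool(reports, config.pool_auc_threshold)
            except Exception:
                pool_names = []
        if pool_names:
            pool_sets = [
                ps for ps in prediction_sets if ps.predictor_name in pool_names
            ]
            difficulty = difficult_lists(curated, pool_sets, top_k=config.difficult_top_k)

    manifest = {
        "seed": config.seed,
        "B": config.B,
        "threshold": config.threshold,
        "inclusive_threshold": config.inclusive_threshold,
        "evaluation_mode": config.evaluation_mode,
        "impute_scope": config.impute_scope,
        "n_curated": curated.n,
        "n_evaluation": int(curated.evaluation_mask.sum()),
        "n_pathogenic": int(np.nansum(curated.labels[curated.evaluation_mask])),
        "predictors": [
            {
                "name": ps.predictor_name,
                "team": ps.team,
                "category": ps.category,
                "transform_used": ps.transform_used,
                "orientation_auc": ps.orientation_auc,
                "n_missing": ps.n_missing,
            }
            for ps in prediction_sets
        ],
        "difficult_pool": pool_names,
        "package_version": _pkg_version,
    }

    result = AssessmentResult(
        curated=curated,
        evaluation=evaluation,
        prediction_sets=prediction_sets,
        reports=reports,
        leaderboards=leaderboards,
        pairwise=pairwise,
        difficulty=difficulty,
        manifest=manifest,
    )
    if out_dir is not None:
        write_reports(result, out_dir)
    return result


def leaderboard_frame(boards: dict[str, list[MetricReport]]):
    """Flatten ranked leaderboards into one tidy DataFrame."""
    import pandas as pd

    rows = []
    for group, board in boards.items():
        for rep in board:
            row = {
                "group": group,
                "predictor": rep.predictor_name,
                "team": rep.team,
                "average_rank": rep.average_rank,
            }
            for m in ALL_METRICS:
                row[m] = rep.point_estimates[m]
            for m in RANKING_METRICS:
                row[f"rank_{m}"] = rep.per_metric_rank[m]
            rows.append(row)
    return pd.DataFrame(rows)


def write_reports(result: AssessmentResult, out_dir: str | Path) -> None:
    """Emit leaderboard.tsv, metric_cis.tsv, pairwise.tsv, difficult tables and
    manifest.json."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    leaderboard_frame(result.leaderboards).to_csv(
        out / "leaderboard.tsv", sep="\t", index=False, float_format="%.6g"
    )
    ci_rows = []
    for rep in result.reports:
        for m in ALL_METRICS:
            ci_rows.append(
                {
                    "predictor": rep.predictor_name,
                    "metric": m,
                    "estimate": rep.point_estimates[m],
                    "ci_low": rep.ci_low[m],
                    "ci_high": rep.ci_high[m],
                    "gaussian_half_width": rep.gaussian_half_width[m],
                }
            )
    pd.DataFrame(ci_rows).to_csv(
        out / "metric_cis.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(
        [
            {
                "predictor_a": c.predictor_a,
                "predictor_b": c.predictor_b,
                "metric": c.metric_name,
                "wins_a": c.wins_a,
                "B": c.B,
                "p_value": c.p_value,
                "log10_p_value": c.log10_p_value,
            }
            for c in result.pairwise
        ]
    ).to_csv(out / "pairwise.tsv", sep="\t", index=False, float_format="%.6g")
    if result.difficulty is not None:
        result.difficulty.pathogenic.table().to_csv(
            out / "difficult_pathogenic.tsv", sep="\t", index=False, float_format="%.6g"
        )
        result.difficulty.benign.table().to_csv(
            out / "difficult_benign.tsv", sep="\t", index=False, float_format="%.6g"
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
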