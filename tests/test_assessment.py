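"""Bootstrap, confidence intervals, win test, ranking and orchestration."""

import math
from fractions import Fraction

import numpy as np
import pytest

from vepeval import (
    AssessmentConfig,
    BootstrapDistribution,
    MetricReport,
    bootstrap_indices,
    bootstrap_metrics,
    exact_binomial_tail,
    gaussian_ci,
    log10_binomial_tail,
    pairwise_win_test,
    percentile_ci,
    rank_models,
    run_full_assessment,
    select_team_representative,
)
from vepeval.errors import (
    ConfidenceIntervalError,
    PairingError,
    ParameterError,
)
from vepeval.normalization import normalize_predictions
from vepeval.datasets import PredictionSet
from tests.test_datasets import make_dataset


def dist(values, metric="pearson", seed=1, n=10):
    return BootstrapDistribution(
        metric_name=metric, estimates=np.asarray(values, float), seed=seed, n=n
    )


def report(name, team, category, pearson, tau, a, ta):
    return MetricReport(
        predictor_name=name,
        team=team,
        category=category,
        point_estimates={
            "pearson": pearson,
            "kendall_tau": tau,
            "auc": a,
            "truncated_auc": ta,
            "r_squared": 0.0,
        },
    )


@pytest.fixture()
def small_eval():
    rng = np.random.default_rng(3)
    acts = np.concatenate([rng.uniform(0, 12.5, 25), rng.uniform(13.5, 150, 50)])
    ds = make_dataset(acts.tolist())
    raw = ds.activities / 161.17 + rng.normal(scale=0.15, size=75)
    ps = normalize_predictions(
        PredictionSet(predictor_name="m", raw_scores=raw), ds
    ).prediction_set
    return ds, ps


class TestBootstrap:
    def test_same_seed_is_bit_identical(self, small_eval):
        ds, ps = small_eval
        d1 = bootstrap_metrics(ds, ps, B=50, seed=11)
        d2 = bootstrap_metrics(ds, ps, B=50, seed=11)
        for m in d1:
            np.testing.assert_array_equal(d1[m].estimates, d2[m].estimates)

    def test_perfect_predictor_has_degenerate_auc(self):
        acts = [1.0, 2.0, 50.0, 60.0, 70.0]
        ds = make_dataset(acts)
        ps = normalize_predictions(
            PredictionSet(predictor_name="p", raw_scores=np.asarray(acts) / 100), ds
        ).prediction_set
        d = bootstrap_metrics(ds, ps, B=100, seed=5, metrics=("auc",))
        assert np.all(d["auc"].defined == 1.0)

    def test_b_below_one_rejected(self, small_eval):
        ds, ps = small_eval
        with pytest.raises(ParameterError):
            bootstrap_metrics(ds, ps, B=0, seed=1)

    def test_single_class_resamples_recorded_undefined(self):
        # tiny evaluation set makes single-class resamples common, not fatal
        ds = make_dataset([1.0, 50.0, 60.0])
        ps = normalize_predictions(
            PredictionSet(predictor_name="p", raw_scores=np.array([0.1, 0.5, 0.9])), ds
        ).prediction_set
        d = bootstrap_metrics(ds, ps, B=200, seed=2, metrics=("auc",))
        assert d["auc"].n_undefined > 0
        assert len(d["auc"].defined) + d["auc"].n_undefined == 200


class TestIntervals:
    def test_constant_estimates_collapse(self):
        assert percentile_ci(dist([0.5] * 10)) == (0.5, 0.5)
        assert gaussian_ci(dist([0.5] * 10)) == 0.0

    def test_percentile_rule_on_1_to_100(self):
        # type-6 positions: 0.05*(101) = 5.05 and 0.95*(101) = 95.95
        lo, hi = percentile_ci(dist(np.arange(1.0, 101.0)))
        assert lo == pytest.approx(5.05)
        assert hi == pytest.approx(95.95)

    def test_percentile_matches_sorted_array_oracle(self, rng):
        # type-6 plotting position: position q*(n+1) in the sorted sample
        x = rng.normal(size=137)
        s = np.sort(x)
        n = len(s)
        for q in (0.05, 0.95):
            pos = q * (n + 1) - 1
            k = int(math.floor(pos))
            frac = pos - k
            expected = s[k] + frac * (s[k + 1] - s[k])
            lo, hi = percentile_ci(dist(x))
            got = lo if q == 0.05 else hi
            assert got == pytest.approx(expected, abs=1e-12)

    def test_gaussian_ci_is_196_sd(self, rng):
        x = rng.normal(size=500)
        want = 1.96 * np.std(x, ddof=1)
        assert gaussian_ci(dist(x)) == pytest.approx(want, abs=1e-12)

    def test_two_pass_sd_hand_check(self):
        x = [0.0, 1.0] * 50
        mean = 0.5
        var = sum((v - mean) ** 2 for v in x) / (len(x) - 1)
        assert gaussian_ci(dist(x)) == pytest.approx(1.96 * math.sqrt(var))

    def test_single_estimate_rejected(self):
        with pytest.raises(ConfidenceIntervalError):
            percentile_ci(dist([0.5]))


class TestWinTest:
    def test_all_wins_closed_form(self):
        assert exact_binomial_tail(1000, 1000) == pytest.approx(0.5**1000, rel=1e-12)

    def test_half_wins(self):
        # exact rational oracle for wins=500, B=1000
        expected = float(
            Fraction(sum(math.comb(1000, k) for k in range(500, 1001)), 2**1000)
        )
        assert exact_binomial_tail(500, 1000) == pytest.approx(expected, rel=1e-13)
        assert expected == pytest.approx(0.5126, abs=5e-4)

    def test_zero_wins_is_one(self):
        assert exact_binomial_tail(0, 1000) == 1.0

    @pytest.mark.parametrize("wins", [500, 600, 700, 800, 875, 950, 990, 999, 1000])
    def test_exact_tail_matches_log_space_oracle(self, wins):
        """Exact big-integer tail vs gammaln/logsumexp down to p ~ 1e-300."""
        p = exact_binomial_tail(wins, 1000)
        log10p = log10_binomial_tail(wins, 1000)
        assert math.log10(p) == pytest.approx(log10p, abs=1e-10)

    def test_self_comparison_never_wins(self):
        a = dist(np.linspace(0, 1, 100))
        cmp = pairwise_win_test(a, a, "x", "x")
        assert cmp.wins_a == 0
        assert cmp.p_value == 1.0

    def test_ties_count_against_challenger(self):
        a = dist([0.5, 0.6, 0.7])
        b = dist([0.5, 0.5, 0.8])
        cmp = pairwise_win_test(a, b)
        assert cmp.wins_a == 1  # only the strict win at index 1

    def test_unpaired_distributions_rejected(self):
        a = dist([0.1, 0.2], seed=1)
        b = dist([0.1, 0.2], seed=2)
        with pytest.raises(PairingError):
            pairwise_win_test(a, b)


class TestRanking:
    def test_average_rank_examples(self):
        reports = [
            report("a", "t1", "submitted", 0.58, 0.45, 0.85, 0.48),
            report("b", "t2", "submitted", 0.59, 0.44, 0.84, 0.47),
            report("c", "t3", "submitted", 0.40, 0.30, 0.80, 0.50),
            report("d", "t4", "submitted", 0.30, 0.20, 0.70, 0.30),
        ]
        ranked = rank_models(reports)
        by_name = {r.predictor_name: r for r in ranked}
        # model a: ranks (2,1,1,2) -> 1.5; model b: (1,2,2,3) -> 2.0
        assert by_name["a"].average_rank == pytest.approx(1.5)
        assert by_name["b"].average_rank == pytest.approx(2.0)
        assert [r.predictor_name for r in ranked] == ["a", "b", "c", "d"]

    def test_tied_metric_values_get_mean_ranks(self):
        reports = [
            report("a", "", "submitted", 0.5, 0.5, 0.8, 0.4),
            report("b", "", "submitted", 0.5, 0.5, 0.8, 0.4),
        ]
        ranked = rank_models(reports)
        assert all(r.average_rank == pytest.approx(1.5) for r in ranked)

    def test_single_model_group(self):
        ranked = rank_models([report("only", "", "public", 0.5, 0.4, 0.8, 0.4)])
        assert ranked[0].average_rank == 1.0

    def test_ranks_stay_within_group_bounds(self, rng):
        reports = [
            report(f"m{i}", "", "submitted", *rng.uniform(0, 1, 4)) for i in range(9)
        ]
        ranked = rank_models(reports)
        for r in ranked:
            assert 1.0 <= r.average_rank <= 9.0

    def test_permutation_invariance(self, rng):
        reports = [
            report(f"m{i}", "", "submitted", *rng.uniform(0, 1, 4)) for i in range(6)
        ]
        r1 = rank_models(reports)
        r2 = rank_models(list(reversed(reports)))
        assert [r.predictor_name for r in r1] == [r.predictor_name for r in r2]

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            rank_models([], group="public")

    def test_representative_dominance(self):
        reports = [
            report("worse", "t", "submitted", 0.3, 0.2, 0.6, 0.2),
            report("better", "t", "submitted", 0.5, 0.4, 0.8, 0.4),
        ]
        assert select_team_representative(reports, "t").predictor_name == "better"

    def test_representative_tie_breaks_on_pearson(self):
        # equal on every ranked metric except a pearson/tau swap: equal average
        reports = [
            report("lo", "t", "submitted", 0.48, 0.45, 0.8, 0.4),
            report("hi", "t", "submitted", 0.50, 0.43, 0.8, 0.4),
        ]
        ranked = {r.predictor_name: r.average_rank for r in rank_models(reports)}
        assert ranked["lo"] == ranked["hi"]
        assert select_team_representative(reports, "t").predictor_name == "hi"


class TestFullAssessment:
    def test_leaderboard_one_row_per_team_and_separate_groups(self, fixture_bundle):
        out, config, manifest = fixture_bundle
        result = run_full_assessment(config)
        submitted = result.leaderboards["submitted"]
        assert len(submitted) == 3  # one representative per team
        assert len({r.team for r in submitted}) == 3
        assert {r.category for r in result.leaderboards["public"]} == {"public"}
        assert {r.category for r in result.leaderboards["feature"]} == {"feature"}

    def test_probability_oriented_submissions_are_flipped(self, fixture_bundle):
        _, config, _ = fixture_bundle
        result = run_full_assessment(config)
        flips = {
            p["name"]: p["transform_used"] for p in result.manifest["predictors"]
        }
        assert flips["public_deep"] == "flip"
        assert flips["public_meta"] == "flip"
        assert flips["team1_rf"] == "direct"
        assert flips["conservation_feature"] in ("minmax", "minmax_negated")

    def test_pipeline_is_bit_reproducible(self, fixture_bundle, tmp_path):
        _, config, _ = fixture_bundle
        r1 = run_full_assessment(config, out_dir=tmp_path / "a")
        r2 = run_full_assessment(config, out_dir=tmp_path / "b")
        for name in ("leaderboard.tsv", "metric_cis.tsv", "pairwise.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
        assert r1.manifest == r2.manifest

    def test_report_bundle_files(self, fixture_bundle, tmp_path):
        _, config, _ = fixture_bundle
        run_full_assessment(config, out_dir=tmp_path / "out")
        for name in (
            "leaderboard.tsv",
            "metric_cis.tsv",
            "pairwise.tsv",
            "manifest.json",
            "difficult_pathogenic.tsv",
            "difficult_benign.tsv",
        ):
            assert (tmp_path / "out" / name).exists()


class TestCoverageCalibration:
    def test_percentile_interval_covers_population_pearson(self):
        """Percentile bootstrap 5-95% interval covers the population correlation
        about 90% of the time for population-calibrated synthetic data."""
        from vepeval import PredictorSpec, SimulationSpec, generate_activity
        from vepeval.simulate import generate_predictions

        rho = 0.6
        hits = 0
        reps = 200
        for rep in range(reps):
            spec = SimulationSpec(
                predictors=(
                    PredictorSpec("m", rho, calibration="population"),
                ),
                seed=50_000 + rep,
                population_size=4001,
            )
            ds = generate_activity(spec)
            ps = generate_predictions(spec, ds)[0]
            ps = normalize_predictions(ps, ds).prediction_set
            d = bootstrap_metrics(ds, ps, B=400, seed=rep, metrics=("pearson",))
            lo, hi = percentile_ci(d["pearson"])
            if lo <= rho <= hi:
                hits += 1
        assert 0.85 <= hits / reps <= 0.95
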