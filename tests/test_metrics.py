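"""Evaluation metrics against closed forms, hand tables and O(n^2) oracles."""

import warnings

import numpy as np
import pytest

from graftsurv import (
    SimulationConfig,
    SurvivalMatrix,
    TimeGrid,
    antolini_cindex,
    brier_score,
    decile_calibration,
    evaluate_model,
    generate_cohort,
    harrell_cindex,
    ici,
    integrated_brier,
    kaplan_meier,
    spline_calibration,
    true_survival,
)
from graftsurv.metrics import CalibrationCurve, CensoringEstimate, MetricReport

from oracles import antolini_oracle, brier_oracle, harrell_oracle, km_curve, km_eval


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [True, True, True])
        np.testing.assert_allclose(km([1.0, 2.0, 3.0]), [2 / 3, 1 / 3, 0.0])

    def test_all_censored_is_flat_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [False] * 3)
        assert km(10.0) == 1.0

    def test_mixed_eight_observations_match_loop_oracle(self):
        times = [1, 2, 2, 3, 4, 5, 6, 7.0]
        events = [1, 0, 1, 1, 0, 1, 0, 0]
        km = kaplan_meier(times, events)
        ot, os_ = km_curve(times, events)
        for t in [0.5, 1, 2, 2.5, 3, 4.5, 5, 7, 9]:
            assert km(t) == pytest.approx(km_eval(ot, os_, t))
            assert km.left(t) == pytest.approx(km_eval(ot, os_, t, left=True))

    def test_agrees_with_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.uniform(0.1, 10, 100)
        events = rng.random(100) < 0.6
        km = kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        qs = np.linspace(0.2, 9.8, 25)
        np.testing.assert_allclose(
            km(qs), kmf.survival_function_at_times(qs).to_numpy(), atol=1e-10
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])

    def test_censoring_estimate_flips_indicators(self, rng):
        times = rng.uniform(0.1, 10, 50)
        events = rng.random(50) < 0.5
        G = CensoringEstimate.fit(times, events)
        direct = kaplan_meier(times, ~events)
        assert G(5.0) == direct(5.0)


class TestHarrellCindex:
    def test_perfect_model_scores_one(self, rng):
        times = rng.uniform(0.5, 10, 50)
        assert harrell_cindex(-times, times, np.ones(50, bool)) == 1.0

    def test_constant_scores_give_half(self, rng):
        times = rng.uniform(0.5, 10, 30)
        events = rng.random(30) < 0.7
        assert harrell_cindex(np.ones(30), times, events) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_under_censoring(self, seed):
        rng = np.random.default_rng(seed)
        n = 6 + seed * 8
        scores = rng.normal(size=n)
        times = rng.uniform(0.1, 5, n)
        events = rng.random(n) < 0.6
        if not events.any():
            events[0] = True
        assert harrell_cindex(scores, times, events) == pytest.approx(
            harrell_oracle(scores, times, events), abs=1e-12
        )

    def test_agrees_with_scikit_survival(self, rng):
        from sksurv.metrics import concordance_index_censored

        n = 200
        scores = rng.normal(size=n)
        times = rng.uniform(0.1, 15, n)
        events = rng.random(n) < 0.6
        ours = harrell_cindex(scores, times, events)
        theirs = concordance_index_censored(events, times, scores)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        n = 40
        scores = rng.normal(size=n)
        times = rng.uniform(0.1, 5, n)
        events = rng.random(n) < 0.5
        events[0] = True
        a = harrell_cindex(scores, times, events)
        b = harrell_cindex(np.exp(3 * scores), times, events)
        assert a == pytest.approx(b)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            harrell_cindex([1.0, 2.0], [1.0, 2.0], [False, False])


class TestAntoliniCindex:
    def test_indicator_curves_score_one(self):
        g = TimeGrid(horizon_years=4, step_years=1)
        intervals = np.array([1, 2, 3, 4])
        S = np.ones((4, 4))
        for i, k in enumerate(intervals):
            S[i, k - 1:] = 0.0
        assert antolini_cindex(SurvivalMatrix(S, g), intervals,
                               np.ones(4, bool)) == 1.0

    def test_proportional_curves_equal_harrell(self, rng):
        """When curves never cross, the time-dependent index equals the
        scalar-score index with any order-consistent score."""
        g = TimeGrid(horizon_years=10, step_years=1)
        n = 50
        base = np.cumprod(np.full(10, 0.85))
        r = rng.uniform(0.3, 3.0, n)
        S = base[None, :] ** r[:, None]
        times = rng.integers(1, 11, n).astype(float)  # on-grid times
        events = rng.random(n) < 0.7
        events[:2] = True
        intervals = times.astype(int)
        c_a = antolini_cindex(SurvivalMatrix(S, g), intervals, events)
        c_h = harrell_cindex(r, times, events)
        assert c_a == pytest.approx(c_h, abs=1e-12)

    def test_crossing_curves_match_enumeration(self):
        g = TimeGrid(horizon_years=3, step_years=1)
        S = np.array(
            [
                [0.9, 0.5, 0.1],
                [0.6, 0.55, 0.5],
                [0.95, 0.9, 0.05],
                [0.5, 0.4, 0.3],
            ]
        )
        intervals = np.array([1, 2, 2, 3])
        events = np.array([True, True, False, True])
        assert antolini_cindex(SurvivalMatrix(S, g), intervals, events) == (
            pytest.approx(antolini_oracle(S, intervals, events))
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = TimeGrid(horizon_years=8, step_years=1)
        n = 30
        S = np.sort(rng.random((n, 8)), axis=1)[:, ::-1]
        intervals = rng.integers(1, 9, n)
        events = rng.random(n) < 0.6
        events[0] = True
        assert antolini_cindex(SurvivalMatrix(S, g), intervals, events) == (
            pytest.approx(antolini_oracle(S, intervals, events), abs=1e-12)
        )


class TestBrierScore:
    def test_oracle_predictions_without_censoring_score_zero(self):
        g = TimeGrid(horizon_years=4, step_years=1)
        times = np.array([1.0, 2.0, 3.5, 4.0])
        events = np.ones(4, bool)
        S = np.ones((4, 4))
        for i, t in enumerate(times):
            S[i, int(np.ceil(t)) - 1:] = 0.0
        assert brier_score(SurvivalMatrix(S, g), times, events, 2.0) == 0.0

    def test_uninformative_half_prediction_scores_quarter(self):
        g = TimeGrid(horizon_years=2, step_years=1)
        S = np.full((6, 2), 0.5)
        times = np.array([0.5, 0.7, 1.5, 1.8, 2.0, 2.0])
        events = np.ones(6, bool)
        assert brier_score(SurvivalMatrix(S, g), times, events, 1.0) == (
            pytest.approx(0.25)
        )

    def test_no_censoring_equals_mean_squared_error(self, rng):
        g = TimeGrid(horizon_years=5, step_years=1)
        n = 40
        S = np.sort(rng.random((n, 5)), axis=1)[:, ::-1]
        times = rng.uniform(0.2, 5, n)
        events = np.ones(n, bool)
        t_star = 3.0
        surv_indicator = (times > t_star).astype(float)
        mse = np.mean((surv_indicator - S[:, 2]) ** 2)
        assert brier_score(SurvivalMatrix(S, g), times, events, t_star) == (
            pytest.approx(mse, rel=1e-12)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_ipcw_matches_per_sample_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        g = TimeGrid(horizon_years=6, step_years=1)
        n = 25
        S = np.sort(rng.random((n, 6)), axis=1)[:, ::-1]
        times = rng.uniform(0.2, 6, n)
        events = rng.random(n) < 0.6
        t_star = 3.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ours = brier_score(SurvivalMatrix(S, g), times, events, t_star)
        assert ours == pytest.approx(brier_oracle(S[:, 2], times, events, t_star),
                                     abs=1e-12)

    def test_integrated_is_mean_of_per_step_scores(self, rng):
        g = TimeGrid(horizon_years=4, step_years=1)
        n = 30
        S = np.sort(rng.random((n, 4)), axis=1)[:, ::-1]
        times = rng.uniform(0.2, 4.5, n)
        events = rng.random(n) < 0.7
        Sm = SurvivalMatrix(S, g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_step = [brier_score(Sm, times, events, t) for t in g.interval_ends]
            assert integrated_brier(Sm, times, events, g) == (
                pytest.approx(np.mean(per_step))
            )

    def test_single_interval_grid_equals_brier(self, rng):
        g = TimeGrid(horizon_years=1, step_years=1)
        S = rng.random((20, 1))
        times = rng.uniform(0.1, 1.5, 20)
        events = np.ones(20, bool)
        Sm = SurvivalMatrix(S, g)
        assert integrated_brier(Sm, times, events, g) == (
            pytest.approx(brier_score(Sm, times, events, 1.0))
        )


class TestCalibrationCurves:
    def test_decile_groups_collapse_without_censoring(self, rng):
        n = 200
        F = rng.random(n)
        times = rng.uniform(0.1, 10, n)
        events = np.ones(n, bool)
        curve = decile_calibration(F, times, events, t_star=5.0)
        # with no censoring the group KM failure rate is the event fraction
        order = np.argsort(F, kind="stable")
        for g in range(10):
            grp = order[g * 20 : (g + 1) * 20]
            assert curve.observed[g] == pytest.approx(
                np.mean(times[grp] <= 5.0), abs=1e-12
            )

    def test_identical_predictions_make_single_group(self, rng):
        F = np.full(50, 0.4)
        curve = decile_calibration(F, rng.uniform(0.1, 9, 50),
                                   np.ones(50, bool), 5.0)
        assert len(curve.predicted) == 1

    def test_well_calibrated_truth_lies_on_diagonal(self, grid):
        cfg = SimulationConfig(n_individuals=50_000, n_continuous=3,
                               baseline_hazard=0.02,
                               coefficient_schedule=np.array([0.6, -0.6, 0.4]),
                               censoring_rate=0.003, seed=31)
        data, _ = generate_cohort(cfg, grid)
        S = true_survival(cfg, data.covariates, grid)
        F = 1.0 - S.at_time(5.0)
        curve = decile_calibration(F, data.observed_time, data.event_observed, 5.0)
        assert np.max(np.abs(curve.predicted - curve.observed)) < 0.02

    def test_spline_recovers_constant_offset(self, grid):
        cfg = SimulationConfig(n_individuals=20_000, n_continuous=2,
                               baseline_hazard=0.02,
                               coefficient_schedule=np.array([0.5, -0.5]),
                               censoring_rate=0.0, seed=37)
        data, _ = generate_cohort(cfg, grid)
        F_true = 1.0 - true_survival(cfg, data.covariates, grid).at_time(5.0)
        delta = 0.05
        curve = spline_calibration(np.clip(F_true + delta, 0, 1),
                                   data.observed_time, data.event_observed, 5.0)
        assert ici(curve) == pytest.approx(delta, abs=0.02)

    def test_spline_on_truth_is_nearly_diagonal(self, grid):
        cfg = SimulationConfig(n_individuals=20_000, n_continuous=2,
                               baseline_hazard=0.02,
                               coefficient_schedule=np.array([0.5, -0.5]),
                               censoring_rate=0.003, seed=41)
        data, _ = generate_cohort(cfg, grid)
        F_true = 1.0 - true_survival(cfg, data.covariates, grid).at_time(5.0)
        curve = spline_calibration(F_true, data.observed_time,
                                   data.event_observed, 5.0)
        assert curve.method == "spline"
        assert np.mean(np.abs(curve.predicted - curve.observed)) < 0.02

    def test_degenerate_predictions_fall_back_to_deciles(self, rng):
        with pytest.warns(RuntimeWarning):
            curve = spline_calibration(np.full(60, 0.3), rng.uniform(0.1, 9, 60),
                                       np.ones(60, bool), 5.0)
        assert curve.method == "decile"

    def test_ici_of_diagonal_and_offset_curves(self):
        p = np.linspace(0.05, 0.9, 20)
        assert ici(CalibrationCurve(5.0, p, p.copy(), "spline")) == 0.0
        assert ici(CalibrationCurve(5.0, p, p + 0.07, "spline")) == (
            pytest.approx(0.07)
        )


@pytest.fixture(scope="module")
def cohort():
    grid = TimeGrid()
    cfg = SimulationConfig(n_individuals=2000, n_continuous=3,
                           baseline_hazard=0.03,
                           coefficient_schedule=np.array([0.7, -0.7, 0.5]),
                           censoring_rate=0.005, seed=55)
    data, _ = generate_cohort(cfg, grid)
    return grid, cfg, data


class TestEvaluateModel:
    def test_report_fields_in_range(self, cohort):
        grid, cfg, data = cohort
        S = true_survival(cfg, data.covariates, grid)
        report = evaluate_model(S, data, grid)
        assert 0 <= report.harrell_c <= 1 and 0 <= report.antolini_c <= 1
        assert report.ibs >= 0
        assert set(report.ici) == {"1y", "5y", "15y"}
        assert all(v >= 0 for v in report.brier.values())

    def test_oracle_dominates_random_predictions(self, cohort, rng):
        grid, cfg, data = cohort
        S_true = true_survival(cfg, data.covariates, grid)
        h_rand = rng.uniform(0.0, 0.1, size=(data.n, grid.n_intervals))
        S_rand = SurvivalMatrix(np.cumprod(1 - h_rand, axis=1), grid)
        good = evaluate_model(S_true, data, grid)
        bad = evaluate_model(S_rand, data, grid)
        assert good.antolini_c > bad.antolini_c
        assert good.harrell_c > bad.harrell_c
        assert good.ibs < bad.ibs

    def test_json_round_trip(self, cohort, tmp_path):
        grid, cfg, data = cohort
        S = true_survival(cfg, data.covariates, grid)
        report = evaluate_model(S, data, grid)
        report.to_json(tmp_path / "report.json")
        back = MetricReport.from_json(tmp_path / "report.json")
        assert back.harrell_c == report.harrell_c
        assert back.ici == report.ici
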