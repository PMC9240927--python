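"""Risk-bin baseline-hazard calibration: cutoffs, estimator, conservation."""

import numpy as np
import pytest

from graftsurv import (
    RiskBinModel,
    SurvivalDataset,
    TimeGrid,
    calibrate_hazards,
    estimate_bin_baseline_hazards,
    estimate_global_baseline_hazard,
    fit_risk_bins,
    transplant_fixture,
)
from graftsurv.calibration import assign_bins


def _dataset(times, events, n_cols=1):
    n = len(times)
    return SurvivalDataset(np.zeros((n, n_cols)), times, events, [f"x{i}" for i in range(n_cols)])


class TestRiskBins:
    def test_single_bin_has_no_cutoffs(self, rng):
        cutoffs = fit_risk_bins(rng.random((20, 4)), 1)
        assert cutoffs.shape == (0, 4)
        assert np.all(assign_bins(rng.random((5, 4)), cutoffs) == 0)

    def test_cutoffs_are_quartiles(self):
        scores = np.tile(np.arange(1.0, 101.0)[:, None], (1, 2))
        cutoffs = fit_risk_bins(scores, 4)
        np.testing.assert_allclose(cutoffs[:, 0], np.quantile(np.arange(1.0, 101.0),
                                                              [0.25, 0.5, 0.75]))

    def test_tied_scores_all_land_in_top_bin(self):
        scores = np.full((10, 3), 0.7)
        cutoffs = fit_risk_bins(scores, 4)
        np.testing.assert_allclose(cutoffs, 0.7)
        assert np.all(assign_bins(scores, cutoffs) == 3)

    def test_out_of_range_scores_use_outer_bins(self, rng):
        train = rng.random((50, 2))
        cutoffs = fit_risk_bins(train, 5)
        new = np.array([[-10.0, 10.0]])
        bins = assign_bins(new, cutoffs)
        assert bins[0, 0] == 0 and bins[0, 1] == 4

    def test_invalid_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_risk_bins(rng.random((10, 2)), 0)
        with pytest.raises(ValueError):
            fit_risk_bins(rng.random((3, 2)), 5)


class TestBaselineHazards:
    def test_unit_scores_single_bin_recover_empirical_hazard(self):
        grid = TimeGrid(horizon_years=3, step_years=1)
        # events at intervals 1,2,2; censored at 3 -> d/|R| = 1/4, 2/3, 0
        data = _dataset([0.5, 1.5, 1.7, 2.5], [True, True, True, False])
        scores = np.ones((4, 3))
        bh = estimate_global_baseline_hazard(data, scores, grid)
        np.testing.assert_allclose(bh, [1 / 4, 2 / 3, 0.0])

    def test_bin_without_events_gets_zero(self):
        grid = TimeGrid(horizon_years=2, step_years=1)
        data = _dataset([1.8, 1.9], [False, False])
        model = RiskBinModel.fit(data, np.array([[0.1, 0.1], [0.9, 0.9]]), grid, 2)
        assert np.all(model.baseline_hazards == 0.0)
        assert np.all(model.event_counts == 0)

    def test_six_individual_worked_example(self):
        """2 bins x 3 steps against explicit hand arithmetic of d_k(t)/sum R."""
        grid = TimeGrid(horizon_years=3, step_years=1)
        times = [0.5, 1.5, 2.5, 0.7, 2.2, 2.8]
        events = [True, True, True, False, True, False]
        data = _dataset(times, events)
        scores = np.array(
            [
                [0.9, 0.8, 0.7],   # event at 1
                [0.8, 0.7, 0.6],   # event at 2
                [0.7, 0.6, 0.5],   # event at 3
                [0.2, 0.3, 0.1],   # censored at 1
                [0.3, 0.2, 0.4],   # event at 3
                [0.1, 0.1, 0.2],   # censored at 3
            ]
        )
        cutoffs = np.array([[0.5, 0.45, 0.45]])  # bin 1 = high scores
        model = estimate_bin_baseline_hazards(data, scores, cutoffs, grid, 2)
        # step 1: low bin {4,5,6} no events, denom .2+.3+.1; high {1,2,3} d=1 denom 2.4
        # step 2: at-risk excludes 1 and 4; low {5,6} d=0; high {2,3} d=1 denom 1.3
        # step 3: at-risk {3,5,6}; high {3} d=1 denom .5; low {5,6} d=1 denom .6
        expected_bh = np.array([[0.0, 0.0, 1 / 0.6], [1 / 2.4, 1 / 1.3, 1 / 0.5]])
        expected_d = np.array([[0, 0, 1], [1, 1, 1]])
        np.testing.assert_allclose(model.baseline_hazards, expected_bh)
        np.testing.assert_allclose(model.event_counts, expected_d)

    def test_global_equals_single_bin(self, rng):
        grid = TimeGrid(horizon_years=5, step_years=1)
        data = _dataset(rng.uniform(0.1, 5, 30), rng.random(30) < 0.6)
        scores = rng.uniform(0.01, 1, (30, 5))
        bh = estimate_global_baseline_hazard(data, scores, grid)
        model = RiskBinModel.fit(data, scores, grid, n_bins=1)
        np.testing.assert_allclose(bh, model.baseline_hazards[0])


class TestCalibration:
    @pytest.fixture()
    def fitted(self, rng):
        grid = TimeGrid()
        data = transplant_fixture(seed=3, n=400)
        scores = rng.uniform(0.005, 0.3, size=(400, grid.n_intervals))
        model = RiskBinModel.fit(data, scores, grid, n_bins=5)
        return grid, data, scores, model

    def test_training_conservation_is_exact(self, fitted):
        """Sum of calibrated hazards over each bin's risk set equals the bin's
        event count — the keystone identity of the estimator."""
        grid, data, scores, model = fitted
        h_cal = model.calibrate(scores).values
        intervals, events = data.discretize(grid)
        bins = model.assign(scores)
        steps = np.arange(1, grid.n_intervals + 1)
        for k in range(model.n_bins):
            in_risk = (bins == k) & (intervals[:, None] >= steps[None, :])
            total = np.where(in_risk, h_cal, 0.0).sum(axis=0)
            d = model.event_counts[k]
            np.testing.assert_allclose(total[d > 0], d[d > 0], rtol=1e-10)

    def test_zero_baseline_zeroes_the_bin(self, fitted):
        grid, data, scores, model = fitted
        h_cal = model.calibrate(scores).values
        bins = model.assign(scores)
        zero_bh = model.baseline_hazards[bins, np.arange(grid.n_intervals)[None, :]] == 0
        assert np.all(h_cal[zero_bh] == 0.0)

    def test_matches_per_cell_reference(self, fitted, rng):
        grid, _, _, model = fitted
        new_scores = rng.uniform(0.0, 0.4, size=(37, grid.n_intervals))
        h_cal = calibrate_hazards(new_scores, model).values
        for i in range(0, 37, 5):
            for t in range(0, grid.n_intervals, 7):
                k = int(np.sum(model.cutoffs[:, t] <= new_scores[i, t]))
                expected = min(new_scores[i, t] * model.baseline_hazards[k, t], 1.0)
                assert h_cal[i, t] == pytest.approx(expected)

    def test_rank_preserved_within_bin(self, fitted):
        grid, _, scores, model = fitted
        h_cal = model.calibrate(scores).values
        bins = model.assign(scores)
        t = 10
        for k in range(model.n_bins):
            members = bins[:, t] == k
            if members.sum() < 2:
                continue
            order_scores = np.argsort(scores[members, t])
            cal = h_cal[members, t][order_scores]
            assert np.all(np.diff(cal) >= -1e-15)

    def test_json_round_trip(self, fitted, tmp_path):
        grid, _, scores, model = fitted
        model.to_json(tmp_path / "bins.json")
        back = RiskBinModel.from_json(tmp_path / "bins.json")
        np.testing.assert_allclose(back.cutoffs, model.cutoffs)
        np.testing.assert_allclose(back.baseline_hazards, model.baseline_hazards)
        np.testing.assert_array_equal(
            back.calibrate(scores).values, model.calibrate(scores).values
        )

    def test_dimension_mismatch_rejected(self, fitted, rng):
        grid, _, _, model = fitted
        with pytest.raises(ValueError):
            calibrate_hazards(rng.random((3, grid.n_intervals + 1)), model)
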