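"""PLS1 fitting, LOOCV/Q2, ONLV selection, VIP, band intervals, metrics."""

import numpy as np
import pytest

from spectrait import (
    calibrate_validate,
    evaluate_predictions,
    extract_band_intervals,
    fit_plsr,
    loocv_curve,
    plsr_on_features,
    select_onlv,
    vip,
)
from spectrait.plsr import CrossValidationCurve


def _random_instance(rng, n=20, p=50, n_factors=3, noise=0.1):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[rng.choice(p, n_factors, replace=False)] = rng.normal(size=n_factors) * 2
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestFit:
    def test_exact_linear_fit_recovers_response(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + 4.0
        model = fit_plsr(X, y, n_lv=5)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)
        assert model.r2y_cum[-1] == pytest.approx(1.0, abs=1e-10)

    def test_single_predictor_equals_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 2.0 * x + rng.normal(size=40)
        model = fit_plsr(x[:, None], y, n_lv=1)
        slope, intercept = np.polyfit(x, y, 1)
        assert model.coefficients[0] == pytest.approx(slope, rel=1e-10)
        assert model.intercept == pytest.approx(intercept, rel=1e-8)

    def test_predictions_match_sklearn_reference(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(2)
        X, y = _random_instance(rng, n=20, p=50)
        for n_lv in (1, 3, 5):
            ours = fit_plsr(X, y, n_lv=n_lv, scale=True)
            ref = sklearn_pls.PLSRegression(n_components=n_lv, scale=True)
            ref.fit(X, y)
            np.testing.assert_allclose(
                ours.predict(X), ref.predict(X).ravel(), atol=1e-6
            )

    def test_constant_columns_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X, y = _random_instance(rng, n=15, p=10)
        X[:, 4] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            model = fit_plsr(X, y, n_lv=3)
        assert model.coefficients[4] == 0.0

    def test_r2y_cum_nondecreasing(self):
        rng = np.random.default_rng(4)
        X, y = _random_instance(rng)
        model = fit_plsr(X, y, n_lv=8)
        assert np.all(np.diff(model.r2y_cum) >= -1e-12)

    def test_excessive_lv_count_rejected(self):
        rng = np.random.default_rng(5)
        X, y = _random_instance(rng, n=10, p=4)
        with pytest.raises(ValueError):
            fit_plsr(X, y, n_lv=5)


class TestVIP:
    def test_single_predictor_vip_is_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        model = fit_plsr(x[:, None], 2 * x + rng.normal(size=30), n_lv=1)
        assert vip(model)[0] == pytest.approx(1.0)

    def test_mean_squared_vip_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            X, y = _random_instance(rng, n=25, p=40)
            model = fit_plsr(X, y, n_lv=4)
            assert (vip(model) ** 2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_informative_predictor_has_max_vip(self):
        rng = np.random.default_rng(8)
        n, p = 200, 12
        X = rng.normal(size=(n, p))
        y = 3.0 * X[:, 7] + 0.05 * rng.normal(size=n)
        model = fit_plsr(X, y, n_lv=2)
        v = vip(model)
        assert np.argmax(v) == 7
        assert v[7] > 1.0


class TestLOOCV:
    def test_perfect_prediction_gives_q2_one(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(15, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        curve = loocv_curve(X, y, max_lv=3)
        assert curve.q2_cum[-1] == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_q2_nonpositive_in_median(self):
        rng = np.random.default_rng(10)
        medians = []
        for _ in range(40):
            X = rng.normal(size=(20, 10))
            y = rng.normal(size=20)
            curve = loocv_curve(X, y, max_lv=3)
            medians.append(curve.q2_cum.max())
        assert np.median(medians) <= 0.0

    def test_press_matches_explicit_loop(self):
        rng = np.random.default_rng(11)
        X, y = _random_instance(rng, n=12, p=6)
        max_lv = 3
        curve = loocv_curve(X, y, max_lv=max_lv)
        press = np.zeros(max_lv)
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            model = fit_plsr(X[mask], y[mask], max_lv)
            for a in range(1, max_lv + 1):
                pred = model.predict(X[i : i + 1], n_lv=a)[0]
                press[a - 1] += (y[i] - pred) ** 2
        np.testing.assert_allclose(curve.press, press, rtol=1e-10)


class TestONLV:
    def test_monotone_curve_picks_last(self):
        curve = CrossValidationCurve(
            q2_cum=np.array([0.1, 0.3, 0.5, 0.7]), press=np.zeros(4), ss_total=1.0
        )
        assert select_onlv(curve).n_lv == 4

    def test_parsimony_tiebreak_rule(self):
        curve = CrossValidationCurve(
            q2_cum=np.array([0.40, 0.60, 0.601, 0.55]), press=np.zeros(4), ss_total=1.0
        )
        sel = select_onlv(curve)
        assert sel.n_lv == 2
        assert sel.acceptable  # 0.60 > 0.5

    def test_low_q2_flagged_unacceptable(self):
        curve = CrossValidationCurve(
            q2_cum=np.array([0.2, 0.3]), press=np.zeros(2), ss_total=1.0
        )
        assert not select_onlv(curve).acceptable

    def test_three_factor_response_selects_few_lvs(self):
        rng = np.random.default_rng(12)
        hits = []
        for _ in range(5):
            n, p = 60, 30
            F = rng.normal(size=(n, 3))
            load = rng.normal(size=(3, p))
            X = F @ load + 0.05 * rng.normal(size=(n, p))
            y = F @ np.array([1.0, -1.0, 0.5]) + 0.05 * rng.normal(size=n)
            sel = select_onlv(loocv_curve(X, y, max_lv=8))
            hits.append(sel.n_lv)
        assert all(2 <= h <= 4 for h in hits)


class TestBandIntervals:
    def test_single_block(self):
        wl = np.arange(700, 761)
        v = np.where((wl >= 700) & (wl <= 750), 1.5, 0.5)
        w = np.where((wl >= 700) & (wl <= 750), 1.0, 0.01)[:, None]
        ivs = extract_band_intervals(v, w, wl)
        assert [(i.start, i.end) for i in ivs] == [(700, 750)]

    def test_small_gap_bridged(self):
        wl = np.arange(700, 721)
        passing = ((wl >= 700) & (wl <= 707)) | ((wl >= 711) & (wl <= 720))
        v = np.where(passing, 1.5, 0.0)
        w = np.where(passing, 1.0, 0.0)[:, None]
        ivs = extract_band_intervals(v, w, wl, merge_gap=5)
        assert [(i.start, i.end) for i in ivs] == [(700, 720)]

    def test_large_gap_splits(self):
        wl = np.arange(700, 741)
        passing = ((wl >= 700) & (wl <= 705)) | ((wl >= 730) & (wl <= 740))
        v = np.where(passing, 1.5, 0.0)
        w = np.where(passing, 1.0, 0.0)[:, None]
        ivs = extract_band_intervals(v, w, wl, merge_gap=5)
        assert [(i.start, i.end) for i in ivs] == [(700, 705), (730, 740)]

    def test_empty_when_nothing_passes(self):
        wl = np.arange(700, 710)
        assert extract_band_intervals(np.full(10, 0.5), np.ones((10, 1)), wl) == []


class TestCalibrationValidation:
    def test_noiseless_linear_gives_perfect_validation(self):
        # rank-2 predictors and a noiseless linear response: the exact fit
        # is reachable at the selected ONLV, so validation is perfect
        rng = np.random.default_rng(13)
        F = rng.normal(size=(40, 2))
        X = F @ rng.normal(size=(2, 6))
        y = F @ np.array([2.0, -1.0]) + 5.0
        cv = calibrate_validate(X, y, validation_fraction=0.25, seed=3, max_lv=2)
        assert cv.validation.r2 == pytest.approx(1.0, abs=1e-8)
        assert cv.validation.re_pct == pytest.approx(0.0, abs=1e-6)

    def test_relative_error_definition(self):
        # RE = 100 * RMSE / mean(observed): RMSE 3.639 at observed mean 74.4
        # must give 4.89%
        obs = np.full(100, 74.4)
        pred = obs + 3.639
        m = evaluate_predictions(obs, pred)
        assert m.rmse == pytest.approx(3.639)
        assert m.re_pct == pytest.approx(4.89, abs=0.01)

    def test_metrics_match_independent_recompute(self):
        rng = np.random.default_rng(14)
        obs = rng.normal(10, 2, size=50)
        pred = obs + rng.normal(0, 0.5, size=50)
        m = evaluate_predictions(obs, pred)
        rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
        r = float(np.corrcoef(obs, pred)[0, 1])
        assert m.rmse == pytest.approx(rmse, abs=1e-10)
        assert m.r2 == pytest.approx(r * r, abs=1e-10)
        assert m.re_pct == pytest.approx(100 * rmse / obs.mean(), abs=1e-10)

    def test_split_sizes(self):
        rng = np.random.default_rng(15)
        X, y = _random_instance(rng, n=40, p=8)
        cv = calibrate_validate(X, y, validation_fraction=0.25, seed=0, max_lv=4)
        assert len(cv.test_idx) == 10
        assert len(cv.train_idx) == 30


class TestFeaturePLSR:
    def test_trait_as_feature_gives_r2_one(self):
        rng = np.random.default_rng(16)
        y = rng.normal(5, 1, size=30)
        F = np.column_stack([y, rng.normal(size=30)])
        res = plsr_on_features(F, y, max_lv=2)
        assert res.metrics.r2 == pytest.approx(1.0, abs=1e-8)

    def test_removing_informative_feature_drops_r2(self):
        rng = np.random.default_rng(17)
        n = 80
        signal = rng.normal(size=n)
        y = 2 * signal + 0.05 * rng.normal(size=n)
        noise_feats = rng.normal(size=(n, 5))
        with_signal = np.column_stack([signal, noise_feats])
        assert plsr_on_features(with_signal, y, max_lv=3).metrics.r2 > 0.95
        assert plsr_on_features(noise_feats, y, max_lv=3).metrics.r2 < 0.2
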