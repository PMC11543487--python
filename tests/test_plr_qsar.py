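"""Piecewise-linear QSAR fitting, prediction semantics and chemometrics."""

import math

import numpy as np
import pandas as pd
import pytest

from descreen.plr_qsar import (
    ModelMetrics,
    PLRModel,
    evaluate_model,
    fit_plr,
    interpret_metrics,
    predict_plr,
    published_model,
    split_calibration_prediction,
)


def planted_model(p=3):
    names = [f"x{i + 1}" for i in range(p)]
    # branches positively correlated so most of the design space realises
    # exactly one branch of the response-side membership rule
    return PLRModel(
        input_names=names,
        coef_low=np.array([0.0, 2.0, 1.0, 0.5][: p + 1]),
        coef_high=np.array([2.0, 3.0, 1.5, 1.0][: p + 1]),
        breakpoint=1.0,
    )


def planted_data(model, n=60, noise_sd=0.0, seed=0):
    """Design points whose noiseless response is self-consistent with the
    response-side membership rule (rejection sampling)."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    while sum(len(x) for x in xs) < n:
        X = rng.uniform(-2, 2, size=(2 * n, len(model.input_names)))
        lo, hi = model.segment_values(X)
        lo_ok = lo <= model.breakpoint
        valid = lo_ok ^ (hi > model.breakpoint)  # exactly one branch realisable
        xs.append(X[valid])
        ys.append(np.where(lo_ok, lo, hi)[valid])
    X = np.vstack(xs)[:n]
    y = np.concatenate(ys)[:n]
    if noise_sd:
        y = y + noise_sd * rng.standard_normal(n)
    return X, y


def oracle_grid_fit(X, y, min_rows):
    """Independent brute-force: midpoint grid + per-segment normal equations."""
    best = (np.inf, None)
    ys = np.unique(y)
    for b in (ys[:-1] + ys[1:]) / 2:
        lo = y <= b
        if lo.sum() < min_rows or (~lo).sum() < min_rows:
            continue
        sse = 0.0
        for mask in (lo, ~lo):
            A = np.column_stack([np.ones(mask.sum()), X[mask]])
            coef = np.linalg.solve(A.T @ A + 1e-12 * np.eye(A.shape[1]), A.T @ y[mask])
            sse += float(np.sum((y[mask] - A @ coef) ** 2))
        if sse < best[0]:
            best = (sse, float(b))
    return best


class TestSplit:
    def test_sixty_three_rows_split_forty_four_nineteen(self):
        df = pd.DataFrame({"a": np.arange(63.0)})
        cal, pred = split_calibration_prediction(df, 0.7, seed=5)
        assert (len(cal), len(pred)) == (44, 19)

    def test_same_seed_reproduces_partition(self):
        df = pd.DataFrame({"a": np.arange(20.0)})
        c1, p1 = split_calibration_prediction(df, 0.7, seed=11)
        c2, p2 = split_calibration_prediction(df, 0.7, seed=11)
        assert list(c1.index) == list(c2.index)
        assert list(p1.index) == list(p2.index)

    def test_degenerate_ratios_rejected(self):
        df = pd.DataFrame({"a": np.arange(20.0)})
        for ratio in (0.0, 1.0, 1.3):
            with pytest.raises(ValueError):
                split_calibration_prediction(df, ratio, seed=1)


class TestFit:
    def test_noiseless_planted_model_recovered_exactly(self):
        model = planted_model()
        X, y = planted_data(model, n=60)
        fitted, metrics = fit_plr(X, y, input_names=model.input_names)
        assert metrics.r2_cal == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(fitted.coef_low, model.coef_low, atol=1e-8)
        np.testing.assert_allclose(fitted.coef_high, model.coef_high, atol=1e-8)
        # breakpoint identified up to the gap between the two segments' y values
        lo_max = y[y <= model.breakpoint].max()
        hi_min = y[y > model.breakpoint].min()
        assert lo_max <= fitted.breakpoint <= hi_min

    def test_single_hyperplane_data_gives_matching_segments(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(50, 2))
        y = 3.0 + 2.0 * X[:, 0] - 1.0 * X[:, 1]
        fitted, metrics = fit_plr(X, y)
        assert metrics.r2_cal == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fitted.coef_low, fitted.coef_high, atol=1e-6)

    def test_agrees_with_independent_grid_search_oracle(self):
        model = planted_model()
        X, y = planted_data(model, n=63, noise_sd=0.3, seed=7)
        fitted, _ = fit_plr(X, y, input_names=model.input_names)
        p = X.shape[1]
        min_rows = max(p + 1, int(math.ceil(0.1 * len(y))))
        sse_oracle, b_oracle = oracle_grid_fit(X, y, min_rows)
        ys = np.sort(np.unique(y))
        step = np.max(np.diff(ys))
        assert abs(fitted.breakpoint - b_oracle) <= step + 1e-12

    def test_piecewise_sse_not_worse_than_single_segment_ols(self):
        model = planted_model()
        X, y = planted_data(model, n=60, noise_sd=0.5, seed=3)
        fitted, _ = fit_plr(X, y, input_names=model.input_names)
        yhat = np.where(y <= fitted.breakpoint,
                        fitted.segment_values(X)[0], fitted.segment_values(X)[1])
        A = np.column_stack([np.ones(len(y)), X])
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.sum((y - yhat) ** 2) <= np.sum((y - A @ coef) ** 2) + 1e-9

    def test_breakpoint_recovery_under_noise(self):
        # 5% of response SD noise, 20 seeds: median breakpoint error
        # below 10% of the response range
        model = planted_model()
        errs = []
        for seed in range(20):
            X, y = planted_data(model, n=63, seed=seed)
            sd = y.std()
            Xn, yn = planted_data(model, n=63, noise_sd=0.05 * sd, seed=100 + seed)
            fitted, _ = fit_plr(Xn, yn, input_names=model.input_names)
            errs.append(abs(fitted.breakpoint - model.breakpoint) / np.ptp(yn))
        assert np.median(errs) < 0.10

    def test_too_few_rows_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError):
            fit_plr(X, np.arange(6.0))

    def test_constant_response_rejected(self):
        X = np.random.default_rng(0).uniform(size=(30, 2))
        with pytest.raises(ValueError):
            fit_plr(X, np.full(30, 5.0))


class TestPredict:
    def test_self_consistent_segment_chosen(self):
        model = planted_model()
        X, y = planted_data(model, n=40, seed=2)
        np.testing.assert_allclose(predict_plr(model, X), y, atol=1e-12)

    def test_tie_break_on_published_activity_model_at_zero_predictors(self):
        # both intercepts are inconsistent with their own domain; the value
        # closer to the breakpoint (31.635 vs 25.079 around 30.081) wins
        model, _ = published_model("fdh_activity")
        pred = predict_plr(model, np.zeros((1, len(model.input_names))))
        assert pred[0] == pytest.approx(31.635)

    def test_forced_segment_tie_breaks(self):
        model, _ = published_model("fdh_activity")
        X = np.zeros((1, len(model.input_names)))
        assert predict_plr(model, X, tie_break="low")[0] == pytest.approx(31.635)
        assert predict_plr(model, X, tie_break="high")[0] == pytest.approx(25.079)

    def test_missing_predictor_column_raises(self):
        model = planted_model()
        df = pd.DataFrame({"x1": [0.0], "x2": [0.0]})
        with pytest.raises(KeyError):
            predict_plr(model, df)


class TestMetrics:
    def test_hand_computed_five_point_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        yhat = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        m = evaluate_model(y, yhat, y, yhat, p=1)
        sse = 0.01 + 0.01 + 0.04 + 0.04 + 0.01
        assert m.rmsec == pytest.approx(math.sqrt(sse / 5), abs=1e-12)
        assert m.r2_cal == pytest.approx(1 - sse / 10.0, abs=1e-12)
        assert m.r2_cal_adj == pytest.approx(1 - (sse / 10.0) * 4 / 3, abs=1e-12)
        assert m.rpd == pytest.approx(np.std(y, ddof=1) / m.rmsep, abs=1e-12)
        assert m.rer == pytest.approx(4.0 / m.rmsep, abs=1e-12)

    def test_perfect_prediction_flags_infinite_ratios(self):
        y = np.array([1.0, 2.0, 3.0])
        m = evaluate_model(y, y, y, y, p=1)
        assert m.r2_cal == 1.0 and m.rmsep == 0.0
        assert math.isinf(m.rpd) and math.isinf(m.rer)

    def test_defining_ratios(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=50)
        # construct predictions with a known RMSEP
        target_rmsep = np.std(y, ddof=1) / 2
        yhat = y + target_rmsep
        m = evaluate_model(y, yhat, y, yhat, p=1)
        assert m.rpd == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize(
        "r2,rpd,rer,expected",
        [
            (0.905, 5.589, 18.324, ("significant", "excellent", "quantification")),
            (0.738, 3.292, 10.456, ("moderate", "excellent", "quality-control")),
            (0.60, 1.0, 5.0, ("moderate", "non-reliable", "screening")),
            (0.30, 1.5, 3.0, ("weak", "fair", "inadequate")),
        ],
    )
    def test_interpretation_thresholds(self, r2, rpd, rer, expected):
        m = ModelMetrics(r2_cal=r2, r2_cal_adj=r2, rmsec=1.0, r2_pred=r2,
                         r2_pred_adj=r2, rmsep=1.0, rpd=rpd, rer=rer)
        labels = interpret_metrics(m)
        assert (labels["r2"], labels["rpd"], labels["rer"]) == expected


class TestPublishedModels:
    def test_activity_model_intercepts_and_breakpoint(self):
        model, _ = published_model("fdh_activity")
        assert model.coef_low[0] == 31.635
        assert model.coef_high[0] == 25.079
        assert model.breakpoint == 30.081

    def test_half_life_model_high_segment_intercept(self):
        model, _ = published_model("fdh_half_life")
        assert model.coef_high[0] == 4.429
        assert model.breakpoint == 14.041

    def test_nadh_model_excludes_ph(self):
        model, _ = published_model("nadh_half_life")
        assert "ph" not in model.input_names
        assert len(model.input_names) == 11
        assert model.breakpoint == 23.872

    def test_reported_activity_metrics_verdict(self):
        _, metrics = published_model("fdh_activity")
        labels = interpret_metrics(metrics)
        assert labels == {"r2": "significant", "rpd": "excellent", "rer": "quantification"}

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            published_model("nope")

    def test_json_round_trip(self):
        model, _ = published_model("fdh_half_life")
        back = PLRModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.coef_low, model.coef_low)
        assert back.breakpoint == model.breakpoint
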