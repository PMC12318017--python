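"""Path model, outcome classifier, change points, early warning."""

import numpy as np
import pytest
from scipy.stats import norm

import teamfuse as tf
from teamfuse.errors import ConfigError, ValidationError
from teamfuse.perform import loso_accuracy
from teamfuse.session import IndicatorSeries

import pandas as pd


def _path_data(n, beta=(0.5, 0.3, 0.2), sigma=0.0, seed=0, n_ath=4):
    rng = np.random.default_rng(seed)
    cs = rng.standard_normal(n)
    ct = rng.standard_normal(n)
    pind = rng.standard_normal((n, n_ath))
    w = np.full(n_ath, 1.0 / n_ath)
    comp = pind @ w
    y = beta[0] * cs + beta[1] * ct + beta[2] * comp + \
        sigma * rng.standard_normal(n)
    return y, cs, ct, pind, w


class TestPathModel:
    def test_exact_recovery_noiseless(self):
        y, cs, ct, pind, w = _path_data(50)
        model = tf.fit_path_model(y, cs, ct, pind, w)
        assert np.abs(model.beta - (0.5, 0.3, 0.2)).max() < 1e-6
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        y, cs, ct, pind, w = _path_data(80, sigma=0.3, seed=2)
        model = tf.fit_path_model(y, cs, ct, pind, w)
        X = np.column_stack([cs, ct, pind @ w])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.abs(model.beta - oracle).max() < 1e-10

    def test_matches_statsmodels_cross_check(self):
        import statsmodels.api as sm
        y, cs, ct, pind, w = _path_data(60, sigma=0.2, seed=5)
        model = tf.fit_path_model(y, cs, ct, pind, w)
        X = np.column_stack([cs, ct, pind @ w])
        fit = sm.OLS(y, X).fit()
        assert np.abs(model.beta - fit.params).max() < 1e-8
        assert np.abs(model.std_errors - fit.bse).max() < 1e-8

    def test_small_sample_bias_bounded(self):
        """n=200, sigma=0.1: estimator is unbiased well under 0.02."""
        errs = np.zeros(3)
        n_rep = 200
        for rep in range(n_rep):
            y, cs, ct, pind, w = _path_data(200, sigma=0.1, seed=rep)
            errs += tf.fit_path_model(y, cs, ct, pind, w).beta
        bias = errs / n_rep - np.array([0.5, 0.3, 0.2])
        assert np.abs(bias).max() < 0.02

    def test_zero_column_unidentifiable(self):
        y, cs, ct, pind, w = _path_data(30)
        with pytest.raises(ValidationError, match="C_spatial"):
            tf.fit_path_model(y, np.zeros_like(cs), ct, pind, w)

    def test_collinear_design_names_predictors(self):
        y, cs, ct, pind, w = _path_data(30)
        with pytest.raises(ValidationError, match="collinear"):
            tf.fit_path_model(y, cs, cs * 2.0, pind * 0 + cs[:, None], w)

    def test_too_few_sessions_rejected(self):
        y, cs, ct, pind, w = _path_data(5)
        with pytest.raises(ValidationError, match="10"):
            tf.fit_path_model(y, cs, ct, pind, w)


class TestOutcomeClassifier:
    def test_log_likelihood_non_decreasing(self):
        data = tf.make_outcome_dataset(tf.SimConfig(seed=4), 80)
        clf = tf.fit_outcome_classifier(data)
        ll = clf.log_likelihood_trace
        assert all(b >= a - 1e-9 for a, b in zip(ll, ll[1:]))

    def test_one_sigma_shift_near_bayes_rate(self):
        """Four independent 1-sigma shifts: Bayes accuracy Phi(1) ~ 84.1%."""
        cfg = tf.SimConfig(outcome_effect=(1.0, 1.0, 1.0, 1.0), seed=10)
        data = tf.make_outcome_dataset(cfg, 400)
        acc = loso_accuracy(data)
        bayes = norm.cdf(np.linalg.norm([1, 1, 1, 1]) / 2)
        assert abs(acc - bayes) < 0.05

    def test_separation_handled_with_warning(self):
        data = [({"TCR": 1.0, "CPR": 1.0, "SSI": 1.0, "ICC": 1.0}, "win")] * 10 \
            + [({"TCR": -1.0, "CPR": -1.0, "SSI": -1.0, "ICC": -1.0}, "loss")] * 10
        clf = tf.fit_outcome_classifier(data)
        assert clf.separation_warning
        p = clf.predict_proba([f for f, _ in data])
        assert ((0 < p) & (p < 1)).all()

    def test_single_class_rejected(self):
        data = [({"TCR": 0.1, "CPR": 0.2, "SSI": 0.3, "ICC": 0.4}, "win")] * 5
        with pytest.raises(ValidationError):
            tf.fit_outcome_classifier(data)


class TestChangePoints:
    def test_noiseless_step_found_exactly(self):
        x = np.zeros(100)
        x[50:] = 1.0
        res = tf.detect_change_points(x)
        assert res.change_indices == [50]

    def test_null_false_positive_rate(self):
        fp = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(100)
            fp += bool(tf.detect_change_points(x).change_indices)
        assert fp <= 5

    def test_three_sigma_step_localized(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(100)
            x[50:] += 3.0
            found = tf.detect_change_points(x).change_indices
            hits += any(abs(k - 50) <= 3 for k in found)
        assert hits >= 90

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            tf.detect_change_points(np.zeros(10))


class TestEarlyWarning:
    @staticmethod
    def _series(ssi, tcr):
        table = pd.DataFrame({"t": 5.0 * np.arange(len(ssi)),
                              "SSI": ssi, "TCR": tcr})
        return IndicatorSeries(table=table)

    def test_single_crossing_single_alert(self):
        ssi = [0.2, 0.2, 0.5, 0.5, 0.5]
        tcr = [0.6, 0.6, 0.6, 0.6, 0.6]
        rules = [{"name": "r", "conditions": [
            {"indicator": "SSI", "op": "delta_gt", "threshold": 0.1},
            {"indicator": "TCR", "op": "gt", "threshold": 0.5}]}]
        alerts = tf.early_warning(self._series(ssi, tcr), rules)
        assert len(alerts) == 1
        assert alerts.table["t"].iloc[0] == pytest.approx(10.0)

    def test_empty_rules_no_alerts(self):
        alerts = tf.early_warning(self._series([0.1] * 5, [0.9] * 5), [])
        assert len(alerts) == 0

    def test_unknown_indicator_rejected(self):
        rules = [{"name": "bad", "conditions": [
            {"indicator": "NOPE", "op": "gt", "threshold": 0}]}]
        with pytest.raises(ConfigError, match="NOPE"):
            tf.early_warning(self._series([0.1] * 5, [0.9] * 5), rules)
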