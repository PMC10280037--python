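"""Feature aggregation, probe wrappers and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pulsepair.bayes import HorseshoeConfig
from pulsepair.downstream import (aggregate_patient_features, auc_score,
                                  build_feature_table, evaluate_classifier,
                                  evaluate_regressor, feature_set_columns,
                                  fit_horseshoe_linear, fit_horseshoe_logistic,
                                  youden_threshold, SSL_COLS)
from pulsepair.encoder import build_encoder


def brute_force_auc(scores, labels):
    """All-pairs concordance count, ties worth one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


FAST = HorseshoeConfig(warmup=200, draws=200, seed=0)


class TestAggregation:
    def test_mean_of_two_segments(self):
        z = np.zeros((2, 32))
        z[0, 0], z[1, 0] = 1.0, 3.0
        out = aggregate_patient_features(z, ["a", "a"])
        assert out.loc["a", "ssl_00"] == 2.0
        assert (out.loc["a"].iloc[1:] == 0).all()

    def test_single_segment_identity_and_order_invariance(self, rng):
        z = rng.normal(size=(5, 32))
        pids = ["a", "b", "b", "c", "c"]
        out = aggregate_patient_features(z, pids)
        np.testing.assert_allclose(out.loc["a"], z[0])
        perm = [4, 2, 0, 3, 1]
        out2 = aggregate_patient_features(z[perm], [pids[i] for i in perm])
        pd.testing.assert_frame_equal(out.sort_index(), out2.sort_index())

    def test_feature_table_shape(self, normalized_recordings):
        model = build_encoder("small")
        table = build_feature_table(model, normalized_recordings[:10])
        assert len(table) == 10
        assert set(SSL_COLS) <= set(table.columns)
        assert {"hospitalized", "heart_rate", "clin_weight"} <= set(table.columns)


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score(np.array([0.9, 0.8, 0.1, 0.2]),
                         np.array([1, 1, 0, 0])) == 1.0

    def test_three_of_four_concordant(self):
        s = np.array([0.8, 0.4, 0.6, 0.2])
        y = np.array([1, 1, 0, 0])
        assert auc_score(s, y) == 0.75

    def test_all_ties_give_half(self):
        assert auc_score(np.full(6, 0.3), np.array([1, 1, 0, 0, 0, 1])) == 0.5

    @given(n=st.integers(2, 50), seed=st.integers(0, 999))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_concordance(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            return
        assert auc_score(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    @given(seed=st.integers(0, 200))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            return
        a = auc_score(scores, labels)
        assert auc_score(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert auc_score(3 * scores - 7, labels) == pytest.approx(a, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score(np.array([0.1, 0.2]), np.array([1, 1]))


class TestThresholdAndRegression:
    def test_youden_picks_separating_cut(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        t = youden_threshold(scores, labels)
        m = evaluate_classifier(scores, labels, threshold=t)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0
        assert m["precision"] == 1.0

    def test_threshold_applied_unchanged(self):
        m = evaluate_classifier(np.array([0.4, 0.6]), np.array([0, 1]),
                                threshold=0.5)
        assert m["threshold"] == 0.5

    def test_regression_trivial_cases(self):
        y = np.array([1.0, 2.0, 3.0])
        assert evaluate_regressor(y, y) == {"rmse": 0.0, "r2": 1.0}
        m = evaluate_regressor(np.full(3, y.mean()), y)
        assert m["r2"] == pytest.approx(0.0)

    def test_two_point_hand_computation(self):
        m = evaluate_regressor(np.array([1.0, 1.0]), np.array([0.0, 2.0]))
        assert m["rmse"] == 1.0 and m["r2"] == 0.0

    def test_zero_variance_truth_flagged(self):
        with pytest.warns(UserWarning, match="R2"):
            m = evaluate_regressor(np.array([1.0, 2.0]), np.array([5.0, 5.0]))
        assert np.isnan(m["r2"])


def synthetic_table(rng, n=120, m=10, target="continuous"):
    x = rng.standard_normal((n, m))
    cols = [f"f{i}" for i in range(m)]
    df = pd.DataFrame(x, columns=cols)
    df["patient_id"] = [f"p{i}" for i in range(n)]
    df["split"] = ["train"] * (n - n // 4) + ["test"] * (n // 4)
    return df, cols


class TestProbes:
    def test_linear_probe_near_interpolation(self, rng):
        table, cols = synthetic_table(rng)
        table["heart_rate"] = table["f0"]  # noiseless single-feature target
        fit = fit_horseshoe_linear(table, cols, "heart_rate", FAST)
        test = table["split"] == "test"
        m = evaluate_regressor(fit.scores[test.to_numpy()].to_numpy(),
                               table.loc[test, "heart_rate"].to_numpy())
        assert m["r2"] > 0.99

    def test_no_signal_target_gives_zero_r2(self, rng):
        table, cols = synthetic_table(rng)
        table["spo2"] = 95.0 + rng.normal(0, 1e-3, len(table))
        fit = fit_horseshoe_linear(table, cols, "spo2", FAST)
        test = (table["split"] == "test").to_numpy()
        m = evaluate_regressor(fit.scores[test].to_numpy(),
                               table.loc[test, "spo2"].to_numpy())
        assert abs(m["r2"]) < 0.2

    def test_logistic_null_auc_near_half(self, rng):
        table, cols = synthetic_table(rng, n=500)
        table["hospitalized"] = rng.integers(0, 2, len(table))
        fit = fit_horseshoe_logistic(table, cols, FAST)
        test = (table["split"] == "test").to_numpy()
        y = table["hospitalized"].to_numpy(dtype=float)
        auc = auc_score(fit.scores[test].to_numpy(), y[test])
        n_test = test.sum()
        se = np.sqrt(1 / 12) / np.sqrt(n_test / 4)  # rough AUC SE at null
        assert abs(auc - 0.5) < 3 * se

    def test_seeded_determinism(self, rng):
        table, cols = synthetic_table(rng, n=60, m=4)
        table["hospitalized"] = (table["f0"] > 0).astype(int)
        a = fit_horseshoe_logistic(table, cols, FAST)
        b = fit_horseshoe_logistic(table, cols, FAST)
        np.testing.assert_array_equal(a.scores.to_numpy(), b.scores.to_numpy())

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(ValueError, match="feature set"):
            feature_set_columns("everything")
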