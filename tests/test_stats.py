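"""Metrics, bootstrap CIs and the mixed-effects slope analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import longchange as lc
from longchange import stats


def auc_brute_force(labels, scores):
    """Oracle: count over all positive-negative pairs, half credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_constant_scores_balanced_labels_exactly_half(self):
        labels = np.array([0, 1] * 10)
        assert stats.auc(labels, np.full(20, 0.3)) == 0.5

    def test_perfectly_ordered_scores_give_one(self):
        assert stats.auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_worked_example(self):
        # 4 positive-negative pairs: (.9>.6), (.9>.1), (.4<.6), (.4>.1) -> 3/4
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        assert stats.auc(labels, scores) == 0.75
        assert auc_brute_force(labels, scores) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            stats.auc(np.ones(5), np.arange(5.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 30))
    def test_matches_brute_force_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 201))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.choice(np.linspace(0, 1, 7), n)  # force ties
        assert stats.auc(labels, scores) == pytest.approx(
            auc_brute_force(labels, scores))


class TestBootstrap:
    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 100)
        scores = labels + rng.normal(0, 0.8, 100)
        lo, hi = stats.bootstrap_auc_ci(labels, scores, n_boot=200, seed=1)
        point = stats.auc(labels, scores)
        assert lo <= point <= hi

    def test_ci_width_shrinks_with_test_set_size(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (40, 400):
            labels = rng.integers(0, 2, n)
            scores = labels + rng.normal(0, 1.0, n)
            lo, hi = stats.bootstrap_auc_ci(labels, scores, n_boot=300, seed=3)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_seeded_bootstrap_is_deterministic(self):
        labels = np.array([0, 1] * 20)
        scores = np.arange(40.0)
        assert stats.bootstrap_auc_ci(labels, scores, n_boot=100, seed=7) == \
            stats.bootstrap_auc_ci(labels, scores, n_boot=100, seed=7)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = stats.regression_metrics(y, y)
        assert m.rmse == 0.0 and m.mae == 0.0 and m.r2 == 1.0

    def test_naive_zero_on_symmetric_targets(self):
        m = stats.naive_zero_metrics(np.array([1.0, -1.0]))
        assert m.rmse == 1.0 and m.mae == 1.0

    def test_worked_example(self):
        m = stats.regression_metrics(np.array([0.0, 2.0, 4.0]),
                                     np.array([1.0, 2.0, 3.0]))
        assert m.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert m.mae == pytest.approx(2.0 / 3.0)

    def test_rmse_never_below_mae(self, rng):
        for _ in range(20):
            y = rng.normal(size=30)
            y_hat = rng.normal(size=30)
            m = stats.regression_metrics(y, y_hat)
            assert m.rmse >= m.mae - 1e-12

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="two observations"):
            stats.regression_metrics(np.array([1.0]), np.array([1.0]))


class TestPearson:
    def test_proportional_predictions_give_one(self):
        t = np.arange(10.0)
        r, p = stats.pearson(t, 2.0 * t)
        assert r == pytest.approx(1.0)
        assert p < 1e-8

    def test_anti_proportional_gives_minus_one(self):
        t = np.arange(10.0)
        assert stats.pearson(t, -t)[0] == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        r, _ = stats.pearson(np.array([1.0, 2.0, 3.0]), np.array([1.0, 3.0, 2.0]))
        assert r == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stats.pearson(np.ones(5), np.arange(5.0))

    def test_tiny_pvalues_formatted_with_floor(self):
        assert stats.format_pvalue(1e-20) == "<1e-16"
        assert stats.format_pvalue(0.03) == "0.03"


class TestLme:
    def test_parameter_recovery_within_20pct(self):
        df = lc.simulate_change_table(n_subjects=60, n_timepoints=8, beta=1.0,
                                      gamma=0.4, sigma_b=0.15, sigma_eps=0.3,
                                      rng=1)
        res = lc.lme_fit(df, group=True)
        assert res.fixed_slope == pytest.approx(1.0, rel=0.2)
        assert res.group_effect == pytest.approx(0.4, rel=0.2)
        assert res.converged

    def test_identical_slopes_give_near_zero_variance(self):
        df = lc.simulate_change_table(n_subjects=10, n_timepoints=5, beta=1.0,
                                      sigma_b=0.0, sigma_eps=0.01, rng=2)
        res = lc.lme_fit(df)
        assert res.random_slope_var == pytest.approx(0.0, abs=1e-4)
        assert res.lrt_random_p > 0.3  # no evidence of subject variability

    def test_strong_subject_variability_detected(self):
        df = lc.simulate_change_table(n_subjects=30, n_timepoints=6, beta=1.0,
                                      sigma_b=0.5, sigma_eps=0.2, rng=3)
        res = lc.lme_fit(df)
        assert res.lrt_random_p < 1e-6
        assert res.random_slope_var == pytest.approx(0.25, rel=0.6)

    def test_too_few_subjects_rejected(self):
        df = lc.simulate_change_table(n_subjects=2, n_timepoints=4, rng=0)
        with pytest.raises(ValueError, match="3 subjects"):
            lc.lme_fit(df)

    def test_missing_group_column_rejected(self):
        df = lc.simulate_change_table(n_subjects=6, rng=0).drop(columns="group")
        with pytest.raises(ValueError, match="group"):
            lc.lme_fit(df, group=True)

    def test_invariants_variance_nonnegative_p_in_unit_interval(self):
        df = lc.simulate_change_table(n_subjects=12, n_timepoints=5, rng=4,
                                      gamma=0.2)
        res = lc.lme_fit(df, group=True)
        assert res.random_slope_var >= 0
        assert 0 <= res.lrt_random_p <= 1
        assert 0 <= res.lrt_group_p <= 1

    def test_summary_renders(self):
        df = lc.simulate_change_table(n_subjects=8, rng=5)
        text = lc.lme_fit(df).summary()
        assert "fixed slope" in text
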