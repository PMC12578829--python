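import numpy as np
import pytest

from selnc import survival_prognosis as sp


def simulate_cox_data(rng, n=200, p=10, beta=None, h0=0.1, censor_q=0.7):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
    lp = X @ beta
    T = rng.exponential(1.0 / (h0 * np.exp(lp)))
    C = rng.uniform(0, np.quantile(T, censor_q) * 3, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return X, time, event, lp


class TestKM:
    def test_hand_example_all_events(self):
        km = sp.km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_censoring_hand_example(self):
        # times 1+ 2 3+ 4: events at 2 (risk 3) and 4 (risk 1)
        km = sp.km_estimate([1, 2, 3, 4], [0, 1, 0, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])

    def test_monotone_nonincreasing(self, rng):
        t = rng.exponential(1, 100)
        e = (rng.random(100) < 0.7).astype(int)
        km = sp.km_estimate(t, e)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.survival_at(0.0) <= 1.0

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            sp.km_estimate([1, 2], [0, 0])


class TestLogrank:
    def test_identical_groups(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 1, 1, 1, 1, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, p = sp.logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_summed_hypergeometric(self):
        # 10-sample toy, manual O-E/V computation
        t = np.array([1, 2, 3, 4, 5, 1.5, 2.5, 3.5, 4.5, 5.5])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        o_minus_e, var = 0.0, 0.0
        for tt in sorted(t[e == 1]):
            at = t >= tt
            n, n1 = at.sum(), (at & (g == 1)).sum()
            d = ((t == tt) & (e == 1)).sum()
            d1 = ((t == tt) & (e == 1) & (g == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2, _ = sp.logrank_test(t, e, g)
        assert chi2 == pytest.approx(o_minus_e ** 2 / var)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sp.logrank_test([1, 2], [1, 1], [0, 0])


class TestCoxFit:
    def test_null_data_small_beta(self):
        rng = np.random.default_rng(0)
        X, time, event, _ = simulate_cox_data(rng, n=200, p=3)
        fit = sp.cox_fit(X, time, event)
        assert fit.converged
        assert (np.abs(fit.beta) < 2 * fit.se).all()

    def test_binary_covariate_matches_grid_oracle(self):
        rng = np.random.default_rng(1)
        x = (rng.random(40) < 0.5).astype(float)
        T = rng.exponential(np.exp(-x))
        event = np.ones(40, int)
        fit = sp.cox_fit(x[:, None], T, event)
        grid = np.linspace(-4, 4, 8001)
        lls = [sp.cox_partial_loglik(np.array([b]), x[:, None], T, event)
               for b in grid]
        assert abs(fit.beta[0] - grid[int(np.argmax(lls))]) < 1e-3

    def test_collinear_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        T = rng.exponential(np.exp(-x))
        fit = sp.cox_fit(np.column_stack([x, x]), T, np.ones(80, int))
        assert not fit.converged

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            sp.cox_fit(np.ones((10, 1)), np.arange(1, 11), np.ones(10, int))

    def test_breslow_loglik_at_zero(self):
        # at beta=0 the Breslow partial likelihood has closed form
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1])
        x = np.array([[0.5], [1.0], [-1.0], [2.0]])
        ll = sp.cox_partial_loglik(np.zeros(1), x, time, event)
        assert ll == pytest.approx(-(np.log(4) + np.log(3) + np.log(1)))


class TestScreen:
    def test_planted_features_found(self):
        rng = np.random.default_rng(3)
        beta = np.zeros(55)
        beta[:5] = 1.0
        X, time, event, _ = simulate_cox_data(rng, n=300, p=55, beta=beta)
        screen = sp.univariate_screen(X, time, event, alpha=0.05)
        for i in range(5):
            assert f"f{i}" in screen.significant

    def test_alpha_zero_empty(self):
        rng = np.random.default_rng(4)
        X, time, event, _ = simulate_cox_data(rng, n=100, p=5)
        screen = sp.univariate_screen(X, time, event, alpha=0.0)
        assert screen.significant == []

    def test_constant_feature_skipped(self):
        rng = np.random.default_rng(5)
        X, time, event, _ = simulate_cox_data(rng, n=50, p=3)
        X[:, 1] = 7.0
        screen = sp.univariate_screen(X, time, event)
        assert screen.skipped == ["f1"]
        assert screen.feature_ids == ["f0", "f2"]


class TestLassoPath:
    def test_zero_at_lambda_max(self):
        rng = np.random.default_rng(6)
        beta = np.zeros(10)
        beta[:2] = 1.0
        X, time, event, _ = simulate_cox_data(rng, n=150, p=10, beta=beta)
        path = sp.lasso_cox_path(X, time, event, cv_folds=3)
        assert np.abs(path.beta[:, 0]).max() == 0.0

    def test_l1_norm_monotone(self):
        rng = np.random.default_rng(7)
        beta = np.zeros(8)
        beta[:3] = 0.8
        X, time, event, _ = simulate_cox_data(rng, n=150, p=8, beta=beta)
        path = sp.lasso_cox_path(X, time, event, cv_folds=3)
        norms = np.abs(path.beta).sum(axis=0)
        assert (np.diff(norms) >= -1e-8).all()  # grid descends, norm grows

    def test_small_lambda_matches_newton(self):
        rng = np.random.default_rng(8)
        X, time, event, _ = simulate_cox_data(
            rng, n=80, p=5, beta=[1, -0.5, 0, 0, 0], censor_q=1.0)
        path = sp.lasso_cox_path(X, time, event, cv_folds=3,
                                 lambdas=[0.5, 1e-5, 1e-6, 1e-7])
        fit = sp.cox_fit(X, time, event)
        np.testing.assert_allclose(path.beta[:, -1], fit.beta, atol=1e-4)

    def test_planted_recovery(self):
        rng = np.random.default_rng(9)
        beta = np.zeros(50)
        beta[:5] = 1.0
        X, time, event, _ = simulate_cox_data(rng, n=300, p=50, beta=beta)
        path = sp.lasso_cox_path(X, time, event, rule="1se", seed=0)
        hits = sum(f"f{i}" in path.selected_features for i in range(5))
        assert hits >= 4

    def test_folds_exceed_events(self):
        with pytest.raises(ValueError):
            sp.lasso_cox_path(np.random.default_rng(0).normal(size=(10, 2)),
                              np.arange(1, 11), np.r_[1, np.zeros(9)].astype(int),
                              cv_folds=5)


class TestRSF:
    def test_monotone_hazard_perfect_ranking(self):
        rng = np.random.default_rng(10)
        x = np.sort(rng.normal(size=80))
        time = np.exp(-x) * 10  # deterministic: larger x -> shorter survival
        event = np.ones(80, int)
        model = sp.rsf_fit(x[:, None], time, event, n_trees=100,
                           min_node_events=1, seed=0)
        scores = sp.risk_score(model, x[:, None])
        from sksurv.metrics import concordance_index_censored

        c = concordance_index_censored(event.astype(bool), time, scores)[0]
        # bootstrap resampling keeps the ensemble from being exactly
        # monotone sample-by-sample; ranking is still essentially perfect
        assert c >= 0.97
        from scipy.stats import spearmanr

        assert spearmanr(scores, x)[0] > 0.99

    def test_identical_rows_equal_scores(self):
        X = np.ones((30, 2))
        rng = np.random.default_rng(11)
        time = rng.exponential(1, 30)
        event = np.ones(30, int)
        model = sp.rsf_fit(X, time, event, n_trees=20, seed=0)
        scores = sp.risk_score(model, X)
        assert np.allclose(scores, scores[0])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        X, time, event, _ = simulate_cox_data(rng, n=80, p=3, beta=[1, 0, 0])
        m1 = sp.rsf_fit(X, time, event, n_trees=30, seed=5)
        m2 = sp.rsf_fit(X, time, event, n_trees=30, seed=5)
        np.testing.assert_array_equal(sp.risk_score(m1, X), sp.risk_score(m2, X))

    def test_importance_ranks_signal_first(self):
        rng = np.random.default_rng(13)
        beta = np.array([1.5, 0.0, 0.0])
        X, time, event, _ = simulate_cox_data(rng, n=300, p=3, beta=beta)
        # importance evaluated on held-out data so in-sample overfitting
        # does not inflate the noise features
        Xt, tt, et, _ = simulate_cox_data(rng, n=300, p=3, beta=beta)
        model = sp.rsf_fit(X, time, event, n_trees=100, seed=0)
        imp = sp.feature_importance(model, Xt, tt, et, n_perm=20, seed=0)
        assert imp[0][0] == "f0"
        noise = dict(imp)
        assert abs(noise["f1"]) < 0.02 and abs(noise["f2"]) < 0.02

    def test_nperm_zero_rejected(self):
        rng = np.random.default_rng(14)
        X, time, event, _ = simulate_cox_data(rng, n=50, p=2, beta=[1, 0])
        model = sp.rsf_fit(X, time, event, n_trees=20, seed=0)
        with pytest.raises(ValueError):
            sp.feature_importance(model, X, time, event, n_perm=0)


class TestTimeDependentAUC:
    def test_perfect_scores(self):
        rng = np.random.default_rng(15)
        time = rng.exponential(5, 100)
        event = np.ones(100, int)
        auc = sp.time_dependent_auc(-time, time, event, float(np.median(time)))
        assert auc == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(16)
        time = rng.exponential(5, 500)
        event = (rng.random(500) < 0.8).astype(int)
        scores = rng.normal(size=500)
        auc = sp.time_dependent_auc(scores, time, event, float(np.median(time)))
        assert 0.45 <= auc <= 0.55

    def test_all_ties_half(self):
        rng = np.random.default_rng(17)
        time = rng.exponential(5, 50)
        event = np.ones(50, int)
        auc = sp.time_dependent_auc(np.zeros(50), time, event,
                                    float(np.median(time)))
        assert auc == pytest.approx(0.5)

    def test_errors_name_missing_side(self):
        with pytest.raises(ValueError, match="no cases"):
            sp.time_dependent_auc([1, 2], [10, 20], [1, 1], 5.0)
        with pytest.raises(ValueError, match="no controls"):
            sp.time_dependent_auc([1, 2], [1, 2], [1, 1], 5.0)


class TestRiskGroups:
    def test_planted_effect(self):
        rng = np.random.default_rng(18)
        X, time, event, lp = simulate_cox_data(rng, n=200, p=1, beta=[1.5])
        res = sp.risk_group_analysis(lp, time, event)
        assert res.logrank_p < 0.01
        assert res.score_time_rho < 0

    def test_null_scores_rarely_significant(self):
        rng = np.random.default_rng(19)
        rejections = 0
        for _ in range(40):
            time = rng.exponential(5, 60)
            event = (rng.random(60) < 0.8).astype(int)
            scores = rng.normal(size=60)
            res = sp.risk_group_analysis(scores, time, event)
            rejections += res.logrank_p < 0.05
        assert rejections <= 8  # ~alpha * 40 with slack

    def test_too_small(self):
        with pytest.raises(ValueError):
            sp.risk_group_analysis([1, 2, 3], [1, 2, 3], [1, 1, 1])

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            sp.risk_group_analysis([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1])
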