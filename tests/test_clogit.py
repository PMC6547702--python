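"""Conditional-logistic estimators against closed forms and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from pwas.clogit import (ConditionalLogisticRegression,
                         ConditionalLogisticRegressionCV, SolverConfig,
                         conditional_loglik, cv_select_lambda, fit_l1,
                         fit_unpenalized, lambda_max, univariable_estimate)

from conftest import random_difference_matrix


def single_drug_d(n10, n01):
    return np.array([[1.0]] * n10 + [[-1.0]] * n01)


class TestUnivariable:
    @pytest.mark.parametrize("n10,n01,ratio", [
        (5, 5, 1.0),
        (2195, 1515, 2195 / 1515),   # morphine, Sweden discordant counts
        (256, 42, 256 / 42),
    ])
    def test_closed_form_ratio(self, n10, n01, ratio):
        res = univariable_estimate(n10, n01)
        assert res.rr[0] == pytest.approx(ratio, abs=1e-12)
        se = np.sqrt(1 / n10 + 1 / n01)
        assert res.se[0] == pytest.approx(se, abs=1e-12)

    def test_wald_interval_morphine_antispasmodics_shape(self):
        # (256, 42): RR ~ 6.10, 95% CI ~ (4.40, 8.45); frozen from the
        # closed form log(256/42) +/- 1.96 sqrt(1/256 + 1/42)
        res = univariable_estimate(256, 42)
        assert res.rr[0] == pytest.approx(6.0952, abs=1e-3)
        b, se = np.log(256 / 42), np.sqrt(1 / 256 + 1 / 42)
        assert res.ci_low[0] == pytest.approx(np.exp(b - 1.959964 * se),
                                              rel=1e-9)
        assert res.ci_high[0] == pytest.approx(np.exp(b + 1.959964 * se),
                                               rel=1e-9)
        assert res.ci_low[0] == pytest.approx(4.40, abs=0.005)
        assert res.ci_high[0] == pytest.approx(8.45, abs=0.005)

    def test_wald_ci_matches_brute_force_likelihood(self):
        # the closed-form MLE maximizes the discordant binomial likelihood
        n10, n01 = 256, 42
        grid = np.linspace(-1, 4, 20001)
        ll = n10 * -np.logaddexp(0, -grid) + n01 * -np.logaddexp(0, grid)
        assert grid[np.argmax(ll)] == pytest.approx(np.log(n10 / n01),
                                                    abs=1e-3)

    @pytest.mark.parametrize("n10,n01", [(0, 5), (5, 0)])
    def test_zero_count_flagged_not_raised(self, n10, n01):
        res = univariable_estimate(n10, n01)
        assert res.degenerate[0]
        assert np.isnan(res.se[0])
        assert np.isinf(res.beta[0])
        assert res.beta[0] > 0 if n01 == 0 else res.beta[0] < 0

    def test_no_discordant_pairs_rejected(self):
        with pytest.raises(ValueError):
            univariable_estimate(0, 0)


class TestLoglik:
    def test_zero_beta_is_n_log2(self, rng):
        d = random_difference_matrix(rng, 10, 2)
        assert conditional_loglik(np.zeros(2), d) == pytest.approx(
            -d.shape[0] * np.log(2))

    def test_single_pair_limit(self):
        d = np.array([[1.0]])
        assert conditional_loglik(np.array([30.0]), d) == pytest.approx(
            0.0, abs=1e-12)
        assert conditional_loglik(np.array([30.0]), d) < 0

    def test_matches_per_pair_summation(self, rng):
        d = random_difference_matrix(rng, 25, 4, probs=(0.25, 0.5, 0.25))
        beta = rng.normal(size=4)
        expected = sum(-np.log1p(np.exp(-(beta @ row))) for row in d)
        assert conditional_loglik(beta, d) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conditional_loglik(np.zeros(3), np.ones((4, 2)))


def grid_optimum(d, lam=0.0, span=4.0, coarse=0.1):
    """Exhaustive grid maximization of the (penalized) conditional
    log-likelihood, refined twice around the best coarse point."""
    p = d.shape[1]

    def objective(B):
        z = B @ d.T
        ll = -np.logaddexp(0.0, -z).sum(axis=1)
        return ll - lam * np.abs(B).sum(axis=1)

    axes = [np.arange(-span, span + 1e-9, coarse)] * p
    B = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, p)
    best = B[np.argmax(objective(B))]
    step = coarse
    for _ in range(2):
        step /= 10.0
        axes = [np.arange(b - 12 * step, b + 12 * step + 1e-12, step)
                for b in best]
        B = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, p)
        best = B[np.argmax(objective(B))]
    return best, float(objective(best[None])[0])


class TestUnpenalized:
    def test_single_drug_equals_closed_form(self):
        res = fit_unpenalized(single_drug_d(7, 3))
        assert res.beta[0] == pytest.approx(np.log(7 / 3), abs=1e-6)
        assert res.se[0] == pytest.approx(np.sqrt(1 / 7 + 1 / 3), rel=1e-6)

    def test_block_diagonal_separates_into_univariable_fits(self):
        d = np.zeros((20, 2))
        d[:7, 0], d[7:10, 0] = 1, -1
        d[10:16, 1], d[16:20, 1] = 1, -1
        res = fit_unpenalized(d)
        assert res.beta[0] == pytest.approx(np.log(7 / 3), abs=1e-8)
        assert res.beta[1] == pytest.approx(np.log(6 / 4), abs=1e-8)

    def test_matches_statsmodels_conditional_logit(self, rng):
        from statsmodels.discrete.conditional_models import ConditionalLogit
        d = random_difference_matrix(rng, 60, 3)
        m = d.shape[0]
        # expand each pair into a 2-row stratum: case row with covariates
        # d_i, control row at 0 — the standard conditional-logit encoding
        y = np.r_[np.ones(m), np.zeros(m)]
        X = np.r_[d, np.zeros_like(d)]
        groups = np.r_[np.arange(m), np.arange(m)]
        sm_fit = ConditionalLogit(y, X, groups=groups).fit(disp=0)
        res = fit_unpenalized(d)
        np.testing.assert_allclose(res.beta, sm_fit.params, atol=2e-4)
        np.testing.assert_allclose(res.se, sm_fit.bse, atol=1e-4)
        assert res.loglik == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_matches_exhaustive_grid(self, rng):
        d = random_difference_matrix(rng, 20, 3)
        res = fit_unpenalized(d)
        _, best = grid_optimum(d)
        assert conditional_loglik(res.beta, d) >= best - 1e-4

    def test_separated_column_flagged(self):
        d = np.array([[1.0, 1.0], [1.0, -1.0], [1.0, 1.0], [1.0, -1.0]])
        res = fit_unpenalized(d)
        assert res.degenerate[0] and not res.degenerate[1]
        assert np.isposinf(res.beta[0])
        assert np.isnan(res.se[0]) and np.isnan(res.ci_low[0])
        assert np.isfinite(res.beta[1])


class TestL1:
    def test_zero_penalty_equals_mle(self, rng):
        d = random_difference_matrix(rng, 30, 3)
        np.testing.assert_allclose(fit_l1(d, 0.0).beta,
                                   fit_unpenalized(d).beta, atol=1e-5)

    def test_at_lambda_max_exactly_zero(self, rng):
        d = random_difference_matrix(rng, 30, 3)
        lmax = lambda_max(d)
        assert np.all(fit_l1(d, lmax).beta == 0.0)
        assert np.all(fit_l1(d, 1.5 * lmax).beta == 0.0)
        assert np.count_nonzero(fit_l1(d, 0.97 * lmax).beta) >= 1

    def test_matches_grid_oracle_midpath(self, rng):
        d = random_difference_matrix(rng, 20, 3)
        lam = 0.5 * lambda_max(d)
        res = fit_l1(d, lam)
        ours = conditional_loglik(res.beta, d) - lam * np.abs(res.beta).sum()
        _, best = grid_optimum(d, lam=lam)
        assert ours >= best - 1e-4

    def test_kkt_conditions_at_solution(self, rng):
        d = random_difference_matrix(rng, 40, 4, probs=(0.25, 0.5, 0.25))
        lam = 0.3 * lambda_max(d)
        res = fit_l1(d, lam)
        z = d @ res.beta
        g = d.T @ (1.0 / (1.0 + np.exp(z)))  # gradient of loglik
        for j in range(4):
            if res.beta[j] == 0.0:
                assert abs(g[j]) <= lam + 1e-6
            else:
                assert g[j] == pytest.approx(-lam * np.sign(-res.beta[j]),
                                             abs=1e-6)

    def test_shrinkage_monotone_in_lambda(self, rng):
        d = random_difference_matrix(rng, 40, 4, probs=(0.25, 0.5, 0.25))
        lmax = lambda_max(d)
        norms = [np.abs(fit_l1(d, f * lmax).beta).sum()
                 for f in (0.0, 0.1, 0.3, 0.5, 0.8, 1.0)]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            fit_l1(np.array([[1.0]]), -0.5)


class TestLambdaMax:
    def test_formula(self):
        d = np.zeros((12, 2))
        d[:11, 0], d[11, 0] = 1, -1  # column sums to 10
        assert lambda_max(d) == pytest.approx(5.0)

    def test_balanced_columns_give_zero(self):
        d = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        assert lambda_max(d) == 0.0


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=15, deadline=None)
def test_sign_equivariance(seed):
    """Negating a drug's difference column negates its coefficient."""
    rng = np.random.default_rng(seed)
    d = random_difference_matrix(rng, 25, 3)
    lam = 0.4 * max(lambda_max(d), 0.1)
    flipped = d.copy()
    flipped[:, 1] *= -1
    for fitter in (lambda x: fit_l1(x, lam), fit_unpenalized):
        a, b = fitter(d), fitter(flipped)
        with np.errstate(invalid="ignore"):
            np.testing.assert_allclose(
                np.nan_to_num(b.beta * np.array([1, -1, 1])),
                np.nan_to_num(a.beta), atol=1e-6)


def test_univariable_consistency_single_column():
    """All three routes agree on a single-drug difference matrix."""
    n10, n01 = 13, 8
    d = single_drug_d(n10, n01)
    b_uni = univariable_estimate(n10, n01).beta[0]
    b_mle = fit_unpenalized(d).beta[0]
    b_l1 = fit_l1(d, 0.0).beta[0]
    assert b_mle == pytest.approx(b_uni, abs=1e-6)
    assert b_l1 == pytest.approx(b_uni, abs=1e-6)


class TestCV:
    def test_same_seed_same_lambda(self, rng):
        d = random_difference_matrix(rng, 60, 4, probs=(0.25, 0.5, 0.25))
        cfg = SolverConfig(n_lambda=15, cv_folds=4)
        l1 = cv_select_lambda(d, cfg, random_state=5)
        l2 = cv_select_lambda(d, cfg, random_state=5)
        assert l1 == l2

    def test_strong_signal_opens_model(self):
        # one overwhelming drug: CV must descend below lambda_max
        d = single_drug_d(90, 10)
        cv = ConditionalLogisticRegressionCV(n_lambda=20, cv=5,
                                             random_state=0).fit(d)
        assert cv.lambda_ < lambda_max(d)
        assert cv.coef_[0] != 0.0

    def test_degenerate_path_warns_and_selects_zero(self):
        d = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        with pytest.warns(RuntimeWarning):
            cv = ConditionalLogisticRegressionCV(cv=2).fit(d)
        assert cv.lambda_ == 0.0


class TestEstimatorInterface:
    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone
        est = ConditionalLogisticRegression(penalty="l1", alpha=0.3)
        params = est.get_params()
        assert params["alpha"] == 0.3
        clone(est)  # must be cloneable for model selection

    def test_score_is_mean_heldout_loglik(self, rng):
        d = random_difference_matrix(rng, 30, 2)
        est = ConditionalLogisticRegression().fit(d)
        manual = conditional_loglik(est.coef_, d) / d.shape[0]
        assert est.score(d) == pytest.approx(manual)

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            ConditionalLogisticRegression().fit(np.array([[2.0]]))
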