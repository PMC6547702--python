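"""BOLASSO selection: consensus logic, resampling audit, refit contract."""

import numpy as np
import pytest

from pwas.bolasso import (BolassoSelector, BootstrapSpec, bolasso_select,
                          selection_metrics)
from pwas.clogit import SolverConfig, fit_unpenalized, univariable_estimate
from pwas.exposure import DifferenceMatrix

from conftest import random_difference_matrix

FAST = SolverConfig(n_lambda=12, cv_folds=3)


def named(d, codes=None):
    codes = codes or [f"D{j:02d}" for j in range(d.shape[1])]
    return DifferenceMatrix(patients=np.arange(d.shape[0]),
                            drugs=np.array(codes), d=d)


@pytest.fixture(scope="module")
def signal_noise_D():
    """300 pairs: drug S0 strongly case-skewed, two balanced noise drugs."""
    rng = np.random.default_rng(99)
    d = np.zeros((300, 3))
    d[:150, 0] = rng.choice([1.0, -1.0], 150, p=[0.85, 0.15])
    d[150:, 1] = rng.choice([1.0, -1.0], 150, p=[0.5, 0.5])
    d[::3, 2] = rng.choice([1.0, -1.0], 100, p=[0.5, 0.5])
    d = d[(d != 0).any(axis=1)]
    return named(d, ["S0", "N1", "N2"])


class TestSpecValidation:
    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BootstrapSpec(n_bootstrap=0)
        with pytest.raises(ValueError):
            BootstrapSpec(consensus=0.0)
        with pytest.raises(ValueError):
            BootstrapSpec(lambda_mode="grid")
        with pytest.raises(ValueError):
            BootstrapSpec(lambda_mode=-0.1)


class TestSelection:
    def test_deterministic_given_seed(self, signal_noise_D):
        spec = BootstrapSpec(n_bootstrap=12, consensus=0.8, seed=4)
        r1 = bolasso_select(signal_noise_D, spec, FAST)
        r2 = bolasso_select(signal_noise_D, spec, FAST)
        np.testing.assert_array_equal(r1.frequencies, r2.frequencies)
        np.testing.assert_array_equal(r1.per_bootstrap_lambdas,
                                      r2.per_bootstrap_lambdas)

    def test_strong_signal_always_selected(self, signal_noise_D):
        res = bolasso_select(signal_noise_D,
                             BootstrapSpec(n_bootstrap=20, consensus=1.0,
                                           seed=1), FAST)
        i = list(res.drugs).index("S0")
        assert res.frequencies[i] == 1.0
        assert "S0" in res.selected

    def test_consensus_monotonicity(self, signal_noise_D):
        sels = {}
        for cons in (0.5, 0.8, 1.0):
            res = bolasso_select(signal_noise_D,
                                 BootstrapSpec(n_bootstrap=15, consensus=cons,
                                               seed=2), FAST)
            sels[cons] = set(res.selected.tolist())
        assert sels[1.0] <= sels[0.8] <= sels[0.5]

    def test_strict_consensus_is_exact_intersection(self, signal_noise_D):
        res = bolasso_select(signal_noise_D,
                             BootstrapSpec(n_bootstrap=15, consensus=1.0,
                                           seed=2), FAST)
        assert set(res.selected.tolist()) == {
            c for c, f in zip(res.drugs, res.frequencies) if f == 1.0}

    def test_single_bootstrap_lambda_zero_collapses_to_mle(self):
        rng = np.random.default_rng(5)
        d = random_difference_matrix(rng, 120, 3, probs=(0.3, 0.4, 0.3))
        D = named(d)
        res = bolasso_select(D, BootstrapSpec(n_bootstrap=1, consensus=1.0,
                                              seed=0, lambda_mode=0.0), FAST)
        # all non-degenerate drugs selected; refit on original data = MLE
        assert set(res.selected.tolist()) == set(res.drugs.tolist())
        np.testing.assert_allclose(res.refit.beta, fit_unpenalized(d).beta,
                                   atol=1e-8)

    def test_refit_of_sole_selected_drug_is_univariable(self, signal_noise_D):
        res = bolasso_select(signal_noise_D,
                             BootstrapSpec(n_bootstrap=20, consensus=1.0,
                                           seed=1), FAST)
        if list(res.selected) != ["S0"]:
            pytest.skip("noise drug entered the strict intersection")
        col = signal_noise_D.d[:, 0]
        n10, n01 = int((col == 1).sum()), int((col == -1).sum())
        uni = univariable_estimate(n10, n01)
        assert res.refit.beta[0] == pytest.approx(uni.beta[0], abs=1e-6)

    def test_resampling_unit_is_the_whole_pair(self):
        # a dataset with a single repeated pattern resamples to itself,
        # so every bootstrap sees the same data: frequency is 0 or 1
        d = np.tile([[1.0, -1.0]], (40, 1))
        res = bolasso_select(named(d), BootstrapSpec(n_bootstrap=10,
                                                     consensus=1.0, seed=3),
                             FAST)
        assert set(np.unique(res.frequencies)) <= {0.0, 1.0}

    def test_empty_selection_is_valid_result(self):
        # balanced noise only: strict intersection should be empty
        rng = np.random.default_rng(17)
        d = np.zeros((200, 2))
        d[:100, 0] = rng.choice([1.0, -1.0], 100)
        d[100:, 1] = rng.choice([1.0, -1.0], 100)
        res = bolasso_select(named(d), BootstrapSpec(n_bootstrap=25,
                                                     consensus=1.0, seed=6),
                             FAST)
        if len(res.selected) == 0:
            assert res.refit is None
        assert res.frequencies.shape == (2,)


class TestSelectorEstimator:
    def test_transform_keeps_selected_columns(self, signal_noise_D):
        sel = BolassoSelector(n_bootstrap=15, consensus=1.0, random_state=1,
                              solver=FAST).fit(signal_noise_D)
        kept = sel.transform(signal_noise_D.d)
        assert kept.shape == (signal_noise_D.d.shape[0],
                              int(sel.support_.sum()))

    def test_get_support_matches_frequencies(self, signal_noise_D):
        sel = BolassoSelector(n_bootstrap=10, consensus=0.7, random_state=2,
                              solver=FAST).fit(signal_noise_D)
        np.testing.assert_array_equal(sel.get_support(),
                                      sel.frequencies_ >= 0.7 - 1e-12)


class TestMetrics:
    def test_perfect_selection(self):
        res = _result(selected=["A", "B"], drugs=["A", "B", "C"])
        m = selection_metrics(res, {"A": 2.0, "B": 1.5, "C": 1.0})
        assert m["sensitivity"] == 1.0
        assert m["false_positive_count"] == 0

    def test_empty_selection_zero_sensitivity(self):
        res = _result(selected=[], drugs=["A", "B", "C"])
        m = selection_metrics(res, {c: 2.0 for c in "ABC"})
        assert m["sensitivity"] == 0.0

    def test_uncovered_drug_rejected(self):
        res = _result(selected=[], drugs=["A", "Z"])
        with pytest.raises(ValueError):
            selection_metrics(res, {"A": 1.0})


def _result(selected, drugs):
    from pwas.bolasso import SelectionResult
    return SelectionResult(
        drugs=np.array(drugs),
        frequencies=np.array([1.0 if c in selected else 0.0 for c in drugs]),
        selected=np.array(selected, dtype=object),
        refit=None, per_bootstrap_lambdas=np.zeros(1))
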