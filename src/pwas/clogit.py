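"""Conditional logistic regression for 1:1 case-crossover pairs.

The 1:1 matched conditional likelihood reduces to a no-intercept logistic
model on the within-pair exposure differences ``d_i = case_i - control_i``
(entries in {-1, 0, 1}).  For a coefficient vector ``beta`` (log rate
ratios) the conditional log-likelihood is

    l(beta) = sum_i w_i * log sigma(beta' d_i)
            = -sum_i w_i * log(1 + exp(-beta' d_i)),

where ``sigma`` is the logistic function and the optional weights ``w_i``
carry bootstrap multiplicities.  This module provides

* the exact likelihood and its Newton MLE with observed-information
  standard errors (:class:`ConditionalLogisticRegression` with
  ``penalty=None`` / :func:`fit_unpenalized`),
* an L1-penalized solver (proximal Newton with an inner cyclic coordinate
  descent on the local quadratic model) maximizing
  ``l(beta) - lam * ||beta||_1`` (``penalty='l1'`` / :func:`fit_l1`),
* the penalty-path anchor :func:`lambda_max` and cross-validated penalty
  choice by held-out conditional log-likelihood
  (:class:`ConditionalLogisticRegressionCV` / :func:`cv_select_lambda`),
* the closed-form discordant-pair estimator :func:`univariable_estimate`
  (``RR = n10 / n01``).

Covariates are same-scale binary differences, so no standardization is
applied before penalization and no covariate is exempt from the penalty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "FitResult",
    "ConditionalLogisticRegression",
    "ConditionalLogisticRegressionCV",
    "conditional_loglik",
    "univariable_estimate",
    "fit_unpenalized",
    "fit_l1",
    "lambda_max",
    "cv_select_lambda",
]


@dataclass
class SolverConfig:
    """Numerical settings for the conditional-logistic solvers.

    ``tol`` is the convergence tolerance on the maximum coefficient change,
    ``z_level`` the normal quantile used for 95% Wald intervals.
    """

    tol: float = 1e-8
    max_iter: int = 10_000
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 5
    z_level: float = 1.959964
    cv_tol: float = 1e-5  # looser tolerance for CV path scoring fits

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class FitResult:
    """Coefficients on the log-RR scale plus Wald CIs on the ratio scale.

    ``degenerate`` flags drugs whose MLE is not finite (single-signed
    difference column: all case-only or all control-only discordance);
    their ``beta`` is +/-inf with no CI.
    """

    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    lam: float
    converged: bool
    iterations: int
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    drugs: Optional[np.ndarray] = None

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.beta)


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------


def _as_diff_array(D) -> np.ndarray:
    """Accept a DifferenceMatrix-like object or a plain array."""
    d = getattr(D, "d", D)
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2:
        raise ValueError("difference matrix must be 2-D (pairs x drugs)")
    return d


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -z)


def conditional_loglik(beta, D, sample_weight=None) -> float:
    """Exact 1:1 conditional log-likelihood ``sum_i w_i log sigma(beta'd_i)``.

    At ``beta = 0`` this equals ``-n log 2`` for ``n`` (weighted) pairs.
    """
    d = _as_diff_array(D)
    beta = np.asarray(beta, dtype=np.float64)
    if beta.shape != (d.shape[1],):
        raise ValueError(
            f"beta has length {beta.shape}, expected ({d.shape[1]},)"
        )
    w = np.ones(d.shape[0]) if sample_weight is None else np.asarray(sample_weight, float)
    return float(w @ _log_sigmoid(d @ beta))


def _degenerate_columns(d: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Columns whose weighted nonzero entries are single-signed (or absent).

    Such columns have no finite conditional MLE (complete separation of the
    pair differences): the likelihood increases monotonically in |beta_j|.
    """
    active = w > 0
    pos = ((d > 0) & active[:, None]).any(axis=0)
    neg = ((d < 0) & active[:, None]).any(axis=0)
    return ~(pos & neg)


def lambda_max(D, sample_weight=None) -> float:
    """Smallest L1 penalty whose solution is identically zero.

    Equals ``max_j |0.5 * sum_i w_i d_ij|``, the gradient magnitude of the
    conditional log-likelihood at the origin.
    """
    d = _as_diff_array(D)
    if d.size == 0:
        raise ValueError("empty difference matrix")
    w = np.ones(d.shape[0]) if sample_weight is None else np.asarray(sample_weight, float)
    return float(np.max(np.abs(0.5 * (w @ d)))) if d.shape[1] else 0.0


# ---------------------------------------------------------------------------
# solvers (internal, weighted)
# ---------------------------------------------------------------------------


def _newton_mle(d, w, tol, max_iter):
    """Newton maximization of the weighted conditional log-likelihood.

    Returns (beta, cov, loglik, converged, iters).  Caller must have removed
    degenerate columns.
    """
    n, p = d.shape
    beta = np.zeros(p)
    ll = float(w @ _log_sigmoid(d @ beta))
    cov = np.full((p, p), np.nan)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = d @ beta
        mu = expit(z)
        g = d.T @ (w * (1.0 - mu))
        wt = w * mu * (1.0 - mu)
        H = (d * wt[:, None]).T @ d
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # backtracking keeps the ascent monotone far from the optimum
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            ll_new = float(w @ _log_sigmoid(d @ cand))
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        delta = np.max(np.abs(t * step)) if p else 0.0
        ll = ll_new
        if delta < tol or np.max(np.abs(g), initial=0.0) < tol:
            converged = True
            break
    z = d @ beta
    mu = expit(z)
    wt = w * mu * (1.0 - mu)
    H = (d * wt[:, None]).T @ d
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, ll, converged, it


def _soft(u: float, lam: float) -> float:
    if u > lam:
        return u - lam
    if u < -lam:
        return u + lam
    return 0.0


def _l1_objective(beta, d, w, lam):
    return -float(w @ _log_sigmoid(d @ beta)) + lam * float(np.abs(beta).sum())


def _majorizer(d, w):
    """Global curvature bound ``0.25 * d' diag(w) d`` for the logistic loss.

    Since ``mu (1 - mu) <= 1/4`` everywhere, this matrix dominates the
    Hessian of ``-l`` in the PSD order, so the quadratic surrogate built
    from it majorizes the loss and every surrogate minimization step
    decreases the true objective (no line search needed).  With |beta'd|
    small — the regime of sparse log rate ratios — the bound is nearly
    tight and convergence is close to Newton.
    """
    return 0.25 * (d * w[:, None]).T @ d


@njit(cache=False)
def _mm_l1_core(d, w, lam, beta0, H, Hdiag, tol, max_iter, inner_tol):
    """Compiled majorization-minimization loop for the L1 objective."""
    m, p = d.shape
    beta = beta0.copy()
    z = np.dot(d, beta)

    def _wll(zv):  # weighted sum of log sigma(z), numerically stable
        s = 0.0
        for i in range(zv.shape[0]):
            if zv[i] > 0.0:
                s += -w[i] * np.log1p(np.exp(-zv[i]))
            else:
                s += w[i] * (zv[i] - np.log1p(np.exp(zv[i])))
        return s

    obj = -_wll(z) + lam * np.abs(beta).sum()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # gradient of the log-likelihood: d' (w * (1 - sigma(z)))
        r = np.empty(m)
        for i in range(m):
            if z[i] > 0.0:
                e = np.exp(-z[i])
                r[i] = w[i] * e / (1.0 + e)
            else:
                r[i] = w[i] / (1.0 + np.exp(z[i]))
        g = np.dot(d.T, r)
        bn = beta.copy()
        q = -g  # gradient of the smooth surrogate at bn
        for _ in range(1000):
            max_delta = 0.0
            for j in range(p):
                u = Hdiag[j] * bn[j] - q[j]
                if u > lam:
                    new = (u - lam) / Hdiag[j]
                elif u < -lam:
                    new = (u + lam) / Hdiag[j]
                else:
                    new = 0.0
                dlt = new - bn[j]
                if dlt != 0.0:
                    q = q + H[:, j] * dlt
                    bn[j] = new
                    if abs(dlt) > max_delta:
                        max_delta = abs(dlt)
            if max_delta < inner_tol:
                break
        delta = 0.0
        for j in range(p):
            if abs(bn[j] - beta[j]) > delta:
                delta = abs(bn[j] - beta[j])
        if delta == 0.0:
            converged = True
            break
        z_new = z + np.dot(d, bn - beta)
        obj_new = -_wll(z_new) + lam * np.abs(bn).sum()
        if obj_new > obj + 1e-10:  # safeguard; majorization forbids this
            converged = True
            break
        beta, z, obj = bn, z_new, obj_new
        if delta < tol:
            converged = True
            break
    return beta, converged, it


def _prox_newton_l1(d, w, lam, beta0, tol, max_iter, H=None):
    """Minimize ``-l(beta) + lam ||beta||_1``.

    Majorization-minimization with the fixed curvature bound from
    :func:`_majorizer`: each outer step solves the lasso-penalized
    quadratic surrogate at the current gradient exactly by cyclic
    coordinate descent (soft-thresholding), which yields exact zeros, so
    the support is well defined.  ``H`` may be precomputed once and shared
    across a penalty path or CV fold (it depends only on ``d`` and ``w``).
    """
    d = np.ascontiguousarray(d, dtype=np.float64)
    w = np.ascontiguousarray(w, dtype=np.float64)
    if H is None:
        H = _majorizer(d, w)
    H = np.ascontiguousarray(H)
    Hdiag = np.clip(np.diag(H).copy(), 1e-10, None)
    inner_tol = max(tol * 0.1, 1e-13)
    beta, converged, it = _mm_l1_core(
        d, w, float(lam), np.ascontiguousarray(beta0, dtype=np.float64),
        H, Hdiag, float(tol), int(max_iter), float(inner_tol))
    beta = np.where(np.abs(beta) < 1e-12, 0.0, beta)
    ll = float(w @ _log_sigmoid(d @ beta))
    return beta, ll, converged, it


def _path_lambdas(lmax: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    """Geometric penalty path, descending from lambda_max."""
    if lmax <= 0:
        return np.zeros(1)
    return lmax * np.exp(
        np.linspace(0.0, np.log(min_ratio), n_lambda)
    )


def _cv_lambda_weighted(d, fold_weights, lambdas, tol, max_iter):
    """Mean held-out conditional log-likelihood over a penalty path.

    ``fold_weights`` is a (k, n) array of nonnegative pair multiplicities;
    fold k trains on the sum of the other folds and scores on its own.
    Returns the per-lambda mean held-out log-likelihood (per held-out pair).
    """
    k = fold_weights.shape[0]
    total = fold_weights.sum(axis=0)
    held = np.zeros((k, len(lambdas)))
    held_n = np.zeros(k)
    for f in range(k):
        w_tr = total - fold_weights[f]
        w_te = fold_weights[f]
        held_n[f] = w_te.sum()
        if held_n[f] == 0 or w_tr.sum() == 0:
            held[f] = np.nan
            continue
        H = _majorizer(d, w_tr)
        beta = np.zeros(d.shape[1])
        for li, lam in enumerate(lambdas):
            beta, _, _, _ = _prox_newton_l1(d, w_tr, lam, beta, tol,
                                            max_iter, H=H)
            held[f, li] = float(w_te @ _log_sigmoid(d @ beta))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_ll = np.nansum(held, axis=0) / held_n.sum()
    return mean_ll


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class ConditionalLogisticRegression(BaseEstimator):
    """1:1 conditional logistic regression on pair-difference matrices.

    Parameters
    ----------
    penalty : None or 'l1'
        ``None`` fits the unpenalized conditional MLE (Newton, with
        observed-information standard errors); ``'l1'`` maximizes the
        lasso-penalized conditional likelihood at penalty ``alpha``.
    alpha : float
        L1 penalty weight (``lambda``); ignored when ``penalty is None``.
    tol, max_iter : solver controls (max coefficient change / iterations).
    z_level : normal quantile for 95% Wald intervals.

    Attributes
    ----------
    coef_ : (p,) log rate ratios (``+/-inf`` for degenerate columns).
    se_, ci_low_, ci_high_ : Wald SEs (log scale) and 95% CI bounds on the
        ratio scale; ``nan`` for penalized fits and degenerate columns.
    degenerate_ : boolean mask of separated (single-signed) columns.
    loglik_ : conditional log-likelihood at ``coef_``.
    converged_, n_iter_ : solver diagnostics.
    """

    def __init__(self, penalty=None, alpha=0.0, tol=1e-8, max_iter=10_000,
                 z_level=1.959964):
        self.penalty = penalty
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.z_level = z_level

    def _validate(self, X, sample_weight):
        d = _as_diff_array(X)
        if not np.isin(d, (-1.0, 0.0, 1.0)).all():
            raise ValueError("difference matrix entries must be in {-1, 0, 1}")
        w = (np.ones(d.shape[0]) if sample_weight is None
             else np.asarray(sample_weight, float))
        if w.shape != (d.shape[0],) or (w < 0).any():
            raise ValueError("sample_weight must be nonnegative, one per pair")
        return d, w

    def fit(self, X, y=None, sample_weight=None):
        if self.penalty not in (None, "none", "l1"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if self.penalty == "l1" and self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        d, w = self._validate(X, sample_weight)
        p = d.shape[1]
        degen = _degenerate_columns(d, w)
        beta = np.zeros(p)
        se = np.full(p, np.nan)
        if self.penalty == "l1" and self.alpha > 0:
            # penalty keeps the optimum finite; degenerate flag still reported
            b, ll, conv, it = _prox_newton_l1(
                d, w, float(self.alpha), np.zeros(p), self.tol, self.max_iter)
            beta = b
            if not conv:
                warnings.warn("L1 solver did not converge", RuntimeWarning)
        else:
            keep = ~degen
            if keep.any():
                b, cov, ll, conv, it = _newton_mle(
                    d[:, keep], w, self.tol, self.max_iter)
                beta[keep] = b
                se[keep] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
                if not conv:
                    warnings.warn("Newton solver did not converge",
                                  RuntimeWarning)
            else:
                ll, conv, it = float(w @ _log_sigmoid(d @ beta)), True, 0
            # direction of divergence for separated columns
            col_sign = np.sign((w @ d))
            beta[degen & (col_sign > 0)] = np.inf
            beta[degen & (col_sign < 0)] = -np.inf
            beta[degen & (col_sign == 0)] = 0.0
            ll = float(w @ _log_sigmoid(np.nan_to_num(d @ np.where(
                np.isfinite(beta), beta, 0.0))))
        self.coef_ = beta
        self.se_ = se
        with np.errstate(invalid="ignore", over="ignore"):
            self.ci_low_ = np.exp(beta - self.z_level * se)
            self.ci_high_ = np.exp(beta + self.z_level * se)
        self.degenerate_ = degen
        self.lambda_ = float(self.alpha) if self.penalty == "l1" else 0.0
        self.loglik_ = ll
        self.converged_ = bool(conv)
        self.n_iter_ = int(it)
        self.n_features_in_ = p
        return self

    def decision_function(self, X):
        d = _as_diff_array(X)
        beta = np.where(np.isfinite(self.coef_), self.coef_, 0.0)
        return d @ beta

    def score(self, X, y=None, sample_weight=None):
        """Mean per-pair held-out conditional log-likelihood."""
        d, w = self._validate(X, sample_weight)
        beta = np.where(np.isfinite(self.coef_), self.coef_, 0.0)
        return float(w @ _log_sigmoid(d @ beta)) / max(w.sum(), 1.0)

    def result(self, drugs=None) -> FitResult:
        """Package fitted attributes as a :class:`FitResult`."""
        return FitResult(
            beta=self.coef_, se=self.se_, ci_low=self.ci_low_,
            ci_high=self.ci_high_, loglik=self.loglik_, lam=self.lambda_,
            converged=self.converged_, iterations=self.n_iter_,
            degenerate=self.degenerate_,
            drugs=None if drugs is None else np.asarray(drugs))


class ConditionalLogisticRegressionCV(BaseEstimator):
    """L1 conditional logistic regression with cross-validated penalty.

    Builds a geometric penalty path from ``lambda_max`` down to
    ``lambda_min_ratio * lambda_max`` and picks the penalty maximizing the
    mean held-out conditional log-likelihood over ``cv`` pair folds; ties
    break toward the larger (sparser) penalty.  Refits at the chosen
    penalty on all pairs.
    """

    def __init__(self, n_lambda=100, lambda_min_ratio=1e-3, cv=5,
                 tol=1e-8, max_iter=10_000, random_state=None):
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        d = _as_diff_array(X)
        n = d.shape[0]
        if n < self.cv:
            raise ValueError("need at least cv pairs")
        lmax = lambda_max(d)
        if lmax <= 0:
            warnings.warn("lambda path degenerate (lambda_max = 0); "
                          "selecting 0", RuntimeWarning)
            self.lambda_ = 0.0
            self.lambdas_ = np.zeros(1)
            self.cv_loglik_ = np.zeros(1)
        else:
            lambdas = _path_lambdas(lmax, self.n_lambda, self.lambda_min_ratio)
            folds = np.zeros((self.cv, n))
            kf = KFold(n_splits=self.cv, shuffle=True,
                       random_state=self.random_state)
            for f, (_, test_idx) in enumerate(kf.split(d)):
                folds[f, test_idx] = 1.0
            mean_ll = _cv_lambda_weighted(d, folds, lambdas,
                                          max(self.tol, 1e-5), self.max_iter)
            best = int(np.argmax(mean_ll))  # lambdas descend: first max wins
            self.lambda_ = float(lambdas[best])
            self.lambdas_ = lambdas
            self.cv_loglik_ = mean_ll
        est = ConditionalLogisticRegression(
            penalty="l1", alpha=self.lambda_, tol=self.tol,
            max_iter=self.max_iter).fit(d)
        self.coef_ = est.coef_
        self.loglik_ = est.loglik_
        self.converged_ = est.converged_
        self.n_iter_ = est.n_iter_
        self.n_features_in_ = d.shape[1]
        return self

    def score(self, X, y=None, sample_weight=None):
        est = ConditionalLogisticRegression()
        est.coef_ = self.coef_
        return est.score(X, y, sample_weight)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def univariable_estimate(n10, n01=None, config: SolverConfig | None = None
                         ) -> FitResult:
    """Closed-form 1:1 discordant-pair estimator ``RR = n10 / n01``.

    ``n10`` may be a DiscordantCounts-like object with ``n10``/``n01``
    attributes, or the two counts may be given positionally.  Zero counts
    yield a flagged infinite/zero estimate with no Wald CI rather than an
    exception.
    """
    if n01 is None:
        n10, n01 = n10.n10, n10.n01
    if n10 < 0 or n01 < 0:
        raise ValueError("counts must be nonnegative")
    if n10 + n01 == 0:
        raise ValueError("no discordant pairs")
    config = config or SolverConfig()
    degenerate = (n10 == 0) or (n01 == 0)
    if degenerate:
        beta = np.inf if n01 == 0 else -np.inf
        se = ci_low = ci_high = np.nan
        ll = 0.0
    else:
        beta = float(np.log(n10 / n01))
        se = float(np.sqrt(1.0 / n10 + 1.0 / n01))
        ci_low = float(np.exp(beta - config.z_level * se))
        ci_high = float(np.exp(beta + config.z_level * se))
        # binomial log-likelihood of the discordant split at the MLE
        pr = n10 / (n10 + n01)
        ll = float(n10 * np.log(pr) + n01 * np.log(1 - pr))
    return FitResult(
        beta=np.array([beta]), se=np.array([se]),
        ci_low=np.array([ci_low]), ci_high=np.array([ci_high]),
        loglik=ll, lam=0.0, converged=True, iterations=0,
        degenerate=np.array([degenerate]))


def fit_unpenalized(D, config: SolverConfig | None = None,
                    sample_weight=None) -> FitResult:
    """Unpenalized conditional MLE with observed-information Wald CIs."""
    config = config or SolverConfig()
    est = ConditionalLogisticRegression(
        penalty=None, tol=config.tol, max_iter=config.max_iter,
        z_level=config.z_level).fit(D, sample_weight=sample_weight)
    return est.result(drugs=getattr(D, "drugs", None))


def fit_l1(D, lam: float, config: SolverConfig | None = None,
           sample_weight=None) -> FitResult:
    """L1-penalized conditional logistic fit at penalty ``lam``."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    config = config or SolverConfig()
    est = ConditionalLogisticRegression(
        penalty="l1" if lam > 0 else None, alpha=lam, tol=config.tol,
        max_iter=config.max_iter, z_level=config.z_level
    ).fit(D, sample_weight=sample_weight)
    return est.result(drugs=getattr(D, "drugs", None))


def cv_select_lambda(D, config: SolverConfig | None = None,
                     random_state=None) -> float:
    """Cross-validated penalty choice (held-out conditional log-likelihood)."""
    config = config or SolverConfig()
    cvest = ConditionalLogisticRegressionCV(
        n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        cv=config.cv_folds, tol=config.tol, max_iter=config.max_iter,
        random_state=random_state).fit(D)
    return cvest.lambda_
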