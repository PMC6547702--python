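"""Bootstrap-enhanced LASSO (BOLASSO) selection over case-crossover pairs.

The lasso alone is not model-selection consistent: over repeated samples
it drags in varying noise variables.  BOLASSO draws bootstrap samples of
the independent sampling units — here the informative case/control pairs —
fits the L1-penalized conditional logistic model on each, and keeps the
drugs whose coefficient is nonzero in (nearly) all bootstraps: the strict
intersection of supports, or a softer consensus fraction.  The kept drugs
are then jointly refit *without* penalty on the original data, so the
reported rate ratios are mutually adjusted and free of shrinkage bias.

Internally the pair rows are collapsed to unique difference patterns with
multiplicity weights; a bootstrap resample is then a multinomial redraw of
the pattern weights, which makes a full 1000-bootstrap run cheap even for
thousands of pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .clogit import (
    FitResult,
    SolverConfig,
    _cv_lambda_weighted,
    _degenerate_columns,
    _path_lambdas,
    _prox_newton_l1,
    fit_unpenalized,
    lambda_max,
    _as_diff_array,
)

logger = logging.getLogger(__name__)

__all__ = ["BootstrapSpec", "SelectionResult", "BolassoSelector",
           "bolasso_select", "selection_metrics", "write_selection_report"]


@dataclass
class BootstrapSpec:
    """Bootstrap plan for BOLASSO.

    ``consensus`` is the minimum fraction of bootstraps in which a drug
    must be selected: 1.0 is the strict intersection of supports, 0.9 the
    soft variant.  ``lambda_mode`` is ``"per_bootstrap_cv"`` (cross-validated
    penalty inside each bootstrap) or a fixed nonnegative penalty value.
    """

    n_bootstrap: int = 1000
    consensus: float = 1.0
    seed: int = 0
    lambda_mode: Union[str, float] = "per_bootstrap_cv"

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 < self.consensus <= 1.0:
            raise ValueError("consensus must be in (0, 1]")
        if isinstance(self.lambda_mode, str):
            if self.lambda_mode != "per_bootstrap_cv":
                raise ValueError("lambda_mode must be 'per_bootstrap_cv' "
                                 "or a fixed penalty value")
        elif self.lambda_mode < 0:
            raise ValueError("fixed lambda must be >= 0")


@dataclass
class SelectionResult:
    """BOLASSO output: frequencies, consensus set, unpenalized refit."""

    drugs: np.ndarray
    frequencies: np.ndarray
    selected: np.ndarray          # drug codes with frequency >= consensus
    refit: Optional[FitResult]    # joint MLE on the selected columns
    per_bootstrap_lambdas: np.ndarray

    @property
    def selected_mask(self) -> np.ndarray:
        sel = set(self.selected.tolist())
        return np.array([c in sel for c in self.drugs])


def _collapse_patterns(d: np.ndarray):
    """Unique difference patterns and their multiplicities."""
    patterns, inverse, counts = np.unique(
        d, axis=0, return_inverse=True, return_counts=True)
    return patterns.astype(np.float64), counts.astype(np.float64), inverse


class BolassoSelector(SelectorMixin, BaseEstimator):
    """Feature selector running BOLASSO on a pair-difference matrix.

    Parameters mirror :class:`BootstrapSpec`; ``solver`` bundles the
    L1/CV settings.  After ``fit``:

    frequencies_ : fraction of bootstraps selecting each drug.
    support_ : boolean consensus mask (``get_support()``/``transform`` use it).
    refit_ : unpenalized joint :class:`~pwas.clogit.FitResult` of the
        selected drugs on the *original* (unresampled) pairs.
    per_bootstrap_lambdas_ : penalty used in each bootstrap.

    One master seed spawns independent per-bootstrap substreams, so
    enlarging ``n_bootstrap`` extends — never reshuffles — earlier streams.
    """

    def __init__(self, n_bootstrap=1000, consensus=1.0,
                 lambda_mode="per_bootstrap_cv", random_state=0,
                 solver: Optional[SolverConfig] = None):
        self.n_bootstrap = n_bootstrap
        self.consensus = consensus
        self.lambda_mode = lambda_mode
        self.random_state = random_state
        self.solver = solver

    def fit(self, X, y=None):
        spec = BootstrapSpec(n_bootstrap=self.n_bootstrap,
                             consensus=self.consensus,
                             seed=self.random_state,
                             lambda_mode=self.lambda_mode)
        solver = self.solver or SolverConfig()
        d = _as_diff_array(X)
        if d.size == 0:
            raise ValueError("empty difference matrix")
        n, p = d.shape
        patterns, counts, _ = _collapse_patterns(d)
        probs = counts / counts.sum()

        seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_bootstrap)
        support_counts = np.zeros(p)
        lambdas_used = np.zeros(spec.n_bootstrap)
        lambda_grid = None
        for b in range(spec.n_bootstrap):
            rng = np.random.default_rng(seeds[b])
            w = rng.multinomial(n, probs).astype(np.float64)
            keep = ~_degenerate_columns(patterns, w)
            if not keep.any():
                continue
            sub = patterns[:, keep]
            if isinstance(spec.lambda_mode, str):
                lam_b = self._cv_lambda(sub, w, solver, rng)
            else:
                lam_b = float(spec.lambda_mode)
            lambdas_used[b] = lam_b
            beta, _, conv, _ = _prox_newton_l1(
                sub, w, lam_b, np.zeros(keep.sum()), solver.tol,
                solver.max_iter)
            if not conv:
                logger.warning("bootstrap %d: L1 solver not converged", b)
            nz = np.flatnonzero(keep)[beta != 0.0]
            support_counts[nz] += 1

        frequencies = support_counts / spec.n_bootstrap
        support = frequencies >= spec.consensus - 1e-12
        self.frequencies_ = frequencies
        self.support_ = support
        self.per_bootstrap_lambdas_ = lambdas_used
        self.n_features_in_ = p
        self.drugs_ = np.asarray(getattr(X, "drugs",
                                         np.arange(p).astype(str)))
        if support.any():
            self.refit_ = fit_unpenalized(d[:, support], solver)
            self.refit_.drugs = self.drugs_[support]
        else:
            self.refit_ = None
        return self

    @staticmethod
    def _cv_lambda(patterns, w, solver: SolverConfig,
                   rng: np.random.Generator) -> float:
        lmax = lambda_max(patterns, sample_weight=w)
        if lmax <= 0:
            return 0.0
        lambdas = _path_lambdas(lmax, solver.n_lambda,
                                solver.lambda_min_ratio)
        k = solver.cv_folds
        # multinomial thinning of pattern weights == random fold assignment
        # of the resampled pairs
        folds = np.stack([
            rng.multinomial(int(wi), [1.0 / k] * k) for wi in w
        ], axis=1).astype(np.float64)
        mean_ll = _cv_lambda_weighted(patterns, folds, lambdas,
                                      max(solver.tol, solver.cv_tol),
                                      solver.max_iter)
        return float(lambdas[int(np.argmax(mean_ll))])

    def _get_support_mask(self):
        return self.support_


def bolasso_select(D, spec: Optional[BootstrapSpec] = None,
                   solver: Optional[SolverConfig] = None) -> SelectionResult:
    """Run BOLASSO and return a :class:`SelectionResult`."""
    spec = spec or BootstrapSpec()
    est = BolassoSelector(n_bootstrap=spec.n_bootstrap,
                          consensus=spec.consensus,
                          lambda_mode=spec.lambda_mode,
                          random_state=spec.seed,
                          solver=solver).fit(D)
    return SelectionResult(
        drugs=est.drugs_, frequencies=est.frequencies_,
        selected=est.drugs_[est.support_], refit=est.refit_,
        per_bootstrap_lambdas=est.per_bootstrap_lambdas_)


def selection_metrics(result: SelectionResult,
                      truth: Dict[str, float]) -> dict:
    """Evaluate a selection against a planted-truth map.

    sensitivity = selected truly-nonnull / truly-nonnull;
    mean_signed_bias = mean of (refit log-RR - true log-RR) over truly
    nonnull selected drugs (nan when none).
    """
    missing = [c for c in result.drugs if c not in truth]
    if missing:
        raise ValueError(f"truth map does not cover drugs {missing[:5]}")
    nonnull = {c for c, rr in truth.items() if rr != 1.0}
    selected = set(result.selected.tolist())
    tp = selected & nonnull
    sensitivity = len(tp) / len(nonnull) if nonnull else float("nan")
    false_positive_count = len(selected - nonnull)
    bias = float("nan")
    if tp and result.refit is not None:
        diffs = []
        for i, code in enumerate(result.refit.drugs):
            if code in tp and np.isfinite(result.refit.beta[i]):
                diffs.append(result.refit.beta[i] - np.log(truth[code]))
        if diffs:
            bias = float(np.mean(diffs))
    return {"sensitivity": sensitivity,
            "false_positive_count": false_positive_count,
            "mean_signed_bias": bias}


def write_selection_report(result: SelectionResult, path) -> None:
    """Tab-separated report: frequency, selected flag, refit RR and CI."""
    sel_mask = result.selected_mask
    rr = np.full(len(result.drugs), np.nan)
    lo = np.full(len(result.drugs), np.nan)
    hi = np.full(len(result.drugs), np.nan)
    if result.refit is not None:
        pos = {c: i for i, c in enumerate(result.refit.drugs)}
        for i, code in enumerate(result.drugs):
            if code in pos:
                j = pos[code]
                rr[i] = np.exp(result.refit.beta[j])
                lo[i] = result.refit.ci_low[j]
                hi[i] = result.refit.ci_high[j]
    pd.DataFrame({
        "drug_code": result.drugs,
        "frequency": result.frequencies,
        "selected": sel_mask.astype(int),
        "rr": rr, "ci_low": lo, "ci_high": hi,
    }).to_csv(path, sep="\t", index=False)
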