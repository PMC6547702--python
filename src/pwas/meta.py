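"""Cross-country combination of drug effect estimates.

Fixed-effect (inverse-variance) meta-analysis on the log rate-ratio
scale: with per-country estimates ``b_c`` and standard errors ``se_c``,
weights are ``w_c = 1 / se_c**2``, the combined estimate is
``sum(w_c b_c) / sum(w_c)`` with standard error ``(sum w_c)**-0.5``.
Ratio-scale I/O is converted at the boundary only, and standard errors
can be reconstructed from printed 95% confidence intervals via
``se = (ln U - ln L) / (2 z)``, which makes published tables directly
re-combinable.  Heterogeneity (Cochran's Q, I^2) is computed and logged
but never gates combination.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Set

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CountryEstimate", "MetaEstimate", "se_from_ci", "fixed_effect",
           "common_hits", "heterogeneity", "country_estimate_from_ci",
           "Z95"]

Z95 = 1.959964


@dataclass(frozen=True)
class CountryEstimate:
    """One country's log rate ratio and standard error for one drug."""

    drug_code: str
    log_rr: float
    se: float
    country_label: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass(frozen=True)
class MetaEstimate:
    """Inverse-variance combined estimate with 95% CI on the ratio scale."""

    drug_code: str
    log_rr: float
    se: float
    rr: float
    ci_low: float
    ci_high: float


def se_from_ci(ci_low: float, ci_high: float, z_level: float = Z95) -> float:
    """Log-scale SE implied by a ratio-scale CI: ``(ln U - ln L) / (2 z)``.

    Exact algebraic inverse of the Wald interval, so
    ``exp(log_rr +/- z * se_from_ci(L, U))`` reproduces (L, U).
    """
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("CI bounds must be positive")
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z_level)
    if se == 0.0:
        warnings.warn("degenerate CI (zero width) gives zero SE",
                      RuntimeWarning)
    return se


def country_estimate_from_ci(drug_code: str, rr: float, ci_low: float,
                             ci_high: float, country_label: str = "",
                             z_level: float = Z95) -> CountryEstimate:
    """Build a :class:`CountryEstimate` from a printed RR and 95% CI."""
    if rr <= 0:
        raise ValueError("rr must be positive")
    return CountryEstimate(drug_code=drug_code, log_rr=math.log(rr),
                           se=se_from_ci(ci_low, ci_high, z_level),
                           country_label=country_label)


def fixed_effect(estimates: Sequence[CountryEstimate],
                 z_level: float = Z95) -> MetaEstimate:
    """Inverse-variance fixed-effect combination on the log-RR scale."""
    if not estimates:
        raise ValueError("need at least one estimate")
    codes = {e.drug_code for e in estimates}
    if len(codes) != 1:
        raise ValueError(f"mixed drug codes in combination: {sorted(codes)}")
    w = np.array([1.0 / e.se**2 for e in estimates])
    b = np.array([e.log_rr for e in estimates])
    log_rr = float(w @ b / w.sum())
    se = float(w.sum() ** -0.5)
    if len(estimates) > 1:
        q, i2 = heterogeneity(estimates)
        logger.info("%s: Q=%.3f I2=%.1f%% over %d strata",
                    next(iter(codes)), q, 100 * i2, len(estimates))
    return MetaEstimate(
        drug_code=next(iter(codes)), log_rr=log_rr, se=se,
        rr=math.exp(log_rr),
        ci_low=math.exp(log_rr - z_level * se),
        ci_high=math.exp(log_rr + z_level * se))


def heterogeneity(estimates: Sequence[CountryEstimate]) -> tuple:
    """Cochran's Q and I^2 (diagnostic only)."""
    w = np.array([1.0 / e.se**2 for e in estimates])
    b = np.array([e.log_rr for e in estimates])
    pooled = w @ b / w.sum()
    q = float(w @ (b - pooled) ** 2)
    df = len(estimates) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, i2


def common_hits(selections: Sequence) -> Set[str]:
    """Intersection of per-country selected drug sets.

    Accepts :class:`~pwas.bolasso.SelectionResult` objects or plain
    iterables of drug codes.
    """
    if len(selections) < 2:
        raise ValueError("need selections from at least two countries")
    sets = []
    for sel in selections:
        codes = getattr(sel, "selected", sel)
        sets.append({str(c) for c in codes})
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out
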