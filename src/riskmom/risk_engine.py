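"""Posterior risk of prostate cancer from age and a marker MoM panel.

The screening variable is a man's risk of prostate cancer over a horizon:
posterior odds = prior odds (from an age-incidence table) x likelihood
ratio (affected / unaffected multivariate Gaussian density of the
truncated log10 MoM panel).  A screen-positive result is a risk at or
above the chosen cut-off.  Truncating the marker values before the
density evaluation caps the attainable likelihood ratio, so extreme
values cannot drive the risk arbitrarily high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import multivariate_normal

from .distribution_params import GroupParams

__all__ = [
    "IncidencePrior",
    "RiskAssessment",
    "likelihood_ratio",
    "prior_risk",
    "posterior_risk",
    "classify",
    "assess",
]


@dataclass(frozen=True)
class IncidencePrior:
    """Age-specific annual incidence table plus a screening horizon.

    ``ages``/``rates`` tabulate annual incidence (events per person-year);
    rates at intermediate ages are linearly interpolated, and ages beyond
    the table clamp to the nearest tabulated rate (with a warning).

    ``method``: "sum" adds the annual rates over the horizon; the
    "exp-cumulative" alternative returns 1 - exp(-sum).  Annual rates are
    small, so the two differ negligibly.
    """

    ages: np.ndarray
    rates: np.ndarray
    horizon: float = 5.0
    method: str = "sum"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if ages.ndim != 1 or ages.shape != rates.shape or len(ages) < 2:
            raise ValueError("ages and rates must be matching 1-D arrays, length >= 2")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(rates < 0):
            raise ValueError("negative incidence rate in table")
        if not np.all(np.isfinite(rates)):
            raise ValueError("non-finite incidence rate in table")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0 years")
        if self.method not in ("sum", "exp-cumulative"):
            raise ValueError(f"unknown method {self.method!r}")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)

    def annual_rate(self, age) -> np.ndarray:
        """Interpolated annual incidence at ``age`` (clamped at the ends)."""
        return np.interp(np.asarray(age, dtype=float), self.ages, self.rates)


def prior_risk(age, prior: IncidencePrior) -> np.ndarray | float:
    """Prior probability of prostate cancer in [age, age + horizon).

    Sums the (interpolated) annual rate at ages age, age+1, ..., covering
    the horizon; a fractional final year contributes proportionally.
    """
    age = np.asarray(age, dtype=float)
    scalar = age.ndim == 0
    age = np.atleast_1d(age)
    if np.any(age < prior.ages[0]) or np.any(age + prior.horizon - 1 > prior.ages[-1]):
        warnings.warn(
            "age (+ horizon) outside the incidence table; clamping to nearest "
            "tabulated rate",
            stacklevel=2,
        )
    whole = int(np.floor(prior.horizon))
    frac = prior.horizon - whole
    total = np.zeros_like(age)
    for k in range(whole):
        total += prior.annual_rate(age + k)
    if frac > 0:
        total += frac * prior.annual_rate(age + whole)
    if prior.method == "exp-cumulative":
        risk = 1.0 - np.exp(-total)
    else:
        risk = np.minimum(total, 1.0 - 1e-12)
    return float(risk[0]) if scalar else risk


def _truncate_log_mom(log_mom: np.ndarray, params: GroupParams) -> np.ndarray:
    return np.clip(log_mom, np.log10(params.trunc_lo), np.log10(params.trunc_hi))


def likelihood_ratio(
    mom_vector: Sequence[float] | np.ndarray,
    affected: GroupParams,
    unaffected: GroupParams,
) -> float | np.ndarray:
    """Affected:unaffected density ratio of the truncated log10 MoM panel.

    Both densities are evaluated at the same clipped point; the clipping
    limits are the unaffected set's truncation limits (shared by both
    groups), so the LR is constant for inputs beyond them.

    ``mom_vector`` may be a single panel (length k) or an (n, k) batch.
    """
    if affected.markers != unaffected.markers:
        raise ValueError(
            f"marker mismatch: affected {affected.markers} vs "
            f"unaffected {unaffected.markers}"
        )
    mom = np.asarray(mom_vector, dtype=float)
    if np.any(mom <= 0):
        raise ValueError("MoM values must be strictly positive")
    single = mom.ndim == 1
    mom = np.atleast_2d(mom)
    if mom.shape[1] != len(unaffected.markers):
        raise ValueError(
            f"expected {len(unaffected.markers)} markers, got {mom.shape[1]}"
        )
    x = _truncate_log_mom(np.log10(mom), unaffected)
    log_num = multivariate_normal.logpdf(x, mean=affected.mean, cov=affected.cov)
    log_den = multivariate_normal.logpdf(x, mean=unaffected.mean, cov=unaffected.cov)
    lr = np.exp(np.atleast_1d(log_num) - np.atleast_1d(log_den))
    return float(lr[0]) if single else lr


def posterior_risk(prior, lr) -> float | np.ndarray:
    """risk = prior*lr / (1 - prior + prior*lr)  (posterior odds = prior odds x LR)."""
    prior = np.asarray(prior, dtype=float)
    lr = np.asarray(lr, dtype=float)
    if np.any(prior < 0) or np.any(prior >= 1):
        raise ValueError("prior must be in [0, 1)")
    if np.any(lr <= 0):
        raise ValueError("likelihood ratio must be > 0")
    risk = prior * lr / (1.0 - prior + prior * lr)
    return float(risk) if risk.ndim == 0 else risk


def classify(risk: float, cutoff: float) -> str:
    """"screen positive" iff risk >= cutoff (ties positive)."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    return "screen positive" if risk >= cutoff else "screen negative"


def risk_display(risk: float) -> str:
    """Format a probability as "1 in N", N rounded to the nearest integer."""
    if risk <= 0:
        return "less than 1 in 1000000"
    return f"1 in {max(1, round(1.0 / risk))}"


@dataclass(frozen=True)
class RiskAssessment:
    """One man's risk computation, from MoM panel to classification."""

    markers: tuple[str, ...]
    moms: tuple[float, ...]
    truncated_log_moms: tuple[float, ...]
    likelihood_ratio: float
    prior: float
    risk: float
    cutoff: float
    horizon: float
    age: float

    @property
    def risk_display(self) -> str:
        return risk_display(self.risk)

    @property
    def cutoff_display(self) -> str:
        return risk_display(self.cutoff)

    @property
    def classification(self) -> str:
        return classify(self.risk, self.cutoff)


def assess(
    moms: Sequence[float],
    age: float,
    affected: GroupParams,
    unaffected: GroupParams,
    prior: IncidencePrior,
    cutoff: float,
) -> RiskAssessment:
    """Full assessment: prior from age, LR from the panel, posterior risk."""
    moms = tuple(float(m) for m in moms)
    lr = likelihood_ratio(np.asarray(moms), affected, unaffected)
    p = prior_risk(age, prior)
    risk = posterior_risk(p, lr)
    x = _truncate_log_mom(np.log10(np.asarray(moms)), unaffected)
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    return RiskAssessment(
        markers=unaffected.markers,
        moms=moms,
        truncated_log_moms=tuple(float(v) for v in x),
        likelihood_ratio=float(lr),
        prior=float(p),
        risk=float(risk),
        cutoff=float(cutoff),
        horizon=float(prior.horizon),
        age=float(age),
    )
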