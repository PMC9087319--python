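"""Age-specific median curves and multiple-of-the-median (MoM) conversion.

A marker concentration is standardised for age by dividing it by the median
concentration of unaffected men of the same age.  Medians are modelled as
log-linear or log-quadratic functions of age, fitted by ordinary least
squares on log10 concentrations: under the log-Gaussian assumption the
fitted mean of the logs equals the log of the median, so the regression
prediction is the log10 median.  MoM values additionally cancel assay,
laboratory and sample-storage effects, because those act multiplicatively
on cases and controls alike.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MedianCurve",
    "BmiCurve",
    "MomResult",
    "fit_median_curve",
    "to_mom",
    "fit_bmi_curve",
    "adjust_for_bmi",
]


class DegenerateFitError(ValueError):
    """Raised when a regression has too few points or no variation."""


@dataclass(frozen=True)
class MedianCurve:
    """Regression of log10 median concentration (ng/ml) on age (years).

    predicted median(age) = 10**(b0 + b1*age + b2*age**2); ``b2 == 0``
    for a log-linear curve.  ``quad_p`` is the nested-model p-value for
    the quadratic term (None when the curve was fitted as linear).
    """

    marker: str
    b0: float
    b1: float
    b2: float = 0.0
    age_range: tuple[float, float] = (40.0, 75.0)
    quad_p: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must be increasing, got {self.age_range}")
        ages = np.linspace(lo, hi, 64)
        pred = self.log10_median(ages)
        if not np.all(np.isfinite(pred)):
            raise ValueError("median curve is not finite over its age range")

    def log10_median(self, age):
        age = np.asarray(age, dtype=float)
        return self.b0 + self.b1 * age + self.b2 * age**2

    def median(self, age):
        """Predicted median concentration in ng/ml at ``age``."""
        return 10.0 ** self.log10_median(age)

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "b0": self.b0,
            "b1": self.b1,
            "b2": self.b2,
            "age_range": list(self.age_range),
            "quad_p": self.quad_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MedianCurve":
        return cls(
            marker=d["marker"],
            b0=float(d["b0"]),
            b1=float(d["b1"]),
            b2=float(d.get("b2", 0.0)),
            age_range=tuple(d.get("age_range", (40.0, 75.0))),
            quad_p=d.get("quad_p"),
        )


@dataclass(frozen=True)
class MomResult:
    """A MoM value plus an extrapolation flag.

    Behaves like a float in arithmetic.  ``extrapolated`` is True when the
    age fell outside the curve's fitted range (permitted — screening ages
    may exceed the cohort's — but flagged).
    """

    value: float
    extrapolated: bool = False

    def __float__(self) -> float:
        return self.value


def fit_median_curve(
    pairs: Sequence[tuple[float, float]],
    marker: str = "marker",
    form: Literal["linear", "quadratic", "auto"] = "auto",
    alpha: float = 0.05,
) -> MedianCurve:
    """Fit the age trend of the median concentration on unaffected men.

    Parameters
    ----------
    pairs : sequence of (age years, concentration ng/ml)
    form : "linear", "quadratic", or "auto" — in auto mode the quadratic
        term is kept iff its partial F-test p-value is below ``alpha``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (age, concentration)")
    ages, conc = arr[:, 0], arr[:, 1]
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    n = len(ages)
    if n < 10:
        raise DegenerateFitError(f"need >= 10 (age, concentration) pairs, got {n}")
    y = np.log10(conc)

    def _ols(X):
        coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise DegenerateFitError("design matrix is rank deficient")
        rss = float(np.sum((y - X @ coef) ** 2))
        return coef, rss

    X_lin = np.column_stack([np.ones(n), ages])
    X_quad = np.column_stack([np.ones(n), ages, ages**2])

    quad_p: float | None = None
    if form == "linear":
        coef, _ = _ols(X_lin)
        b0, b1, b2 = coef[0], coef[1], 0.0
    elif form == "quadratic":
        coef, _ = _ols(X_quad)
        b0, b1, b2 = coef
    elif form == "auto":
        _, rss_lin = _ols(X_lin)
        coef_q, rss_quad = _ols(X_quad)
        df_resid = n - 3
        if df_resid <= 0:
            raise DegenerateFitError("too few points for the quadratic comparison")
        if rss_quad <= 0:
            quad_p = 0.0  # exact quadratic interpolation
        else:
            f = (rss_lin - rss_quad) / (rss_quad / df_resid)
            quad_p = float(stats.f.sf(max(f, 0.0), 1, df_resid))
        if quad_p < alpha:
            b0, b1, b2 = coef_q
        else:
            coef, _ = _ols(X_lin)
            b0, b1, b2 = coef[0], coef[1], 0.0
    else:
        raise ValueError(f"unknown form {form!r}")

    return MedianCurve(
        marker=marker,
        b0=float(b0),
        b1=float(b1),
        b2=float(b2),
        age_range=(float(ages.min()), float(ages.max())),
        quad_p=quad_p,
    )


def to_mom(concentration: float, age: float, curve: MedianCurve) -> MomResult:
    """Convert a concentration (ng/ml) to a multiple of the median.

    MoM = concentration / predicted median(age).  Ages outside the curve's
    fitted range extrapolate with a warning flag rather than an error.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    lo, hi = curve.age_range
    extrapolated = not (lo <= age <= hi)
    if extrapolated:
        warnings.warn(
            f"age {age} outside fitted range {curve.age_range} for "
            f"{curve.marker}; extrapolating median",
            stacklevel=2,
        )
    mom = float(concentration) / float(curve.median(age))
    return MomResult(value=mom, extrapolated=extrapolated)


def to_mom_array(
    concentrations: np.ndarray, ages: np.ndarray, curve: MedianCurve
) -> np.ndarray:
    """Vectorised MoM conversion (no extrapolation flagging)."""
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations[np.isfinite(concentrations)] <= 0):
        raise ValueError("concentrations must be strictly positive")
    return concentrations / curve.median(np.asarray(ages, dtype=float))


# ---------------------------------------------------------------------------
# BMI adjustment

@dataclass(frozen=True)
class BmiCurve:
    """Log-linear association of MoM with body-mass index.

    ``slope`` is the change in log10 MoM per kg/m^2; ``reference_bmi`` is
    the BMI at which the adjustment is the multiplicative identity.
    """

    marker: str
    slope: float
    reference_bmi: float


def fit_bmi_curve(
    pairs: Sequence[tuple[float, float]],
    marker: str = "marker",
    reference_bmi: float | None = None,
) -> BmiCurve:
    """Fit log10 MoM on BMI; ``pairs`` are (BMI kg/m^2, log10 MoM).

    The reference BMI defaults to the sample median, so the adjustment is
    neutral for a typical man.
    """
    arr = np.asarray(pairs, dtype=float)
    bmi, logmom = arr[:, 0], arr[:, 1]
    if np.any((bmi < 10) | (bmi > 80)):
        raise ValueError("BMI values outside the physiologic range 10-80")
    if np.ptp(bmi) == 0:
        raise DegenerateFitError("all BMI values identical; slope not estimable")
    slope, _ = np.polyfit(bmi, logmom, 1)
    ref = float(np.median(bmi)) if reference_bmi is None else float(reference_bmi)
    return BmiCurve(marker=marker, slope=float(slope), reference_bmi=ref)


def adjust_for_bmi(mom: float, bmi: float, curve: BmiCurve) -> float:
    """Adjusted MoM = mom / 10**(slope * (bmi - reference_bmi))."""
    mom = float(mom)
    if mom <= 0:
        raise ValueError("MoM must be > 0")
    return mom / 10.0 ** (curve.slope * (bmi - curve.reference_bmi))
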