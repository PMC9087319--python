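"""Synthetic reference parameter set and study-condition defaults.

No individual-level data ship with this package, so the defaults below are
a *synthetic* reference set constructed to have the published summary
structure of a nested case-control cohort of stored sera: unaffected
median MoM of 1 for every marker; affected median MoMs that are high
shortly before death/registration and decline with follow-up (total PSA
14.4 at 0-5 years falling to 1.4 at 20+ years); PSA forms highly
correlated with each other and weakly with hK2; MSP carrying no
discrimination; and a national-statistics-style age-incidence curve
peaking near age 80.  They let every pipeline stage run end-to-end and
define the conditions under which the test suite and the reproduction
script operate.  They are illustrative, not measured assay parameters.
"""

from __future__ import annotations

import numpy as np

from .distribution_params import GroupParams
from .median_model import MedianCurve
from .risk_engine import IncidencePrior

MARKERS = ("total_psa", "free_psa", "intact_psa", "hk2", "msp")

# Unaffected median concentration (ng/ml) at the cohort median age of 54.
MEDIAN_AT_54 = {
    "total_psa": 0.90,
    "free_psa": 0.18,
    "intact_psa": 0.10,
    "hk2": 0.029,
    "msp": 27.8,
}

# Follow-up bands (years between sampling and death/registration) and the
# probability a case falls in each; the long tail reflects sera stored for
# decades before the outcome.
FOLLOWUP_BANDS = ("0-5", "6-9", "10-14", "15-19", "20+")
BAND_PROBS = np.array([0.021, 0.060, 0.13, 0.24, 0.55])
BAND_PROBS = BAND_PROBS / BAND_PROBS.sum()
BAND_EDGES = {"0-5": (0.0, 5.0), "6-9": (6.0, 9.0), "10-14": (10.0, 14.0),
              "15-19": (15.0, 19.0), "20+": (20.0, 30.0)}

# Affected median total-PSA MoM per band: high close to the event and
# declining with follow-up.
BAND_MEDIAN_TOTAL_PSA = {"0-5": 14.4, "6-9": 3.7, "10-14": 2.4,
                         "15-19": 1.7, "20+": 1.4}

# Affected median MoM at 0-5 years per marker; other bands scale each
# marker log-proportionally to the total-PSA decline.
AFFECTED_MEDIAN_5Y = {
    "total_psa": 14.4,
    "free_psa": 6.0,
    "intact_psa": 7.2,
    "hk2": 3.2,
    "msp": 1.0,   # no discrimination
}


def band_median_mom(marker: str, band: str) -> float:
    """Affected median MoM of ``marker`` in follow-up ``band``.

    log10 median scales with the band's total-PSA decline:
    log10 m(band) = log10 m(0-5) * log10 T(band) / log10 T(0-5).
    MSP stays at 1 in every band.
    """
    m5 = AFFECTED_MEDIAN_5Y[marker]
    if m5 == 1.0:
        return 1.0
    frac = np.log10(BAND_MEDIAN_TOTAL_PSA[band]) / np.log10(BAND_MEDIAN_TOTAL_PSA["0-5"])
    return float(10.0 ** (np.log10(m5) * frac))


# log10 MoM standard deviations.
UNAFFECTED_SD = np.array([0.33, 0.31, 0.33, 0.28, 0.21])
AFFECTED_SD_5Y = np.array([0.41, 0.43, 0.42, 0.35, 0.21])
AFFECTED_SD_10Y = np.array([0.46, 0.47, 0.46, 0.38, 0.23])
AFFECTED_SD_ALL = np.array([0.45, 0.42, 0.43, 0.36, 0.22])

# Shared correlation structure: the three PSA forms move nearly together,
# hK2 is only weakly related to them (which is why it adds information),
# MSP nearly independent of everything.
CORR = np.array([
    [1.00, 0.90, 0.92, 0.30, 0.10],
    [0.90, 1.00, 0.88, 0.32, 0.10],
    [0.92, 0.88, 1.00, 0.30, 0.10],
    [0.30, 0.32, 0.30, 1.00, 0.15],
    [0.10, 0.10, 0.10, 0.15, 1.00],
])

_Z99 = 2.3263478740408408  # norm.ppf(0.99)


def _trunc_limits(sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # 1st/99th percentiles of the unaffected fitted distribution, shared
    # by both groups.
    return 10.0 ** (-_Z99 * sd), 10.0 ** (_Z99 * sd)


def default_unaffected(followup_window: str = "all") -> GroupParams:
    lo, hi = _trunc_limits(UNAFFECTED_SD)
    return GroupParams(
        group="unaffected",
        followup_window=followup_window,
        markers=MARKERS,
        mean=np.zeros(5),
        sd=UNAFFECTED_SD,
        corr=CORR,
        trunc_lo=lo,
        trunc_hi=hi,
    )


_AFF_MEAN = {
    # log10 of the affected median MoMs per follow-up window.
    "<=5y": np.log10([14.4, 6.0, 7.2, 3.2, 1.0]),
    "<10y": np.log10([4.2, 2.2, 2.4, 1.95, 1.0]),
    "all": np.log10([1.68, 1.28, 1.27, 1.26, 1.0]),
}
_AFF_SD = {"<=5y": AFFECTED_SD_5Y, "<10y": AFFECTED_SD_10Y, "all": AFFECTED_SD_ALL}


def default_affected(followup_window: str = "<=5y") -> GroupParams:
    if followup_window not in _AFF_MEAN:
        raise ValueError(f"no default affected parameters for {followup_window!r}")
    lo, hi = _trunc_limits(UNAFFECTED_SD)
    return GroupParams(
        group="affected",
        followup_window=followup_window,
        markers=MARKERS,
        mean=_AFF_MEAN[followup_window],
        sd=_AFF_SD[followup_window],
        corr=CORR,
        trunc_lo=lo,
        trunc_hi=hi,
    )


def default_median_curves() -> dict[str, MedianCurve]:
    """Synthetic age-median curves anchored at the age-54 medians.

    The PSA forms rise log-quadratically with age; hK2 and MSP rise
    log-linearly (MSP only gently).
    """
    curves = {}
    quad = {"total_psa": (0.013, 2e-4), "free_psa": (0.012, 1.8e-4),
            "intact_psa": (0.012, 1.8e-4)}
    lin = {"hk2": 0.009, "msp": 0.003}
    for m, (slope54, b2) in quad.items():
        b1 = slope54 - 2 * b2 * 54.0
        b0 = np.log10(MEDIAN_AT_54[m]) - b1 * 54.0 - b2 * 54.0**2
        curves[m] = MedianCurve(marker=m, b0=float(b0), b1=float(b1), b2=float(b2),
                                age_range=(40.0, 75.0), quad_p=0.005)
    for m, b1 in lin.items():
        b0 = np.log10(MEDIAN_AT_54[m]) - b1 * 54.0
        curves[m] = MedianCurve(marker=m, b0=float(b0), b1=float(b1), b2=0.0,
                                age_range=(40.0, 75.0), quad_p=None)
    return curves


# National-statistics-style annual prostate-cancer incidence (events per
# person-year), rising steeply with age.  Synthetic but of the magnitude
# seen in UK registry data.
INCIDENCE_AGES = np.array([40, 45, 50, 55, 60, 65, 70, 75, 80, 85], dtype=float)
INCIDENCE_RATES = np.array([0.00003, 0.0001, 0.0004, 0.0012, 0.0028,
                            0.0048, 0.0065, 0.0075, 0.0078, 0.0072])


def default_incidence(horizon: float = 5.0, method: str = "sum") -> IncidencePrior:
    return IncidencePrior(ages=INCIDENCE_AGES, rates=INCIDENCE_RATES,
                          horizon=horizon, method=method)


# Screened population: uniform weights over ages 55-74 (screening from 55,
# trial-like upper bound).
SCREEN_AGES = np.arange(55, 75, dtype=float)
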