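"""Descriptive statistics for marker MoM values.

Medians with distribution-free (order-statistic) confidence intervals,
two-group rank-sum comparisons, and median-MoM-by-follow-up summaries.
Rank-based methods are used throughout because marker distributions are
strongly right-skewed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MedianEstimate", "median_with_ci", "compare_groups", "mom_by_followup"]


@dataclass(frozen=True)
class MedianEstimate:
    n: int
    median: float
    ci_lo: float | None   # None when n < 6 (CI not defined)
    ci_hi: float | None

    @property
    def ci_available(self) -> bool:
        return self.ci_lo is not None


def median_with_ci(sample, coverage: float = 0.95) -> MedianEstimate:
    """Sample median with a binomial order-statistic confidence interval.

    The CI bounds are the order statistics x_(l) and x_(u) with l chosen
    so that P(Binomial(n, 1/2) < l) <= (1 - coverage)/2; guaranteed
    distribution-free coverage of at least ``coverage``.  For n < 6 no
    95% interval exists and the bounds are flagged unavailable.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    x = x[np.isfinite(x)]
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    if n < 6:
        return MedianEstimate(n=n, median=med, ci_lo=None, ci_hi=None)
    tail = (1.0 - coverage) / 2.0
    # largest l with P(B < l) <= tail, i.e. P(B <= l-1) <= tail
    l = int(stats.binom.ppf(tail, n, 0.5))
    if stats.binom.cdf(l, n, 0.5) > tail:
        l = max(l - 1, 0)
    lo_idx = l            # 0-based index of order statistic x_(l+1)
    hi_idx = n - 1 - l
    return MedianEstimate(n=n, median=med, ci_lo=float(x[lo_idx]),
                          ci_hi=float(x[hi_idx]))


def compare_groups(sample_a, sample_b) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value comparing two groups.

    Exact enumeration when the smaller group has <= 8 observations and
    there are no ties; normal approximation with continuity correction
    otherwise.  Completely tied data give p = 1 with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return 1.0
    method = "exact" if min(len(a), len(b)) <= 8 else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=True)
    except ValueError:
        # exact method refuses ties; fall back to the approximation
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(min(res.pvalue, 1.0))


def mom_by_followup(
    moms: pd.DataFrame,
    markers: list[str] | None = None,
    band_order: tuple[str, ...] = ("0-5", "6-9", "10-14", "15-19", "20+"),
) -> pd.DataFrame:
    """Median MoM (with CI) per follow-up band, marker and group.

    ``moms`` needs ``status`` and ``followup_band`` columns plus one MoM
    column per marker.  Affected medians are expected to decline with
    follow-up; a ``non_monotone`` flag marks (diagnostically, not as an
    error) markers whose affected band medians rise somewhere.
    """
    df = moms.copy()
    df["group"] = np.where(df["status"].astype(str).str.startswith("affected"),
                           "affected", "unaffected")
    if markers is None:
        markers = [c for c in df.columns
                   if c not in ("status", "followup_band", "group")
                   and np.issubdtype(df[c].dtype, np.number)]
    rows = []
    for (group, band), sub in df.groupby(["group", "followup_band"]):
        for m in markers:
            vals = sub[m].dropna()
            if len(vals) == 0:
                continue
            est = median_with_ci(vals)
            rows.append({"group": group, "followup_band": band, "marker": m,
                         "n": est.n, "median": est.median,
                         "ci_lo": est.ci_lo, "ci_hi": est.ci_hi})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    order = {b: i for i, b in enumerate(band_order)}
    out["band_rank"] = out["followup_band"].map(order)
    out = out.sort_values(["marker", "group", "band_rank"]).drop(columns="band_rank")
    out["non_monotone"] = False
    for m in markers:
        sel = (out["marker"] == m) & (out["group"] == "affected")
        med = out.loc[sel, "median"].to_numpy()
        if len(med) >= 2 and np.any(np.diff(med) > 0):
            out.loc[sel, "non_monotone"] = True
    return out.reset_index(drop=True)
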