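"""Glue between cohort tables and the model-fitting stages.

These helpers run the standard analysis path on a cohort DataFrame:
fit age-median curves on unaffected men, convert concentrations to MoM,
estimate per-group distribution parameters for a follow-up window, and
compute every subject's posterior risk.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distribution_params import GroupParams, estimate_group_params
from .median_model import MedianCurve, fit_median_curve, to_mom_array
from .risk_engine import IncidencePrior, likelihood_ratio, posterior_risk, prior_risk

__all__ = ["fit_cohort_medians", "cohort_moms", "estimate_cohort_params",
           "cohort_risks", "WINDOW_BANDS"]

# Follow-up windows over which group parameters are estimated, and the
# follow-up bands each one covers.
WINDOW_BANDS = {
    "<=5y": ("0-5",),
    "<10y": ("0-5", "6-9"),
    "all": ("0-5", "6-9", "10-14", "15-19", "20+"),
}


def _is_affected(status: pd.Series) -> pd.Series:
    return status.astype(str).str.startswith("affected")


def fit_cohort_medians(
    cohort: pd.DataFrame,
    markers: Sequence[str],
    form: str = "auto",
    alpha: float = 0.05,
) -> dict[str, MedianCurve]:
    """Fit each marker's age-median curve on the unaffected men."""
    unaff = cohort[~_is_affected(cohort["status"])]
    curves = {}
    for m in markers:
        sub = unaff[["age_at_sample", m]].dropna()
        sub = sub[sub[m] > 0]
        curves[m] = fit_median_curve(
            list(zip(sub["age_at_sample"], sub[m])), marker=m, form=form, alpha=alpha)
    return curves


def cohort_moms(
    cohort: pd.DataFrame,
    curves: Mapping[str, MedianCurve],
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Replace concentration columns by MoM values (other columns kept)."""
    markers = list(curves) if markers is None else list(markers)
    out = cohort.copy()
    for m in markers:
        out[m] = to_mom_array(cohort[m].to_numpy(float),
                              cohort["age_at_sample"].to_numpy(float), curves[m])
    return out


def estimate_cohort_params(
    mom_cohort: pd.DataFrame,
    markers: Sequence[str],
    followup_window: str = "<=5y",
    trunc_policy: str | tuple = "percentile",
) -> tuple[GroupParams, GroupParams]:
    """(affected, unaffected) GroupParams for one follow-up window.

    Truncation limits under the percentile policy come from the
    unaffected fit and are shared by both groups.
    """
    bands = WINDOW_BANDS[followup_window]
    sub = mom_cohort[mom_cohort["followup_band"].isin(bands)]
    aff_mask = _is_affected(sub["status"])
    log_mom = np.log10(sub[list(markers)].astype(float))
    unaff = estimate_group_params(log_mom[~aff_mask], markers=markers,
                                  group="unaffected",
                                  followup_window=followup_window,
                                  trunc_policy=trunc_policy)
    aff = estimate_group_params(log_mom[aff_mask], markers=markers,
                                group="affected", followup_window=followup_window,
                                trunc_policy=trunc_policy, trunc_ref=unaff)
    return aff, unaff


def cohort_risks(
    mom_cohort: pd.DataFrame,
    markers: Sequence[str],
    affected: GroupParams,
    unaffected: GroupParams,
    prior: IncidencePrior,
) -> pd.DataFrame:
    """Per-subject posterior risk; rows with missing panel values dropped."""
    aff = affected.subset(markers)
    unaff = unaffected.subset(markers)
    sub = mom_cohort.dropna(subset=list(markers)).copy()
    lr = likelihood_ratio(sub[list(markers)].to_numpy(float), aff, unaff)
    pri = prior_risk(sub["age_at_sample"].to_numpy(float), prior)
    sub["risk"] = posterior_risk(pri, lr)
    return sub
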