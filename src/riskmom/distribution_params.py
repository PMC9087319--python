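"""Multivariate log-Gaussian distribution parameters for marker MoM panels.

Each group of men (affected / unaffected, within a follow-up window) is
summarised by the mean and SD of each marker's log10 MoM, the pairwise
correlation matrix, and per-marker truncation limits (in MoM units) that
cap the likelihood ratio attainable by extreme values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupParams",
    "MassUnitParams",
    "estimate_group_params",
    "qq_fit_statistic",
    "nearest_psd_correlation",
]

_PSD_EPS = 1e-8


class EstimationError(ValueError):
    """Raised for degenerate or insufficient estimation inputs."""


def nearest_psd_correlation(corr: np.ndarray, eps: float = _PSD_EPS) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at ``eps`` and the result rescaled to unit
    diagonal.  Pairwise-complete sample correlations need not be jointly
    positive semi-definite, so this repair may be required before the
    matrix can parameterise a multivariate Gaussian.
    """
    corr = np.asarray(corr, dtype=float)
    corr = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(corr)
    if w.min() >= eps:
        return corr
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


@dataclass(frozen=True)
class GroupParams:
    """Log10-MoM Gaussian parameters for one group of men.

    ``trunc_lo``/``trunc_hi`` are in MoM units (not logs); log10 MoM
    values are clipped to their log10 before any density evaluation.
    """

    group: str                      # "affected" | "unaffected"
    followup_window: str            # e.g. "<=5y", "<10y", "all"
    markers: tuple[str, ...]
    mean: np.ndarray                # mean log10 MoM
    sd: np.ndarray                  # SD of log10 MoM
    corr: np.ndarray
    trunc_lo: np.ndarray            # MoM units
    trunc_hi: np.ndarray
    n: int | None = None

    def __post_init__(self) -> None:
        k = len(self.markers)
        object.__setattr__(self, "markers", tuple(self.markers))
        for name in ("mean", "sd", "trunc_lo", "trunc_hi"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "corr", np.asarray(self.corr, dtype=float))
        problems = self.validate()
        if problems:
            raise ValueError("invalid GroupParams: " + "; ".join(problems))

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        k = len(self.markers)
        problems: list[str] = []
        for name in ("mean", "sd", "trunc_lo", "trunc_hi"):
            if getattr(self, name).shape != (k,):
                problems.append(f"{name} has shape {getattr(self, name).shape}, expected ({k},)")
        if self.corr.shape != (k, k):
            problems.append(f"corr has shape {self.corr.shape}, expected ({k}, {k})")
            return problems
        if problems:
            return problems
        if np.any(self.sd <= 0):
            problems.append(f"sd must be > 0 elementwise, got {self.sd.tolist()}")
        asym = np.argwhere(~np.isclose(self.corr, self.corr.T, atol=1e-10))
        if asym.size:
            i, j = asym[0]
            problems.append(
                f"corr not symmetric: entry ({self.markers[i]}, {self.markers[j]}) "
                f"= {self.corr[i, j]} vs {self.corr[j, i]}"
            )
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-10):
            problems.append("corr diagonal is not all ones")
        if np.any(np.abs(self.corr) > 1 + 1e-10):
            problems.append("corr has entries outside [-1, 1]")
        if not problems:
            w = np.linalg.eigvalsh((self.corr + self.corr.T) / 2.0)
            if w.min() < -1e-8:
                problems.append(f"corr not positive semi-definite (min eigenvalue {w.min():.3g})")
        if np.any(self.trunc_lo >= self.trunc_hi):
            problems.append("trunc_lo must be < trunc_hi elementwise")
        if np.any(self.trunc_lo <= 0):
            problems.append("trunc_lo must be > 0 (MoM units)")
        return problems

    @property
    def cov(self) -> np.ndarray:
        """Covariance of log10 MoM implied by sd and corr."""
        return self.corr * np.outer(self.sd, self.sd)

    def subset(self, markers: Sequence[str]) -> "GroupParams":
        """Restrict the parameter set to a marker subset, preserving order."""
        idx = [self.markers.index(m) for m in markers]
        return GroupParams(
            group=self.group,
            followup_window=self.followup_window,
            markers=tuple(self.markers[i] for i in idx),
            mean=self.mean[idx],
            sd=self.sd[idx],
            corr=self.corr[np.ix_(idx, idx)],
            trunc_lo=self.trunc_lo[idx],
            trunc_hi=self.trunc_hi[idx],
            n=self.n,
        )

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "followup_window": self.followup_window,
            "markers": list(self.markers),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "corr": self.corr.tolist(),
            "trunc_lo": self.trunc_lo.tolist(),
            "trunc_hi": self.trunc_hi.tolist(),
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupParams":
        return cls(
            group=d["group"],
            followup_window=d["followup_window"],
            markers=tuple(d["markers"]),
            mean=d["mean"],
            sd=d["sd"],
            corr=d["corr"],
            trunc_lo=d["trunc_lo"],
            trunc_hi=d["trunc_hi"],
            n=d.get("n"),
        )


class MassUnitParams(GroupParams):
    """Same shape as GroupParams but on the log10(ng/ml) scale.

    Used for fixed mass-unit-threshold screening comparisons; truncation
    limits are then in ng/ml.
    """


def estimate_group_params(
    log_mom: np.ndarray | pd.DataFrame,
    markers: Sequence[str] | None = None,
    group: str = "unaffected",
    followup_window: str = "all",
    trunc_policy: str | tuple = "percentile",
    trunc_ref: GroupParams | None = None,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> GroupParams:
    """Estimate GroupParams from a subjects x markers matrix of log10 MoM.

    Missing values (NaN) are dropped casewise per marker for means/SDs and
    pairwise for correlations.  The pairwise correlation matrix is
    projected to the nearest positive semi-definite matrix if needed.

    ``trunc_policy``:
      * ``"percentile"`` — limits at the 1st/99th percentiles of the
        *unaffected* fitted log-Gaussian (``trunc_ref`` if given, else the
        fit itself when ``group == "unaffected"``), shared by both groups;
      * ``"none"`` — effectively unbounded limits;
      * an explicit ``(lo_array, hi_array)`` pair in MoM units.
    """
    if isinstance(log_mom, pd.DataFrame):
        markers = tuple(log_mom.columns) if markers is None else tuple(markers)
        df = log_mom[list(markers)]
    else:
        arr = np.asarray(log_mom, dtype=float)
        if arr.ndim != 2:
            raise EstimationError("log_mom must be 2-D (subjects x markers)")
        if markers is None:
            markers = tuple(f"m{i}" for i in range(arr.shape[1]))
        df = pd.DataFrame(arr, columns=list(markers))
    markers = tuple(markers)

    counts = df.notna().sum()
    if (counts < 5).any():
        bad = counts[counts < 5].index.tolist()
        raise EstimationError(f"fewer than 5 observations for markers {bad}")
    if not np.isfinite(df.to_numpy()[df.notna().to_numpy()]).all():
        raise EstimationError("log MoM matrix contains non-finite values")

    mean = df.mean().to_numpy()
    sd = df.std(ddof=1).to_numpy()
    if np.any(sd <= 1e-12) or np.any(~np.isfinite(sd)):
        zero = [m for m, s in zip(markers, sd) if not s > 1e-12]
        raise EstimationError(f"zero variance for markers {zero}")

    # zero-variance columns are reported before the correlation attempt
    corr = df.corr(method="pearson", min_periods=3).to_numpy()
    if np.any(~np.isfinite(corr)):
        raise EstimationError("correlation not estimable for some marker pair")
    corr = nearest_psd_correlation(corr)

    if trunc_policy == "percentile":
        ref_mean, ref_sd = mean, sd
        if trunc_ref is not None:
            ref = trunc_ref.subset(markers)
            ref_mean, ref_sd = ref.mean, ref.sd
        elif group != "unaffected":
            raise EstimationError(
                "percentile truncation for an affected group needs trunc_ref "
                "(the unaffected parameter set)"
            )
        z_lo, z_hi = stats.norm.ppf(percentiles[0] / 100), stats.norm.ppf(percentiles[1] / 100)
        trunc_lo = 10.0 ** (ref_mean + z_lo * ref_sd)
        trunc_hi = 10.0 ** (ref_mean + z_hi * ref_sd)
    elif trunc_policy == "none":
        trunc_lo = np.full(len(markers), 1e-12)
        trunc_hi = np.full(len(markers), 1e12)
    elif isinstance(trunc_policy, tuple) and len(trunc_policy) == 2:
        trunc_lo = np.asarray(trunc_policy[0], dtype=float)
        trunc_hi = np.asarray(trunc_policy[1], dtype=float)
    else:
        raise ValueError(f"unknown trunc_policy {trunc_policy!r}")

    return GroupParams(
        group=group,
        followup_window=followup_window,
        markers=markers,
        mean=mean,
        sd=sd,
        corr=corr,
        trunc_lo=trunc_lo,
        trunc_hi=trunc_hi,
        n=int(len(df)),
    )


def qq_fit_statistic(log_mom_sample: np.ndarray) -> float:
    """Correlation between sample and theoretical Gaussian quantiles.

    Values near 1 indicate the sample is adequately log-Gaussian (the
    sample here is already on the log scale).  Heavy tails pull the
    statistic down.
    """
    x = np.asarray(log_mom_sample, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise EstimationError(f"need n >= 10, got {len(x)}")
    if np.ptp(x) == 0:
        raise EstimationError("zero variance sample")
    (_, _), (_, _, r) = stats.probplot(x, dist="norm")
    return float(r)
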