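"""Screening-performance estimation: DR, FPR and OAPR.

Detection rate (DR) is the percentage of affected men with a positive
result, the false-positive rate (FPR) the percentage of unaffected men
with one, and the OAPR the odds of being affected given a positive result
(written 1:x).  Rates are estimated by Monte Carlo simulation from the
fitted group distributions, with a deterministic numerical-integration
oracle for 1-2 marker panels, percentile-bootstrap confidence intervals
over matched sets, fixed mass-unit-threshold comparisons, and the
"once-only" low-risk analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm

from .distribution_params import GroupParams
from .median_model import MedianCurve
from .risk_engine import IncidencePrior, likelihood_ratio, posterior_risk, prior_risk

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationModel",
    "PerfResult",
    "simulate_performance",
    "fpr_at_dr",
    "dr_at_fpr",
    "quadrature_performance",
    "mass_unit_performance",
    "bootstrap_ci",
    "once_only",
]


@dataclass(frozen=True)
class PopulationModel:
    """The screened population: age distribution, prior, group parameters."""

    affected: GroupParams
    unaffected: GroupParams
    prior: IncidencePrior
    ages: np.ndarray = field(default_factory=lambda: np.arange(55, 75, dtype=float))
    age_weights: np.ndarray | None = None
    median_curves: Mapping[str, MedianCurve] | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        w = self.age_weights
        w = np.full(len(ages), 1.0 / len(ages)) if w is None else np.asarray(w, dtype=float)
        if len(w) != len(ages):
            raise ValueError("age_weights length must match ages")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("age weights must be non-negative with positive sum")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "age_weights", w / w.sum())

    @property
    def prevalence(self) -> float:
        """Overall probability of becoming affected within the horizon."""
        return float(np.sum(self.age_weights * prior_risk(self.ages, self.prior)))

    def group_age_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Age weights within the affected and unaffected subpopulations."""
        p = prior_risk(self.ages, self.prior)
        wa = self.age_weights * p
        wu = self.age_weights * (1.0 - p)
        return wa / wa.sum(), wu / wu.sum()


@dataclass(frozen=True)
class PerfResult:
    """One operating point of a screening test."""

    dr: float                   # detection rate, %
    fpr: float                  # false-positive rate, %
    oapr_x: float               # the x of "1:x"
    cutoff: float               # risk probability or marker threshold
    n_sim: int
    seed: int | None = None
    se_dr: float | None = None  # Monte-Carlo standard errors, percentage points
    se_fpr: float | None = None
    ci: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.dr <= 100 and 0 <= self.fpr <= 100):
            raise ValueError("dr and fpr must be percentages in [0, 100]")


def _oapr_x(dr: float, fpr: float, prevalence: float) -> float:
    """x in OAPR 1:x = (unaffected fraction * fpr) / (affected fraction * dr)."""
    if dr <= 0:
        return float("inf")
    return ((1.0 - prevalence) * fpr) / (prevalence * dr)


def _simulate_group_risks(
    pop: PopulationModel,
    markers: Sequence[str],
    n_sim: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated posterior risks for n_sim affected and n_sim unaffected men.

    Each subject gets an age (drawn from the group-specific age
    distribution), a log10-MoM panel from the group's multivariate
    Gaussian, and the risk a screener would compute for them.
    """
    markers = tuple(markers)
    if not markers:
        raise ValueError("empty marker subset")
    aff = pop.affected.subset(markers)
    unaff = pop.unaffected.subset(markers)
    wa, wu = pop.group_age_weights()

    risks = []
    for params, w in ((aff, wa), (unaff, wu)):
        ages = rng.choice(pop.ages, size=n_sim, p=w)
        z = rng.multivariate_normal(params.mean, params.cov, size=n_sim,
                                    method="cholesky")
        lr = likelihood_ratio(10.0 ** z, aff, unaff)
        risks.append(posterior_risk(prior_risk(ages, pop.prior), lr))
    return risks[0], risks[1]


def simulate_performance(
    pop: PopulationModel,
    markers: Sequence[str],
    cutoff: float,
    n_sim: int = 200_000,
    seed: int | None = None,
) -> PerfResult:
    """Monte-Carlo DR/FPR/OAPR at a posterior-risk cut-off."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    if n_sim < 10_000:
        raise ValueError("n_sim must be >= 10^4 for stable rates")
    rng = np.random.default_rng(seed)
    aff_risk, unaff_risk = _simulate_group_risks(pop, markers, n_sim, rng)
    dr = 100.0 * np.mean(aff_risk >= cutoff)
    fpr = 100.0 * np.mean(unaff_risk >= cutoff)
    se_dr = 100.0 * np.sqrt(max(dr / 100 * (1 - dr / 100), 1e-12) / n_sim)
    se_fpr = 100.0 * np.sqrt(max(fpr / 100 * (1 - fpr / 100), 1e-12) / n_sim)
    logger.info("simulate_performance markers=%s cutoff=%g n_sim=%d seed=%s "
                "ages=%s-%s", markers, cutoff, n_sim, seed, pop.ages.min(),
                pop.ages.max())
    return PerfResult(dr=dr, fpr=fpr, oapr_x=_oapr_x(dr, fpr, pop.prevalence),
                      cutoff=cutoff, n_sim=n_sim, seed=seed,
                      se_dr=se_dr, se_fpr=se_fpr)


def _fixed_rate(
    pop: PopulationModel,
    markers: Sequence[str],
    target: float,
    fix: str,
    n_sim: int,
    seed: int | None,
) -> PerfResult:
    if not 0 < target < 100:
        raise ValueError("target rate must be in (0, 100) percent")
    rng = np.random.default_rng(seed)
    aff_risk, unaff_risk = _simulate_group_risks(pop, markers, n_sim, rng)
    # Implied cut-off: the (100 - target) percentile of the fixed group's
    # risks; ties at the cut-off count positive, as in classify().
    src = aff_risk if fix == "dr" else unaff_risk
    cutoff = float(np.quantile(src, 1.0 - target / 100.0))
    dr = 100.0 * np.mean(aff_risk >= cutoff)
    fpr = 100.0 * np.mean(unaff_risk >= cutoff)
    se_dr = 100.0 * np.sqrt(max(dr / 100 * (1 - dr / 100), 1e-12) / n_sim)
    se_fpr = 100.0 * np.sqrt(max(fpr / 100 * (1 - fpr / 100), 1e-12) / n_sim)
    return PerfResult(dr=dr, fpr=fpr, oapr_x=_oapr_x(dr, fpr, pop.prevalence),
                      cutoff=cutoff, n_sim=n_sim, seed=seed,
                      se_dr=se_dr, se_fpr=se_fpr)


def fpr_at_dr(pop: PopulationModel, markers: Sequence[str], target_dr: float,
              n_sim: int = 200_000, seed: int | None = None) -> PerfResult:
    """FPR at the risk cut-off that achieves ``target_dr`` percent detection."""
    return _fixed_rate(pop, markers, target_dr, "dr", n_sim, seed)


def dr_at_fpr(pop: PopulationModel, markers: Sequence[str], target_fpr: float,
              n_sim: int = 200_000, seed: int | None = None) -> PerfResult:
    """DR at the risk cut-off that yields ``target_fpr`` percent false positives."""
    return _fixed_rate(pop, markers, target_fpr, "fpr", n_sim, seed)


def _cell_grid(affected, unaffected, j, n, span):
    """Cell edges and midpoints covering both group densities of marker j."""
    lo = min(affected.mean[j] - span * affected.sd[j],
             unaffected.mean[j] - span * unaffected.sd[j])
    hi = max(affected.mean[j] + span * affected.sd[j],
             unaffected.mean[j] + span * unaffected.sd[j])
    edges = np.linspace(lo, hi, n + 1)
    return edges, 0.5 * (edges[:-1] + edges[1:])


def quadrature_performance(
    affected: GroupParams,
    unaffected: GroupParams,
    cutoff: float | None = None,
    threshold: float | None = None,
    prior: IncidencePrior | None = None,
    ages: np.ndarray | None = None,
    age_weights: np.ndarray | None = None,
    grid_n: int = 2001,
    span: float = 8.0,
) -> PerfResult:
    """Deterministic DR/FPR by numerical integration (1-2 marker panels).

    Either a posterior-risk ``cutoff`` (with ``prior`` and an age grid) or
    a direct log10-MoM ``threshold`` on a single marker may be supplied.
    Serves as the independent oracle for the Monte-Carlo estimator.

    Because the posterior risk is monotone in the likelihood ratio, the
    screen-positive region at age a is {LR >= t(a)} with t(a) the cut-off
    odds over the prior odds; LR is evaluated once on a cell grid and each
    cell contributes its exact Gaussian mass (1-D: CDF increments; 2-D:
    marginal x conditional CDF increments), so discretisation error is
    confined to boundary cells of width (range / grid_n).
    """
    if affected.markers != unaffected.markers:
        raise ValueError("marker mismatch between groups")
    k = len(affected.markers)
    if k > 2:
        raise ValueError("quadrature supports panels of 1 or 2 markers only")

    if threshold is not None:
        if k != 1:
            raise ValueError("threshold mode requires a single marker")
        dr = 100.0 * norm.sf(threshold, loc=affected.mean[0], scale=affected.sd[0])
        fpr = 100.0 * norm.sf(threshold, loc=unaffected.mean[0], scale=unaffected.sd[0])
        prev = 0.5
        if prior is not None and ages is not None:
            w = (np.full(len(ages), 1 / len(ages)) if age_weights is None
                 else np.asarray(age_weights) / np.sum(age_weights))
            prev = float(np.sum(w * prior_risk(np.asarray(ages, float), prior)))
        return PerfResult(dr=float(dr), fpr=float(fpr),
                          oapr_x=_oapr_x(dr, fpr, prev), cutoff=threshold,
                          n_sim=0, seed=None)

    if cutoff is None or prior is None or ages is None:
        raise ValueError("cutoff mode requires cutoff, prior and ages")
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    ages = np.asarray(ages, dtype=float)
    w = (np.full(len(ages), 1 / len(ages)) if age_weights is None
         else np.asarray(age_weights, float) / np.sum(age_weights))
    p_age = prior_risk(ages, prior)
    wa = w * p_age
    wu = w * (1 - p_age)
    prev = float(wa.sum())
    wa, wu = wa / wa.sum(), wu / wu.sum()
    # risk >= cutoff  <=>  LR >= cutoff-odds / prior-odds
    t_age = (cutoff / (1 - cutoff)) * (1 - p_age) / p_age

    if k == 1:
        edges, mids = _cell_grid(affected, unaffected, 0, grid_n, span)
        lr = likelihood_ratio(10.0 ** mids[:, None], affected, unaffected)
        mass_a = np.diff(norm.cdf(edges, loc=affected.mean[0], scale=affected.sd[0]))
        mass_u = np.diff(norm.cdf(edges, loc=unaffected.mean[0], scale=unaffected.sd[0]))
    else:
        n2 = max(grid_n // 5, 201)
        edges1, mids1 = _cell_grid(affected, unaffected, 0, grid_n, span)
        edges2, mids2 = _cell_grid(affected, unaffected, 1, n2, span)
        g1, g2 = np.meshgrid(mids1, mids2, indexing="ij")
        pts = np.column_stack([g1.ravel(), g2.ravel()])
        lr = likelihood_ratio(10.0 ** pts, affected, unaffected).reshape(len(mids1), len(mids2))

        def _mass(params):
            m1, m2 = params.mean
            s1, s2 = params.sd
            rho = params.corr[0, 1]
            marg2 = np.diff(norm.cdf(edges2, loc=m2, scale=s2))          # (n2,)
            cond_mean = m1 + rho * s1 / s2 * (mids2 - m2)                # (n2,)
            cond_sd = s1 * np.sqrt(max(1 - rho**2, 1e-12))
            cdf = norm.cdf((edges1[:, None] - cond_mean[None, :]) / cond_sd)
            return np.diff(cdf, axis=0) * marg2[None, :]                 # (grid_n, n2)

        mass_a, mass_u = _mass(affected), _mass(unaffected)

    dr = fpr = 0.0
    for a_w, u_w, t in zip(wa, wu, t_age):
        pos = lr >= t
        dr += a_w * float(np.sum(mass_a * pos))
        fpr += u_w * float(np.sum(mass_u * pos))
    dr, fpr = 100.0 * dr, 100.0 * fpr
    return PerfResult(dr=float(np.clip(dr, 0, 100)), fpr=float(np.clip(fpr, 0, 100)),
                      oapr_x=_oapr_x(dr, fpr, prev), cutoff=cutoff, n_sim=0, seed=None)


def mass_unit_performance(
    threshold: float,
    mass_affected: GroupParams | None = None,
    mass_unaffected: GroupParams | None = None,
    pop: PopulationModel | None = None,
    marker: str = "total_psa",
    n_sim: int = 200_000,
    seed: int | None = None,
) -> PerfResult:
    """DR/FPR of the fixed rule "concentration >= threshold ng/ml".

    With ``mass_affected``/``mass_unaffected`` (single-marker parameters on
    the log10 ng/ml scale) the rates are closed-form Gaussian tails.
    Otherwise concentrations are reconstructed from a population model as
    MoM x age-specific median, with age drawn from the model, and the
    rates estimated empirically.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0:
        prev = pop.prevalence if pop is not None else 0.5
        return PerfResult(dr=100.0, fpr=100.0, oapr_x=_oapr_x(100, 100, prev),
                          cutoff=0.0, n_sim=0, seed=seed)

    if mass_affected is not None and mass_unaffected is not None:
        if len(mass_affected.markers) != 1 or len(mass_unaffected.markers) != 1:
            raise ValueError("mass-unit closed form requires single-marker parameters")
        t = np.log10(threshold)
        dr = 100.0 * norm.sf(t, loc=mass_affected.mean[0], scale=mass_affected.sd[0])
        fpr = 100.0 * norm.sf(t, loc=mass_unaffected.mean[0], scale=mass_unaffected.sd[0])
        prev = pop.prevalence if pop is not None else 0.5
        return PerfResult(dr=float(dr), fpr=float(fpr),
                          oapr_x=_oapr_x(dr, fpr, prev), cutoff=threshold,
                          n_sim=0, seed=seed)

    if pop is None or pop.median_curves is None or marker not in pop.median_curves:
        raise ValueError(
            f"need either mass-unit parameters or a population model with a "
            f"median curve for {marker!r}"
        )
    rng = np.random.default_rng(seed)
    curve = pop.median_curves[marker]
    aff = pop.affected.subset([marker])
    unaff = pop.unaffected.subset([marker])
    wa, wu = pop.group_age_weights()
    rates = []
    for params, w in ((aff, wa), (unaff, wu)):
        ages = rng.choice(pop.ages, size=n_sim, p=w)
        z = rng.normal(params.mean[0], params.sd[0], size=n_sim)
        conc = 10.0 ** z * curve.median(ages)
        rates.append(100.0 * np.mean(conc >= threshold))
    dr, fpr = rates
    return PerfResult(dr=dr, fpr=fpr, oapr_x=_oapr_x(dr, fpr, pop.prevalence),
                      cutoff=threshold, n_sim=n_sim, seed=seed)


def bootstrap_ci(
    cohort: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], Mapping[str, float]],
    n_reps: int = 500,
    seed: int | None = None,
    max_failure_fraction: float = 0.10,
) -> dict[str, tuple[float, float]]:
    """Percentile-bootstrap 95% CIs, resampling matched sets.

    The resampling unit is the matched set (a case plus its controls,
    identified by ``matched_set_id``), preserving the matched design.
    ``estimator`` refits whatever pipeline it needs on each replicate
    cohort and returns named scalar quantities.
    """
    if "matched_set_id" not in cohort.columns:
        raise ValueError("cohort must have a matched_set_id column")
    set_ids = cohort["matched_set_id"].unique()
    if len(set_ids) < 2:
        raise ValueError("need at least 2 matched sets to bootstrap")
    rng = np.random.default_rng(seed)
    cohort = cohort.reset_index(drop=True)
    positions = cohort.groupby("matched_set_id").indices

    samples: dict[str, list[float]] = {}
    failures = 0
    for _ in range(n_reps):
        chosen = rng.choice(set_ids, size=len(set_ids), replace=True)
        take = np.concatenate([positions[sid] for sid in chosen])
        rep = cohort.iloc[take].reset_index(drop=True)
        try:
            est = estimator(rep)
        except Exception as exc:  # noqa: BLE001 - failures are counted, then re-raised in bulk
            failures += 1
            if failures > max_failure_fraction * n_reps:
                raise RuntimeError(
                    f"estimator failed in {failures}/{n_reps} bootstrap "
                    f"replicates (> {max_failure_fraction:.0%}); last error: {exc!r}"
                ) from exc
            continue
        for key, val in est.items():
            samples.setdefault(key, []).append(float(val))
    logger.info("bootstrap_ci n_reps=%d seed=%s failures=%d", n_reps, seed, failures)
    return {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for k, v in samples.items()}


def once_only(
    risks: pd.DataFrame,
    low_risk_cutoff: float = 1.0 / 5000.0,
) -> pd.DataFrame:
    """Once-only screening analysis: what a very low initial risk buys.

    For men whose computed risk is at or below ``low_risk_cutoff`` (so low
    that further periodic testing might be skipped), counts per follow-up
    band the affected men who would be missed and the unaffected men whose
    further screening examinations would be avoided.

    ``risks`` needs columns ``status`` ("affected"/"unaffected" — any
    affected_* label counts as affected), ``followup_band`` and ``risk``.
    Returns a DataFrame indexed by band with ``missed_pct`` and
    ``avoided_pct``.
    """
    df = risks.copy()
    df["is_affected"] = df["status"].astype(str).str.startswith("affected")
    rows = {}
    for band, sub in df.groupby("followup_band", sort=False):
        aff = sub[sub["is_affected"]]
        unaff = sub[~sub["is_affected"]]
        if len(aff) == 0 and len(unaff) == 0:
            warnings.warn(f"follow-up band {band!r} empty; omitted", stacklevel=2)
            continue
        missed = 100.0 * np.mean(aff["risk"] <= low_risk_cutoff) if len(aff) else np.nan
        avoided = 100.0 * np.mean(unaff["risk"] <= low_risk_cutoff) if len(unaff) else np.nan
        rows[band] = {"missed_pct": missed, "avoided_pct": avoided,
                      "n_affected": len(aff), "n_unaffected": len(unaff)}
    return pd.DataFrame.from_dict(rows, orient="index")
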