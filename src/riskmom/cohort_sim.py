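"""Synthetic matched nested case-control cohort generator.

Emulates the structure of a cohort of stored sera analysed decades later:
cases of prostate cancer (ascertained by death or registration) each
matched to ``control_ratio`` unaffected men of the same 5-year age group
and follow-up band.  Unaffected log10 MoM panels come from the unaffected
multivariate Gaussian with median MoM 1; affected panels are shifted so
their median MoM equals the configured per-band median, which declines
with follow-up (marker elevation is largest shortly before the event).
Concentrations in ng/ml are reconstructed as MoM x age-specific median.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .distribution_params import GroupParams
from .median_model import BmiCurve, MedianCurve

__all__ = ["SimConfig", "SubjectRecord", "generate_cohort", "split_death_status",
           "cohort_to_frame"]

COHORT_COLUMNS = ["id", "matched_set_id", "status", "age_at_sample",
                  "followup_years", "followup_band", "total_psa", "free_psa",
                  "intact_psa", "hk2", "msp", "bmi"]


@dataclass(frozen=True)
class SubjectRecord:
    """One man in the synthetic cohort."""

    id: str
    matched_set_id: str
    status: str              # affected_died_of | affected_died_with | unaffected
    age_at_sample: float
    followup_years: float
    followup_band: str
    concentrations: dict[str, float]   # marker -> ng/ml (NaN when assay missing)
    bmi: float | None = None


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the package's synthetic
    reference study conditions (see :mod:`riskmom.defaults`)."""

    n_cases: int = 571
    control_ratio: int = 4
    age_median: float = 54.0
    age_sd: float = 7.4          # IQR 49-59 under a normal
    age_limits: tuple[float, float] = (35.0, 74.0)
    band_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(zip(defaults.FOLLOWUP_BANDS, defaults.BAND_PROBS)))
    band_medians: Mapping[str, Mapping[str, float]] | None = None
    unaffected: GroupParams | None = None
    affected_sd: np.ndarray | None = None
    median_curves: Mapping[str, MedianCurve] | None = None
    bmi_curves: Mapping[str, BmiCurve] | None = None
    bmi_mean: float = 26.0
    bmi_sd: float = 3.5
    missingness: float = 0.0     # per-assay missing probability
    p_died_of: float = 324.0 / 571.0
    seed: int | None = None

    def resolved(self) -> "SimConfig":
        """Fill None fields with the package defaults."""
        out = self
        if out.unaffected is None:
            out = replace(out, unaffected=defaults.default_unaffected())
        if out.affected_sd is None:
            out = replace(out, affected_sd=defaults.AFFECTED_SD_5Y)
        if out.median_curves is None:
            out = replace(out, median_curves=defaults.default_median_curves())
        if out.band_medians is None:
            bm = {band: {m: defaults.band_median_mom(m, band)
                         for m in out.unaffected.markers}
                  for band in out.band_probs}
            out = replace(out, band_medians=bm)
        return out

    def validate(self) -> None:
        probs = np.array(list(self.band_probs.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValueError(f"band probabilities sum to {probs.sum()}, not 1")
        if self.control_ratio < 1:
            raise ValueError("control_ratio must be >= 1")
        if self.band_medians is not None:
            for band, med in self.band_medians.items():
                if any(v <= 0 for v in med.values()):
                    raise ValueError(f"non-positive band median in band {band}")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")


def _truncnorm_ages(rng, n, cfg: SimConfig) -> np.ndarray:
    lo, hi = cfg.age_limits
    ages = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(cfg.age_median, cfg.age_sd, size=2 * (n - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        ages[filled:filled + take] = draw[:take]
        filled += take
    return ages


def generate_cohort(config: SimConfig | None = None) -> list[SubjectRecord]:
    """Generate the matched cohort; deterministic given ``config.seed``."""
    cfg = (config or SimConfig()).resolved()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    unaff = cfg.unaffected
    markers = unaff.markers
    if cfg.band_medians is not None:
        for band, med in cfg.band_medians.items():
            if set(med) != set(markers):
                raise ValueError(
                    f"band {band} medians cover {sorted(med)} but the "
                    f"unaffected parameters cover {sorted(markers)}")
    aff_sd = np.asarray(cfg.affected_sd, dtype=float)
    aff_cov = unaff.corr * np.outer(aff_sd, aff_sd)

    bands = list(cfg.band_probs)
    probs = np.array([cfg.band_probs[b] for b in bands])
    case_bands = rng.choice(bands, size=cfg.n_cases, p=probs)
    case_ages = _truncnorm_ages(rng, cfg.n_cases, cfg)

    records: list[SubjectRecord] = []
    for i in range(cfg.n_cases):
        band = case_bands[i]
        set_id = f"set{i:05d}"
        b_lo, b_hi = defaults.BAND_EDGES.get(band, (0.0, 30.0))
        followup = float(rng.uniform(b_lo, b_hi))
        mean_aff = np.log10([cfg.band_medians[band][m] for m in markers])
        members = [("affected", case_ages[i])]
        # Controls matched on the same 5-year age group (and band/storage
        # duration implicitly, by sharing the matched set's band).  Control
        # ages come from the cohort age distribution restricted to that
        # group, so case and control age distributions are exchangeable.
        age_lo = max(5.0 * np.floor(case_ages[i] / 5.0), cfg.age_limits[0])
        age_hi = min(age_lo + 5.0, cfg.age_limits[1])
        ctrl_ages = []
        while len(ctrl_ages) < cfg.control_ratio:
            draw = rng.normal(cfg.age_median, cfg.age_sd, size=8)
            ctrl_ages.extend(draw[(draw >= age_lo) & (draw < age_hi)])
        members += [("unaffected", a) for a in ctrl_ages[:cfg.control_ratio]]

        for j, (status, age) in enumerate(members):
            if status == "affected":
                z = rng.multivariate_normal(mean_aff, aff_cov, method="cholesky")
            else:
                z = rng.multivariate_normal(unaff.mean, unaff.cov, method="cholesky")
            bmi = None
            if cfg.bmi_curves is not None:
                bmi = float(rng.normal(cfg.bmi_mean, cfg.bmi_sd))
                for mi, m in enumerate(markers):
                    curve = cfg.bmi_curves.get(m)
                    if curve is not None:
                        z[mi] += curve.slope * (bmi - curve.reference_bmi)
            conc = {}
            for mi, m in enumerate(markers):
                if cfg.missingness and rng.random() < cfg.missingness:
                    conc[m] = float("nan")
                else:
                    conc[m] = float(10.0 ** z[mi] * cfg.median_curves[m].median(age))
            records.append(SubjectRecord(
                id=f"{set_id}-{j}",
                matched_set_id=set_id,
                status=status,
                age_at_sample=float(age),
                followup_years=followup,
                followup_band=band,
                concentrations=conc,
                bmi=bmi,
            ))
    records = split_death_status(records, p_died_of=cfg.p_died_of, rng=rng)
    return records


def split_death_status(
    records: Sequence[SubjectRecord],
    p_died_of: float = 324.0 / 571.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[SubjectRecord]:
    """Label affected men as died-of vs died-with prostate cancer.

    Labels are assigned independently of marker values, so the two
    affected subgroups are exchangeable — the marker distributions do not
    differ by cause of death.
    """
    if not 0 <= p_died_of <= 1:
        raise ValueError("p_died_of must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = []
    for rec in records:
        if rec.status.startswith("affected"):
            label = ("affected_died_of" if rng.random() < p_died_of
                     else "affected_died_with")
            out.append(replace(rec, status=label))
        else:
            out.append(rec)
    return out


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabular view of a cohort (one row per man, markers as columns)."""
    rows = []
    for r in records:
        row = {
            "id": r.id, "matched_set_id": r.matched_set_id, "status": r.status,
            "age_at_sample": r.age_at_sample, "followup_years": r.followup_years,
            "followup_band": r.followup_band, "bmi": r.bmi,
        }
        row.update(r.concentrations)
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    return df[cols + [c for c in df.columns if c not in cols]]
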