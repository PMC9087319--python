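"""Screening-performance estimation: Monte Carlo, quadrature, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from riskmom import defaults
from riskmom.distribution_params import GroupParams
from riskmom.performance import (
    PerfResult,
    PopulationModel,
    bootstrap_ci,
    dr_at_fpr,
    fpr_at_dr,
    mass_unit_performance,
    once_only,
    quadrature_performance,
    simulate_performance,
)
from riskmom.risk_engine import IncidencePrior


def _uni(group, mean, sd, lo=1e-9, hi=1e9):
    return GroupParams(group=group, followup_window="all", markers=("m",),
                       mean=[mean], sd=[sd], corr=[[1.0]],
                       trunc_lo=[lo], trunc_hi=[hi])


FLAT_PRIOR = IncidencePrior(ages=[40, 90], rates=[0.004, 0.004], horizon=5)
ONE_AGE = np.array([60.0])


def _pop(aff, unaff, prior=FLAT_PRIOR, ages=ONE_AGE):
    return PopulationModel(affected=aff, unaffected=unaff, prior=prior, ages=ages)


def _mc_se(rate_pct, n):
    p = rate_pct / 100
    return 100 * np.sqrt(max(p * (1 - p), 1e-9) / n)


class TestSimulatePerformance:
    def test_identical_distributions_dr_equals_fpr(self):
        p = _uni("affected", 0.0, 0.3)
        u = _uni("unaffected", 0.0, 0.3)
        for cutoff in (0.01, 0.05, 0.2):
            res = simulate_performance(_pop(p, u), ["m"], cutoff,
                                       n_sim=50_000, seed=1)
            assert abs(res.dr - res.fpr) < 3 * np.sqrt(2) * _mc_se(res.fpr, res.n_sim)

    def test_closed_form_tail_single_marker(self):
        """Affected N(0.5, 0.25) vs unaffected N(0, 0.25), cut-off at the
        unaffected 97th percentile: DR must match the normal tail
        P(N(0.5,0.25) > 0.25 * z_0.97) = 54.7%."""
        p = _uni("affected", 0.5, 0.25)
        u = _uni("unaffected", 0.0, 0.25)
        res = dr_at_fpr(_pop(p, u), ["m"], target_fpr=3.0, n_sim=200_000, seed=2)
        expected_dr = 100 * norm.sf(0.25 * norm.ppf(0.97), 0.5, 0.25)
        assert expected_dr == pytest.approx(54.7, abs=0.05)
        assert res.dr == pytest.approx(expected_dr, abs=3 * _mc_se(expected_dr, res.n_sim))
        assert res.fpr == pytest.approx(3.0, abs=3 * _mc_se(3.0, res.n_sim))

    def test_reproducible_given_seed(self, population):
        a = simulate_performance(population, ["total_psa"], 0.05, n_sim=20_000, seed=9)
        b = simulate_performance(population, ["total_psa"], 0.05, n_sim=20_000, seed=9)
        assert (a.dr, a.fpr) == (b.dr, b.fpr)

    def test_dr_fpr_monotone_in_cutoff(self, population):
        cutoffs = [1 / 50, 1 / 40, 1 / 30, 1 / 20, 1 / 10]
        results = [simulate_performance(population, ["total_psa", "hk2"], c,
                                        n_sim=50_000, seed=3) for c in cutoffs]
        drs = [r.dr for r in results]
        fprs = [r.fpr for r in results]
        assert drs == sorted(drs, reverse=True)
        assert fprs == sorted(fprs, reverse=True)

    def test_oapr_identity(self, population):
        res = simulate_performance(population, ["total_psa", "hk2"], 1 / 20,
                                   n_sim=20_000, seed=4)
        prev = population.prevalence
        assert res.oapr_x == pytest.approx(((1 - prev) * res.fpr) / (prev * res.dr))

    def test_empty_marker_subset_raises(self, population):
        with pytest.raises(ValueError, match="empty marker"):
            simulate_performance(population, [], 0.05, n_sim=10_000, seed=0)

    def test_small_n_sim_refused(self, population):
        with pytest.raises(ValueError, match="n_sim"):
            simulate_performance(population, ["hk2"], 0.05, n_sim=100, seed=0)


class TestFixedRateInversion:
    def test_exchangeable_distributions_fpr_at_dr90_is_90(self):
        """Groups separated by a negligible mean shift are exchangeable, so
        the cut-off hitting DR 90% also passes ~90% of unaffected men.
        (An exactly-zero shift degenerates: LR = 1 ties every risk at the
        prior, and the tie rule marks everyone positive.)"""
        p = _uni("affected", 1e-3, 0.3)
        u = _uni("unaffected", 0.0, 0.3)
        res = fpr_at_dr(_pop(p, u), ["m"], target_dr=90.0, n_sim=100_000, seed=5)
        assert res.fpr == pytest.approx(90.0, abs=0.5)

    def test_achieved_rate_matches_target(self, population):
        res = fpr_at_dr(population, ["total_psa", "hk2"], 90.0,
                        n_sim=100_000, seed=6)
        assert res.dr == pytest.approx(90.0, abs=0.2)
        res2 = dr_at_fpr(population, ["total_psa", "hk2"], 3.0,
                         n_sim=100_000, seed=7)
        assert res2.fpr == pytest.approx(3.0, abs=0.2)

    def test_extreme_target_refused(self, population):
        for bad in (0.0, 100.0):
            with pytest.raises(ValueError):
                fpr_at_dr(population, ["hk2"], bad, n_sim=10_000, seed=0)


class TestQuadrature:
    def test_median_split_gives_fpr_50(self):
        p = _uni("affected", 0.5, 0.25)
        u = _uni("unaffected", 0.0, 0.25)
        res = quadrature_performance(p, u, threshold=0.0)
        assert res.fpr == pytest.approx(50.0)

    def test_threshold_mode_closed_form(self):
        p = _uni("affected", 0.5, 0.25)
        u = _uni("unaffected", 0.0, 0.25)
        res = quadrature_performance(p, u, threshold=0.4702)
        assert res.fpr == pytest.approx(3.0, abs=0.01)
        assert res.dr == pytest.approx(54.7, abs=0.1)

    def test_monte_carlo_agrees_one_marker(self, affected_params,
                                           unaffected_params, incidence5):
        aff = affected_params.subset(["total_psa"])
        unaff = unaffected_params.subset(["total_psa"])
        pop = _pop(aff, unaff, incidence5, defaults.SCREEN_AGES)
        q = quadrature_performance(aff, unaff, cutoff=1 / 20, prior=incidence5,
                                   ages=defaults.SCREEN_AGES)
        m = simulate_performance(pop, ["total_psa"], 1 / 20, n_sim=200_000, seed=8)
        assert m.dr == pytest.approx(q.dr, abs=3 * _mc_se(q.dr, m.n_sim))
        assert m.fpr == pytest.approx(q.fpr, abs=3 * _mc_se(q.fpr, m.n_sim))

    def test_monte_carlo_agrees_two_independent_markers(self):
        mk = ("a", "b")
        eye = np.eye(2)
        aff = GroupParams(group="affected", followup_window="all", markers=mk,
                          mean=[0.3, 0.3], sd=[0.3, 0.3], corr=eye,
                          trunc_lo=[1e-9] * 2, trunc_hi=[1e9] * 2)
        unaff = GroupParams(group="unaffected", followup_window="all", markers=mk,
                            mean=[0.0, 0.0], sd=[0.3, 0.3], corr=eye,
                            trunc_lo=[1e-9] * 2, trunc_hi=[1e9] * 2)
        pop = _pop(aff, unaff)
        q = quadrature_performance(aff, unaff, cutoff=0.05, prior=FLAT_PRIOR,
                                   ages=ONE_AGE)
        m = simulate_performance(pop, list(mk), 0.05, n_sim=1_000_000, seed=10)
        assert m.dr == pytest.approx(q.dr, abs=3 * _mc_se(q.dr, m.n_sim))
        assert m.fpr == pytest.approx(q.fpr, abs=3 * _mc_se(q.fpr, m.n_sim))

    def test_three_markers_unsupported(self, affected_params, unaffected_params):
        with pytest.raises(ValueError, match="1 or 2"):
            quadrature_performance(
                affected_params.subset(["total_psa", "free_psa", "hk2"]),
                unaffected_params.subset(["total_psa", "free_psa", "hk2"]),
                cutoff=0.05, prior=FLAT_PRIOR, ages=ONE_AGE)


class TestUninformativeMarker:
    def test_adding_null_marker_is_a_no_op(self):
        """A marker with identical group distributions and no correlation
        contributes nothing: DR at fixed FPR changes by less than
        Monte-Carlo error."""
        mk2 = ("m", "null")
        corr = np.eye(2)
        aff1 = _uni("affected", 0.5, 0.3)
        unaff1 = _uni("unaffected", 0.0, 0.3)
        aff2 = GroupParams(group="affected", followup_window="all", markers=mk2,
                           mean=[0.5, 0.0], sd=[0.3, 0.25], corr=corr,
                           trunc_lo=[1e-9] * 2, trunc_hi=[1e9] * 2)
        unaff2 = GroupParams(group="unaffected", followup_window="all", markers=mk2,
                             mean=[0.0, 0.0], sd=[0.3, 0.25], corr=corr,
                             trunc_lo=[1e-9] * 2, trunc_hi=[1e9] * 2)
        n = 400_000
        r1 = dr_at_fpr(_pop(aff1, unaff1), ["m"], 3.0, n_sim=n, seed=11)
        r2 = dr_at_fpr(_pop(aff2, unaff2), list(mk2), 3.0, n_sim=n, seed=12)
        assert r2.dr == pytest.approx(r1.dr, abs=3 * np.sqrt(2) * _mc_se(r1.dr, n))


class TestMassUnit:
    def test_zero_threshold_catches_everyone(self):
        res = mass_unit_performance(0.0)
        assert (res.dr, res.fpr) == (100.0, 100.0)

    def test_threshold_at_unaffected_mean_gives_fpr_50(self):
        mass_a = _uni("affected", np.log10(3.0), 0.4)
        mass_u = _uni("unaffected", np.log10(1.0), 0.35)
        res = mass_unit_performance(1.0, mass_affected=mass_a, mass_unaffected=mass_u)
        assert res.fpr == pytest.approx(50.0)
        assert res.dr == pytest.approx(100 * norm.sf(0.0, np.log10(3.0), 0.4))

    def test_reconstruction_mode_matches_closed_form_with_flat_curve(
            self, affected_params, unaffected_params):
        """With a constant median curve, MoM x median is a plain lognormal,
        so the empirical reconstruction must match the Gaussian tails."""
        from riskmom.median_model import MedianCurve
        flat = MedianCurve(marker="total_psa", b0=np.log10(0.9), b1=0.0, b2=0.0,
                           age_range=(40.0, 80.0))
        pop = PopulationModel(affected=affected_params, unaffected=unaffected_params,
                              prior=FLAT_PRIOR, ages=ONE_AGE,
                              median_curves={"total_psa": flat})
        thr = 4.0
        res = mass_unit_performance(thr, pop=pop, marker="total_psa",
                                    n_sim=200_000, seed=13)
        t = np.log10(thr / 0.9)
        exp_dr = 100 * norm.sf(t, affected_params.mean[0], affected_params.sd[0])
        exp_fpr = 100 * norm.sf(t, unaffected_params.mean[0], unaffected_params.sd[0])
        assert res.dr == pytest.approx(exp_dr, abs=3 * _mc_se(exp_dr, res.n_sim))
        assert res.fpr == pytest.approx(exp_fpr, abs=3 * _mc_se(max(exp_fpr, 0.1), res.n_sim))

    def test_missing_curves_raise(self):
        with pytest.raises(ValueError, match="median curve"):
            mass_unit_performance(4.0)

    def test_mom_with_age_dominates_mass_units_at_matched_dr(
            self, population, affected_params, unaffected_params):
        """At the DR achieved by a fixed ng/ml cut-off, the risk-based
        algorithm (MoM + age + hK2) yields a lower FPR — the advantage of
        age standardisation plus marker combination."""
        curves = defaults.default_median_curves()
        pop = PopulationModel(affected=affected_params, unaffected=unaffected_params,
                              prior=population.prior, ages=population.ages,
                              median_curves=curves)
        mass = mass_unit_performance(4.0, pop=pop, marker="total_psa",
                                     n_sim=200_000, seed=14)
        algo = fpr_at_dr(pop, ["total_psa", "hk2"], mass.dr, n_sim=200_000, seed=15)
        assert algo.fpr < mass.fpr


class TestBootstrap:
    @staticmethod
    def _toy_cohort(n_sets=30, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sets):
            for j in range(3):
                rows.append({
                    "matched_set_id": f"s{s}",
                    "status": "affected" if j == 0 else "unaffected",
                    "total_psa": 1.0 + jitter * rng.normal(),
                })
        return pd.DataFrame(rows)

    def test_zero_variance_estimator_gives_zero_width(self):
        cohort = self._toy_cohort(jitter=0.0)
        ci = bootstrap_ci(cohort, lambda df: {"m": df["total_psa"].mean()},
                          n_reps=50, seed=1)
        lo, hi = ci["m"]
        assert lo == hi == 1.0

    def test_resamples_matched_sets_reproducibly(self):
        cohort = self._toy_cohort(jitter=0.3, seed=2)
        est = lambda df: {"m": df["total_psa"].median()}
        a = bootstrap_ci(cohort, est, n_reps=100, seed=7)
        b = bootstrap_ci(cohort, est, n_reps=100, seed=7)
        assert a == b
        lo, hi = a["m"]
        assert lo < hi

    def test_persistent_estimator_failure_aborts(self):
        cohort = self._toy_cohort(jitter=0.3)

        def broken(df):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="bootstrap"):
            bootstrap_ci(cohort, broken, n_reps=50, seed=3)

    def test_default_replication_count_is_500(self):
        import inspect
        sig = inspect.signature(bootstrap_ci)
        assert sig.parameters["n_reps"].default == 500


class TestOnceOnly:
    @staticmethod
    def _risks(band_risks):
        rows = []
        for band, (aff_risks, unaff_risks) in band_risks.items():
            rows += [{"status": "affected_died_of", "followup_band": band, "risk": r}
                     for r in aff_risks]
            rows += [{"status": "unaffected", "followup_band": band, "risk": r}
                     for r in unaff_risks]
        return pd.DataFrame(rows)

    def test_zero_cutoff_misses_and_avoids_nothing(self):
        df = self._risks({"0-5": ([0.1, 0.2], [0.01, 0.02])})
        out = once_only(df, low_risk_cutoff=0.0)
        assert out.loc["0-5", "missed_pct"] == 0.0
        assert out.loc["0-5", "avoided_pct"] == 0.0

    def test_all_above_cutoff_is_zero_zero(self):
        df = self._risks({"0-5": ([0.01] * 5, [0.01] * 5)})
        out = once_only(df, low_risk_cutoff=1 / 5000)
        assert out.loc["0-5", "missed_pct"] == 0.0
        assert out.loc["0-5", "avoided_pct"] == 0.0

    def test_counts_fractions_at_or_below_cutoff(self):
        cutoff = 1 / 5000
        df = self._risks({"20+": ([cutoff, 0.1, 0.1, 0.1], [cutoff / 2, 0.1])})
        out = once_only(df, low_risk_cutoff=cutoff)
        assert out.loc["20+", "missed_pct"] == pytest.approx(25.0)
        assert out.loc["20+", "avoided_pct"] == pytest.approx(50.0)
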