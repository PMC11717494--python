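"""Survival analysis: stratification, log-rank, Kaplan-Meier, hazards fits.

The log-rank statistic and product-limit sequences are checked against
hand-derived values on small toys and cross-checked against lifelines on
random data (dual route: direct implementation vs library).
"""

import numpy as np
import pandas as pd
import pytest

from histocoloc.survival import (
    FitError,
    StratifiedCohort,
    associate,
    dichotomise,
    fit_adjusted_hazards,
    km_curve,
    km_curves,
    logrank_test,
    subgroup_analysis,
)
from histocoloc.synth import SurvivalSimParams, simulate_cohort_survival


def records_frame(times, events, groups=None, ids=None):
    df = pd.DataFrame(
        {
            "patient_id": ids or [f"P{i}" for i in range(len(times))],
            "pfs_months": times,
            "event": events,
        }
    )
    if groups is not None:
        df["group"] = groups
    return df


class TestDichotomise:
    def test_balanced_split(self):
        c = dichotomise(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert sorted(c.labels) == ["high", "high", "low", "low"]
        assert c.cutpoint == 2.5

    def test_ties_at_median_go_low(self):
        c = dichotomise(pd.Series([1.0, 1.0, 1.0, 2.0], index=list("abcd")))
        assert c.cutpoint == 1.0
        assert (c.labels == "high").sum() == 1

    def test_order_invariant(self):
        v = pd.Series([5.0, 1.0, 3.0, 9.0], index=list("abcd"))
        a = dichotomise(v)
        b = dichotomise(v.sample(frac=1, random_state=1))
        assert a.labels.sort_index().equals(b.labels.sort_index())

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomise(pd.Series([2.0, 2.0, 2.0]))


class TestLogrank:
    def test_identical_group_histories_give_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [True] * 6
        g = ["a", "a", "a", "b", "b", "b"]
        stat, p = logrank_test(t, e, g)
        assert stat == 0.0
        assert p == 1.0

    def test_six_patient_toy_matches_hand_computation(self):
        """Group A events at 1,2,3; group B events at 4,5,6.

        By hand: O_A - E_A = (1-3/6) + (1-2/5) + (1-1/4) = 1.85;
        V = 1/4 + 6/25 + 3/16 = 0.6775; chi2 = 1.85^2 / 0.6775.
        """
        t = [1, 2, 3, 4, 5, 6]
        e = [True] * 6
        g = ["a", "a", "a", "b", "b", "b"]
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(1.85**2 / 0.6775, abs=1e-12)

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t = rng.exponential(10, 80)
        e = rng.uniform(size=80) < 0.7
        g = np.where(rng.uniform(size=80) < 0.5, "a", "b")
        stat, p = logrank_test(t, e, g)
        ll = ll_logrank(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
        assert stat == pytest.approx(ll.test_statistic, rel=1e-9)
        assert p == pytest.approx(ll.p_value, rel=1e-9)

    def test_time_rescaling_invariance(self, rng):
        t = rng.exponential(10, 60)
        e = rng.uniform(size=60) < 0.8
        g = np.where(rng.uniform(size=60) < 0.5, "a", "b")
        s1, _ = logrank_test(t, e, g)
        s2, _ = logrank_test(t * 12.0, e, g)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [True, True], ["a", "a"])

    def test_power_under_planted_effect(self):
        """Simulated hazard ratio 3 at n=200: p < 0.01 in nearly all runs."""
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            labels = np.array(["high"] * 100 + ["low"] * 100)
            rec = simulate_cohort_survival(
                labels,
                SurvivalSimParams(true_log_hr=np.log(3.0), n_patients=200, seed=900 + rep),
            )
            _, p = logrank_test(rec.pfs_months, rec.event, rec.group)
            hits += p < 0.01
        assert hits >= 0.95 * n_rep


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        tab = km_curve([5.0, 6.0, 7.0], [False, False, False])
        assert (tab.survival == 1.0).all()

    def test_five_record_toy_matches_hand_product_limit(self):
        """Events at 1, 3, 4 with censoring at 2 and 5:
        S = 4/5, then 4/5 * 2/3 = 8/15, then 8/15 * 1/2 = 4/15."""
        tab = km_curve([1, 2, 3, 4, 5], [True, False, True, True, False])
        np.testing.assert_allclose(
            tab.survival.to_numpy(), [1.0, 0.8, 8 / 15, 4 / 15], atol=1e-12
        )

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 70)
        e = rng.uniform(size=70) < 0.6
        if not e.any():
            e[0] = True
        tab = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in tab.iloc[1:].iterrows():
            assert row.survival == pytest.approx(
                float(kmf.survival_function_at_times(row.time).iloc[0]), abs=1e-9
            )

    def test_numbers_at_risk_start_at_group_size(self):
        rec = records_frame([1, 2, 3, 4], [True, True, False, True])
        cohort = StratifiedCohort(
            pd.Series(["high", "high", "low", "low"], index=rec.patient_id, name="group"),
            0.0,
            "m",
        )
        curves = km_curves(rec, cohort, at_risk_times=np.array([0.0]))
        for g, tab in curves.items():
            assert tab.attrs["numbers_at_risk"].n_at_risk.iloc[0] == 2


class TestAdjustedHazards:
    @staticmethod
    def simulated(n, log_hr, seed, censor=0.3):
        labels = np.array(["high", "low"] * (n // 2))
        rec = simulate_cohort_survival(
            labels,
            SurvivalSimParams(true_log_hr=log_hr, n_patients=n, seed=seed, censor_rate=censor),
        )
        rec["metric"] = (rec.group == "high").astype(float)
        return rec

    def test_null_effect_recovered(self):
        rec = self.simulated(2000, 0.0, 4)
        res = fit_adjusted_hazards(rec, "metric")
        assert abs(res.hazard_table.log_hr.iloc[0]) <= 0.15

    def test_noise_covariate_has_nominal_coverage(self):
        rng = np.random.default_rng(5)
        cover = 0
        n_rep = 40
        for rep in range(n_rep):
            rec = self.simulated(400, np.log(1.5), 1000 + rep)
            rec["noise"] = rng.normal(size=len(rec))
            res = fit_adjusted_hazards(rec, "metric", ["noise"])
            lo, hi = res.ci("noise")
            cover += lo <= 1.0 <= hi
        assert 0.85 * n_rep <= cover <= n_rep

    def test_constant_covariate_rejected(self):
        rec = self.simulated(100, 0.0, 6)
        rec["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_adjusted_hazards(rec, "metric", ["flat"])

    def test_too_few_events_rejected(self):
        rec = self.simulated(10, 0.0, 7, censor=0.0)
        rec.loc[:, "event"] = False
        rec.loc[0, "event"] = True
        rec["c1"], rec["c2"] = rec.pfs_months * 0.1, rec.pfs_months * 0.2
        with pytest.raises(ValueError, match="events"):
            fit_adjusted_hazards(rec, "metric", ["c1", "c2"])

    def test_missing_covariates_dropped_listwise(self):
        rec = self.simulated(200, 0.0, 8)
        rec["cov"] = np.where(np.arange(len(rec)) < 20, np.nan, 1.0 * np.arange(len(rec)) % 3)
        res = fit_adjusted_hazards(rec, "metric", ["cov"])
        assert res.n_dropped == 20
        assert res.n_patients == 180


class TestSubgroupAnalysis:
    def test_constant_stratifier_equals_unstratified(self):
        rec = TestAdjustedHazards.simulated(200, np.log(2.0), 9)
        rec["patient_id"] = [f"P{i}" for i in range(len(rec))]
        rec["arm"] = "A"
        cohort = StratifiedCohort(
            pd.Series(rec.group.to_numpy(), index=rec.patient_id, name="group"), 0.0, "m"
        )
        whole = associate(rec, cohort)
        strat = subgroup_analysis(rec, cohort, "arm")
        assert list(strat) == ["A"]
        assert strat["A"].hr("group") == pytest.approx(whole.hr("group"))
        assert strat["A"].logrank_stat == pytest.approx(whole.logrank_stat)

    def test_strata_partition_cohort(self):
        rec = TestAdjustedHazards.simulated(300, np.log(2.0), 10)
        rec["patient_id"] = [f"P{i}" for i in range(len(rec))]
        rec["arm"] = np.where(np.arange(len(rec)) % 4 < 2, "A", "B")
        cohort = StratifiedCohort(
            pd.Series(rec.group.to_numpy(), index=rec.patient_id, name="group"), 0.0, "m"
        )
        strat = subgroup_analysis(rec, cohort, "arm")
        assert sum(r.n_patients for r in strat.values()) == 300

    def test_planted_interaction_detected(self):
        """HR 2 in stratum A, HR 1 in stratum B: the stratum-A CI should
        exclude 1 and the stratum-B CI cover 1 in most replicates."""
        hits_a, hits_b = 0, 0
        n_rep = 25
        for rep in range(n_rep):
            rec_a = TestAdjustedHazards.simulated(500, np.log(2.0), 2000 + rep)
            rec_b = TestAdjustedHazards.simulated(500, 0.0, 3000 + rep)
            rec_a["arm"], rec_b["arm"] = "A", "B"
            rec = pd.concat([rec_a, rec_b], ignore_index=True)
            rec["patient_id"] = [f"P{i}" for i in range(len(rec))]
            cohort = StratifiedCohort(
                pd.Series(rec.group.to_numpy(), index=rec.patient_id, name="group"), 0.0, "m"
            )
            strat = subgroup_analysis(rec, cohort, "arm")
            lo_a, hi_a = strat["A"].ci("group")
            lo_b, hi_b = strat["B"].ci("group")
            hits_a += not (lo_a <= 1.0 <= hi_a)
            hits_b += lo_b <= 1.0 <= hi_b
        assert hits_a >= 0.9 * n_rep
        assert hits_b >= 0.8 * n_rep
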