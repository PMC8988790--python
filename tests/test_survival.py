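import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crpc_kinetics.survival import (aalen_johansen, baseline_table, cox_fit,
                                    harrell_c, km_median)


def brute_force_harrell(times, events, marker):
    """Exhaustive pair enumeration, independent of the implementation."""
    conc, comp = 0.0, 0
    n = len(times)
    for i, j in itertools.permutations(range(n), 2):
        if not events[i] or times[i] >= times[j]:
            continue
        comp += 1
        if marker[i] > marker[j]:
            conc += 1
        elif marker[i] == marker[j]:
            conc += 0.5
    return conc / comp


class TestKmMedian:
    def test_single_death(self):
        m = km_median([100.0], [1])
        assert m is not None and m[0] == 100.0

    def test_uncensored_sample_matches_hand_km_table(self):
        # S drops by 1/10 at each death; S(5) = 0.5 -> first t with S <= 0.5
        times = np.arange(1.0, 11.0)
        m = km_median(times, np.ones(10, int))
        assert m[0] == 5.0

    def test_all_censored_returns_none(self):
        assert km_median([10.0, 20.0], [0, 0]) is None

    def test_censoring_shifts_median_right(self):
        times = np.arange(1.0, 11.0)
        events = np.ones(10, int)
        events[:4] = 0  # censor the four earliest
        m = km_median(times, events)
        assert m[0] > 5.0


class TestHarrellC:
    def test_perfectly_ordered_marker(self):
        times = np.array([1.0, 2, 3, 4, 5])
        marker = np.array([5.0, 4, 3, 2, 1])  # highest risk dies first
        assert harrell_c(times, np.ones(5, bool), marker) == 1.0

    def test_null_marker_near_half(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(100, 3000)
        marker = rng.normal(size=3000)
        c = harrell_c(times, np.ones(3000, bool), marker)
        assert abs(c - 0.5) < 0.03

    def test_hand_listed_fixture_matches_enumeration(self):
        times = np.array([5.0, 8.0, 8.0, 12.0])
        events = np.array([1, 0, 1, 1], bool)
        marker = np.array([3.0, 1.0, 3.0, 0.5])
        got = harrell_c(times, events, marker)
        want = brute_force_harrell(times, events, marker)
        assert got == want

    def test_random_fixtures_match_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            times = np.round(rng.exponential(50, n), 0) + 1  # tied times
            events = rng.random(n) < 0.7
            marker = np.round(rng.normal(size=n), 1)  # tied markers
            got = harrell_c(times, events, marker)
            assert got == pytest.approx(brute_force_harrell(times, events,
                                                            marker))

    def test_matches_lifelines_on_tie_free_times(self):
        # lifelines additionally scores death-death pairs at tied times,
        # so agreement is exact only without ties in the time axis
        from lifelines.utils import concordance_index
        rng = np.random.default_rng(18)
        for _ in range(10):
            n = int(rng.integers(5, 80))
            times = rng.exponential(50, n)
            events = rng.random(n) < 0.7
            marker = np.round(rng.normal(size=n), 1)
            if events.sum() == 0:
                continue
            # lifelines orders by predicted survival time (low marker = long)
            assert harrell_c(times, events, marker) == pytest.approx(
                concordance_index(times, -marker, events))

    def test_no_comparable_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            harrell_c([5.0, 6.0], [0, 0], [1.0, 2.0])


class TestAalenJohansen:
    def test_single_cause_reduces_to_one_minus_km(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(3)
        times = rng.exponential(50, 200)
        statuses = np.where(rng.random(200) < 0.7, "pc_death", "censored")
        curve = aalen_johansen(times, statuses)
        kmf = KaplanMeierFitter().fit(times, statuses == "pc_death")
        for t in (10, 30, 80):
            km_surv = float(kmf.survival_function_at_times(t).iloc[0])
            assert curve.at(t)[0] == pytest.approx(1 - km_surv, abs=1e-9)

    def test_partition_of_unity_at_every_step(self):
        rng = np.random.default_rng(4)
        times = np.round(rng.exponential(30, 500)) + 1  # many ties
        statuses = rng.choice(["pc_death", "other_death", "censored"], 500)
        c = aalen_johansen(times, statuses)
        np.testing.assert_allclose(c.cif_pc + c.cif_other + c.surv, 1.0,
                                   atol=1e-12)
        assert (np.diff(c.cif_pc) >= 0).all()
        assert (np.diff(c.cif_other) >= 0).all()

    def test_equal_hazards_split_evenly(self):
        rng = np.random.default_rng(6)
        n = 5000
        t_pc = rng.exponential(100, n)
        t_other = rng.exponential(100, n)
        times = np.minimum(t_pc, t_other)
        statuses = np.where(t_pc <= t_other, "pc_death", "other_death")
        c = aalen_johansen(times, statuses)
        assert c.final[0] == pytest.approx(0.5, abs=0.02)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import AalenJohansenFitter
        rng = np.random.default_rng(9)
        times = rng.exponential(50, 300)  # continuous: no ties
        statuses = rng.choice(["pc_death", "other_death", "censored"], 300,
                              p=[0.4, 0.3, 0.3])
        curve = aalen_johansen(times, statuses)
        event = np.where(statuses == "pc_death", 1,
                         np.where(statuses == "other_death", 2, 0))
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(times, event, event_of_interest=1)
        for t in (20, 60, 120):
            ours = curve.at(t)[0]
            theirs = float(ajf.cumulative_density_.loc[
                :t].iloc[-1, 0])
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestCoxFit:
    @staticmethod
    def _records(times, statuses, group):
        return pd.DataFrame({"time": times, "status": statuses,
                             "group": group})

    def test_known_hazard_ratio_recovered(self):
        rng = np.random.default_rng(12)
        n = 4000
        group = np.where(np.arange(n) < n // 2, "high", "low")
        lam = np.where(group == "high", 3.0 / 1000, 1.0 / 1000)
        times = rng.exponential(1.0 / lam)
        rec = self._records(times, ["pc_death"] * n, group)
        res = cox_fit(rec, {"group": "low"}, outcome="pc_specific")
        hr = res.hr("group", "high")
        lo, hi = res.ci("group", "high")
        assert lo < 3.0 < hi
        assert hr == pytest.approx(3.0, rel=0.15)

    def test_reference_level_flagged_with_unit_hr(self):
        rng = np.random.default_rng(13)
        rec = self._records(rng.exponential(100, 200),
                            ["pc_death"] * 200,
                            rng.choice(["a", "b"], 200))
        res = cox_fit(rec, {"group": "a"})
        ref = res.table[res.table["reference"]]
        assert list(ref["level"]) == ["a"]
        assert (ref["hr"] == 1.0).all()

    def test_competing_cause_censored_for_pc_specific(self):
        # other-cause deaths must not count as events in the PC-specific fit
        rng = np.random.default_rng(14)
        n = 500
        times = rng.exponential(100, n)
        statuses = np.array(["other_death"] * n)
        statuses[:5] = "pc_death"
        rec = self._records(times, statuses, rng.choice(["a", "b"], n))
        res = cox_fit(rec, {"group": "a"}, outcome="pc_specific")
        assert res.table["hr"].notna().all()

    def test_eventless_level_merged_into_reference(self, caplog):
        times = [10.0, 20, 30, 40, 50, 60]
        statuses = ["pc_death", "pc_death", "pc_death", "pc_death",
                    "censored", "censored"]
        group = ["a", "a", "b", "b", "c", "c"]
        res = cox_fit(self._records(times, statuses, group), {"group": "a"})
        assert "c" not in set(res.table["level"])


class TestBaselineTable:
    def test_exact_counts_and_percentages(self):
        cohort = pd.DataFrame({
            "adt_context": ["primary"] * 6 + ["secondary"] * 4,
            "psa_dt_cat": ["<=1 month"] * 3 + ["1+ years"] * 3
                          + ["<=1 month"] * 2 + ["1+ years"] * 2,
            "m_stage": ["M0", "M1", "MX", "M0", "M1", "MX",
                        "M0", "M1", "M0", "M1"],
        })
        table = baseline_table(cohort)
        row = table[(table["variable"] == "PSA doubling time")
                    & (table["level"] == "<=1 month")].iloc[0]
        assert row["primary_n"] == 3 and row["primary_pct"] == 50.0
        assert row["secondary_n"] == 2 and row["all_n"] == 5

    def test_percentages_sum_to_100_per_variable(self):
        rng = np.random.default_rng(2)
        cohort = pd.DataFrame({
            "adt_context": rng.choice(["primary", "secondary"], 100),
            "psa_dt_cat": rng.choice(["<=1 month", "1+ years"], 100),
        })
        table = baseline_table(cohort)
        sums = table.groupby("variable")["all_pct"].sum()
        assert ((sums - 100).abs() < 0.5).all()

    def test_missing_rendered_as_explicit_row(self):
        cohort = pd.DataFrame({
            "adt_context": ["primary", "primary"],
            "psa_at_gnrh_cat": [np.nan, "<=10 ng/ml"],
        })
        table = baseline_table(cohort)
        assert "Missing" in set(table["level"])
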