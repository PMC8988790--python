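import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crpc_kinetics.castration import CastrationInterval, castration_intervals
from crpc_kinetics.config import AnalysisConfig
from crpc_kinetics.detect import (apply_inclusion, classify_adt_context,
                                  detect_crpc, running_nadir)

from conftest import make_timeline

EPOCH = pd.Timestamp("2010-01-01")


def day(n):
    return EPOCH + pd.Timedelta(days=n)


def psa_series(values, start=0, step=30):
    return [(day(start + step * i), v) for i, v in enumerate(values)]


def timeline_with_castration(values, step=30):
    """PSA series starting at castration; one long fill keeps coverage."""
    n_days = step * len(values) + 400
    t = make_timeline(psa=psa_series(values, start=89, step=step),
                      fills=[(day(0), n_days)])
    return t


def brute_force_crpc(dates, values, eligible_from, eligible_mask=None):
    """Re-evaluate both clauses at every measurement against a freshly
    recomputed prefix minimum. Independent of the implementation."""
    nadir = None
    for i, (d, v) in enumerate(zip(dates, values)):
        if d < eligible_from:
            continue
        if nadir is None or v < nadir:
            nadir = v
        if eligible_mask is not None and not eligible_mask[i]:
            continue
        doubling = v >= 2 * nadir and v > 2.0
        absolute = v - nadir >= 5.0
        if doubling and absolute:
            return d, "both"
        if doubling:
            return d, "doubling_gt2"
        if absolute:
            return d, "absolute_plus5"
    return None


class TestRunningNadir:
    def test_tracks_prefix_minimum(self):
        t = make_timeline(psa=psa_series([10, 4, 1, 3, 8]))
        states = running_nadir(t.psa, day(0))
        assert [s.nadir_value for s in states] == [10, 4, 1, 1, 1]
        assert states[-1].nadir_date == day(60)

    def test_monotone_rising_series_keeps_first_point(self):
        t = make_timeline(psa=psa_series([2, 3, 4]))
        states = running_nadir(t.psa, day(0))
        assert states[-1].nadir_value == 2
        assert states[-1].nadir_date == day(0)

    def test_tied_minimum_keeps_earliest_date(self):
        t = make_timeline(psa=psa_series([5, 2.0, 3, 2.0]))
        states = running_nadir(t.psa, day(0))
        assert states[-1].nadir_date == day(30)

    def test_pre_castration_values_excluded(self):
        t = make_timeline(psa=psa_series([0.5, 4, 9]))
        states = running_nadir(t.psa, day(15))
        assert states[0].nadir_value == 4

    def test_empty_eligible_series(self):
        t = make_timeline(psa=psa_series([1, 2]))
        assert running_nadir(t.psa, day(100)) == []


class TestDetectCrpc:
    def test_doubling_requires_reaching_twice_nadir(self, analysis_cfg):
        # nadir 1.5: 2.5 < 3.0 is no event; 3.2 >= 3.0 and > 2 fires
        t = timeline_with_castration([1.5, 2.5, 3.2])
        ev = detect_crpc(t, castration_intervals(t, analysis_cfg), analysis_cfg)
        assert ev is not None
        assert ev.psa_at_crpc == 3.2
        assert ev.rule == "doubling_gt2"

    def test_doubling_below_2_ng_ml_does_not_fire(self, analysis_cfg):
        # 0.9 >= 2*0.5 but the last value must exceed 2 ng/ml
        t = timeline_with_castration([0.5, 0.9])
        assert detect_crpc(t, castration_intervals(t, analysis_cfg),
                           analysis_cfg) is None

    def test_absolute_rise_of_5_fires_without_doubling(self, analysis_cfg):
        t = timeline_with_castration([40, 45])
        ev = detect_crpc(t, castration_intervals(t, analysis_cfg), analysis_cfg)
        assert ev is not None
        assert ev.rule == "absolute_plus5"
        assert ev.psa_at_crpc == 45

    def test_both_clauses_recorded(self, analysis_cfg):
        t = timeline_with_castration([4.0, 9.5])
        ev = detect_crpc(t, castration_intervals(t, analysis_cfg), analysis_cfg)
        assert ev.rule == "both"

    def test_no_event_returns_none(self, analysis_cfg):
        t = timeline_with_castration([5, 4, 4.5, 5.0])
        assert detect_crpc(t, castration_intervals(t, analysis_cfg),
                           analysis_cfg) is None

    def test_measurement_outside_grace_cannot_trigger(self):
        cfg = AnalysisConfig(strict_castration=True)
        # coverage ends day 90; riser measured at day 200 is ineligible
        t = make_timeline(psa=[(day(89), 1.0), (day(200), 8.0)],
                          fills=[(day(0), 90)])
        assert detect_crpc(t, castration_intervals(t, cfg), cfg) is None

    def test_grace_window_allows_trailing_measurement(self, analysis_cfg):
        t = make_timeline(psa=[(day(89), 1.0), (day(170), 8.0)],
                          fills=[(day(0), 90)])
        ev = detect_crpc(t, castration_intervals(t, analysis_cfg),
                         analysis_cfg)
        assert ev is not None and ev.crpc_date == day(170)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.1, 100), min_size=1, max_size=20),
           st.integers(5, 60))
    def test_agrees_with_brute_force_scan(self, analysis_cfg, values, step):
        t = timeline_with_castration(values, step=step)
        ivs = castration_intervals(t, analysis_cfg)
        ev = detect_crpc(t, ivs, analysis_cfg)
        dates = list(t.psa["date"])
        want = brute_force_crpc(dates, list(t.psa["psa_ng_ml"]),
                                eligible_from=ivs[0].start)
        if want is None:
            assert ev is None
        else:
            assert ev is not None
            assert (ev.crpc_date, ev.rule) == want

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.1, 100), min_size=2, max_size=15),
           st.data())
    def test_removing_a_pre_event_measurement_never_predates(
            self, analysis_cfg, values, data):
        t = timeline_with_castration(values)
        ivs = castration_intervals(t, analysis_cfg)
        ev = detect_crpc(t, ivs, analysis_cfg)
        if ev is None:
            return
        pre = t.psa[t.psa["date"] < ev.crpc_date]
        if pre.empty:
            return
        drop = data.draw(st.sampled_from(list(pre.index)))
        t2 = make_timeline(psa=[(d, v) for i, (d, v) in
                                enumerate(zip(t.psa["date"],
                                              t.psa["psa_ng_ml"]))
                                if i != drop],
                           fills=[(day(0), 30 * len(values) + 400)])
        ev2 = detect_crpc(t2, castration_intervals(t2, analysis_cfg),
                          analysis_cfg)
        if ev2 is not None:
            assert ev2.crpc_date >= ev.crpc_date


class TestAdtContext:
    def test_primary_adt(self):
        assert classify_adt_context(
            make_timeline(primary_treatment="primary_adt")) == "primary"

    def test_curative_then_relapse_is_secondary(self):
        assert classify_adt_context(
            make_timeline(primary_treatment="curative")) == "secondary"

    def test_deferred_is_secondary(self):
        assert classify_adt_context(
            make_timeline(primary_treatment="deferred")) == "secondary"

    def test_neoadjuvant_flag_excludes(self):
        assert classify_adt_context(
            make_timeline(primary_treatment="curative",
                          neoadjuvant=True)) == "excluded_neoadjuvant"

    def test_missing_treatment_is_unknown(self):
        t = make_timeline()
        t.diagnosis["primary_treatment"] = None
        assert classify_adt_context(t) == "unknown"


class TestInclusion:
    def test_early_gnrh_excluded(self, analysis_cfg):
        t = make_timeline("A", psa=psa_series([1.0, 8.0], start=89),
                          fills=[(pd.Timestamp("2005-06-01"), 900)])
        res = apply_inclusion({"A": t}, analysis_cfg)
        assert res.tally["castration_before_cutoff"] == 1
        assert res.included == []

    def test_no_crpc_excluded(self, analysis_cfg):
        t = timeline_with_castration([5, 4, 4])
        res = apply_inclusion({t.patient_id: t}, analysis_cfg)
        assert res.tally["no_crpc"] == 1

    def test_tally_partitions_the_input(self, analysis_cfg, small_cohort):
        _, timelines, _ = small_cohort
        res = apply_inclusion(timelines, analysis_cfg)
        tally = res.tally
        parts = (tally["no_diagnosis"] + tally["castration_before_cutoff"]
                 + tally["never_castrated"] + tally["no_crpc"]
                 + tally["neoadjuvant"] + tally["included"])
        assert parts == tally["input"] == len(timelines)
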