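"""CRPC ascertainment from the PSA series of a castrated patient.

A patient enters the CRPC cohort at the first PSA measurement, taken
whilst castrated, that satisfies either clause of the detection rule
against the running nadir n (the minimum eligible PSA since castration
start):

* doubling:  value >= 2*n  and  value > 2 ng/ml, or
* absolute:  value - n >= 5 ng/ml.

The nadir is tracked from castration start; pre-castration PSA never
contributes.  Nadir ties resolve to the earliest date.  "Whilst castrated"
means inside a castration interval, or (by default) within ``grace_days``
after a medical interval's coverage end; ``strict_castration`` disables
the grace extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .castration import CastrationInterval, castration_intervals, first_castration_event
from .config import AnalysisConfig
from .registry import PatientTimeline

DOUBLING_FLOOR_NG_ML = 2.0
ABSOLUTE_RISE_NG_ML = 5.0


@dataclass(frozen=True)
class NadirState:
    """Running PSA minimum since castration start and its first date."""

    nadir_value: float
    nadir_date: pd.Timestamp


@dataclass(frozen=True)
class CrpcEvent:
    """A detected CRPC date with its triggering measurement and rule."""

    patient_id: str
    crpc_date: pd.Timestamp
    rule: str  # "doubling_gt2" | "absolute_plus5" | "both"
    psa_at_crpc: float
    nadir: NadirState


def running_nadir(psa: pd.DataFrame, from_date: pd.Timestamp) -> list[NadirState]:
    """Prefix-minimum states for each measurement at or after ``from_date``.

    Ties keep the earliest attaining date.  Empty eligible series -> [].
    """
    eligible = psa[psa["date"] >= from_date]
    states: list[NadirState] = []
    best: NadirState | None = None
    for date, value in zip(eligible["date"], eligible["psa_ng_ml"]):
        if best is None or value < best.nadir_value:
            best = NadirState(float(value), date)
        states.append(best)
    return states


def _rule_fired(value: float, nadir: float) -> str | None:
    doubling = value >= 2.0 * nadir and value > DOUBLING_FLOOR_NG_ML
    absolute = value - nadir >= ABSOLUTE_RISE_NG_ML
    if doubling and absolute:
        return "both"
    if doubling:
        return "doubling_gt2"
    if absolute:
        return "absolute_plus5"
    return None


def _eligible_as_trigger(date: pd.Timestamp,
                         intervals: list[CastrationInterval],
                         cfg: AnalysisConfig) -> bool:
    slack = 0 if cfg.strict_castration else cfg.grace_days
    return any(iv.contains(date, slack_days=slack) for iv in intervals)


def detect_crpc(t: PatientTimeline,
                intervals: list[CastrationInterval],
                cfg: AnalysisConfig) -> CrpcEvent | None:
    """First measurement satisfying the CRPC rule whilst castrated, or None."""
    if not intervals:
        return None
    start = min(iv.start for iv in intervals)
    eligible = t.psa[t.psa["date"] >= start]
    best: NadirState | None = None
    for date, value in zip(eligible["date"], eligible["psa_ng_ml"]):
        value = float(value)
        if best is None or value < best.nadir_value:
            best = NadirState(value, date)
        if _eligible_as_trigger(date, intervals, cfg):
            rule = _rule_fired(value, best.nadir_value)
            if rule is not None:
                return CrpcEvent(t.patient_id, date, rule, value, best)
    return None


def classify_adt_context(t: PatientTimeline) -> str:
    """primary / secondary / excluded_neoadjuvant / unknown.

    Primary ADT was the first treatment for the cancer; secondary ADT
    followed curative-intent treatment or deferred management.  ADT given
    as neoadjuvant to radiotherapy excludes the patient from the cohort.
    """
    dx = t.diagnosis
    if bool(dx.get("neoadjuvant", False)):
        return "excluded_neoadjuvant"
    treatment = dx.get("primary_treatment")
    if treatment == "primary_adt":
        return "primary"
    if treatment in ("curative", "deferred"):
        return "secondary"
    return "unknown"


@dataclass
class InclusionResult:
    """Included patient ids plus a consort-style exclusion tally."""

    included: list[str]
    events: dict[str, CrpcEvent]
    tally: dict[str, int]


def apply_inclusion(timelines: dict[str, PatientTimeline],
                    cfg: AnalysisConfig) -> InclusionResult:
    """Apply the three cohort criteria and the neoadjuvant exclusion.

    Criteria: a cancer diagnosis on record; first castration event after
    the GnRH cutoff date; a detected CRPC event.  The tally counts each
    excluded patient once, by the first failing criterion in that order.
    """
    cutoff = pd.Timestamp(cfg.gnrh_cutoff_date)
    included: list[str] = []
    events: dict[str, CrpcEvent] = {}
    tally = {
        "input": len(timelines),
        "no_diagnosis": 0,
        "castration_before_cutoff": 0,
        "never_castrated": 0,
        "no_crpc": 0,
        "neoadjuvant": 0,
        "included": 0,
    }
    for pid, t in timelines.items():
        if t.diagnosis is None or pd.isna(t.diagnosis.get("dx_date")):
            tally["no_diagnosis"] += 1
            continue
        first = first_castration_event(t)
        if first is None:
            tally["never_castrated"] += 1
            continue
        if first <= cutoff:
            tally["castration_before_cutoff"] += 1
            continue
        if classify_adt_context(t) == "excluded_neoadjuvant":
            tally["neoadjuvant"] += 1
            continue
        intervals = castration_intervals(t, cfg)
        event = detect_crpc(t, intervals, cfg)
        if event is None:
            tally["no_crpc"] += 1
            continue
        included.append(pid)
        events[pid] = event
    tally["included"] = len(included)
    return InclusionResult(included, events, tally)
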