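"""Castration status over time, derived from dispensations and surgery.

Medical castration is established once a patient has accumulated at least
90 days of GnRH coverage inside some 183-day window ("at least 3 months of
ADT within a total period of 6 months").  The castration date is the day
the criterion is first fulfilled — the 90th covered day of the earliest
qualifying window — not the first fill date.  Surgical castration starts
at the hospital admission date and never ends.

Antiandrogen monotherapy dispensations never establish castration (men on
bicalutamide monotherapy are excluded from the cohort upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .registry import PatientTimeline

ONE_DAY = pd.Timedelta(days=1)


def _day_number(ts: pd.Timestamp) -> int:
    """Calendar date as integer days since the unix epoch."""
    return int(pd.Timestamp(ts).to_datetime64().astype("datetime64[D]").astype(int))


def _from_day_number(day: int) -> pd.Timestamp:
    return pd.Timestamp(np.datetime64(int(day), "D"))


@dataclass(frozen=True)
class CastrationInterval:
    """A period during which the patient counts as castrated.

    ``end`` is None for open-ended intervals (surgical castration, or
    medical castration with coverage running to the end of records).
    """

    patient_id: str
    start: pd.Timestamp
    end: pd.Timestamp | None
    kind: str  # "medical" | "surgical"

    def contains(self, date: pd.Timestamp, slack_days: int = 0) -> bool:
        if date < self.start:
            return False
        if self.end is None:
            return True
        return date <= self.end + pd.Timedelta(days=slack_days)


def _gnrh_fills(dispensations: pd.DataFrame) -> pd.DataFrame:
    return dispensations[dispensations["drug_class"] == "GnRH"]


def _supply_intervals(fills: pd.DataFrame) -> list[tuple[int, int]]:
    """Merged half-open [start, end) day intervals of drug supply.

    Days are integer offsets from an arbitrary epoch (ns since 1970 // day).
    """
    if fills.empty:
        return []
    start = fills["date"].values.astype("datetime64[D]").astype(int)
    end = start + fills["days_supplied"].to_numpy(int)
    order = np.argsort(start, kind="stable")
    merged: list[tuple[int, int]] = []
    for s, e in zip(start[order], end[order]):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((int(s), int(e)))
    return merged


def coverage_days(dispensations: pd.DataFrame,
                  window_start: pd.Timestamp,
                  window_end: pd.Timestamp) -> int:
    """Days in [window_start, window_end) covered by >=1 supply period.

    Overlapping fills count once (union, not sum).
    """
    if window_start >= window_end:
        raise ValueError("window_start must precede window_end")
    ws = _day_number(window_start)
    we = _day_number(window_end)
    total = 0
    for s, e in _supply_intervals(dispensations):
        total += max(0, min(e, we) - max(s, ws))
    return total


def medical_castration_start(t: PatientTimeline,
                             cfg: AnalysisConfig) -> pd.Timestamp | None:
    """Earliest date on which the 3-months-in-6 criterion is fulfilled.

    Returns the first day d such that the 183-day window ending at d holds
    at least 90 covered days — necessarily a covered day, the 90th of that
    window.  None if the criterion is never met.
    """
    intervals = _supply_intervals(_gnrh_fills(t.dispensations))
    if not intervals:
        return None
    first, last = intervals[0][0], intervals[-1][1]
    n = last - first
    covered = np.zeros(n, dtype=bool)
    for s, e in intervals:
        covered[s - first:e - first] = True
    w = cfg.castration_window_days
    csum = np.concatenate([[0], np.cumsum(covered)])
    # coverage inside the w-day window ending at day i (inclusive)
    lo = np.maximum(0, np.arange(1, n + 1) - w)
    in_window = csum[1:] - csum[lo]
    hits = np.nonzero((in_window >= cfg.min_castration_days) & covered)[0]
    if len(hits) == 0:
        return None
    return _from_day_number(first + int(hits[0]))


def castration_intervals(t: PatientTimeline,
                         cfg: AnalysisConfig) -> list[CastrationInterval]:
    """All castration intervals for one patient, merged and sorted.

    Surgical: one open interval from the admission date.  Medical: starts
    at ``medical_castration_start``; coverage runs separated by a gap of
    more than ``cfg.grace_days`` are split into separate intervals, each
    closing on its run's last covered day.
    """
    out: list[CastrationInterval] = []
    if t.surgery is not None:
        out.append(CastrationInterval(t.patient_id, pd.Timestamp(t.surgery),
                                      None, "surgical"))

    med_start = medical_castration_start(t, cfg)
    if med_start is not None:
        supply = _supply_intervals(_gnrh_fills(t.dispensations))
        # merge supply runs whose gap is within grace
        runs: list[list[int]] = []
        for s, e in supply:
            if runs and s - runs[-1][1] <= cfg.grace_days:
                runs[-1][1] = max(runs[-1][1], e)
            else:
                runs.append([s, e])
        start_day = _day_number(med_start)
        for s, e in runs:
            if e <= start_day:
                continue  # run exhausted before castration was established
            s = max(s, start_day)
            out.append(CastrationInterval(
                t.patient_id,
                _from_day_number(s),
                _from_day_number(e - 1),  # last covered day
                "medical",
            ))

    out.sort(key=lambda iv: iv.start)
    # drop medical intervals swallowed by an earlier open surgical interval
    merged: list[CastrationInterval] = []
    for iv in out:
        if merged and merged[-1].end is None and iv.start >= merged[-1].start:
            continue
        merged.append(iv)
    return merged


def first_castration_event(t: PatientTimeline) -> pd.Timestamp | None:
    """Date of the first castration exposure: first GnRH fill or surgery.

    Used by the inclusion rule "treated with GnRH for the first time after
    2006-01-01" (applied to the first castration event so that surgically
    castrated men without GnRH records are handled the same way).
    """
    dates = []
    fills = _gnrh_fills(t.dispensations)
    if len(fills):
        dates.append(fills["date"].min())
    if t.surgery is not None:
        dates.append(pd.Timestamp(t.surgery))
    return min(dates) if dates else None
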