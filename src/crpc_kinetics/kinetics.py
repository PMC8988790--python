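"""PSA kinetics after castration: doubling time, halving time, landmarks.

PSA doubling time (PSA-DT) is estimated as ln 2 divided by the slope of an
ordinary least-squares fit of ln(PSA) on time in days, over the regrowth
window [nadir date, CRPC date] inclusive.  A non-positive slope yields an
infinite doubling time.  A two-point estimator (nadir and triggering
measurements only) is available as ``method="two_point"`` for sensitivity
analysis.  PSA halving time applies the same fit to the decay window
[castration start, nadir date]; it is "not applicable" when PSA never fell
below its value at castration start or the fitted slope is non-negative.

Continuous variables are binned into the categorical levels used for
baseline tables and Cox models.  Month-denominated bins use 30.44 days per
month; printed category names like "1-2 months" / "3-4 months" are rounded
labels of contiguous intervals, with internal edges placed at the midpoints
(1, 2.5, 4.5, 6.5, 12 months for PSA-DT), left-open right-closed.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import DAYS_PER_MONTH
from .detect import CrpcEvent
from .registry import PatientTimeline

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer than two usable (positive) PSA values in the fit window."""


def _log_slope_per_day(dates: pd.Series, values: pd.Series) -> float:
    """OLS slope of ln(value) on days; drops non-positive values."""
    values = np.asarray(values, dtype=float)
    days = (pd.to_datetime(dates) - pd.to_datetime(dates).iloc[0]).dt.days.to_numpy(float)
    keep = values > 0
    if not keep.all():
        log.info("dropping %d non-positive PSA value(s) from kinetics fit",
                 int((~keep).sum()))
    days, values = days[keep], values[keep]
    if len(values) < 2 or np.ptp(days) == 0:
        raise InsufficientDataError("insufficient points for log-linear fit")
    return float(np.polyfit(days, np.log(values), 1)[0])


def psa_doubling_time(psa: pd.DataFrame, nadir_date: pd.Timestamp,
                      crpc_date: pd.Timestamp, method: str = "ols") -> float:
    """PSA-DT in days over [nadir_date, crpc_date]; +inf if not rising."""
    window = psa[(psa["date"] >= nadir_date) & (psa["date"] <= crpc_date)]
    if method == "ols":
        slope = _log_slope_per_day(window["date"], window["psa_ng_ml"])
    elif method == "two_point":
        w = window[window["psa_ng_ml"] > 0]
        if len(w) < 2:
            raise InsufficientDataError("insufficient points")
        dt_days = (w["date"].iloc[-1] - w["date"].iloc[0]).days
        ratio = w["psa_ng_ml"].iloc[-1] / w["psa_ng_ml"].iloc[0]
        if dt_days == 0:
            raise InsufficientDataError("insufficient points")
        slope = math.log(ratio) / dt_days
    else:
        raise ValueError(f"unknown method {method!r}")
    if slope <= 0:
        return math.inf
    return math.log(2.0) / slope


def psa_halving_time(psa: pd.DataFrame, castration_start: pd.Timestamp,
                     nadir_date: pd.Timestamp, method: str = "ols") -> float:
    """Halving time in days over the decay window; NaN = not applicable."""
    window = psa[(psa["date"] >= castration_start) & (psa["date"] <= nadir_date)]
    window = window[window["psa_ng_ml"] > 0]
    if len(window) < 2:
        raise InsufficientDataError("insufficient points for halving time")
    if window["psa_ng_ml"].min() >= window["psa_ng_ml"].iloc[0]:
        return math.nan  # PSA never fell below its value at castration start
    if method == "two_point":
        dt_days = (window["date"].iloc[-1] - window["date"].iloc[0]).days
        slope = math.log(window["psa_ng_ml"].iloc[-1]
                         / window["psa_ng_ml"].iloc[0]) / dt_days
    else:
        slope = _log_slope_per_day(window["date"], window["psa_ng_ml"])
    if slope >= 0:
        return math.nan
    return math.log(2.0) / abs(slope)


@dataclass
class KineticsSummary:
    """Continuous kinetic variables for one CRPC patient (days / ng/ml)."""

    patient_id: str
    psa_at_gnrh_start: float  # NaN = missing
    psa_at_nadir: float
    psa_at_crpc: float
    psa_dt_days: float        # +inf = flat/falling
    psa_halving_days: float   # NaN = not applicable
    time_from_nadir_days: int
    time_from_gnrh_days: int
    time_from_dx_days: int
    crpc_year: int
    age_at_crpc: float


def compute_kinetics(t: PatientTimeline, event: CrpcEvent,
                     castration_start: pd.Timestamp,
                     dt_method: str = "ols") -> KineticsSummary:
    """All kinetic variables for one patient with a detected CRPC event."""
    psa = t.psa
    nadir = event.nadir

    # PSA at castration start: latest measurement in [start-90d, start+30d]
    lo = castration_start - pd.Timedelta(days=90)
    hi = castration_start + pd.Timedelta(days=30)
    near = psa[(psa["date"] >= lo) & (psa["date"] <= hi)]
    psa_at_start = float(near["psa_ng_ml"].iloc[-1]) if len(near) else math.nan

    dt_days = psa_doubling_time(psa, nadir.nadir_date, event.crpc_date,
                                method=dt_method)
    try:
        halving = psa_halving_time(psa, castration_start, nadir.nadir_date,
                                   method=dt_method)
    except InsufficientDataError:
        halving = math.nan

    dx_date = t.diagnosis["dx_date"]
    age_at_dx = float(t.diagnosis["age_at_dx"])
    age_at_crpc = age_at_dx + (event.crpc_date - dx_date).days / 365.25
    return KineticsSummary(
        patient_id=t.patient_id,
        psa_at_gnrh_start=psa_at_start,
        psa_at_nadir=nadir.nadir_value,
        psa_at_crpc=event.psa_at_crpc,
        psa_dt_days=dt_days,
        psa_halving_days=halving,
        time_from_nadir_days=(event.crpc_date - nadir.nadir_date).days,
        time_from_gnrh_days=(event.crpc_date - castration_start).days,
        time_from_dx_days=(event.crpc_date - dx_date).days,
        crpc_year=int(event.crpc_date.year),
        age_at_crpc=age_at_crpc,
    )


# ---------------------------------------------------------------------------
# Categorical binning
# ---------------------------------------------------------------------------

def _bin(value: float, edges: list[float], labels: list[str]) -> str:
    """Left-open right-closed bins: value in (edges[k-1], edges[k]] -> labels[k]."""
    return labels[bisect_left(edges, value)]


def _months(days: float) -> float:
    return days / DAYS_PER_MONTH


PSA_DT_LABELS = ["<=1 month", "1-2 months", "3-4 months", "5-6 months",
                 "7-12 months", "1+ years"]
PSA_DT_EDGES_MONTHS = [1.0, 2.5, 4.5, 6.5, 12.0]

HALVING_LABELS = ["<=1 month", "1-2 months", "3-12 months", "1+ years"]
HALVING_EDGES_MONTHS = [1.0, 2.5, 12.0]

PSA_CRPC_LABELS = ["<=3 ng/ml", "3-5 ng/ml", "5-10 ng/ml", "10-20 ng/ml",
                   "20-50 ng/ml", "50-100 ng/ml", "100-500 ng/ml", "500+ ng/ml"]
PSA_CRPC_EDGES = [3.0, 5.0, 10.0, 20.0, 50.0, 100.0, 500.0]

PSA_NADIR_LABELS = ["<=0.5 ng/ml", "0.5-1 ng/ml", "1-3 ng/ml", "3-5 ng/ml",
                    "5-10 ng/ml", "10-20 ng/ml", "20-50 ng/ml", "50+ ng/ml"]
PSA_NADIR_EDGES = [0.5, 1.0, 3.0, 5.0, 10.0, 20.0, 50.0]

PSA_START_LABELS = ["<=10 ng/ml", "10-20 ng/ml", "20-50 ng/ml", "50-100 ng/ml",
                    "100-500 ng/ml", "500+ ng/ml"]
PSA_START_EDGES = [10.0, 20.0, 50.0, 100.0, 500.0]

TIME_NADIR_LABELS = ["0-3 months", "4-6 months", "7-12 months", "1-2 years",
                     "2+ years"]
TIME_NADIR_EDGES_MONTHS = [3.5, 6.5, 12.0, 24.0]

TIME_GNRH_LABELS = ["0-6 months", "7-12 months", "1-2 years", "2+ years"]
TIME_GNRH_EDGES_MONTHS = [6.5, 12.0, 24.0]

TIME_DX_LABELS = ["0-6 months", "7-12 months", "1-2 years", "2-4 years",
                  "4+ years"]
TIME_DX_EDGES_MONTHS = [6.5, 12.0, 24.0, 48.0]

AGE_LABELS = ["<=65", "66-70", "71-75", "76-80", "81-85", "86+"]
AGE_EDGES = [65.0, 70.0, 75.0, 80.0, 85.0]

CRPC_YEAR_LABELS = ["2006-2009", "2010-2013", "2014-2017"]


def bin_crpc_year(year: int) -> str:
    if year <= 2009:
        return CRPC_YEAR_LABELS[0]
    if year <= 2013:
        return CRPC_YEAR_LABELS[1]
    return CRPC_YEAR_LABELS[2]


def bin_variables(k: KineticsSummary) -> dict[str, str]:
    """Map each continuous variable to its printed categorical level."""
    out = {
        "patient_id": k.patient_id,
        "psa_dt_cat": _bin(_months(k.psa_dt_days), PSA_DT_EDGES_MONTHS,
                           PSA_DT_LABELS),
        "psa_halving_cat": ("Not applicable" if math.isnan(k.psa_halving_days)
                            else _bin(_months(k.psa_halving_days),
                                      HALVING_EDGES_MONTHS, HALVING_LABELS)),
        "psa_at_crpc_cat": _bin(k.psa_at_crpc, PSA_CRPC_EDGES, PSA_CRPC_LABELS),
        "psa_at_nadir_cat": _bin(k.psa_at_nadir, PSA_NADIR_EDGES,
                                 PSA_NADIR_LABELS),
        "psa_at_gnrh_cat": ("Missing" if math.isnan(k.psa_at_gnrh_start)
                            else _bin(k.psa_at_gnrh_start, PSA_START_EDGES,
                                      PSA_START_LABELS)),
        "time_from_nadir_cat": _bin(_months(k.time_from_nadir_days),
                                    TIME_NADIR_EDGES_MONTHS, TIME_NADIR_LABELS),
        "time_from_gnrh_cat": _bin(_months(k.time_from_gnrh_days),
                                   TIME_GNRH_EDGES_MONTHS, TIME_GNRH_LABELS),
        "time_from_dx_cat": _bin(_months(k.time_from_dx_days),
                                 TIME_DX_EDGES_MONTHS, TIME_DX_LABELS),
        "crpc_year_cat": bin_crpc_year(k.crpc_year),
        "age_cat": _bin(k.age_at_crpc, AGE_EDGES, AGE_LABELS),
    }
    return out


def kinetics_table(summaries: list[KineticsSummary]) -> pd.DataFrame:
    """One row per patient: continuous values plus category labels."""
    cont = pd.DataFrame([asdict(k) for k in summaries])
    cats = pd.DataFrame([bin_variables(k) for k in summaries])
    return cont.merge(cats, on="patient_id")
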