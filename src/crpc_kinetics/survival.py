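"""Survival stage: KM medians, cause-specific Cox models, Harrell's C,
and Aalen-Johansen cumulative incidence under competing risks.

Time zero is the CRPC date; follow-up ends at death, migration, or the
region's administrative end of follow-up.  Death from prostate cancer and
death from other causes are competing events.  Cox models for PC-specific
mortality are cause-specific (the competing cause is censored); ties are
handled with Efron's approximation, as befits registry data with many
same-day deaths.

The Aalen-Johansen estimator is computed directly from the event table:
at each distinct event time s, cause k's incidence increments by
S(s-) * d_k(s) / n(s) with S the all-cause Kaplan-Meier survivor function,
so surv + cif_pc + cif_other = 1 holds to machine precision at every step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times

log = logging.getLogger(__name__)

PC_DEATH = "pc_death"
OTHER_DEATH = "other_death"
CENSORED = "censored"


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_median(times: np.ndarray, events: np.ndarray
              ) -> tuple[float, float, float] | None:
    """KM median survival with 95% log-log CI, or None if undefined.

    ``events`` is 1 for death (any cause), 0 for censored.  Times in days.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() == 0:
        log.warning("all observations censored; median undefined")
        return None
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    median = kmf.median_survival_time_
    if not np.isfinite(median):
        return None
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return float(median), lo, hi


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Per-level hazard ratios with Wald 95% CIs.

    ``table`` columns: covariate, level, hr, ci_low, ci_high, reference.
    Reference levels appear with hr == 1 and the flag set.
    """

    table: pd.DataFrame
    model_type: str  # "univariable" | "multivariable"
    outcome: str     # "overall" | "pc_specific"
    concordance: float

    def hr(self, covariate: str, level: str) -> float:
        m = (self.table["covariate"] == covariate) & (self.table["level"] == level)
        return float(self.table.loc[m, "hr"].iloc[0])

    def ci(self, covariate: str, level: str) -> tuple[float, float]:
        m = (self.table["covariate"] == covariate) & (self.table["level"] == level)
        row = self.table.loc[m].iloc[0]
        return float(row["ci_low"]), float(row["ci_high"])


def _event_indicator(status: pd.Series, outcome: str) -> pd.Series:
    if outcome == "overall":
        return status.isin([PC_DEATH, OTHER_DEATH]).astype(int)
    if outcome == "pc_specific":
        return (status == PC_DEATH).astype(int)
    raise ValueError(f"unknown outcome {outcome!r}")


def cox_fit(records: pd.DataFrame, covariates: dict[str, str],
            outcome: str = "pc_specific") -> CoxResult:
    """Cause-specific Cox model over categorical covariates.

    ``records`` needs columns ``time`` (days), ``status`` (pc_death /
    other_death / censored) and one column per covariate.  ``covariates``
    maps column name -> reference level.  Levels without any event are
    merged into the reference with a warning (degenerate dummies would
    otherwise separate).
    """
    df = records.copy()
    df["event"] = _event_indicator(df["status"], outcome)
    design = df[["time", "event"]].copy()
    rows = []
    for cov, ref in covariates.items():
        levels = [lv for lv in pd.unique(df[cov]) if lv != ref]
        kept = []
        for lv in sorted(map(str, levels)):
            mask = df[cov].astype(str) == lv
            if df.loc[mask, "event"].sum() == 0 or mask.all():
                log.warning("covariate %s level %r has no events; "
                            "merged into reference %r", cov, lv, ref)
                continue
            design[f"{cov}::{lv}"] = mask.astype(float)
            kept.append(lv)
        rows.append((cov, ref, kept))

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(design, duration_col="time", event_col="event")
    summary = cph.summary

    out = []
    for cov, ref, kept in rows:
        out.append({"covariate": cov, "level": ref, "hr": 1.0,
                    "ci_low": np.nan, "ci_high": np.nan, "reference": True})
        for lv in kept:
            s = summary.loc[f"{cov}::{lv}"]
            out.append({
                "covariate": cov, "level": lv,
                "hr": float(np.exp(s["coef"])),
                "ci_low": float(np.exp(s["coef lower 95%"])),
                "ci_high": float(np.exp(s["coef upper 95%"])),
                "reference": False,
            })
    model_type = "univariable" if len(covariates) == 1 else "multivariable"
    return CoxResult(pd.DataFrame(out), model_type, outcome,
                     float(cph.concordance_index_))


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def harrell_c(times: np.ndarray, events: np.ndarray,
              marker: np.ndarray) -> float:
    """Concordance of a risk marker with event ordering.

    A pair is comparable when the earlier time is an observed event;
    concordant when the earlier-event member has the higher marker; marker
    ties count 0.5.  Higher marker = higher risk.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    marker = np.asarray(marker, float)
    idx = np.nonzero(events)[0]
    concordant = 0.0
    comparable = 0
    for i in idx:
        later = times > times[i]
        comparable += int(later.sum())
        concordant += (marker[i] > marker[later]).sum()
        concordant += 0.5 * (marker[i] == marker[later]).sum()
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return float(concordant / comparable)


# ---------------------------------------------------------------------------
# Aalen-Johansen cumulative incidence
# ---------------------------------------------------------------------------

@dataclass
class CIFCurve:
    """Cumulative incidence by cause on a common step grid."""

    times: np.ndarray      # distinct event times, prefixed with 0
    cif_pc: np.ndarray
    cif_other: np.ndarray
    surv: np.ndarray

    def at(self, t: float) -> tuple[float, float, float]:
        """(cif_pc, cif_other, surv) at time t (right-continuous steps)."""
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.cif_pc[i]), float(self.cif_other[i]), float(self.surv[i])

    @property
    def final(self) -> tuple[float, float, float]:
        return float(self.cif_pc[-1]), float(self.cif_other[-1]), float(self.surv[-1])


def aalen_johansen(times: np.ndarray, statuses: np.ndarray) -> CIFCurve:
    """Aalen-Johansen estimator for two competing causes of death."""
    times = np.asarray(times, float)
    statuses = np.asarray(statuses)
    order = np.argsort(times, kind="stable")
    times, statuses = times[order], statuses[order]
    n = len(times)

    event_times = np.unique(times[(statuses == PC_DEATH)
                                  | (statuses == OTHER_DEATH)])
    grid = [0.0]
    cif_pc, cif_other, surv = [0.0], [0.0], [1.0]
    s = 1.0
    for t in event_times:
        at_risk = int((times >= t).sum())
        d_pc = int(((times == t) & (statuses == PC_DEATH)).sum())
        d_other = int(((times == t) & (statuses == OTHER_DEATH)).sum())
        inc_pc = s * d_pc / at_risk
        inc_other = s * d_other / at_risk
        s = s - inc_pc - inc_other
        grid.append(float(t))
        cif_pc.append(cif_pc[-1] + inc_pc)
        cif_other.append(cif_other[-1] + inc_other)
        surv.append(s)
    return CIFCurve(np.array(grid), np.array(cif_pc), np.array(cif_other),
                    np.array(surv))


def cif_by_group(records: pd.DataFrame, group_col: str = "risk_group"
                 ) -> dict[object, CIFCurve]:
    """Aalen-Johansen curve per group; empty groups are skipped."""
    out: dict[object, CIFCurve] = {}
    for g, sub in records.groupby(group_col, sort=True):
        if len(sub) == 0:  # pragma: no cover
            log.warning("group %r empty; skipped", g)
            continue
        out[g] = aalen_johansen(sub["time"].to_numpy(),
                                sub["status"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Baseline table
# ---------------------------------------------------------------------------

BASELINE_VARIABLES = [
    ("Age", "age_cat"),
    ("Time from nadir", "time_from_nadir_cat"),
    ("Time from GnRH", "time_from_gnrh_cat"),
    ("Time from diagnosis", "time_from_dx_cat"),
    ("CRPC year", "crpc_year_cat"),
    ("PSA at GnRH start", "psa_at_gnrh_cat"),
    ("PSA at nadir", "psa_at_nadir_cat"),
    ("PSA at CRPC", "psa_at_crpc_cat"),
    ("PSA halving time", "psa_halving_cat"),
    ("PSA doubling time", "psa_dt_cat"),
    ("M stage", "m_stage"),
    ("Risk group", "risk_group"),
]


def baseline_table(cohort: pd.DataFrame,
                   strata_col: str = "adt_context") -> pd.DataFrame:
    """Counts and percentages per category, stratified primary/secondary.

    Missing values are rendered as explicit "Missing" rows.  Percentages
    are within stratum (columns: each stratum plus "All").
    """
    strata = list(pd.unique(cohort[strata_col])) if strata_col in cohort else []
    rows = []
    for var_label, col in BASELINE_VARIABLES:
        if col not in cohort.columns:
            continue
        values = cohort[col].astype(object).where(cohort[col].notna(), "Missing")
        for level in sorted(values.unique(), key=str):
            row: dict[str, object] = {"variable": var_label, "level": level}
            sel = values == level
            for stratum in strata:
                in_s = cohort[strata_col] == stratum
                n = int((sel & in_s).sum())
                denom = int(in_s.sum())
                row[f"{stratum}_n"] = n
                row[f"{stratum}_pct"] = round(100.0 * n / denom, 1) if denom else 0.0
            row["all_n"] = int(sel.sum())
            row["all_pct"] = round(100.0 * sel.sum() / len(cohort), 1)
            rows.append(row)
    return pd.DataFrame(rows)
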