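"""Synthetic patient-registry generator with known ground truth.

Emulates the statistical structure the analysis assumes for a
Swedish-style prostate-cancer registry: PSA decline to a nadir after ADT
start, patient-specific exponential regrowth with a true doubling time,
multiplicative log-normal measurement noise, irregular sampling,
prescription-refill behaviour with imperfect adherence, surgical
castration for a fraction of primary-ADT men, and competing risks of
prostate-cancer death versus other-cause death whose hazards are
log-linear in the risk score and in age respectively.

The noise-free trajectory is bi-exponential with a single nadir::

    v(t) = psa0 * (nadir/psa0)^(t/t_nadir)          for 0 <= t < t_nadir
    v(t) = nadir * 2^((t - t_nadir)/DT)             for t >= t_nadir

Every patient's ground truth (nadir, doubling time, the first date the
noise-free curve satisfies the CRPC rule whilst castrated, event time and
cause) is recoverable from the truth table, so downstream stages can be
tested against it.

Randomness: one global seed feeds a per-patient stream seeded with
``(seed, patient_index)``, so enlarging the cohort never reshuffles
existing patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .config import MEDICAL_CASTRATION_MIN_DAYS
from .registry import PatientTimeline, write_registry

DOUBLING_FLOOR = 2.0
ABSOLUTE_RISE = 5.0
LN2 = math.log(2.0)


@dataclass(frozen=True)
class LogNormal:
    """Log-normal distribution parameterised by median and log-sd."""

    median: float
    sigma: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.median * math.exp(self.sigma * rng.standard_normal()))


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults emulate a registry cohort of elderly men starting ADT with a
    broad PSA distribution (median 40 ng/ml), deep but variable nadirs
    (median 5% of the starting value, a tail that never declines), a
    doubling-time distribution centred between 3 and 6 months, quarterly
    PSA testing and 90-day GnRH refills.  Event-time hazards are
    calibrated so that group-level survival reproduces the qualitative
    structure of the published cohort (see docs/methods.md).
    """

    n_patients: int = 500
    seed: int = 0
    # trajectory
    psa_at_adt_start: LogNormal = field(default_factory=lambda: LogNormal(40.0, 1.4))
    nadir_fraction: LogNormal = field(default_factory=lambda: LogNormal(0.05, 1.6))
    nadir_time_days: LogNormal = field(default_factory=lambda: LogNormal(180.0, 0.5))
    true_doubling_time: LogNormal = field(default_factory=lambda: LogNormal(140.0, 0.7))
    measurement_cv: float = 0.15
    # sampling & treatment
    sampling_interval_days: float = 75.0
    refill_interval: int = 90
    refill_adherence: float = 0.95
    surgical_fraction: float = 0.10
    # event-time model (per-day log hazards)
    hazard_pc_intercept: float = -5.49
    hazard_pc_slope: float = 0.41
    hazard_other_intercept: float = -14.39
    hazard_other_age_slope: float = 0.08
    migration_rate_per_year: float = 0.01
    # cohort composition
    m1_fraction: float = 0.27
    curative_fraction: float = 0.13
    deferred_fraction: float = 0.24
    neoadjuvant_fraction: float = 0.03
    mean_age_at_dx: float = 76.0
    sd_age_at_dx: float = 8.0
    dx_window: tuple[str, str] = ("2005-07-01", "2012-12-31")
    followup_end_by_region: dict[str, str] = field(default_factory=lambda: {
        "uppsala": "2014-12-31", "stockholm": "2016-12-31"})

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in ("refill_adherence", "surgical_fraction", "m1_fraction",
                     "curative_fraction", "deferred_fraction",
                     "neoadjuvant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be non-negative")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for name in ("psa_at_adt_start", "nadir_fraction", "nadir_time_days",
                     "true_doubling_time"):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = LogNormal(**kwargs[name])
        if "dx_window" in kwargs:
            kwargs["dx_window"] = tuple(kwargs["dx_window"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["dx_window"] = list(d["dx_window"])
        return d


@dataclass
class TruePatientState:
    """Noise-free ground truth for one simulated patient."""

    patient_id: str
    psa0: float
    nadir_value: float
    nadir_rel_days: float      # days from ADT start to nadir
    dt_days: float             # +inf = never regrows
    adt_start: pd.Timestamp
    castration_kind: str       # "medical" | "surgical"
    castration_start: pd.Timestamp
    true_crpc_date: pd.Timestamp | None = None
    true_psa_at_crpc: float = math.nan
    true_score: float = math.nan
    event_date: pd.Timestamp | None = None
    cause: str = "censored"

    @property
    def nadir_date(self) -> pd.Timestamp:
        return self.adt_start + pd.Timedelta(days=round(self.nadir_rel_days))


def noise_free_value(state: TruePatientState, rel_days: float) -> float:
    """Model PSA at ``rel_days`` after ADT start, without noise."""
    psa0, nadir, tn = state.psa0, state.nadir_value, state.nadir_rel_days
    if rel_days < 0:
        return psa0
    if nadir >= psa0:  # never declines
        nadir, tn = psa0, 0.0
    if rel_days < tn:
        return psa0 * (nadir / psa0) ** (rel_days / tn)
    if math.isinf(state.dt_days):
        return nadir
    return nadir * 2.0 ** ((rel_days - tn) / state.dt_days)


def true_crpc_rel_days(state: TruePatientState,
                       eligible_from_rel: float | None = None) -> float:
    """First time the noise-free curve satisfies the CRPC rule, relative
    to ADT start; +inf if never.

    The running nadir is tracked from ``eligible_from_rel`` (default: the
    castration start), matching the detector: if eligibility begins after
    the curve's minimum, the reference nadir is the curve value at
    eligibility start, because earlier values can never be observed whilst
    castrated.  During decline the running nadir equals the current value,
    so the rule can only fire during regrowth, where it is closed-form.
    """
    if math.isinf(state.dt_days):
        return math.inf
    if eligible_from_rel is None:
        eligible_from_rel = float(
            (state.castration_start - state.adt_start).days)
    tn = 0.0 if state.nadir_value >= state.psa0 else state.nadir_rel_days
    t0 = max(tn, eligible_from_rel)
    n = noise_free_value(state, t0)
    t_doubling = t0 + state.dt_days * math.log2(max(2.0 * n, DOUBLING_FLOOR) / n)
    t_absolute = t0 + state.dt_days * math.log2((n + ABSOLUTE_RISE) / n)
    return min(t_doubling, t_absolute)


def simulate_psa_trajectory(state: TruePatientState, dates: pd.DatetimeIndex,
                            cv: float, rng: np.random.Generator) -> pd.DataFrame:
    """Observed PSA series at ``dates``: model value times log-normal noise."""
    if state.dt_days <= 0:
        raise ValueError("doubling time must be positive")
    rel = (dates - state.adt_start).days.to_numpy(float)
    model = np.array([noise_free_value(state, r) for r in rel])
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        noise = np.exp(sigma * rng.standard_normal(len(model)))
    else:
        noise = 1.0
    return pd.DataFrame({"date": dates, "psa_ng_ml": model * noise})


def hazard_pc(score: float, cfg: SimConfig) -> float:
    """Per-day PC-death hazard, log-linear in the risk score."""
    return math.exp(cfg.hazard_pc_intercept + cfg.hazard_pc_slope * score)


def hazard_other(age: float, cfg: SimConfig) -> float:
    """Per-day other-cause hazard, log-linear (Gompertz-like) in age."""
    return math.exp(cfg.hazard_other_intercept + cfg.hazard_other_age_slope * age)


def simulate_event_times(score: float, age: float, cfg: SimConfig,
                         rng: np.random.Generator) -> tuple[float, str]:
    """Competing exponential draw: (days from time zero, cause)."""
    h_pc = hazard_pc(score, cfg)
    h_other = hazard_other(age, cfg)
    t_pc = rng.exponential(1.0 / h_pc) if h_pc > 0 else math.inf
    t_other = rng.exponential(1.0 / h_other) if h_other > 0 else math.inf
    if t_pc <= t_other:
        return float(t_pc), "pc_death"
    return float(t_other), "other_death"


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_GGG_LEVELS = ["1", "2", "3", "4", "5", "WHO-only", "missing"]
_GGG_PROBS = [0.10, 0.11, 0.15, 0.19, 0.28, 0.04, 0.13]
_T_LEVELS = ["T1", "T2", "T3", "T4", "missing"]
_T_PROBS = [0.18, 0.27, 0.42, 0.10, 0.03]
_N_LEVELS = ["N0", "N1", "NX"]
_N_PROBS = [0.07, 0.07, 0.86]


def _simulate_patient(i: int, cfg: SimConfig, rng: np.random.Generator
                      ) -> tuple[PatientTimeline, TruePatientState]:
    pid = f"P{i:05d}"
    region = "uppsala" if rng.random() < 0.5 else "stockholm"
    followup_end = pd.Timestamp(cfg.followup_end_by_region[region])
    age = float(np.clip(cfg.mean_age_at_dx
                        + cfg.sd_age_at_dx * rng.standard_normal(), 50, 95))

    w0, w1 = (pd.Timestamp(d) for d in cfg.dx_window)
    dx_date = w0 + pd.Timedelta(days=int(rng.integers(0, (w1 - w0).days + 1)))

    u = rng.random()
    if u < cfg.curative_fraction:
        treatment = "curative"
        delay = int(rng.uniform(550, 1825))
    elif u < cfg.curative_fraction + cfg.deferred_fraction:
        treatment = "deferred"
        delay = int(rng.exponential(730))
    else:
        treatment = "primary_adt"
        delay = int(rng.uniform(0, 60))
    adt_start = dx_date + pd.Timedelta(days=delay)

    surgical = treatment == "primary_adt" and rng.random() < cfg.surgical_fraction
    castration_start = adt_start if surgical else (
        adt_start + pd.Timedelta(days=MEDICAL_CASTRATION_MIN_DAYS - 1))

    psa0 = cfg.psa_at_adt_start.sample(rng)
    frac = cfg.nadir_fraction.sample(rng)
    nadir = psa0 * min(frac, 1.0)
    tn = cfg.nadir_time_days.sample(rng)
    dt = cfg.true_doubling_time.sample(rng)
    state = TruePatientState(pid, psa0, nadir, tn, dt, adt_start,
                             "surgical" if surgical else "medical",
                             castration_start)
    if frac >= 1.0:
        state.dt_days = math.inf  # never declines, never regrows

    # ground-truth CRPC date: rule on the noise-free curve, first eligible day
    crpc_rel = true_crpc_rel_days(state)  # accounts for castration start

    # competing clocks (days from ADT start)
    t_other = rng.exponential(1.0 / hazard_other(age, cfg))
    t_migration = (rng.exponential(365.25 / cfg.migration_rate_per_year)
                   if cfg.migration_rate_per_year > 0 else math.inf)
    end_rel = (followup_end - adt_start).days
    if math.isfinite(crpc_rel):
        true_psa = noise_free_value(state, crpc_rel)
        score = math.log(true_psa) - 1.40 * math.log(state.dt_days)
        t_pc_from_crpc = rng.exponential(1.0 / hazard_pc(score, cfg))
        t_pc = crpc_rel + t_pc_from_crpc
    else:
        true_psa, score, t_pc = math.nan, math.nan, math.inf

    horizon = min(t_pc, t_other, t_migration, end_rel)
    if horizon == t_pc:
        cause, censor_reason = "pc_death", "none"
    elif horizon == t_other:
        cause, censor_reason = "other_death", "none"
    elif horizon == t_migration:
        cause, censor_reason = "censored", "migration"
    else:
        cause, censor_reason = "censored", "end_of_followup"
    event_date = adt_start + pd.Timedelta(days=int(math.ceil(max(horizon, 1))))

    state.event_date = event_date
    state.cause = cause
    if math.isfinite(crpc_rel) and crpc_rel < horizon:
        state.true_crpc_date = adt_start + pd.Timedelta(days=round(crpc_rel))
        state.true_psa_at_crpc = true_psa
        state.true_score = score
    else:
        state.true_crpc_date = None

    # dispensations: 90-day GnRH refills with imperfect adherence
    disp_rows = []
    if not surgical:
        day = 0
        while adt_start + pd.Timedelta(days=day) < event_date:
            if day == 0 or rng.random() < cfg.refill_adherence:
                disp_rows.append({
                    "patient_id": pid,
                    "date": adt_start + pd.Timedelta(days=day),
                    "drug_class": "GnRH",
                    "days_supplied": cfg.refill_interval,
                })
            day += cfg.refill_interval
    dispensations = pd.DataFrame(
        disp_rows, columns=["patient_id", "date", "drug_class", "days_supplied"])

    # PSA sampling: one test at diagnosis, then irregular tests from ADT start
    sample_days = [float((dx_date - adt_start).days)]
    t = 0.0
    while True:
        t += cfg.sampling_interval_days * rng.uniform(0.5, 1.5)
        if adt_start + pd.Timedelta(days=int(t)) >= event_date:
            break
        sample_days.append(t)
    dates = pd.DatetimeIndex(
        [adt_start + pd.Timedelta(days=int(d)) for d in sample_days]).unique()
    psa = simulate_psa_trajectory(state, dates, cfg.measurement_cv, rng)
    psa.insert(0, "patient_id", pid)
    psa = psa.sort_values("date").reset_index(drop=True)

    diagnosis = pd.Series({
        "patient_id": pid,
        "dx_date": dx_date,
        "t_stage": _choice(rng, _T_LEVELS, _T_PROBS),
        "n_stage": _choice(rng, _N_LEVELS, _N_PROBS),
        "m_stage": _choice(rng, ["M1", "M0", "MX"],
                           [cfg.m1_fraction, 0.33,
                            1.0 - cfg.m1_fraction - 0.33]),
        "gleason_grade_group": _choice(rng, _GGG_LEVELS, _GGG_PROBS),
        "psa_at_dx": round(psa0 * rng.uniform(0.8, 1.2), 2),
        "primary_treatment": treatment,
        "neoadjuvant": bool(treatment == "curative"
                            and rng.random() < cfg.neoadjuvant_fraction / max(
                                cfg.curative_fraction, 1e-9)),
        "age_at_dx": round(age, 1),
        "region": region,
        "followup_end": followup_end,
    })
    vital = pd.Series({
        "patient_id": pid,
        "event_date": event_date,
        "cause": cause,
        "censor_reason": censor_reason,
    })
    timeline = PatientTimeline(
        patient_id=pid, psa=psa, dispensations=dispensations,
        surgery=adt_start if surgical else None,
        diagnosis=diagnosis, vital=vital)
    return timeline, state


def _choice(rng: np.random.Generator, levels: list[str],
            probs: list[float]) -> str:
    p = np.asarray(probs, float)
    return levels[int(rng.choice(len(levels), p=p / p.sum()))]


def truth_table(states: list[TruePatientState]) -> pd.DataFrame:
    rows = []
    for s in states:
        rows.append({
            "patient_id": s.patient_id,
            "psa_at_adt_start": s.psa0,
            "true_nadir_value": min(s.nadir_value, s.psa0),
            "true_nadir_date": s.nadir_date if s.nadir_value < s.psa0 else s.adt_start,
            "true_dt_days": s.dt_days,
            "adt_start": s.adt_start,
            "castration_kind": s.castration_kind,
            "castration_start": s.castration_start,
            "true_crpc_date": s.true_crpc_date,
            "true_psa_at_crpc": s.true_psa_at_crpc,
            "true_score": s.true_score,
            "event_date": s.event_date,
            "cause": s.cause,
        })
    return pd.DataFrame(rows)


def generate_cohort(cfg: SimConfig
                    ) -> tuple[dict[str, PatientTimeline], pd.DataFrame]:
    """Simulate a full registry bundle plus its ground-truth table.

    Identical configs (including seed) give identical bundles.
    """
    timelines: dict[str, PatientTimeline] = {}
    states: list[TruePatientState] = []
    for i in range(cfg.n_patients):
        rng = np.random.default_rng([cfg.seed, i])
        t, s = _simulate_patient(i, cfg, rng)
        timelines[t.patient_id] = t
        states.append(s)
    return timelines, truth_table(states)


def write_cohort(cfg: SimConfig, outdir: Path | str) -> dict[str, Path]:
    """Write the five registry CSVs plus truth.csv to ``outdir``."""
    outdir = Path(outdir)
    timelines, truth = generate_cohort(cfg)
    written = write_registry(timelines, outdir)
    truth_path = outdir / "truth.csv"
    out = truth.copy()
    for col in ("true_nadir_date", "adt_start", "castration_start",
                "true_crpc_date", "event_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(truth_path, index=False)
    written["truth"] = truth_path
    return written
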