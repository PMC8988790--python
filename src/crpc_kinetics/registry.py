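"""Registry data model: record schemas, CSV readers/writers, validation.

The registry is five per-patient record collections, shipped as plain CSV:

=================  =====================================================
file               columns
=================  =====================================================
psa.csv            patient_id, date, psa_ng_ml
dispensations.csv  patient_id, date, drug_class, days_supplied
surgery.csv        patient_id, admission_date
diagnosis.csv      patient_id, dx_date, t_stage, n_stage, m_stage,
                   gleason_grade_group, psa_at_dx, primary_treatment,
                   neoadjuvant, age_at_dx, region, followup_end
vital.csv          patient_id, event_date, cause, censor_reason
=================  =====================================================

``drug_class`` is one of {GnRH, antiandrogen_mono, other}; only GnRH
dispensations can establish medical castration.  ``cause`` is one of
{pc_death, other_death, censored}.  Dates are ISO-8601 calendar dates.

Same-day duplicate PSA tests are collapsed to the LAST row per
(patient, date) after a stable sort, on the assumption that later lab
entries supersede earlier ones; collapses are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

DRUG_CLASSES = ("GnRH", "antiandrogen_mono", "other")
CAUSES = ("pc_death", "other_death", "censored")
CENSOR_REASONS = ("end_of_followup", "migration", "none")
T_STAGES = ("T1", "T2", "T3", "T4", "missing")
N_STAGES = ("N0", "N1", "NX")
M_STAGES = ("M0", "M1", "MX")
TREATMENTS = ("curative", "primary_adt", "deferred")

REQUIRED_COLUMNS: dict[str, list[str]] = {
    "psa": ["patient_id", "date", "psa_ng_ml"],
    "dispensations": ["patient_id", "date", "drug_class", "days_supplied"],
    "surgery": ["patient_id", "admission_date"],
    "diagnosis": [
        "patient_id", "dx_date", "t_stage", "n_stage", "m_stage",
        "gleason_grade_group", "psa_at_dx", "primary_treatment",
        "neoadjuvant", "age_at_dx", "region", "followup_end",
    ],
    "vital": ["patient_id", "event_date", "cause", "censor_reason"],
}

DATE_COLUMNS: dict[str, list[str]] = {
    "psa": ["date"],
    "dispensations": ["date"],
    "surgery": ["admission_date"],
    "diagnosis": ["dx_date", "followup_end"],
    "vital": ["event_date"],
}

FILENAMES = {name: f"{name}.csv" for name in REQUIRED_COLUMNS}


@dataclass
class Violation:
    """One data-model violation: which record collection, which rule, detail."""

    record: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.record}/{self.rule}] {self.message}"


@dataclass
class PatientTimeline:
    """One patient's full longitudinal record, sorted by date.

    ``psa`` and ``dispensations`` are DataFrames sorted ascending by date;
    ``surgery`` is the admission Timestamp or None; ``diagnosis`` and
    ``vital`` are single Series.
    """

    patient_id: str
    psa: pd.DataFrame
    dispensations: pd.DataFrame
    surgery: pd.Timestamp | None
    diagnosis: pd.Series
    vital: pd.Series

    @property
    def terminal_date(self) -> pd.Timestamp:
        return self.vital["event_date"]

    @property
    def followup_end(self) -> pd.Timestamp:
        return self.diagnosis["followup_end"]


def _parse_dates(df: pd.DataFrame, name: str, cols: Iterable[str],
                 date_format: str) -> pd.DataFrame:
    for col in cols:
        parsed = pd.to_datetime(df[col], format=date_format, errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{name}: unparseable date {df.loc[row, col]!r} in column "
                f"{col!r} at row {row}"
            )
        df[col] = parsed
    return df


def read_table(path: Path | str, name: str,
               date_format: str = "%Y-%m-%d") -> pd.DataFrame:
    """Read one registry CSV, enforcing its column dictionary."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing required column(s) {missing}")
    df = _parse_dates(df, name, DATE_COLUMNS[name], date_format)
    if name == "psa":
        neg = df["psa_ng_ml"] < 0
        if neg.any():
            row = int(neg.idxmax())
            raise ValueError(f"psa: negative PSA value at row {row}")
    if name == "dispensations":
        bad = df["days_supplied"] <= 0
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"dispensations: non-positive days_supplied at row {row}")
    return df


def _collapse_same_day_psa(psa: pd.DataFrame) -> pd.DataFrame:
    # Keep the LAST value per (patient, date) after a stable sort: later
    # lab rows are taken to supersede earlier ones.
    before = len(psa)
    psa = psa.sort_values(["patient_id", "date"], kind="stable")
    psa = psa.drop_duplicates(["patient_id", "date"], keep="last")
    dropped = before - len(psa)
    if dropped:
        log.info("collapsed %d same-day duplicate PSA rows (kept last)", dropped)
    return psa.reset_index(drop=True)


def load_registry(
    paths: Path | str | Mapping[str, Path | str],
    date_format: str = "%Y-%m-%d",
) -> dict[str, PatientTimeline]:
    """Load the five registry CSVs into one PatientTimeline per patient.

    ``paths`` is either a directory containing the standard file names or a
    mapping {table name -> path}.  Malformed input raises ``ValueError``
    naming the offending column or row.
    """
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        paths = {name: root / fn for name, fn in FILENAMES.items()}

    tables = {name: read_table(paths[name], name, date_format)
              for name in REQUIRED_COLUMNS}
    tables["psa"] = _collapse_same_day_psa(tables["psa"])

    timelines: dict[str, PatientTimeline] = {}
    psa_by = dict(iter(tables["psa"].groupby("patient_id", sort=False)))
    disp_by = dict(iter(tables["dispensations"].groupby("patient_id", sort=False)))
    surg_by = tables["surgery"].set_index("patient_id")["admission_date"]
    if surg_by.index.has_duplicates:
        dup = surg_by.index[surg_by.index.duplicated()][0]
        raise ValueError(f"surgery: more than one record for patient {dup!r}")

    empty_psa = tables["psa"].iloc[0:0]
    empty_disp = tables["dispensations"].iloc[0:0]
    for _, dx in tables["diagnosis"].iterrows():
        pid = dx["patient_id"]
        vital_rows = tables["vital"][tables["vital"]["patient_id"] == pid]
        if len(vital_rows) != 1:
            raise ValueError(
                f"vital: expected exactly one terminal record for patient "
                f"{pid!r}, found {len(vital_rows)}"
            )
        psa = psa_by.get(pid, empty_psa).sort_values("date").reset_index(drop=True)
        disp = disp_by.get(pid, empty_disp).sort_values("date").reset_index(drop=True)
        timelines[pid] = PatientTimeline(
            patient_id=pid,
            psa=psa,
            dispensations=disp,
            surgery=surg_by.get(pid, None),
            diagnosis=dx,
            vital=vital_rows.iloc[0],
        )
    return timelines


def write_registry(timelines: Mapping[str, PatientTimeline],
                   outdir: Path | str) -> dict[str, Path]:
    """Write timelines back out as the five standard CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    def _cat(frames: list[pd.DataFrame], name: str) -> pd.DataFrame:
        frames = [f for f in frames if len(f)]
        if not frames:
            return pd.DataFrame(columns=REQUIRED_COLUMNS[name])
        return pd.concat(frames, ignore_index=True)

    psa = _cat([t.psa for t in timelines.values()], "psa")
    disp = _cat([t.dispensations for t in timelines.values()], "dispensations")
    surgery = pd.DataFrame(
        [{"patient_id": t.patient_id, "admission_date": t.surgery}
         for t in timelines.values() if t.surgery is not None],
        columns=REQUIRED_COLUMNS["surgery"],
    )
    diagnosis = pd.DataFrame([t.diagnosis for t in timelines.values()])
    vital = pd.DataFrame([t.vital for t in timelines.values()])
    frames = {"psa": psa, "dispensations": disp, "surgery": surgery,
              "diagnosis": diagnosis, "vital": vital}
    written = {}
    for name, df in frames.items():
        df = df.copy()
        for col in DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = outdir / FILENAMES[name]
        df.to_csv(path, index=False)
        written[name] = path
    return written


def validate_timeline(t: PatientTimeline) -> list[Violation]:
    """Check every data-model invariant; violations are data, not errors."""
    v: list[Violation] = []
    if (t.psa["psa_ng_ml"] < 0).any():
        v.append(Violation("psa", "non_negative", "negative PSA value"))
    if t.psa["date"].duplicated().any():
        v.append(Violation("psa", "unique_dates",
                           "two PSA values on the same date"))
    if not t.psa["date"].is_monotonic_increasing:
        v.append(Violation("psa", "sorted", "PSA series not sorted by date"))
    if (t.dispensations["days_supplied"] <= 0).any():
        v.append(Violation("dispensations", "positive_supply",
                           "non-positive days_supplied"))
    bad_class = ~t.dispensations["drug_class"].isin(DRUG_CLASSES)
    if bad_class.any():
        v.append(Violation("dispensations", "drug_class",
                           f"unknown drug class "
                           f"{t.dispensations.loc[bad_class.idxmax(), 'drug_class']!r}"))

    dx = t.diagnosis
    for col, allowed in (("t_stage", T_STAGES), ("n_stage", N_STAGES),
                         ("m_stage", M_STAGES),
                         ("primary_treatment", TREATMENTS)):
        if dx[col] not in allowed:
            v.append(Violation("diagnosis", col, f"invalid {col}: {dx[col]!r}"))

    vit = t.vital
    if vit["cause"] not in CAUSES:
        v.append(Violation("vital", "cause", f"invalid cause {vit['cause']!r}"))
    if vit["cause"] == "censored":
        if vit["censor_reason"] not in ("end_of_followup", "migration"):
            v.append(Violation("vital", "censor_reason",
                               "censored record needs a censor reason"))
    elif vit["censor_reason"] != "none":
        v.append(Violation("vital", "censor_reason",
                           "death and censoring are mutually exclusive"))

    terminal = vit["event_date"]
    for name, dates in (
        ("psa", t.psa["date"]),
        ("dispensations", t.dispensations["date"]),
    ):
        if len(dates) and dates.max() > terminal:
            v.append(Violation(name, "chronology",
                               f"{name} record after terminal date"))
    if t.surgery is not None and t.surgery > terminal:
        v.append(Violation("surgery", "chronology",
                           "surgery after terminal date"))
    if dx["dx_date"] > terminal:
        v.append(Violation("diagnosis", "chronology",
                           "diagnosis after terminal date"))
    return v


def validate_registry(timelines: Mapping[str, PatientTimeline]
                      ) -> dict[str, list[Violation]]:
    """validate_timeline over a whole registry; only offenders are returned."""
    out = {}
    for pid, t in timelines.items():
        v = validate_timeline(t)
        if v:
            out[pid] = v
    return out
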