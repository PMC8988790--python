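import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from crpc_kinetics.config import AnalysisConfig
from crpc_kinetics.registry import PatientTimeline
from crpc_kinetics.simulate import SimConfig, generate_cohort

D = pd.Timestamp  # shorthand for dates in fixtures


def make_timeline(
    patient_id="T001",
    psa=(),                   # iterable of (date, value)
    fills=(),                 # iterable of (date, days_supplied[, drug_class])
    surgery=None,
    dx_date="2008-01-01",
    primary_treatment="primary_adt",
    neoadjuvant=False,
    m_stage="M0",
    event_date="2020-12-31",
    cause="censored",
    censor_reason="end_of_followup",
    followup_end="2020-12-31",
) -> PatientTimeline:
    """Hand-built timeline for rule-level tests."""
    psa_df = pd.DataFrame(
        [{"patient_id": patient_id, "date": D(d), "psa_ng_ml": float(v)}
         for d, v in psa],
        columns=["patient_id", "date", "psa_ng_ml"])
    disp_rows = []
    for f in fills:
        d, days = f[0], f[1]
        drug = f[2] if len(f) > 2 else "GnRH"
        disp_rows.append({"patient_id": patient_id, "date": D(d),
                          "drug_class": drug, "days_supplied": int(days)})
    disp_df = pd.DataFrame(
        disp_rows,
        columns=["patient_id", "date", "drug_class", "days_supplied"])
    diagnosis = pd.Series({
        "patient_id": patient_id, "dx_date": D(dx_date), "t_stage": "T2",
        "n_stage": "NX", "m_stage": m_stage, "gleason_grade_group": "3",
        "psa_at_dx": 20.0, "primary_treatment": primary_treatment,
        "neoadjuvant": neoadjuvant, "age_at_dx": 72.0, "region": "uppsala",
        "followup_end": D(followup_end),
    })
    vital = pd.Series({
        "patient_id": patient_id, "event_date": D(event_date),
        "cause": cause, "censor_reason": censor_reason,
    })
    return PatientTimeline(patient_id, psa_df, disp_df,
                           None if surgery is None else D(surgery),
                           diagnosis, vital)


@pytest.fixture(scope="session")
def analysis_cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient synthetic registry with ground truth (shared, read-only)."""
    cfg = SimConfig(n_patients=120, seed=7)
    timelines, truth = generate_cohort(cfg)
    return cfg, timelines, truth
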