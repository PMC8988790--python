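"""Orchestration: simulate -> phenotype -> kinetics -> risk -> survival.

``run_pipeline`` executes the full analysis on a registry directory and
writes CSV outputs plus a run manifest recording the configuration, seed,
versions, and per-stage cohort counts, so any run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .castration import castration_intervals
from .config import AnalysisConfig
from .detect import apply_inclusion, classify_adt_context
from .kinetics import InsufficientDataError, compute_kinetics, kinetics_table
from .registry import PatientTimeline, load_registry, validate_registry
from .risk import DEFAULT_MODEL, RiskModel, assign
from .survival import (CoxResult, baseline_table, cif_by_group, cox_fit,
                       km_median)

log = logging.getLogger(__name__)

#: Adjusted-model covariate set (reference levels as in the forest plot).
MULTIVARIABLE_COVARIATES = {
    "age_cat": "<=65",
    "crpc_year_cat": "2014-2017",
    "time_from_nadir_cat": "0-3 months",
    "psa_at_nadir_cat": "<=0.5 ng/ml",
    "psa_at_gnrh_cat": "<=10 ng/ml",
    "psa_halving_cat": "1+ years",
    "psa_dt_cat": "1+ years",
    "psa_at_crpc_cat": "<=3 ng/ml",
    "m_stage": "M0",
}


@dataclass
class PipelineConfig:
    """Everything a full run depends on, serializable to one YAML file."""

    registry_dir: str = "."
    out_dir: str = "report"
    seed: int = 0
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    risk_model: RiskModel = field(default_factory=RiskModel)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if isinstance(kwargs.get("analysis"), dict):
            kwargs["analysis"] = AnalysisConfig.from_dict(kwargs["analysis"])
        if isinstance(kwargs.get("risk_model"), dict):
            rm = dict(kwargs["risk_model"])
            unknown_rm = set(rm) - {"coefficient", "cutoffs"}
            if unknown_rm:
                raise ValueError(f"unknown risk_model keys: {sorted(unknown_rm)}")
            if "cutoffs" in rm:
                rm["cutoffs"] = tuple(rm["cutoffs"])
            kwargs["risk_model"] = RiskModel(**rm)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["risk_model"]["cutoffs"] = list(d["risk_model"]["cutoffs"])
        return d


def phenotype_cohort(timelines: dict[str, PatientTimeline],
                     cfg: AnalysisConfig,
                     model: RiskModel = DEFAULT_MODEL) -> dict[str, Any]:
    """Phenotyping through risk assignment; returns the cohort frame.

    The returned dict has keys ``cohort`` (one row per included patient
    with kinetics, categories, score and group), ``inclusion`` (the
    consort tally) and ``events``.
    """
    bad = validate_registry(timelines)
    if bad:
        pid, violations = next(iter(bad.items()))
        raise ValueError(
            f"registry failed validation for {len(bad)} patient(s); first: "
            f"{pid}: {violations[0]}")

    inclusion = apply_inclusion(timelines, cfg)
    summaries = []
    contexts = {}
    cast_start = {}
    for pid in inclusion.included:
        t = timelines[pid]
        event = inclusion.events[pid]
        intervals = castration_intervals(t, cfg)
        start = min(iv.start for iv in intervals)
        cast_start[pid] = start
        contexts[pid] = classify_adt_context(t)
        try:
            summaries.append(compute_kinetics(t, event, start,
                                              dt_method=cfg.dt_method))
        except InsufficientDataError as exc:
            log.warning("kinetics failed for %s: %s; patient dropped", pid, exc)

    cohort = kinetics_table(summaries)
    scores, groups = [], []
    for _, row in cohort.iterrows():
        a = assign(row["psa_at_crpc"], row["psa_dt_days"], model)
        scores.append(a.score)
        groups.append(a.group)
    cohort["score"] = scores
    cohort["risk_group"] = groups
    cohort["adt_context"] = cohort["patient_id"].map(contexts)

    meta = pd.DataFrame([
        {"patient_id": pid,
         "crpc_date": inclusion.events[pid].crpc_date,
         "crpc_rule": inclusion.events[pid].rule,
         "castration_start": cast_start[pid],
         "m_stage": timelines[pid].diagnosis["m_stage"],
         "event_date": timelines[pid].vital["event_date"],
         "status": timelines[pid].vital["cause"]}
        for pid in inclusion.included])
    cohort = cohort.merge(meta, on="patient_id")
    return {"cohort": cohort, "inclusion": inclusion,
            "events": inclusion.events}


def survival_records(cohort: pd.DataFrame,
                     time_origin: str = "crpc") -> pd.DataFrame:
    """Add follow-up time in days from the configured origin."""
    origin = cohort["crpc_date"] if time_origin == "crpc" else (
        cohort["crpc_date"] - pd.to_timedelta(cohort["time_from_gnrh_days"],
                                              unit="D"))
    out = cohort.copy()
    out["time"] = (out["event_date"] - origin).dt.days.clip(lower=0)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Full analysis on a registry directory; writes outputs + manifest."""
    t0 = time.time()
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timelines = load_registry(cfg.registry_dir,
                              date_format=cfg.analysis.date_format)
    pheno = phenotype_cohort(timelines, cfg.analysis, cfg.risk_model)
    cohort = survival_records(pheno["cohort"], cfg.analysis.time_origin)

    results: dict[str, Any] = {"cohort": cohort,
                               "inclusion_tally": pheno["inclusion"].tally}

    # survival stage
    medians = []
    overall = km_median(cohort["time"].to_numpy(),
                        cohort["status"].isin(["pc_death", "other_death"])
                        .to_numpy(int))
    if overall:
        medians.append({"group": "all", "median_days": overall[0],
                        "ci_low": overall[1], "ci_high": overall[2]})
    for g, sub in cohort.groupby("risk_group"):
        m = km_median(sub["time"].to_numpy(),
                      sub["status"].isin(["pc_death", "other_death"])
                      .to_numpy(int))
        if m:
            medians.append({"group": g, "median_days": m[0],
                            "ci_low": m[1], "ci_high": m[2]})
    results["medians"] = pd.DataFrame(medians)

    curves = cif_by_group(cohort)
    cif_rows = []
    for g, c in curves.items():
        for t, p, o, s in zip(c.times, c.cif_pc, c.cif_other, c.surv):
            cif_rows.append({"risk_group": g, "time": t, "cif_pc": p,
                             "cif_other": o, "surv": s})
    results["cif"] = pd.DataFrame(cif_rows)
    results["pc_death_proportions"] = {g: c.final[0] for g, c in curves.items()}

    cox_tables = []
    covs = {k: v for k, v in MULTIVARIABLE_COVARIATES.items()
            if k in cohort.columns}
    for outcome in ("overall", "pc_specific"):
        for cov, ref in covs.items():
            try:
                r = cox_fit(cohort, {cov: ref}, outcome)
            except Exception as exc:  # degenerate small cohorts
                log.warning("univariable Cox failed for %s/%s: %s",
                            cov, outcome, exc)
                continue
            tab = r.table.assign(model="univariable", outcome=outcome)
            cox_tables.append(tab)
        try:
            r = cox_fit(cohort, covs, outcome)
            cox_tables.append(r.table.assign(model="multivariable",
                                             outcome=outcome))
        except Exception as exc:
            log.warning("multivariable Cox failed for %s: %s", outcome, exc)
    results["cox"] = (pd.concat(cox_tables, ignore_index=True)
                      if cox_tables else pd.DataFrame())

    results["baseline"] = baseline_table(cohort)

    # write outputs
    cohort_out = cohort.copy()
    for col in ("crpc_date", "castration_start", "event_date"):
        cohort_out[col] = pd.to_datetime(cohort_out[col]).dt.strftime("%Y-%m-%d")
    cohort_out.to_csv(outdir / "cohort.csv", index=False)
    results["medians"].to_csv(outdir / "medians.csv", index=False)
    results["cif"].to_csv(outdir / "cif_curves.csv", index=False)
    results["cox"].to_csv(outdir / "cox_results.csv", index=False)
    results["baseline"].to_csv(outdir / "baseline_table.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        # hash covers the scientific configuration, not I/O paths
        "config_hash": hashlib.sha256(json.dumps(
            {k: v for k, v in cfg.to_dict().items()
             if k not in ("registry_dir", "out_dir")},
            sort_keys=True).encode()).hexdigest(),
        "counts": {
            **pheno["inclusion"].tally,
            "analyzed": int(len(cohort)),
            "per_risk_group": {int(g): int(n) for g, n in
                               cohort["risk_group"].value_counts().items()},
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
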