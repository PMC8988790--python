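"""Shared analysis configuration.

All rule constants that the phenotyping algorithm depends on live here so
that a run manifest can record exactly which definitions were in force.
Durations are integer days; "month" in bin definitions means 30.44 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any

#: Days per month used when rule text says "months" without a day count.
DAYS_PER_MONTH = 30.44

#: "3 months of ADT" expressed in days.
MEDICAL_CASTRATION_MIN_DAYS = 90
#: "within a total period of 6 months" expressed in days.
MEDICAL_CASTRATION_WINDOW_DAYS = 183


@dataclass
class AnalysisConfig:
    """Tunable constants for phenotyping, kinetics and survival stages.

    Parameters
    ----------
    grace_days:
        A medical castration interval closes when the dispensation coverage
        gap exceeds this many days; PSA values up to ``grace_days`` after
        coverage ends still count as "whilst castrated" unless
        ``strict_castration`` is set.
    strict_castration:
        If True, only PSA values strictly inside a castration interval may
        trigger CRPC detection (sensitivity analysis ignoring PSA after
        long GnRH gaps).
    dt_method:
        ``"ols"`` (log-linear least squares over the regrowth window,
        default) or ``"two_point"`` (nadir and CRPC measurements only).
    time_origin:
        ``"crpc"`` (default) or ``"gnrh"`` — time zero of survival records.
    gnrh_cutoff_date:
        Inclusion requires the first castration event after this date.
    """

    grace_days: int = 90
    strict_castration: bool = False
    min_castration_days: int = MEDICAL_CASTRATION_MIN_DAYS
    castration_window_days: int = MEDICAL_CASTRATION_WINDOW_DAYS
    dt_method: str = "ols"
    time_origin: str = "crpc"
    gnrh_cutoff_date: str = "2006-01-01"
    date_format: str = "%Y-%m-%d"

    def __post_init__(self) -> None:
        if self.dt_method not in ("ols", "two_point"):
            raise ValueError(f"unknown dt_method: {self.dt_method!r}")
        if self.time_origin not in ("crpc", "gnrh"):
            raise ValueError(f"unknown time_origin: {self.time_origin!r}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
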