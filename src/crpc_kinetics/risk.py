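"""Five-level CRPC risk grouping from PSA at CRPC and PSA doubling time.

The score combines the two kinetic variables most strongly associated with
prostate-cancer death::

    score = ln(PSA at CRPC) - 1.40 * ln(PSA-DT in days)

and is cut at -6.09, -4.73, -3.34, -1.58 into risk groups 1 (lowest risk:
low PSA, long doubling time) through 5.  Boundary values belong to the
lower group (score <= -6.09 is group 1; score > -1.58 is group 5).

Logarithms are natural and doubling time is in days.  Neither is stated
with the published constants, but only this combination is consistent with
the qualitative description of group 1 reaching PSA near 200 ng/ml at
multi-year doubling times; both are recorded in :class:`RiskModel` so
alternates are a one-line configuration change.

An infinite doubling time (flat or falling PSA) maps to score -inf, hence
group 1 — no PSA growth is the lowest-risk limit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RiskModel:
    """Published score coefficient and group cutoffs."""

    coefficient: float = 1.40
    cutoffs: tuple[float, ...] = (-6.09, -4.73, -3.34, -1.58)

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")
        if list(self.cutoffs) != sorted(self.cutoffs):
            raise ValueError("cutoffs must be strictly increasing")


DEFAULT_MODEL = RiskModel()


@dataclass(frozen=True)
class RiskAssignment:
    score: float
    group: int  # 1..5


def compute_score(psa_at_crpc: float, psa_dt: float,
                  model: RiskModel = DEFAULT_MODEL) -> float:
    """ln(psa_at_crpc) - coefficient * ln(psa_dt); -inf for infinite DT."""
    if psa_at_crpc <= 0:
        raise ValueError("psa_at_crpc must be positive")
    if psa_dt <= 0:
        raise ValueError("psa_dt must be positive")
    if math.isinf(psa_dt):
        log.warning("infinite doubling time -> score -inf (risk group 1)")
        return -math.inf
    return math.log(psa_at_crpc) - model.coefficient * math.log(psa_dt)


def assign_group(score: float, model: RiskModel = DEFAULT_MODEL) -> int:
    """Risk group 1-5; boundaries belong to the lower group."""
    group = 1
    for cut in model.cutoffs:
        if score <= cut:
            return group
        group += 1
    return group


def assign(psa_at_crpc: float, psa_dt: float,
           model: RiskModel = DEFAULT_MODEL) -> RiskAssignment:
    score = compute_score(psa_at_crpc, psa_dt, model)
    return RiskAssignment(score, assign_group(score, model))


def heatmap_grid(model: RiskModel = DEFAULT_MODEL,
                 psa_range: tuple[float, float] = (0.1, 1000.0),
                 dt_range: tuple[float, float] = (10.0, 4000.0),
                 resolution: int = 200
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Risk group over a log-spaced (PSA, DT) grid, for heat-map plots.

    Returns (psa_values, dt_values, groups) where ``groups[i, j]`` is the
    group at ``dt_values[i]``, ``psa_values[j]``.
    """
    if min(psa_range) <= 0 or min(dt_range) <= 0:
        raise ValueError("ranges must be positive")
    psa = np.geomspace(*psa_range, resolution)
    dt = np.geomspace(*dt_range, resolution)
    scores = np.log(psa)[None, :] - model.coefficient * np.log(dt)[:, None]
    # group = 1 + number of cutoffs strictly below the score
    groups = 1 + (scores[..., None] > np.asarray(model.cutoffs)).sum(axis=-1)
    return psa, dt, groups
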