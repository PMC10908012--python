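"""Per-arm, per-cycle transition machinery.

Every alive from-state shares one destination distribution over alive
states, conditional on surviving the cycle: the published inputs are a
single per-cohort outcome distribution, not a full from-to matrix. Death
acts first as a competing event with a state-specific probability; the
survivors redistribute. The intervention arm gets its distribution shifted
by per-state relative risks, with the stable-management state absorbing
the residual mass.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .parameters import (
    ALIVE_STATES,
    STATE_INDEX,
    STATE_ORDER,
    MedicalState,
    MortalityRatioSet,
    ParameterError,
    RiskRatioSet,
    StateDistribution,
)
from .synthetic_data import LifeTable


class Arm(enum.Enum):
    TCS = "TCS"
    USUAL_CARE = "USUAL_CARE"


def annualize_period_ratio(ratio: float, period: float) -> float:
    """Annual-equivalent of a risk ratio observed over ``period`` years.

    Constant proportionality over the period gives ``ratio ** (1/period)``.
    Full precision is returned; round to 3 decimals for display.
    """
    if ratio <= 0:
        raise ParameterError("annualize_period_ratio.ratio", f"need > 0, got {ratio}")
    if period <= 0:
        raise ParameterError("annualize_period_ratio.period", f"need > 0, got {period}")
    return ratio ** (1.0 / period)


def annual_to_cycle_prob(q_annual: float, cycles_per_year: int) -> float:
    """Convert an annual event probability to a per-cycle probability."""
    if not 0.0 <= q_annual <= 1.0:
        raise ParameterError("annual_to_cycle_prob.q_annual", f"{q_annual} outside [0, 1]")
    if cycles_per_year < 1:
        raise ParameterError("annual_to_cycle_prob.cycles_per_year", f"{cycles_per_year} < 1")
    return 1.0 - (1.0 - q_annual) ** (1.0 / cycles_per_year)


def apply_relative_risks(
    dist: StateDistribution, rr: RiskRatioSet, arm: Arm
) -> StateDistribution:
    """Arm-specific destination distribution.

    Usual care is returned unchanged. For the intervention arm each
    RR-bearing state's probability is multiplied by its relative risk and
    the stable-management state receives the residual mass.
    """
    if arm is Arm.USUAL_CARE:
        return dist
    adjusted = {}
    non_stable_mass = 0.0
    for s in ALIVE_STATES:
        if s is MedicalState.STABLE:
            continue
        p = min(1.0, max(0.0, dist.prob(s) * rr.point(s)))
        adjusted[s] = p
        non_stable_mass += p
    if non_stable_mass > 1.0 + 1e-12:
        raise ParameterError(
            "apply_relative_risks",
            f"RR-adjusted non-stable mass {non_stable_mass:.6f} exceeds 1",
        )
    adjusted[MedicalState.STABLE] = max(0.0, 1.0 - non_stable_mass)
    return StateDistribution(probs=adjusted, cohort=dist.cohort)


def cycle_death_prob(
    age: int,
    state: MedicalState,
    life_table: LifeTable,
    ratios: MortalityRatioSet,
    cycles_per_year: int = 4,
) -> float:
    """Per-cycle death probability for an occupant of ``state`` at ``age``.

    The state's additional-mortality ratio multiplies the annual all-cause
    death probability (capped at 1) before conversion to the cycle scale.
    """
    if state is MedicalState.DEAD:
        raise ParameterError("cycle_death_prob.state", "DEAD has no death probability")
    q_annual = life_table.annual_death_prob(age)
    q_adj = min(1.0, ratios.annual(state) * q_annual)
    return annual_to_cycle_prob(q_adj, cycles_per_year)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 6x6 movement rule for one cycle of one arm."""

    matrix: np.ndarray
    arm: Arm
    cycle: int = 0
    age: Optional[int] = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (6, 6):
            raise ParameterError("transition_matrix", f"shape {m.shape} != (6, 6)")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ParameterError("transition_matrix", "entries outside [0, 1]")
        rows = m.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ParameterError("transition_matrix", f"rows sum to {rows}, expected 1")
        dead = STATE_INDEX[MedicalState.DEAD]
        unit = np.zeros(6)
        unit[dead] = 1.0
        if not np.allclose(m[dead], unit, atol=1e-12):
            raise ParameterError("transition_matrix", "DEAD row must be absorbing")

    def prob(self, from_state: MedicalState, to_state: MedicalState) -> float:
        return float(self.matrix[STATE_INDEX[from_state], STATE_INDEX[to_state]])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fs in STATE_ORDER:
            for ts in STATE_ORDER:
                rows.append(
                    {
                        "from_state": fs.value,
                        "to_state": ts.value,
                        "probability": self.prob(fs, ts),
                        "cycle": self.cycle,
                        "arm": self.arm.value,
                    }
                )
        return pd.DataFrame(rows)


def build_cycle_matrix(
    dist: StateDistribution,
    death_probs: Mapping[MedicalState, float],
    arm: Arm,
    cycle: int = 0,
    age: Optional[int] = None,
) -> TransitionMatrix:
    """Assemble the cycle matrix from the (arm-adjusted) destination
    distribution and per-state death probabilities.

    Row for from-state s: P(s -> DEAD) = d(s); P(s -> t) = (1 - d(s)) * dist(t).
    """
    m = np.zeros((6, 6), dtype=float)
    dest = np.array([dist.prob(s) for s in ALIVE_STATES], dtype=float)
    dead = STATE_INDEX[MedicalState.DEAD]
    for fs in ALIVE_STATES:
        d = death_probs[fs]
        if not 0.0 <= d <= 1.0:
            raise ParameterError(f"death_probs.{fs.value}", f"{d} outside [0, 1]")
        i = STATE_INDEX[fs]
        m[i, :5] = (1.0 - d) * dest
        m[i, dead] = d
    m[dead, dead] = 1.0
    return TransitionMatrix(matrix=m, arm=arm, cycle=cycle, age=age)
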