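"""Cohort trace over the 40-cycle horizon and accumulation of discounted,
half-cycle-corrected costs and QALYs per arm.

The half-cycle correction is the trapezoid (life-table) variant: each of
the 40 cycles contributes the average of its boundary state values,
discounted at mid-cycle. The one-time intervention cost is charged at
model entry, undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import (
    ALIVE_STATES,
    STATE_INDEX,
    STATE_ORDER,
    MedicalState,
    ParameterError,
    ParameterSet,
)
from .synthetic_data import LifeTable
from .transition_model import (
    Arm,
    apply_relative_risks,
    build_cycle_matrix,
    cycle_death_prob,
)


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions, cycles 0..H, for one arm of one cohort."""

    occupancy: np.ndarray  # shape (H + 1, 6), rows indexed by cycle
    arm: Arm
    cohort: str
    start_age: int

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 6:
            raise ParameterError("trace", f"occupancy shape {occ.shape} invalid")
        if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
            raise ParameterError("trace", "occupancies outside [0, 1]")
        sums = occ.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ParameterError("trace", "occupancies must sum to 1 at every cycle")
        dead = occ[:, STATE_INDEX[MedicalState.DEAD]]
        if np.any(np.diff(dead) < -1e-12):
            raise ParameterError("trace", "DEAD occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.occupancy.shape[0]):
            for s in STATE_ORDER:
                rows.append(
                    {
                        "cycle": k,
                        "state": s.value,
                        "occupancy": float(self.occupancy[k, STATE_INDEX[s]]),
                        "arm": self.arm.value,
                        "cohort": self.cohort,
                    }
                )
        return pd.DataFrame(rows)


def run_cohort(
    params: ParameterSet,
    arm: Arm,
    cohort: str,
    life_table: Optional[LifeTable] = None,
) -> CohortTrace:
    """Propagate the cohort through all cycles of the horizon.

    Cycle 0 holds the arm's full (alive) state distribution; the cohort's
    age advances one year every ``cycles_per_year`` cycles and drives the
    life-table lookup.
    """
    lt = life_table or params.life_table
    if lt is None:
        raise ParameterError("run_cohort.life_table", "no life table supplied or attached")
    if cohort not in params.distributions:
        raise ParameterError("run_cohort.cohort", f"unknown cohort {cohort!r}")

    dist = apply_relative_risks(params.distributions[cohort], params.risk_ratios, arm)
    horizon = params.economics.horizon_cycles
    cpy = params.economics.cycles_per_year
    start_age = params.start_ages[cohort]

    occ = np.zeros((horizon + 1, 6), dtype=float)
    occ[0, :5] = dist.as_array()

    death_cache: dict[int, dict[MedicalState, float]] = {}
    for k in range(1, horizon + 1):
        age = start_age + (k - 1) // cpy
        if age not in death_cache:
            death_cache[age] = {
                s: cycle_death_prob(age, s, lt, params.mortality, cpy) for s in ALIVE_STATES
            }
        tm = build_cycle_matrix(dist, death_cache[age], arm, cycle=k, age=age)
        occ[k] = occ[k - 1] @ tm.matrix

    return CohortTrace(occupancy=occ, arm=arm, cohort=cohort, start_age=start_age)


def discount_factor(cycle: float, annual_rate: float, cycles_per_year: int) -> float:
    """Present-value factor for a quantity realized at ``cycle``."""
    if annual_rate < 0:
        raise ParameterError("discount_factor.annual_rate", f"negative rate {annual_rate}")
    return (1.0 + annual_rate) ** (-cycle / cycles_per_year)


@dataclass(frozen=True)
class ArmResult:
    """Accumulated per-arm totals; streams are boundary state values."""

    cost: float
    qalys: float
    cost_undiscounted: float
    qalys_undiscounted: float
    cost_stream: np.ndarray  # per-cycle-boundary expected cost, length H + 1
    qaly_stream: np.ndarray  # per-cycle-boundary expected QALYs, length H + 1
    arm: Arm
    cohort: str

    def __post_init__(self):
        if self.cost > self.cost_undiscounted + 1e-9:
            raise ParameterError("arm_result.cost", "discounted total exceeds undiscounted")
        if self.qalys > self.qalys_undiscounted + 1e-9:
            raise ParameterError("arm_result.qalys", "discounted total exceeds undiscounted")

    def to_dict(self) -> dict:
        return {
            "arm": self.arm.value,
            "cohort": self.cohort,
            "cost": self.cost,
            "qalys": self.qalys,
            "cost_undiscounted": self.cost_undiscounted,
            "qalys_undiscounted": self.qalys_undiscounted,
            "cost_stream": [float(v) for v in self.cost_stream],
            "qaly_stream": [float(v) for v in self.qaly_stream],
        }


def accumulate_outcomes(trace: CohortTrace, params: ParameterSet, arm: Arm) -> ArmResult:
    """Half-cycle-corrected discounted cost and QALY totals for a trace."""
    econ = params.economics
    cohort = trace.cohort
    cycle_years = econ.cycle_length_years
    cpy = econ.cycles_per_year

    cost_reward = np.array(
        [params.costs.cost(cohort, s) for s in STATE_ORDER], dtype=float
    )
    qaly_reward = np.array(
        [params.utilities.utility(s) * cycle_years for s in STATE_ORDER], dtype=float
    )

    occ = trace.occupancy
    cost_stream = occ @ cost_reward
    qaly_stream = occ @ qaly_reward

    horizon = trace.n_cycles
    k = np.arange(1, horizon + 1)
    df_mid = (1.0 + econ.annual_discount_rate) ** (-(k - 0.5) / cpy)
    trap_cost = 0.5 * (cost_stream[:-1] + cost_stream[1:])
    trap_qaly = 0.5 * (qaly_stream[:-1] + qaly_stream[1:])

    cost = float(np.sum(df_mid * trap_cost))
    qalys = float(np.sum(df_mid * trap_qaly))
    cost_undisc = float(np.sum(trap_cost))
    qalys_undisc = float(np.sum(trap_qaly))

    if arm is Arm.TCS:
        tcs = params.tcs_costs.total  # one-time, charged at entry, undiscounted
        cost += tcs
        cost_undisc += tcs

    return ArmResult(
        cost=cost,
        qalys=qalys,
        cost_undiscounted=cost_undisc,
        qalys_undiscounted=qalys_undisc,
        cost_stream=cost_stream,
        qaly_stream=qaly_stream,
        arm=arm,
        cohort=cohort,
    )


def run_arm(
    params: ParameterSet,
    arm: Arm,
    cohort: str,
    life_table: Optional[LifeTable] = None,
) -> ArmResult:
    """Convenience: trace the cohort and accumulate its outcomes."""
    trace = run_cohort(params, arm, cohort, life_table=life_table)
    return accumulate_outcomes(trace, params, arm)
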