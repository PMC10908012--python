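"""Synthetic stand-ins for the two external data sources: an age-indexed
annual mortality schedule (national-life-table-like) and patient-level
90-day post-discharge outcome records (claims-like), from which transition
proportions can be re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    ALIVE_STATES,
    MedicalState,
    ParameterError,
    StateDistribution,
)


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability per integer age."""

    ages: Sequence[int]
    annual_death_probs: Sequence[float]

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.annual_death_probs, dtype=float)
        if ages.size != q.size or ages.size == 0:
            raise ParameterError("life_table", "ages and probabilities must align and be non-empty")
        if not np.all(np.diff(ages) == 1):
            raise ParameterError("life_table.ages", "ages must increase by exactly 1")
        if np.any(q <= 0) or np.any(q > 1):
            raise ParameterError("life_table.q", "probabilities must lie in (0, 1]")
        if q[-1] != 1.0:
            raise ParameterError("life_table.q", "terminal age must have probability 1")

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])

    def annual_death_prob(self, age: int) -> float:
        age = int(age)
        lo, hi = int(self.ages[0]), self.terminal_age
        if not lo <= age <= hi:
            raise ParameterError("life_table.age", f"age {age} outside table range [{lo}, {hi}]")
        return float(self.annual_death_probs[age - lo])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age": list(self.ages), "annual_death_probability": list(self.annual_death_probs)}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(
            ages=tuple(int(a) for a in df["age"]),
            annual_death_probs=tuple(float(q) for q in df["annual_death_probability"]),
        )


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz-Makeham hazard ``h(age) = baseline + level * exp(slope * (age - 60))``.

    Defaults give q(60) near 0.6% rising to roughly 20% by age 100 — a
    plausible shape for an East-Asian national table.
    """

    baseline: float = 0.001
    level: float = 0.005
    slope: float = 0.09
    start_age: int = 60
    terminal_age: int = 110

    def __post_init__(self):
        if self.baseline < 0 or self.level <= 0 or self.slope < 0:
            raise ParameterError("life_table_spec", "need baseline >= 0, level > 0, slope >= 0")
        if self.terminal_age <= self.start_age:
            raise ParameterError("life_table_spec.terminal_age", "must exceed start_age")

    def hazard(self, age: float) -> float:
        return self.baseline + self.level * np.exp(self.slope * (age - 60.0))


def make_life_table(spec: LifeTableSpec = LifeTableSpec()) -> LifeTable:
    """Deterministic life table with ``q(age) = 1 - exp(-h(age))``.

    If the hazard drives q to 1 before the configured terminal age the table
    is truncated there and that age becomes terminal.
    """
    ages, qs = [], []
    for age in range(spec.start_age, spec.terminal_age + 1):
        q = 1.0 - float(np.exp(-spec.hazard(age)))
        if q >= 1.0 or age == spec.terminal_age:
            ages.append(age)
            qs.append(1.0)
            break
        ages.append(age)
        qs.append(q)
    return LifeTable(ages=tuple(ages), annual_death_probs=tuple(qs))


@dataclass(frozen=True)
class ClaimsOutcomeRecord:
    """One patient's 90-day post-discharge outcome."""

    patient_id: str
    cohort: str
    outcome: MedicalState

    def __post_init__(self):
        if self.outcome not in ALIVE_STATES:
            raise ParameterError("claims_record.outcome", f"invalid outcome {self.outcome}")


def simulate_claims_cohort(
    dist: StateDistribution, n: int, seed: int
) -> list[ClaimsOutcomeRecord]:
    """Draw ``n`` independent categorical outcomes from ``dist``."""
    if n <= 0:
        raise ParameterError("simulate_claims_cohort.n", f"need n > 0, got {n}")
    rng = np.random.default_rng(seed)
    p = dist.as_array()
    draws = rng.choice(len(ALIVE_STATES), size=n, p=p / p.sum())
    cohort = dist.cohort or "unknown"
    return [
        ClaimsOutcomeRecord(
            patient_id=f"{cohort}-{i:06d}", cohort=cohort, outcome=ALIVE_STATES[k]
        )
        for i, k in enumerate(draws)
    ]


def estimate_distribution(
    records: Sequence[ClaimsOutcomeRecord],
) -> tuple[StateDistribution, dict[MedicalState, tuple[float, float]]]:
    """Empirical state distribution with normal-approximation 95% intervals.

    Returns ``(distribution, intervals)`` where each interval is
    ``p +/- 1.96 * sqrt(p (1 - p) / n)`` truncated to [0, 1].
    """
    if not records:
        raise ParameterError("estimate_distribution.records", "empty input")
    n = len(records)
    counts = {s: 0 for s in ALIVE_STATES}
    for rec in records:
        counts[rec.outcome] += 1
    cohorts = {rec.cohort for rec in records}
    cohort = cohorts.pop() if len(cohorts) == 1 else None
    from .parameters import distribution_from_counts

    dist = distribution_from_counts(counts, cohort=cohort)
    z = 1.959964
    intervals = {}
    for s in ALIVE_STATES:
        p = dist.prob(s)
        half = z * np.sqrt(p * (1.0 - p) / n)
        intervals[s] = (max(0.0, p - half), min(1.0, p + half))
    return dist, intervals


def records_to_csv(records: Sequence[ClaimsOutcomeRecord], path) -> None:
    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "cohort": r.cohort, "outcome": r.outcome.value}
            for r in records
        ]
    ).to_csv(path, index=False)


def records_from_csv(path) -> list[ClaimsOutcomeRecord]:
    df = pd.read_csv(path)
    return [
        ClaimsOutcomeRecord(
            patient_id=str(r.patient_id), cohort=str(r.cohort), outcome=MedicalState(r.outcome)
        )
        for r in df.itertuples(index=False)
    ]
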