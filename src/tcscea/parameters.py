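"""Model inputs: health states, per-cohort outcome distributions, relative
risks, costs, utilities, mortality ratios and economic constants.

All monetary values are USD. The canonical input bundle ("paper_params")
ships with the package; :func:`load_parameter_set` reads the same layout
from any directory, and :func:`write_parameter_set` writes it back
losslessly.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import LifeTable

SCHEMA_VERSION = "1.0"

COHORTS = ("60s", "70s", "80s")


class MedicalState(enum.Enum):
    """Post-discharge medical-use states; ``DEAD`` is absorbing."""

    STABLE = "STABLE"
    NO_MGMT = "NO_MGMT"
    READMIT_COPD = "READMIT_COPD"
    READMIT_RESP = "READMIT_RESP"
    READMIT_OTHER = "READMIT_OTHER"
    DEAD = "DEAD"


ALIVE_STATES = (
    MedicalState.STABLE,
    MedicalState.NO_MGMT,
    MedicalState.READMIT_COPD,
    MedicalState.READMIT_RESP,
    MedicalState.READMIT_OTHER,
)

#: Canonical ordering used for vectors/matrices throughout the package.
STATE_ORDER = ALIVE_STATES + (MedicalState.DEAD,)

STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}


class ParameterError(ValueError):
    """Invalid model input; ``field_path`` locates the offending value."""

    def __init__(self, field_path: str, message: str):
        self.field_path = field_path
        super().__init__(f"{field_path}: {message}")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (presentation rounding for USD amounts)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateDistribution:
    """Probability of each alive state at the end of a cycle.

    ``counts`` carries the source patient counts when the distribution was
    estimated from records.
    """

    probs: Mapping[MedicalState, float]
    cohort: Optional[str] = None
    counts: Optional[Mapping[MedicalState, int]] = None

    def __post_init__(self):
        missing = [s for s in ALIVE_STATES if s not in self.probs]
        if missing:
            raise ParameterError(
                f"distribution[{self.cohort}]",
                f"missing states: {[s.value for s in missing]}",
            )
        for s, p in self.probs.items():
            if s is MedicalState.DEAD:
                raise ParameterError(
                    f"distribution[{self.cohort}].DEAD",
                    "distribution is over alive states only",
                )
            if not 0.0 <= p <= 1.0:
                raise ParameterError(
                    f"distribution[{self.cohort}].{s.value}",
                    f"probability {p} outside [0, 1]",
                )
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"distribution[{self.cohort}]",
                f"probabilities sum to {total!r}, expected 1",
            )

    def prob(self, state: MedicalState) -> float:
        if state is MedicalState.DEAD:
            return 0.0
        return self.probs[state]

    def as_array(self):
        import numpy as np

        return np.array([self.probs[s] for s in ALIVE_STATES], dtype=float)


def distribution_from_counts(
    counts: Mapping[MedicalState, int], cohort: Optional[str] = None
) -> StateDistribution:
    """Empirical state distribution ``count / total`` from patient counts."""
    for s, c in counts.items():
        if c < 0:
            raise ParameterError(
                f"counts[{cohort}].{s.value}", f"negative count {c}"
            )
    total = sum(counts.values())
    if total == 0:
        raise ParameterError(f"counts[{cohort}]", "total count is zero")
    raw = {s: counts.get(s, 0) / total for s in ALIVE_STATES}
    # force an exact unit sum despite float division
    residual = 1.0 - sum(p for s, p in raw.items() if s is not MedicalState.STABLE)
    raw[MedicalState.STABLE] = residual
    return StateDistribution(probs=raw, cohort=cohort, counts=dict(counts))


@dataclass(frozen=True)
class RiskRatio:
    point: float
    range_low: float
    range_high: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self):
        if self.point <= 0:
            raise ParameterError("risk_ratio.point", f"must be > 0, got {self.point}")
        if not self.range_low <= self.point <= self.range_high:
            raise ParameterError(
                "risk_ratio.range", f"{self.range_low} <= {self.point} <= {self.range_high} violated"
            )
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.point <= self.ci_high:
                raise ParameterError(
                    "risk_ratio.ci", f"{self.ci_low} <= {self.point} <= {self.ci_high} violated"
                )


@dataclass(frozen=True)
class RiskRatioSet:
    """TCS-arm relative risks; STABLE is the residual state and carries none."""

    ratios: Mapping[MedicalState, RiskRatio]

    RR_STATES = (
        MedicalState.NO_MGMT,
        MedicalState.READMIT_COPD,
        MedicalState.READMIT_RESP,
        MedicalState.READMIT_OTHER,
    )

    def __post_init__(self):
        for s in self.RR_STATES:
            if s not in self.ratios:
                raise ParameterError(f"risk_ratios.{s.value}", "missing relative risk")
        if MedicalState.STABLE in self.ratios:
            raise ParameterError("risk_ratios.STABLE", "residual state carries no RR")

    def point(self, state: MedicalState) -> float:
        return self.ratios[state].point if state in self.ratios else 1.0

    def sampling_ci(self, state: MedicalState) -> tuple[float, float]:
        """95% CI used by the PSA; falls back to the tabulated range."""
        rr = self.ratios[state]
        if rr.ci_low is not None and rr.ci_high is not None:
            return rr.ci_low, rr.ci_high
        return rr.range_low, rr.range_high


@dataclass(frozen=True)
class StateCost:
    """Per-cycle cost of occupying a state, with printed components."""

    total: float
    reimbursed: float = 0.0
    non_reimbursed: float = 0.0
    nursing_fee: float = 0.0
    inhaler: float = 0.0

    def __post_init__(self):
        for name in ("total", "reimbursed", "non_reimbursed", "nursing_fee", "inhaler"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"cost.{name}", f"negative cost {v}")
        component_sum = self.reimbursed + self.non_reimbursed + self.nursing_fee + self.inhaler
        # printed totals and component sums disagree by <= 0.02 USD (rounding)
        if abs(component_sum - self.total) > 0.02:
            raise ParameterError(
                "cost.total",
                f"total {self.total} != component sum {component_sum:.2f} (tol 0.02)",
            )


def state_total_cost(
    reimbursed: float, non_reimbursed: float, nursing: float, inhaler: float
) -> float:
    """Sum of cost components, rounded half-up to cents."""
    for name, v in (
        ("reimbursed", reimbursed),
        ("non_reimbursed", non_reimbursed),
        ("nursing", nursing),
        ("inhaler", inhaler),
    ):
        if v < 0:
            raise ParameterError(f"state_total_cost.{name}", f"negative component {v}")
    return round_half_up(reimbursed + non_reimbursed + nursing + inhaler)


def nonreimbursed_cost(reimbursed: float, share: float) -> float:
    """Non-reimbursed amount as a fixed share of the reimbursed amount."""
    if reimbursed < 0:
        raise ParameterError("nonreimbursed_cost.reimbursed", f"negative {reimbursed}")
    if not 0 <= share < 1:
        raise ParameterError("nonreimbursed_cost.share", f"{share} outside [0, 1)")
    return round_half_up(reimbursed * share)


@dataclass(frozen=True)
class CostTable:
    """Per-cohort, per-state occupancy costs (USD per 3-month cycle)."""

    by_cohort: Mapping[str, Mapping[MedicalState, StateCost]]

    def __post_init__(self):
        for cohort in COHORTS:
            if cohort not in self.by_cohort:
                raise ParameterError(f"costs[{cohort}]", "missing cohort")
        for cohort, states in self.by_cohort.items():
            for s in (MedicalState.NO_MGMT,):
                if s in states and states[s].total != 0:
                    raise ParameterError(
                        f"costs[{cohort}].NO_MGMT", "state involves no medical use; cost must be 0"
                    )

    def cost(self, cohort: str, state: MedicalState) -> float:
        if state is MedicalState.DEAD:
            return 0.0
        sc = self.by_cohort[cohort].get(state)
        return sc.total if sc is not None else 0.0


@dataclass(frozen=True)
class TcsCostItem:
    label: str
    quantity: str
    cost: float


@dataclass(frozen=True)
class TcsCostSchedule:
    """One-time per-patient intervention cost, itemized."""

    items: Sequence[TcsCostItem]

    def __post_init__(self):
        if not self.items:
            raise ParameterError("tcs_costs", "empty schedule")
        for item in self.items:
            if item.cost < 0:
                raise ParameterError(f"tcs_costs[{item.label}]", f"negative cost {item.cost}")

    @property
    def total(self) -> float:
        return tcs_total_cost(self)


def tcs_total_cost(schedule: TcsCostSchedule) -> float:
    """Per-patient one-time intervention cost: sum of the item costs."""
    return round_half_up(sum(item.cost for item in schedule.items))


def krw_to_usd(amount: float, rate: float, rounding: str = "cents") -> float:
    """Convert KRW to USD at ``rate`` KRW per USD.

    ``rounding`` is ``"cents"`` (half-up to 2 decimals) or ``"nearest_ten"``.
    """
    if amount < 0:
        raise ParameterError("krw_to_usd.amount", f"negative amount {amount}")
    if rate <= 0:
        raise ParameterError("krw_to_usd.rate", f"non-positive rate {rate}")
    usd = amount / rate
    if rounding == "cents":
        return round_half_up(usd, 2)
    if rounding == "nearest_ten":
        return float(Decimal(repr(usd / 10)).quantize(Decimal(1), rounding=ROUND_HALF_UP)) * 10
    raise ParameterError("krw_to_usd.rounding", f"unknown mode {rounding!r}")


@dataclass(frozen=True)
class Utility:
    point: float
    low: float
    high: float

    def __post_init__(self):
        if not 0 <= self.low <= self.point <= self.high <= 1:
            raise ParameterError(
                "utility", f"0 <= {self.low} <= {self.point} <= {self.high} <= 1 violated"
            )


@dataclass(frozen=True)
class UtilityTable:
    """Annual utility weight per alive state; DEAD is 0 by definition."""

    by_state: Mapping[MedicalState, Utility]

    def __post_init__(self):
        for s in ALIVE_STATES:
            if s not in self.by_state:
                raise ParameterError(f"utilities.{s.value}", "missing utility")

    def utility(self, state: MedicalState) -> float:
        if state is MedicalState.DEAD:
            return 0.0
        return self.by_state[state].point


@dataclass(frozen=True)
class MortalityRatio:
    annual: float
    period_ratio: Optional[float] = None
    period_years: Optional[float] = None

    def __post_init__(self):
        if self.annual < 1:
            raise ParameterError("mortality_ratio.annual", f"{self.annual} < 1")
        if self.period_ratio is not None:
            if self.period_years is None or self.period_years <= 0:
                raise ParameterError("mortality_ratio.period_years", "missing or non-positive")
            annualized = self.period_ratio ** (1.0 / self.period_years)
            if abs(annualized - self.annual) > 1e-3:
                raise ParameterError(
                    "mortality_ratio.annual",
                    f"{self.annual} inconsistent with {self.period_ratio} over "
                    f"{self.period_years}y (annualizes to {annualized:.4f})",
                )


@dataclass(frozen=True)
class MortalityRatioSet:
    """Multipliers on the all-cause annual death probability, per state."""

    ratios: Mapping[MedicalState, MortalityRatio]

    def __post_init__(self):
        for s in ALIVE_STATES:
            if s not in self.ratios:
                raise ParameterError(f"mortality_ratios.{s.value}", "missing ratio")
        if self.ratios[MedicalState.STABLE].annual != 1.0:
            raise ParameterError("mortality_ratios.STABLE", "reference state must have ratio 1")

    def annual(self, state: MedicalState) -> float:
        return self.ratios[state].annual


@dataclass(frozen=True)
class EconomicConstants:
    annual_discount_rate: float = 0.045
    cycle_length_years: float = 0.25
    horizon_cycles: int = 40
    wtp_usd_per_qaly: float = 23050.0
    krw_per_usd: float = 1301.5
    nonreimbursement_share: float = 0.2137
    psa_iterations: int = 10000

    def __post_init__(self):
        if self.annual_discount_rate < 0:
            raise ParameterError("economics.annual_discount_rate", "negative")
        for name in (
            "cycle_length_years",
            "horizon_cycles",
            "wtp_usd_per_qaly",
            "krw_per_usd",
            "nonreimbursement_share",
            "psa_iterations",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"economics.{name}", "must be strictly positive")

    @property
    def cycles_per_year(self) -> int:
        return round(1.0 / self.cycle_length_years)


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated model input bundle."""

    distributions: Mapping[str, StateDistribution]
    risk_ratios: RiskRatioSet
    costs: CostTable
    tcs_costs: TcsCostSchedule
    utilities: UtilityTable
    mortality: MortalityRatioSet
    economics: EconomicConstants
    start_ages: Mapping[str, int]
    life_table: Optional["LifeTable"] = None
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        for cohort in COHORTS:
            if cohort not in self.distributions:
                raise ParameterError(f"distributions[{cohort}]", "missing cohort")
            if cohort not in self.start_ages:
                raise ParameterError(f"start_ages[{cohort}]", "missing cohort")

    def with_life_table(self, life_table: "LifeTable") -> "ParameterSet":
        return replace(self, life_table=life_table)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FILES = (
    "transition_counts.csv",
    "risk_ratios.csv",
    "costs.csv",
    "tcs_costs.csv",
    "utilities.csv",
    "mortality_ratios.csv",
    "constants.json",
)


def paper_params_path() -> Path:
    """Directory of the bundled canonical parameter fixture."""
    return Path(resources.files("tcscea").joinpath("data/paper_params"))


def _state(label: str, context: str) -> MedicalState:
    try:
        return MedicalState(label)
    except ValueError:
        raise ParameterError(context, f"unknown state label {label!r}") from None


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_parameter_set(path, schema_version: str = SCHEMA_VERSION) -> ParameterSet:
    """Read and validate a parameter bundle from ``path`` (a directory).

    Raises :class:`ParameterError` with a field path on any invariant
    violation, and ``FileNotFoundError`` for missing files.
    """
    path = Path(path)
    for fname in _FILES:
        if not (path / fname).exists():
            raise FileNotFoundError(path / fname)

    constants = json.loads((path / "constants.json").read_text())
    found = constants.get("schema_version")
    if found != schema_version:
        raise ParameterError(
            "constants.schema_version", f"expected {schema_version!r}, found {found!r}"
        )

    counts_df = pd.read_csv(path / "transition_counts.csv")
    distributions = {}
    for cohort, grp in counts_df.groupby("cohort"):
        # note: "count" clashes with the namedtuple method, so no itertuples here
        counts = {
            _state(label, f"transition_counts[{cohort}]"): int(n)
            for label, n in zip(grp["state"], grp["count"])
        }
        missing = [s for s in ALIVE_STATES if s not in counts]
        if missing:
            raise ParameterError(
                f"transition_counts[{cohort}]",
                f"missing state rows: {[s.value for s in missing]}",
            )
        distributions[cohort] = distribution_from_counts(counts, cohort=str(cohort))

    rr_df = pd.read_csv(path / "risk_ratios.csv")
    ratios = {}
    for row in rr_df.itertuples(index=False):
        s = _state(row.state, "risk_ratios")
        ratios[s] = RiskRatio(
            point=float(row.point),
            range_low=float(row.range_low),
            range_high=float(row.range_high),
            ci_low=_opt(row.ci_low),
            ci_high=_opt(row.ci_high),
        )
    risk_ratios = RiskRatioSet(ratios=ratios)

    cost_df = pd.read_csv(path / "costs.csv").fillna(0.0)
    by_cohort: dict[str, dict[MedicalState, StateCost]] = {}
    for row in cost_df.itertuples(index=False):
        s = _state(row.state, f"costs[{row.cohort}]")
        by_cohort.setdefault(str(row.cohort), {})[s] = StateCost(
            total=float(row.total),
            reimbursed=float(row.reimbursed),
            non_reimbursed=float(row.non_reimbursed),
            nursing_fee=float(row.nursing_fee),
            inhaler=float(row.inhaler),
        )
    costs = CostTable(by_cohort=by_cohort)

    tcs_df = pd.read_csv(path / "tcs_costs.csv")
    tcs = TcsCostSchedule(
        items=tuple(
            TcsCostItem(label=row.intervention, quantity=row.quantity, cost=float(row.unit_cost_usd))
            for row in tcs_df.itertuples(index=False)
        )
    )

    util_df = pd.read_csv(path / "utilities.csv")
    utilities = UtilityTable(
        by_state={
            _state(row.state, "utilities"): Utility(
                point=float(row.point), low=float(row.low), high=float(row.high)
            )
            for row in util_df.itertuples(index=False)
        }
    )

    mort_df = pd.read_csv(path / "mortality_ratios.csv")
    mortality = MortalityRatioSet(
        ratios={
            _state(row.state, "mortality_ratios"): MortalityRatio(
                annual=float(row.annual_ratio),
                period_ratio=_opt(row.period_ratio),
                period_years=_opt(row.period_years),
            )
            for row in mort_df.itertuples(index=False)
        }
    )

    economics = EconomicConstants(
        annual_discount_rate=constants["annual_discount_rate"],
        cycle_length_years=constants["cycle_length_years"],
        horizon_cycles=constants["horizon_cycles"],
        wtp_usd_per_qaly=constants["wtp_usd_per_qaly"],
        krw_per_usd=constants["krw_per_usd"],
        nonreimbursement_share=constants["nonreimbursement_share"],
        psa_iterations=constants["psa_iterations"],
    )

    return ParameterSet(
        distributions=distributions,
        risk_ratios=risk_ratios,
        costs=costs,
        tcs_costs=tcs,
        utilities=utilities,
        mortality=mortality,
        economics=economics,
        start_ages={k: int(v) for k, v in constants["start_ages"].items()},
        schema_version=schema_version,
    )


def load_paper_params() -> ParameterSet:
    """The bundled canonical parameter set (no life table attached)."""
    return load_parameter_set(paper_params_path())


def write_parameter_set(params: ParameterSet, path) -> None:
    """Write ``params`` in the on-disk layout read by :func:`load_parameter_set`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for cohort in COHORTS:
        dist = params.distributions[cohort]
        if dist.counts is None:
            raise ParameterError(
                f"distributions[{cohort}].counts",
                "cannot serialize a distribution without source counts",
            )
        for s in ALIVE_STATES:
            rows.append({"cohort": cohort, "state": s.value, "count": dist.counts[s]})
    pd.DataFrame(rows).to_csv(path / "transition_counts.csv", index=False)

    rows = []
    for s in RiskRatioSet.RR_STATES:
        rr = params.risk_ratios.ratios[s]
        rows.append(
            {
                "state": s.value,
                "point": rr.point,
                "range_low": rr.range_low,
                "range_high": rr.range_high,
                "ci_low": rr.ci_low,
                "ci_high": rr.ci_high,
            }
        )
    pd.DataFrame(rows).to_csv(path / "risk_ratios.csv", index=False)

    rows = []
    for cohort in COHORTS:
        for s, sc in params.costs.by_cohort[cohort].items():
            rows.append(
                {
                    "cohort": cohort,
                    "state": s.value,
                    "total": sc.total,
                    "reimbursed": sc.reimbursed,
                    "non_reimbursed": sc.non_reimbursed,
                    "nursing_fee": sc.nursing_fee,
                    "inhaler": sc.inhaler,
                }
            )
    pd.DataFrame(rows).to_csv(path / "costs.csv", index=False)

    pd.DataFrame(
        [
            {"intervention": it.label, "quantity": it.quantity, "unit_cost_usd": it.cost}
            for it in params.tcs_costs.items
        ]
    ).to_csv(path / "tcs_costs.csv", index=False)

    pd.DataFrame(
        [
            {
                "state": s.value,
                "point": params.utilities.by_state[s].point,
                "low": params.utilities.by_state[s].low,
                "high": params.utilities.by_state[s].high,
            }
            for s in ALIVE_STATES
        ]
    ).to_csv(path / "utilities.csv", index=False)

    pd.DataFrame(
        [
            {
                "state": s.value,
                "annual_ratio": params.mortality.ratios[s].annual,
                "period_ratio": params.mortality.ratios[s].period_ratio,
                "period_years": params.mortality.ratios[s].period_years,
            }
            for s in ALIVE_STATES
        ]
    ).to_csv(path / "mortality_ratios.csv", index=False)

    constants = {
        "schema_version": params.schema_version,
        "annual_discount_rate": params.economics.annual_discount_rate,
        "cycle_length_years": params.economics.cycle_length_years,
        "horizon_cycles": params.economics.horizon_cycles,
        "wtp_usd_per_qaly": params.economics.wtp_usd_per_qaly,
        "krw_per_usd": params.economics.krw_per_usd,
        "nonreimbursement_share": params.economics.nonreimbursement_share,
        "psa_iterations": params.economics.psa_iterations,
        "start_ages": dict(params.start_ages),
    }
    (path / "constants.json").write_text(json.dumps(constants, indent=2) + "\n")
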