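"""Incremental cost-utility results: delta cost, delta QALYs, ICUR with
dominance classification, and net monetary benefit."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .cohort_engine import ArmResult
from .parameters import ParameterError
from .transition_model import Arm


class Dominance(enum.Enum):
    COST_SAVING_DOMINANT = "cost_saving_dominant"  # cheaper and more effective
    DOMINATED = "dominated"  # costlier and less effective
    TRADEOFF_NE = "tradeoff_ne"  # costlier, more effective
    TRADEOFF_SW = "tradeoff_sw"  # cheaper, less effective
    NO_DIFFERENCE = "no_difference"


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of the intervention arm against usual care."""

    delta_cost: float
    delta_effect: float
    label: Dominance
    cohort: str
    tcs_cost: float = float("nan")
    usual_cost: float = float("nan")
    tcs_effect: float = float("nan")
    usual_effect: float = float("nan")

    @property
    def icur(self) -> Optional[float]:
        """Cost per QALY; undefined (None) when the effect difference is 0."""
        if self.delta_effect == 0:
            return None
        return self.delta_cost / self.delta_effect

    @property
    def icur_display(self) -> str:
        """Table-style ICUR cell: dominance labels instead of signed ratios."""
        if self.label is Dominance.COST_SAVING_DOMINANT:
            return "Cost-saving"
        if self.label is Dominance.DOMINATED:
            return "Dominated"
        if self.icur is None:
            return "undefined"
        return f"{self.icur:.2f}"


def _classify(delta_cost: float, delta_effect: float) -> Dominance:
    if delta_cost < 0 and delta_effect > 0:
        return Dominance.COST_SAVING_DOMINANT
    if delta_cost > 0 and delta_effect < 0:
        return Dominance.DOMINATED
    if delta_effect > 0 or (delta_effect == 0 and delta_cost > 0):
        return Dominance.TRADEOFF_NE
    if delta_effect < 0 or (delta_effect == 0 and delta_cost < 0):
        return Dominance.TRADEOFF_SW
    return Dominance.NO_DIFFERENCE


def incremental_result(tcs: ArmResult, usual: ArmResult, cohort: str) -> CEResult:
    """Incremental cost and effect, intervention minus usual care."""
    if tcs.cohort != usual.cohort:
        raise ParameterError("incremental_result", "arm results are from different cohorts")
    if tcs.arm is not Arm.TCS or usual.arm is not Arm.USUAL_CARE:
        raise ParameterError("incremental_result", "expected one TCS and one USUAL_CARE result")
    d_cost = tcs.cost - usual.cost
    d_eff = tcs.qalys - usual.qalys
    return CEResult(
        delta_cost=d_cost,
        delta_effect=d_eff,
        label=_classify(d_cost, d_eff),
        cohort=cohort,
        tcs_cost=tcs.cost,
        usual_cost=usual.cost,
        tcs_effect=tcs.qalys,
        usual_effect=usual.qalys,
    )


@dataclass(frozen=True)
class NetBenefit:
    wtp: float
    nmb: float


def net_monetary_benefit(ce: CEResult, wtp: float) -> NetBenefit:
    """NMB = WTP x delta effect - delta cost; positive means cost-effective."""
    if wtp < 0:
        raise ParameterError("net_monetary_benefit.wtp", f"negative WTP {wtp}")
    return NetBenefit(wtp=wtp, nmb=wtp * ce.delta_effect - ce.delta_cost)


def results_table(results: Sequence[CEResult]) -> pd.DataFrame:
    """Baseline results in the two-rows-per-cohort published layout."""
    rows = []
    for ce in results:
        rows.append(
            {
                "cohort": ce.cohort,
                "arm": "TCS",
                "total_cost_usd": round(ce.tcs_cost, 2),
                "diff_cost_usd": round(ce.delta_cost, 2),
                "total_effect_qalys": round(ce.tcs_effect, 3),
                "diff_effect_qalys": round(ce.delta_effect, 3),
                "icur": ce.icur_display,
            }
        )
        rows.append(
            {
                "cohort": ce.cohort,
                "arm": "Usual care",
                "total_cost_usd": round(ce.usual_cost, 2),
                "diff_cost_usd": None,
                "total_effect_qalys": round(ce.usual_effect, 3),
                "diff_effect_qalys": None,
                "icur": None,
            }
        )
    return pd.DataFrame(rows)
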