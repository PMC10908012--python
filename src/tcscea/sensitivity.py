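"""Uncertainty analysis.

One-way deterministic sensitivity analysis re-runs the baseline pipeline
at each parameter's low/high bound and ranks swings in net monetary
benefit (tornado ordering). The probabilistic sensitivity analysis draws
costs from gamma, utilities and transition probabilities from beta (with
simplex renormalization), and relative risks from log-normal
distributions, then propagates each draw through both arms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_engine import run_arm
from .economics import incremental_result, net_monetary_benefit
from .parameters import (
    ALIVE_STATES,
    COHORTS,
    MedicalState,
    ParameterError,
    ParameterSet,
    RiskRatio,
    RiskRatioSet,
    StateCost,
    StateDistribution,
    TcsCostItem,
    TcsCostSchedule,
    Utility,
    UtilityTable,
)
from .transition_model import Arm

Z95 = 1.959964  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsaDistribution:
    """A fitted sampling distribution for one scalar model parameter."""

    family: str  # "gamma" | "beta" | "lognormal" | "point"
    params: Mapping[str, float]
    target: str = ""

    def sample(self, rng: np.random.Generator, size=None):
        p = self.params
        if self.family == "point":
            value = p["value"]
            return value if size is None else np.full(size, value)
        if self.family == "lognormal":
            return rng.lognormal(mean=p["mu"], sigma=p["sigma"], size=size)
        if self.family == "beta":
            return rng.beta(p["a"], p["b"], size=size)
        if self.family == "gamma":
            return rng.gamma(shape=p["shape"], scale=p["scale"], size=size)
        raise ParameterError("psa_distribution.family", f"unknown family {self.family!r}")

    @property
    def mean(self) -> float:
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "lognormal":
            return float(np.exp(p["mu"] + 0.5 * p["sigma"] ** 2))
        if self.family == "beta":
            return p["a"] / (p["a"] + p["b"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        raise ParameterError("psa_distribution.family", f"unknown family {self.family!r}")

    @property
    def median(self) -> float:
        if self.family == "lognormal":
            return float(np.exp(self.params["mu"]))
        if self.family == "point":
            return self.params["value"]
        raise ParameterError("psa_distribution.median", f"not defined for {self.family}")


def fit_lognormal_from_ci(lo: float, hi: float, target: str = "") -> PsaDistribution:
    """Log-normal whose 2.5/97.5 percentiles match the CI bounds.

    The fitted median is the geometric mean of the bounds.
    """
    if lo <= 0 or hi <= 0:
        raise ParameterError("fit_lognormal_from_ci", f"non-positive bounds ({lo}, {hi})")
    if lo > hi:
        raise ParameterError("fit_lognormal_from_ci", f"inverted bounds ({lo}, {hi})")
    mu = 0.5 * (np.log(lo) + np.log(hi))
    sigma = (np.log(hi) - np.log(lo)) / (2.0 * Z95)
    if sigma == 0.0:
        return PsaDistribution(family="point", params={"value": lo}, target=target)
    return PsaDistribution(family="lognormal", params={"mu": float(mu), "sigma": float(sigma)}, target=target)


def fit_beta_from_range(mean: float, lo: float, hi: float, target: str = "") -> PsaDistribution:
    """Moment-matched beta: given mean, SD = (hi - lo) / (2 * 1.959964)."""
    if not 0 < mean < 1:
        raise ParameterError("fit_beta_from_range.mean", f"{mean} outside (0, 1)")
    if not lo <= mean <= hi:
        raise ParameterError("fit_beta_from_range", f"{lo} <= {mean} <= {hi} violated")
    sd = (hi - lo) / (2.0 * Z95)
    return fit_beta_from_sd(mean, sd, target=target)


def fit_beta_from_sd(mean: float, sd: float, target: str = "") -> PsaDistribution:
    if sd == 0.0:
        return PsaDistribution(family="point", params={"value": mean}, target=target)
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ParameterError(
            "fit_beta_from_sd", f"variance {var:.6g} infeasible for beta with mean {mean}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return PsaDistribution(
        family="beta", params={"a": mean * nu, "b": (1.0 - mean) * nu}, target=target
    )


def fit_gamma(mean: float, cv: float, target: str = "") -> PsaDistribution:
    """Gamma with the requested mean and coefficient of variation."""
    if mean <= 0 or cv <= 0:
        raise ParameterError("fit_gamma", f"need mean > 0 and cv > 0, got ({mean}, {cv})")
    shape = 1.0 / (cv * cv)
    return PsaDistribution(
        family="gamma", params={"shape": shape, "scale": mean / shape}, target=target
    )


# ---------------------------------------------------------------------------
# parameter paths (shared by DSA and PSA)
# ---------------------------------------------------------------------------


def resolve_parameter(params: ParameterSet, path: str) -> float:
    """Current (base-case) value of the scalar at ``path``.

    Paths: ``economics.discount_rate`` | ``tcs.total`` | ``rr.<STATE>`` |
    ``utility.<STATE>`` | ``cost.<cohort>.<STATE>.total`` |
    ``prob.<cohort>.<STATE>``.
    """
    parts = path.split(".")
    try:
        if parts[0] == "economics" and parts[1] == "discount_rate" and len(parts) == 2:
            return params.economics.annual_discount_rate
        if parts[0] == "tcs" and parts[1] == "total" and len(parts) == 2:
            return params.tcs_costs.total
        if parts[0] == "rr" and len(parts) == 2:
            return params.risk_ratios.ratios[MedicalState(parts[1])].point
        if parts[0] == "utility" and len(parts) == 2:
            return params.utilities.by_state[MedicalState(parts[1])].point
        if parts[0] == "cost" and len(parts) == 4 and parts[3] == "total":
            return params.costs.by_cohort[parts[1]][MedicalState(parts[2])].total
        if parts[0] == "prob" and len(parts) == 3:
            return params.distributions[parts[1]].prob(MedicalState(parts[2]))
    except (KeyError, ValueError) as exc:
        raise ParameterError(f"parameter_path.{path}", f"does not resolve: {exc}") from None
    raise ParameterError(f"parameter_path.{path}", "unknown parameter path")


def set_parameter(params: ParameterSet, path: str, value: float) -> ParameterSet:
    """New ParameterSet with the scalar at ``path`` replaced by ``value``."""
    resolve_parameter(params, path)  # reject unknown paths up front
    parts = path.split(".")

    if parts[0] == "economics":
        return replace(params, economics=replace(params.economics, annual_discount_rate=value))

    if parts[0] == "tcs":
        schedule = TcsCostSchedule(
            items=(TcsCostItem(label="bundled intervention", quantity="", cost=float(value)),)
        )
        return replace(params, tcs_costs=schedule)

    if parts[0] == "rr":
        state = MedicalState(parts[1])
        old = params.risk_ratios.ratios[state]
        new_rr = RiskRatio(
            point=value,
            range_low=min(old.range_low, value),
            range_high=max(old.range_high, value),
            ci_low=None if old.ci_low is None else min(old.ci_low, value),
            ci_high=None if old.ci_high is None else max(old.ci_high, value),
        )
        ratios = dict(params.risk_ratios.ratios)
        ratios[state] = new_rr
        return replace(params, risk_ratios=RiskRatioSet(ratios=ratios))

    if parts[0] == "utility":
        state = MedicalState(parts[1])
        old = params.utilities.by_state[state]
        by_state = dict(params.utilities.by_state)
        by_state[state] = Utility(
            point=value, low=min(old.low, value), high=max(old.high, value)
        )
        return replace(params, utilities=UtilityTable(by_state=by_state))

    if parts[0] == "cost":
        cohort, state = parts[1], MedicalState(parts[2])
        old = params.costs.by_cohort[cohort][state]
        if old.total == 0:
            raise ParameterError(f"parameter_path.{path}", "cannot rescale a zero-cost state")
        f = value / old.total
        new_cost = StateCost(
            total=value,
            reimbursed=old.reimbursed * f,
            non_reimbursed=old.non_reimbursed * f,
            nursing_fee=old.nursing_fee * f,
            inhaler=old.inhaler * f,
        )
        by_cohort = {c: dict(states) for c, states in params.costs.by_cohort.items()}
        by_cohort[cohort][state] = new_cost
        from .parameters import CostTable

        return replace(params, costs=CostTable(by_cohort=by_cohort))

    if parts[0] == "prob":
        cohort, state = parts[1], MedicalState(parts[2])
        dist = params.distributions[cohort]
        p_old = dist.prob(state)
        if not 0 <= value <= 1:
            raise ParameterError(f"parameter_path.{path}", f"probability {value} outside [0, 1]")
        if p_old >= 1.0:
            raise ParameterError(f"parameter_path.{path}", "cannot redistribute from mass 1")
        scale = (1.0 - value) / (1.0 - p_old)
        probs = {s: dist.prob(s) * scale for s in ALIVE_STATES}
        probs[state] = value
        total = sum(probs.values())
        probs = {s: p / total for s, p in probs.items()}
        dists = dict(params.distributions)
        dists[cohort] = StateDistribution(probs=probs, cohort=cohort)
        return replace(params, distributions=dists)

    raise ParameterError(f"parameter_path.{path}", "unknown parameter path")


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DsaSpec:
    path: str
    low: float
    high: float
    source: str = "default band"

    def __post_init__(self):
        if self.low > self.high:
            raise ParameterError(f"dsa_spec.{self.path}", f"low {self.low} > high {self.high}")


@dataclass(frozen=True)
class TornadoEntry:
    path: str
    low_outcome: float
    high_outcome: float

    @property
    def swing(self) -> float:
        return abs(self.high_outcome - self.low_outcome)


def default_dsa_specs(params: ParameterSet, cohort: str) -> list[DsaSpec]:
    """Published ranges where available; conventional bands elsewhere.

    Discount rate 0 to 2x base; costs (state occupancy and intervention)
    +/-25%; relative risks and utilities at their printed ranges; transition
    probabilities at their count-based 95% intervals.
    """
    specs = []
    base_rate = params.economics.annual_discount_rate
    specs.append(
        DsaSpec("economics.discount_rate", 0.0, 2.0 * base_rate, source="default band")
    )
    tcs = params.tcs_costs.total
    specs.append(DsaSpec("tcs.total", 0.75 * tcs, 1.25 * tcs, source="default band"))
    for state, rr in params.risk_ratios.ratios.items():
        specs.append(DsaSpec(f"rr.{state.value}", rr.range_low, rr.range_high, source="table range"))
    for state, u in params.utilities.by_state.items():
        specs.append(DsaSpec(f"utility.{state.value}", u.low, u.high, source="table range"))
    for state, sc in params.costs.by_cohort[cohort].items():
        if sc.total > 0:
            specs.append(
                DsaSpec(
                    f"cost.{cohort}.{state.value}.total",
                    0.75 * sc.total,
                    1.25 * sc.total,
                    source="default band",
                )
            )
    dist = params.distributions[cohort]
    n = sum(dist.counts.values()) if dist.counts else None
    if n:
        for state in ALIVE_STATES:
            p = dist.prob(state)
            half = Z95 * np.sqrt(p * (1.0 - p) / n)
            specs.append(
                DsaSpec(
                    f"prob.{cohort}.{state.value}",
                    max(0.0, p - half),
                    min(1.0, p + half),
                    source="count-based 95% interval",
                )
            )
    return specs


def _nmb_at(params: ParameterSet, cohort: str, wtp: float) -> float:
    tcs = run_arm(params, Arm.TCS, cohort)
    usual = run_arm(params, Arm.USUAL_CARE, cohort)
    ce = incremental_result(tcs, usual, cohort)
    return net_monetary_benefit(ce, wtp).nmb


def one_way_dsa(
    params: ParameterSet,
    specs: Sequence[DsaSpec],
    cohort: str,
    wtp: Optional[float] = None,
) -> list[TornadoEntry]:
    """Re-run the pipeline at each spec's bounds; entries sorted by swing."""
    if wtp is None:
        wtp = params.economics.wtp_usd_per_qaly
    entries = []
    for spec in specs:
        low_out = _nmb_at(set_parameter(params, spec.path, spec.low), cohort, wtp)
        high_out = _nmb_at(set_parameter(params, spec.path, spec.high), cohort, wtp)
        entries.append(TornadoEntry(path=spec.path, low_outcome=low_out, high_outcome=high_out))
    return sorted(entries, key=lambda e: e.swing, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.path,
                "low_outcome": e.low_outcome,
                "high_outcome": e.high_outcome,
                "swing": e.swing,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSAResult:
    delta_costs: np.ndarray
    delta_effects: np.ndarray
    n_iter: int
    seed: int
    cohort: str

    def __post_init__(self):
        if len(self.delta_costs) != self.n_iter or len(self.delta_effects) != self.n_iter:
            raise ParameterError("psa_result", "draw count does not match iteration count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iter),
                "delta_cost": self.delta_costs,
                "delta_qaly": self.delta_effects,
            }
        )


def psa_distributions(
    params: ParameterSet, cohort: str, cost_cv: float = 0.2
) -> dict[str, PsaDistribution]:
    """The PSA sampling registry for one cohort.

    Costs: gamma (CV ``cost_cv``). Utilities: beta from their ranges.
    Transition probabilities: per-state beta moment-matched to the
    count-based proportion and its binomial SE (renormalized after
    sampling). Relative risks: log-normal from the 95% CIs.
    """
    registry: dict[str, PsaDistribution] = {}
    for state, u in params.utilities.by_state.items():
        path = f"utility.{state.value}"
        registry[path] = fit_beta_from_range(u.point, u.low, u.high, target=path)
    for state in RiskRatioSet.RR_STATES:
        lo, hi = params.risk_ratios.sampling_ci(state)
        path = f"rr.{state.value}"
        registry[path] = fit_lognormal_from_ci(lo, hi, target=path)
    for state, sc in params.costs.by_cohort[cohort].items():
        if sc.total > 0:
            path = f"cost.{cohort}.{state.value}.total"
            registry[path] = fit_gamma(sc.total, cost_cv, target=path)
    registry["tcs.total"] = fit_gamma(params.tcs_costs.total, cost_cv, target="tcs.total")
    dist = params.distributions[cohort]
    if dist.counts is None:
        raise ParameterError(
            f"distributions[{cohort}].counts", "PSA needs source counts for the binomial SE"
        )
    n = sum(dist.counts.values())
    for state in ALIVE_STATES:
        p = dist.prob(state)
        path = f"prob.{cohort}.{state.value}"
        registry[path] = fit_beta_from_sd(p, float(np.sqrt(p * (1.0 - p) / n)), target=path)
    return registry


def _sampled_params(
    params: ParameterSet, cohort: str, draws: Mapping[str, float]
) -> ParameterSet:
    """Assemble a ParameterSet from one joint PSA draw (fast path)."""
    by_state = {
        s: Utility(point=min(1.0, draws[f"utility.{s.value}"]), low=0.0, high=1.0)
        for s in ALIVE_STATES
    }
    ratios = {}
    for s in RiskRatioSet.RR_STATES:
        v = draws[f"rr.{s.value}"]
        ratios[s] = RiskRatio(point=v, range_low=v, range_high=v)
    by_cohort = {c: dict(states) for c, states in params.costs.by_cohort.items()}
    for s, sc in params.costs.by_cohort[cohort].items():
        if sc.total > 0:
            v = draws[f"cost.{cohort}.{s.value}.total"]
            f = v / sc.total
            by_cohort[cohort][s] = StateCost(
                total=v,
                reimbursed=sc.reimbursed * f,
                non_reimbursed=sc.non_reimbursed * f,
                nursing_fee=sc.nursing_fee * f,
                inhaler=sc.inhaler * f,
            )
    schedule = TcsCostSchedule(
        items=(TcsCostItem(label="bundled intervention", quantity="", cost=draws["tcs.total"]),)
    )
    raw = np.array([draws[f"prob.{cohort}.{s.value}"] for s in ALIVE_STATES])
    raw = np.clip(raw, 0.0, 1.0)
    raw = raw / raw.sum()  # restore the simplex constraint
    probs = {s: float(raw[i]) for i, s in enumerate(ALIVE_STATES)}
    dists = dict(params.distributions)
    dists[cohort] = StateDistribution(probs=probs, cohort=cohort)
    from .parameters import CostTable

    return replace(
        params,
        utilities=UtilityTable(by_state=by_state),
        risk_ratios=RiskRatioSet(ratios=ratios),
        costs=CostTable(by_cohort=by_cohort),
        tcs_costs=schedule,
        distributions=dists,
    )


def run_psa(
    params: ParameterSet,
    n_iter: int,
    seed: int,
    cohort: str,
    cost_cv: float = 0.2,
    registry: Optional[Mapping[str, PsaDistribution]] = None,
) -> PSAResult:
    """Monte-Carlo propagation of the PSA distributions through both arms."""
    if n_iter < 1:
        raise ParameterError("run_psa.n_iter", f"need >= 1, got {n_iter}")
    if registry is None:
        registry = psa_distributions(params, cohort, cost_cv=cost_cv)
    rng = np.random.default_rng(seed)
    paths = sorted(registry)  # fixed draw order for reproducibility
    d_costs = np.empty(n_iter)
    d_effects = np.empty(n_iter)
    for i in range(n_iter):
        draws = {path: float(registry[path].sample(rng)) for path in paths}
        sampled = _sampled_params(params, cohort, draws)
        tcs = run_arm(sampled, Arm.TCS, cohort)
        usual = run_arm(sampled, Arm.USUAL_CARE, cohort)
        d_costs[i] = tcs.cost - usual.cost
        d_effects[i] = tcs.qalys - usual.qalys
    return PSAResult(
        delta_costs=d_costs, delta_effects=d_effects, n_iter=n_iter, seed=seed, cohort=cohort
    )


@dataclass(frozen=True)
class CEACurve:
    wtp_grid: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.wtp_grid, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if grid.size == 0 or grid.size != p.size:
            raise ParameterError("ceac", "grid and probabilities must align and be non-empty")
        if np.any(np.diff(grid) <= 0):
            raise ParameterError("ceac.wtp_grid", "grid must be strictly ascending")
        if np.any(p < 0) or np.any(p > 1):
            raise ParameterError("ceac.probabilities", "outside [0, 1]")

    def probability_at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        return float(self.probabilities[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.probabilities})


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> CEACurve:
    """Acceptance probability: fraction of draws with positive NMB.

    Ties (NMB exactly 0) count as not cost-effective.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("ceac.wtp_grid", "empty grid")
    nmb = grid[:, None] * result.delta_effects[None, :] - result.delta_costs[None, :]
    probs = (nmb > 0).mean(axis=1)
    return CEACurve(wtp_grid=grid, probabilities=probs)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_tornado(entries: Sequence[TornadoEntry], base_nmb: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = list(entries)[::-1]  # largest swing on top
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.low_outcome, e.high_outcome))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", height=0.6)
    ax.axvline(base_nmb, color="black", lw=1)
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.path for e in entries], fontsize=8)
    ax.set_xlabel("Net monetary benefit (USD)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ce_plane(results: Mapping[str, PSAResult], wtp: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    for cohort, res in results.items():
        ax.scatter(res.delta_effects, res.delta_costs, s=4, alpha=0.4, label=cohort)
    xs = np.array(ax.get_xlim())
    ax.plot(xs, wtp * xs, color="grey", ls="--", lw=1, label=f"WTP {wtp:,.0f} USD/QALY")
    ax.axhline(0, color="black", lw=0.8)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("Incremental effect (QALYs)")
    ax.set_ylabel("Incremental cost (USD)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ceac(curves: Mapping[str, CEACurve], wtp: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for cohort, curve in curves.items():
        ax.plot(curve.wtp_grid, curve.probabilities, label=cohort)
    ax.axvline(wtp, color="grey", ls="--", lw=1)
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
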