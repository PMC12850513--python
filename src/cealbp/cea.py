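"""Cost-utility analysis on top of the cohort engine.

Accrues discounted costs under three perspectives (healthcare, restricted
societal, full societal) and discounted QALYs, and summarises the two arms
as incremental cost / incremental QALY / ICER / net monetary benefit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

from .model_core import (
    ARMS,
    STATES,
    CohortTrace,
    ModelSpec,
    ValidationError,
    discount_factor,
    run_cohort,
)

if TYPE_CHECKING:
    from .config import AnalysisConfig

PERSPECTIVES = ("healthcare", "restricted_societal", "full_societal")

#: Conventions searched by :func:`calibrate_conventions`.
CONVENTION_GRID = tuple(
    itertools.product(
        ("tunnel", "matrix_root", "direct"),
        ("none", "half_cycle"),
        ("cycle_start", "cycle_end"),
    )
)


@dataclass(frozen=True)
class PayoffSchedule:
    """Per-cycle payoffs for one arm.

    Treatment costs (medical, transport, time) apply to the treated mass
    (moderate + severe); productivity losses apply state-wise to the whole
    cohort; ``per_cycle_qaly_by_state`` is utility x cycle length.
    """

    arm: str
    medical_cost_per_treated_cycle: float
    transport_cost_per_treated_cycle: float
    time_cost_per_treated_cycle: float
    productivity_loss_per_cycle_by_state: np.ndarray  # (3,) ordered like STATES
    utility_by_state: np.ndarray  # (3,)
    per_cycle_qaly_by_state: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        for name in (
            "productivity_loss_per_cycle_by_state",
            "utility_by_state",
            "per_cycle_qaly_by_state",
        ):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        errors = []
        if self.arm not in ARMS:
            errors.append(f"unknown arm {self.arm!r}")
        for name in (
            "medical_cost_per_treated_cycle",
            "transport_cost_per_treated_cycle",
            "time_cost_per_treated_cycle",
        ):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be non-negative")
        if np.any(self.productivity_loss_per_cycle_by_state < 0):
            errors.append("productivity losses must be non-negative")
        if np.any((self.utility_by_state < 0) | (self.utility_by_state > 1)):
            errors.append("utilities must lie in [0, 1]")
        if errors:
            raise ValidationError("; ".join(errors))

    @classmethod
    def from_utilities(
        cls,
        arm: str,
        medical: float,
        transport: float,
        time: float,
        productivity: np.ndarray,
        utilities: np.ndarray,
        cycle_length_years: float = 0.25,
    ) -> "PayoffSchedule":
        utilities = np.asarray(utilities, float)
        return cls(
            arm=arm,
            medical_cost_per_treated_cycle=medical,
            transport_cost_per_treated_cycle=transport,
            time_cost_per_treated_cycle=time,
            productivity_loss_per_cycle_by_state=productivity,
            utility_by_state=utilities,
            per_cycle_qaly_by_state=utilities * cycle_length_years,
        )

    def with_qaly_weights(self, q: np.ndarray, cycle_length_years: float = 0.25):
        """Replace the per-cycle QALY weights (utilities follow as q / dt)."""
        q = np.asarray(q, float)
        return replace(
            self,
            per_cycle_qaly_by_state=q,
            utility_by_state=q / cycle_length_years,
        )


@dataclass(frozen=True)
class PTScenarioMix:
    """Scenario-weighted physiotherapy cycle cost inputs."""

    scenario_costs: np.ndarray  # (4,)
    weights: np.ndarray  # (4,), sums to 1
    consultation: float
    beta_params: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 2))
    )  # per-scenario (alpha, beta) pairs for the PSA

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario_costs", np.asarray(self.scenario_costs, float))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        object.__setattr__(self, "beta_params", np.asarray(self.beta_params, float))
        if self.scenario_costs.shape != self.weights.shape:
            raise ValidationError("scenario_costs and weights must align")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValidationError(
                f"scenario weights sum to {self.weights.sum():.8f}, expected 1"
            )

    def with_weights(self, weights: np.ndarray) -> "PTScenarioMix":
        return replace(self, weights=np.asarray(weights, float))


def pt_cycle_cost(mix: PTScenarioMix) -> float:
    """Consultation plus the scenario-weighted physiotherapy cost."""
    return float(mix.consultation + mix.weights @ mix.scenario_costs)


@dataclass(frozen=True)
class CEAResult:
    perspective: str
    total_cost: dict  # arm -> USD
    total_qaly: dict  # arm -> QALY
    incremental_cost: float  # PPT - PT
    incremental_qaly: float
    icer: float | None  # None when incremental_qaly == 0
    dominance: str  # ppt_dominant | pt_dominant | tradeoff
    nmb: float  # at the WTP threshold

    def as_dict(self) -> dict:
        return {
            "perspective": self.perspective,
            "cost_PPT": self.total_cost["PPT"],
            "cost_PT": self.total_cost["PT"],
            "qaly_PPT": self.total_qaly["PPT"],
            "qaly_PT": self.total_qaly["PT"],
            "incremental_cost": self.incremental_cost,
            "incremental_qaly": self.incremental_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
            "nmb": self.nmb,
        }


def accrue(
    trace: CohortTrace,
    payoffs: PayoffSchedule,
    spec: ModelSpec,
    perspective: str,
) -> tuple[float, float]:
    """Discounted (total_cost, total_qaly) for one arm.

    Accrual runs over cycles 0..T-1.  Under ``half_cycle`` correction the
    occupancy used in cycle t is the average of the trace rows t and t+1
    (trapezoidal accrual); under ``none`` it is row t.
    """
    if perspective not in PERSPECTIVES:
        raise ValidationError(
            f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}"
        )
    if trace.arm != payoffs.arm:
        raise ValidationError(
            f"trace arm {trace.arm!r} does not match payoff arm {payoffs.arm!r}"
        )
    occ = trace.collapsed_occupancy
    T = trace.n_cycles
    half = spec.cycle_correction == "half_cycle"

    per_treated = payoffs.medical_cost_per_treated_cycle
    if perspective in ("restricted_societal", "full_societal"):
        per_treated += (
            payoffs.transport_cost_per_treated_cycle
            + payoffs.time_cost_per_treated_cycle
        )

    total_cost = 0.0
    total_qaly = 0.0
    for t in range(T):
        o = 0.5 * (occ[t] + occ[t + 1]) if half else occ[t]
        d = discount_factor(t, spec)
        treated = o[1] + o[2]
        cost = treated * per_treated
        if perspective == "full_societal":
            cost += o @ payoffs.productivity_loss_per_cycle_by_state
        total_cost += d * cost
        total_qaly += d * (o @ payoffs.per_cycle_qaly_by_state)
    return total_cost, total_qaly


def compute_icer(
    cost_ppt: float, cost_pt: float, qaly_ppt: float, qaly_pt: float
) -> tuple[float, float, float | None, str]:
    """(incremental_cost, incremental_qaly, icer, dominance), PPT - PT.

    The ICER is reported even when negative; it is None only when the
    incremental QALY is exactly zero, in which case dominance is decided by
    the cost sign alone.
    """
    d_cost = cost_ppt - cost_pt
    d_qaly = qaly_ppt - qaly_pt
    if d_qaly == 0.0:
        icer = None
        dominance = (
            "ppt_dominant" if d_cost < 0 else "pt_dominant" if d_cost > 0 else "tradeoff"
        )
    else:
        icer = d_cost / d_qaly
        if d_cost < 0 and d_qaly > 0:
            dominance = "ppt_dominant"
        elif d_cost > 0 and d_qaly < 0:
            dominance = "pt_dominant"
        else:
            dominance = "tradeoff"
    return d_cost, d_qaly, icer, dominance


def compute_nmb(incremental_cost: float, incremental_qaly: float, wtp: float) -> float:
    """Net monetary benefit: wtp * dQALY - dCost."""
    return wtp * incremental_qaly - incremental_cost


def run_base_case(config: "AnalysisConfig") -> dict[str, CEAResult]:
    """Run both arms and summarise every perspective.

    Returns perspective -> :class:`CEAResult`; convention metadata travels on
    ``config.model``.
    """
    spec = config.model
    traces = {arm: run_cohort(spec, config.transition_models[arm]) for arm in ARMS}
    results: dict[str, CEAResult] = {}
    for perspective in PERSPECTIVES:
        totals = {
            arm: accrue(traces[arm], config.payoffs[arm], spec, perspective)
            for arm in ARMS
        }
        cost = {arm: totals[arm][0] for arm in ARMS}
        qaly = {arm: totals[arm][1] for arm in ARMS}
        d_cost, d_qaly, icer, dominance = compute_icer(
            cost["PPT"], cost["PT"], qaly["PPT"], qaly["PT"]
        )
        results[perspective] = CEAResult(
            perspective=perspective,
            total_cost=cost,
            total_qaly=qaly,
            incremental_cost=d_cost,
            incremental_qaly=d_qaly,
            icer=icer,
            dominance=dominance,
            nmb=compute_nmb(d_cost, d_qaly, spec.wtp_per_qaly),
        )
    return results


def calibrate_conventions(
    config: "AnalysisConfig",
    targets: dict[tuple[str, str], float],
) -> tuple[tuple[str, str, str], "pd.DataFrame"]:
    """Search the convention grid for the tuple best matching the targets.

    ``targets`` maps (arm, perspective) -> published total cost.  Every
    combination of mild handling x cycle correction x discount timing is
    evaluated on a copy of the config (the caller's conventions are never
    overwritten); combinations are scored by the maximum absolute relative
    error over the targets.  Returns the winning tuple and the full
    residual table.
    """
    import pandas as pd

    if not targets:
        raise ValidationError("calibration requires at least one target")
    for (arm, perspective) in targets:
        if arm not in ARMS or perspective not in PERSPECTIVES:
            raise ValidationError(f"unknown target key ({arm!r}, {perspective!r})")

    records = []
    for mode, correction, timing in CONVENTION_GRID:
        trial = config.with_model(
            replace(
                config.model,
                mild_handling_mode=mode,
                cycle_correction=correction,
                discount_timing=timing,
            )
        )
        results = run_base_case(trial)
        errs = {}
        for (arm, perspective), target in targets.items():
            value = results[perspective].total_cost[arm]
            errs[f"{arm}_{perspective}"] = abs(value - target) / abs(target)
        records.append(
            {
                "mild_handling_mode": mode,
                "cycle_correction": correction,
                "discount_timing": timing,
                **errs,
                "max_relative_error": max(errs.values()),
            }
        )
    table = pd.DataFrame.from_records(records).sort_values(
        "max_relative_error", kind="stable", ignore_index=True
    )
    best = table.iloc[0]
    return (
        (
            best["mild_handling_mode"],
            best["cycle_correction"],
            best["discount_timing"],
        ),
        table,
    )
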