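"""One-way deterministic sensitivity analysis.

Each named parameter is moved to the ends of its plausible range while all
others stay at base, the full base case is re-run, and results are ranked
by the spread of net monetary benefit (tornado order).  ICERs are reported
alongside but not used for ranking: they are sign-unstable as the
incremental QALY approaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Callable

import numpy as np

from .cea import PERSPECTIVES, compute_nmb
from .model_core import ARMS, STATES, ValidationError

if TYPE_CHECKING:
    import pandas as pd

    from .config import AnalysisConfig

RANGE_KINDS = ("rate", "cost", "utility", "probability_row", "weight", "horizon")


@dataclass(frozen=True)
class ParameterRange:
    name: str
    base_value: float
    low: float
    high: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in RANGE_KINDS:
            raise ValidationError(f"unknown range kind {self.kind!r}")
        if not (self.low <= self.base_value <= self.high):
            raise ValidationError(
                f"{self.name}: range [{self.low}, {self.high}] must bracket "
                f"base {self.base_value}"
            )


@dataclass(frozen=True)
class DSAResult:
    parameter: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    nmb_low: float
    nmb_high: float

    @property
    def spread(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def perturb_probability_row(
    row: np.ndarray, element_index: int, delta: float
) -> np.ndarray:
    """Shift one element of a probability row, rescaling the complement.

    The target element is clipped to [0, 1]; the remaining elements are
    rescaled proportionally so the row sums to 1.  When the remaining
    elements are all zero the freed mass is split equally among them.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or np.any(row < 0) or abs(row.sum() - 1.0) > 1e-6:
        raise ValidationError(f"not a probability row: {row}")
    new = row.copy()
    target = float(np.clip(row[element_index] + delta, 0.0, 1.0))
    new[element_index] = target
    others = [i for i in range(len(row)) if i != element_index]
    rest = row[others].sum()
    if rest > 0:
        new[others] = row[others] * (1.0 - target) / rest
    else:
        new[others] = (1.0 - target) / len(others)
    if new.sum() <= 0:
        raise ValidationError("perturbation produced an all-zero row")
    return new / new.sum()


def set_probability_element(row: np.ndarray, element_index: int, value: float):
    """Set one element to an absolute value, renormalizing like a perturbation."""
    row = np.asarray(row, dtype=float)
    return perturb_probability_row(row, element_index, value - row[element_index])


# ---------------------------------------------------------------------------
# Parameter registry: name -> function(config, value) -> new config
# ---------------------------------------------------------------------------


def _set_discount_rate(config, value):
    return config.with_model(replace(config.model, annual_discount_rate=value))


def _set_horizon_years(config, value):
    cycles = max(1, round(value / config.model.cycle_length_years))
    return config.with_model(replace(config.model, horizon_cycles=cycles))


def _set_initial_severe_share(config, value):
    value = float(np.clip(value, 0.0, 1.0))
    dist = np.array([0.0, 1.0 - value, value])
    return config.with_model(replace(config.model, initial_distribution=dist))


def _payoff_setter(arm: str, field_name: str):
    def setter(config, value):
        payoffs = dict(config.payoffs)
        payoffs[arm] = replace(payoffs[arm], **{field_name: value})
        return config.with_payoffs(payoffs)

    return setter


def _productivity_setter(state_index: int):
    def setter(config, value):
        payoffs = dict(config.payoffs)
        for arm in ARMS:
            prod = payoffs[arm].productivity_loss_per_cycle_by_state.copy()
            prod[state_index] = value
            payoffs[arm] = replace(
                payoffs[arm], productivity_loss_per_cycle_by_state=prod
            )
        return config.with_payoffs(payoffs)

    return setter


def _qaly_weight_setter(state_index: int):
    def setter(config, value):
        dt = config.model.cycle_length_years
        payoffs = dict(config.payoffs)
        for arm in ARMS:
            q = payoffs[arm].per_cycle_qaly_by_state.copy()
            q[state_index] = value
            payoffs[arm] = payoffs[arm].with_qaly_weights(q, dt)
        return config.with_payoffs(payoffs)

    return setter


def _pt_mix_setter(scenario_index: int):
    def setter(config, value):
        mix = config.pt_mix
        weights = set_probability_element(mix.weights, scenario_index, value)
        return config.with_pt_mix(mix.with_weights(weights))

    return setter


def _transition_setter(arm: str | None, from_state: str, to_state: str):
    i = STATES.index(from_state)
    j = STATES.index(to_state)

    def setter(config, value):
        models = dict(config.transition_models)
        arms = ARMS if arm is None else (arm,)  # mild row is pooled
        for a in arms:
            rows = models[a].rows.copy()
            rows[i] = set_probability_element(rows[i], j, value)
            models[a] = models[a].with_rows(rows)
        return config.with_transition_models(models)

    return setter


def _build_registry() -> dict[str, Callable]:
    registry: dict[str, Callable] = {
        "discount_rate": _set_discount_rate,
        "horizon_years": _set_horizon_years,
        "initial_severe_share": _set_initial_severe_share,
    }
    for arm in ARMS:
        registry[f"transport_cost_{arm}"] = _payoff_setter(
            arm, "transport_cost_per_treated_cycle"
        )
        registry[f"time_cost_{arm}"] = _payoff_setter(
            arm, "time_cost_per_treated_cycle"
        )
        registry[f"medical_cost_{arm}"] = _payoff_setter(
            arm, "medical_cost_per_treated_cycle"
        )
    for k, state in enumerate(STATES):
        registry[f"productivity_loss_{state}"] = _productivity_setter(k)
        registry[f"qaly_weight_{state}"] = _qaly_weight_setter(k)
        registry[f"tp_mild_{state}"] = _transition_setter(None, "mild", state)
        for arm in ARMS:
            for from_state in ("moderate", "severe"):
                registry[f"tp_{arm}_{from_state}_{state}"] = _transition_setter(
                    arm, from_state, state
                )
    for s in range(4):
        registry[f"pt_mix_scenario_{s + 1}"] = _pt_mix_setter(s)
    return registry


PARAMETER_REGISTRY = _build_registry()


def apply_parameter(config: "AnalysisConfig", name: str, value: float):
    """Return a copy of the config with one named parameter set to ``value``."""
    try:
        setter = PARAMETER_REGISTRY[name]
    except KeyError:
        valid = ", ".join(sorted(PARAMETER_REGISTRY))
        raise ValidationError(
            f"unknown DSA parameter {name!r}; valid names: {valid}"
        ) from None
    return setter(config, value)


def run_one_way(
    config: "AnalysisConfig",
    ranges: list[ParameterRange],
    perspective: str = "healthcare",
) -> list[DSAResult]:
    """Evaluate every range end, sorted by descending NMB spread (stable)."""
    from .cea import run_base_case

    if perspective not in PERSPECTIVES:
        raise ValidationError(f"unknown perspective {perspective!r}")
    wtp = config.model.wtp_per_qaly
    results: list[DSAResult] = []
    for pr in ranges:
        ends = {}
        for label, value in (("low", pr.low), ("high", pr.high)):
            res = run_base_case(apply_parameter(config, pr.name, value))[perspective]
            ends[label] = (
                res.icer,
                compute_nmb(res.incremental_cost, res.incremental_qaly, wtp),
            )
        results.append(
            DSAResult(
                parameter=pr.name,
                low=pr.low,
                high=pr.high,
                icer_low=ends["low"][0],
                icer_high=ends["high"][0],
                nmb_low=ends["low"][1],
                nmb_high=ends["high"][1],
            )
        )
    return sorted(results, key=lambda r: -r.spread)


def results_to_frame(results: list[DSAResult]) -> "pd.DataFrame":
    """Tornado-ordered table ready for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "input_low": r.low,
                "input_high": r.high,
                "icer_low": r.icer_low,
                "icer_high": r.icer_high,
                "nmb_low": r.nmb_low,
                "nmb_high": r.nmb_high,
                "nmb_spread": r.spread,
            }
            for r in results
        ]
    )
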