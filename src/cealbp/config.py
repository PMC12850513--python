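"""Configuration loading, validation, and serialization.

The structured YAML schema is documented in the packaged
``data/default_config.yaml``; :func:`load_config` validates everything up
front and reports every violation, not just the first.  Monetary inputs may
be given in KRW (``currency: KRW``) and are converted once at load using the
fixed exchange rate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .cea import PayoffSchedule, PTScenarioMix, pt_cycle_cost
from .dsa import ParameterRange
from .model_core import (
    ARMS,
    STATES,
    ModelSpec,
    TransitionModel,
    ValidationError,
    build_transition_model,
)
from .synthetic_trial import TrialSpec


@dataclass(frozen=True)
class PSASettings:
    n_iterations: int = 1000
    seed: int = 2026
    wtp_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 60000.0 + 1, 500.0)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "wtp_grid", np.asarray(self.wtp_grid, float))
        if self.n_iterations < 1:
            raise ValidationError("psa.n_iterations must be >= 1")
        if self.wtp_grid.size == 0 or np.any(self.wtp_grid < 0):
            raise ValidationError("psa.wtp_grid must be non-empty and non-negative")


@dataclass(frozen=True)
class AnalysisConfig:
    """Fully validated model inputs for every pipeline stage."""

    model: ModelSpec
    transition_models: dict  # arm -> TransitionModel
    payoffs: dict  # arm -> PayoffSchedule
    pt_mix: PTScenarioMix
    psa: PSASettings
    dsa_ranges: list  # list[ParameterRange]
    utility_qaly_beta: dict  # state -> (alpha, beta) for per-cycle QALY weights
    time_cost_se: dict  # arm -> SE of the time cost
    productivity_se: dict  # state -> SE of the productivity loss
    transport_se_fraction: float
    ppt_medical_components: dict  # component -> USD
    trial: TrialSpec | None = None

    # -- functional updates used by the DSA / PSA ---------------------------
    def with_model(self, model: ModelSpec) -> "AnalysisConfig":
        return replace(self, model=model)

    def with_payoffs(self, payoffs: dict) -> "AnalysisConfig":
        return replace(self, payoffs=dict(payoffs))

    def with_pt_mix(self, mix: PTScenarioMix) -> "AnalysisConfig":
        return replace(self, pt_mix=mix)

    def with_transition_models(self, models: dict) -> "AnalysisConfig":
        return replace(self, transition_models=dict(models))

    def config_hash(self) -> str:
        """Stable digest of the serialized configuration."""
        payload = yaml.safe_dump(serialize_config(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config_path() -> Path:
    return Path(resources.files("cealbp").joinpath("data/default_config.yaml"))


def load_default_config() -> AnalysisConfig:
    return load_config(default_config_path())


def load_config(path) -> AnalysisConfig:
    """Parse and validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


_MISSING = object()


def _get(raw: dict, path: str, errors: list, default=_MISSING):
    node = raw
    for key in path.split("."):
        if not isinstance(node, dict) or key not in node:
            if default is not _MISSING:
                return default
            errors.append(f"missing required field {path!r}")
            return None
        node = node[key]
    return node


def config_from_dict(raw: dict) -> AnalysisConfig:
    errors: list[str] = []
    currency = raw.get("currency", "USD")
    if currency not in ("USD", "KRW"):
        errors.append(f"currency must be USD or KRW, got {currency!r}")

    krw_per_usd = float(_get(raw, "model.krw_per_usd", errors, 1144.61))
    fx = krw_per_usd if currency == "KRW" else 1.0

    def money(path, default=None):
        v = _get(raw, path, errors) if default is None else _get(raw, path, errors, default)
        if v is None:
            return 0.0
        return float(v) / fx

    # -- model block --------------------------------------------------------
    init_raw = _get(raw, "model.initial_distribution", errors, {})
    init = np.array([float(init_raw.get(s, 0.0)) for s in STATES])
    wtp_krw = float(_get(raw, "model.wtp_krw", errors, 30_500_000))
    model = None
    try:
        model = ModelSpec(
            cycle_length_years=float(_get(raw, "model.cycle_length_years", errors, 0.25)),
            horizon_cycles=int(_get(raw, "model.horizon_cycles", errors, 12)),
            annual_discount_rate=float(
                _get(raw, "model.annual_discount_rate", errors, 0.045)
            ),
            initial_distribution=init,
            wtp_per_qaly=wtp_krw / krw_per_usd,
            krw_per_usd=krw_per_usd,
            mild_handling_mode=_get(raw, "model.mild_handling_mode", errors, "direct"),
            cycle_correction=_get(raw, "model.cycle_correction", errors, "half_cycle"),
            discount_timing=_get(raw, "model.discount_timing", errors, "cycle_start"),
        )
    except ValidationError as exc:
        errors.append(f"model: {exc}")

    # -- transitions --------------------------------------------------------
    interval = int(_get(raw, "transitions.mild_interval_cycles", errors, 2))
    transition_models: dict[str, TransitionModel] = {}
    for arm in ARMS:
        block = _get(raw, f"transitions.{arm}", errors, {})
        try:
            rows = {s: block[s]["probs"] for s in STATES}
            alphas = {s: block[s]["alphas"] for s in STATES}
            transition_models[arm] = build_transition_model(
                rows, alphas, arm, mild_row_interval_cycles=interval
            )
        except (KeyError, TypeError):
            errors.append(f"transitions.{arm}: needs probs and alphas for every state")
        except ValidationError as exc:
            errors.append(f"transitions.{arm}: {exc}")
    if len(transition_models) == 2 and not np.allclose(
        transition_models["PPT"].rows[0], transition_models["PT"].rows[0]
    ):
        errors.append("transitions: the mild row must be identical across arms (pooled)")

    # -- costs and utilities ------------------------------------------------
    components = _get(raw, "costs.PPT.medical_components", errors, {}) or {}
    ppt_components = {k: float(v) / fx for k, v in components.items()}
    ppt_medical = sum(ppt_components.values())

    scenarios = _get(raw, "costs.PT.scenarios", errors, []) or []
    pt_mix = None
    try:
        pt_mix = PTScenarioMix(
            scenario_costs=[float(s["cost"]) / fx for s in scenarios],
            weights=[float(s["weight"]) for s in scenarios],
            consultation=money("costs.PT.consultation", 0.0),
            beta_params=[
                [float(x) for x in s.get("beta", (1.0, 1.0))] for s in scenarios
            ],
        )
    except (KeyError, TypeError):
        errors.append("costs.PT.scenarios: each scenario needs cost and weight")
    except ValidationError as exc:
        errors.append(f"costs.PT: {exc}")

    utilities_raw = _get(raw, "utilities", errors, {}) or {}
    utility_values = []
    utility_qaly_beta = {}
    for s in STATES:
        node = utilities_raw.get(s, {})
        if "value" not in node:
            errors.append(f"utilities.{s}.value missing")
            utility_values.append(0.0)
        else:
            utility_values.append(float(node["value"]))
        utility_qaly_beta[s] = tuple(
            float(x) for x in node.get("qaly_beta", (1.0, 1.0))
        )
    utility_values = np.array(utility_values)
    if np.any((utility_values < 0) | (utility_values > 1)):
        errors.append("utilities must lie in [0, 1]")

    prod_raw = _get(raw, "productivity_loss", errors, {}) or {}
    productivity = np.array(
        [float(prod_raw.get(s, {}).get("mean", 0.0)) / fx for s in STATES]
    )
    productivity_se = {
        s: float(prod_raw.get(s, {}).get("se", 0.0)) / fx for s in STATES
    }

    time_cost_se = {}
    payoffs: dict[str, PayoffSchedule] = {}
    dt = float(_get(raw, "model.cycle_length_years", errors, 0.25))
    for arm in ARMS:
        time_node = _get(raw, f"costs.{arm}.time", errors, {}) or {}
        time_cost_se[arm] = float(time_node.get("se", 0.0)) / fx
        medical = ppt_medical if arm == "PPT" else (
            pt_cycle_cost(pt_mix) if pt_mix is not None else 0.0
        )
        try:
            payoffs[arm] = PayoffSchedule.from_utilities(
                arm=arm,
                medical=medical,
                transport=money(f"costs.{arm}.transport", 0.0),
                time=float(time_node.get("mean", 0.0)) / fx,
                productivity=productivity,
                utilities=utility_values,
                cycle_length_years=dt,
            )
        except ValidationError as exc:
            errors.append(f"costs.{arm}: {exc}")

    transport_se_fraction = float(_get(raw, "costs.transport_se_fraction", errors, 0.10))

    # -- psa ----------------------------------------------------------------
    grid_raw = _get(raw, "psa.wtp_grid", errors, {})
    if isinstance(grid_raw, dict):
        grid = np.arange(
            float(grid_raw.get("start", 0.0)),
            float(grid_raw.get("stop", 60000.0)) + 1e-9,
            float(grid_raw.get("step", 500.0)),
        )
    else:
        grid = np.asarray(grid_raw, float)
    psa_settings = None
    try:
        psa_settings = PSASettings(
            n_iterations=int(_get(raw, "psa.n_iterations", errors, 1000)),
            seed=int(_get(raw, "psa.seed", errors, 2026)),
            wtp_grid=grid,
        )
    except ValidationError as exc:
        errors.append(f"psa: {exc}")

    # -- trial (optional) ---------------------------------------------------
    trial = None
    trial_raw = raw.get("trial")
    if trial_raw is not None and len(transition_models) == 2:
        base = trial_raw.get("baseline_distribution", {})
        try:
            trial = TrialSpec(
                n_per_arm=int(trial_raw.get("n_per_arm", 50)),
                true_transition_models=transition_models,
                baseline_distribution=np.array(
                    [
                        float(base.get("moderate", 0.12)),
                        float(base.get("severe", 0.88)),
                    ]
                ),
                utility_means_by_state=utility_values,
                utility_sd=float(trial_raw.get("utility_sd", 0.08)),
                seed=int(trial_raw.get("seed", 7)),
                utility_noise=trial_raw.get("utility_noise", "truncated_normal"),
            )
        except ValidationError as exc:
            errors.append(f"trial: {exc}")

    if errors:
        raise ValidationError("invalid configuration:\n  - " + "\n  - ".join(errors))

    config = AnalysisConfig(
        model=model,
        transition_models=transition_models,
        payoffs=payoffs,
        pt_mix=pt_mix,
        psa=psa_settings,
        dsa_ranges=[],
        utility_qaly_beta=utility_qaly_beta,
        time_cost_se=time_cost_se,
        productivity_se=productivity_se,
        transport_se_fraction=transport_se_fraction,
        ppt_medical_components=ppt_components,
        trial=trial,
    )
    return replace(config, dsa_ranges=build_dsa_ranges(config, raw.get("dsa", {}) or {}))


def build_dsa_ranges(config: AnalysisConfig, dsa_raw: dict) -> list[ParameterRange]:
    """One-way ranges from the configured deltas and printed SEs."""
    ranges: list[ParameterRange] = []

    def add(name, base, low, high, kind):
        ranges.append(
            ParameterRange(
                name=name,
                base_value=float(base),
                low=float(min(low, base)),
                high=float(max(high, base)),
                kind=kind,
            )
        )

    dr = dsa_raw.get("discount_rate", {})
    add(
        "discount_rate",
        config.model.annual_discount_rate,
        dr.get("low", 0.035),
        dr.get("high", 0.060),
        "rate",
    )
    hy = dsa_raw.get("horizon_years", {})
    add(
        "horizon_years",
        config.model.horizon_years,
        hy.get("low", 1.0),
        hy.get("high", 5.0),
        "horizon",
    )
    sev = float(config.model.initial_distribution[2])
    delta = float(dsa_raw.get("initial_severe_share", {}).get("delta", 0.03))
    add("initial_severe_share", sev, sev - delta, sev + delta, "probability_row")

    for arm in ARMS:
        p = config.payoffs[arm]
        tr = p.transport_cost_per_treated_cycle
        se = config.transport_se_fraction * tr
        add(f"transport_cost_{arm}", tr, tr - se, tr + se, "cost")
        tc = p.time_cost_per_treated_cycle
        se = config.time_cost_se[arm]
        add(f"time_cost_{arm}", tc, tc - se, tc + se, "cost")
    for k, state in enumerate(STATES):
        base = float(config.payoffs["PPT"].productivity_loss_per_cycle_by_state[k])
        se = config.productivity_se[state]
        add(f"productivity_loss_{state}", base, base - se, base + se, "cost")

    qd = float(dsa_raw.get("qaly_weight_delta", 0.003))
    for k, state in enumerate(STATES):
        q = float(config.payoffs["PPT"].per_cycle_qaly_by_state[k])
        add(f"qaly_weight_{state}", q, q - qd, q + qd, "utility")

    for s in range(4):
        w = float(config.pt_mix.weights[s])
        add(f"pt_mix_scenario_{s + 1}", w, w, 1.0, "weight")

    deltas = dsa_raw.get("transition_deltas", {})
    mild_d = deltas.get("mild", [0.0, 0.0, 0.0])
    for j, to_state in enumerate(STATES):
        base = float(config.transition_models["PPT"].rows[0, j])
        d = float(mild_d[j])
        add(
            f"tp_mild_{to_state}",
            base,
            max(0.0, base - d),
            min(1.0, base + d),
            "probability_row",
        )
    for arm in ARMS:
        arm_d = deltas.get(arm, {})
        for from_state in ("moderate", "severe"):
            row_d = arm_d.get(from_state, [0.0, 0.0, 0.0])
            i = STATES.index(from_state)
            for j, to_state in enumerate(STATES):
                base = float(config.transition_models[arm].rows[i, j])
                d = float(row_d[j])
                add(
                    f"tp_{arm}_{from_state}_{to_state}",
                    base,
                    max(0.0, base - d),
                    min(1.0, base + d),
                    "probability_row",
                )
    return ranges


def serialize_config(config: AnalysisConfig) -> dict:
    """Dict form that :func:`config_from_dict` parses back equivalently."""
    m = config.model
    out = {
        "currency": "USD",
        "model": {
            "cycle_length_years": m.cycle_length_years,
            "horizon_cycles": m.horizon_cycles,
            "annual_discount_rate": m.annual_discount_rate,
            "initial_distribution": {
                s: float(m.initial_distribution[i]) for i, s in enumerate(STATES)
            },
            "wtp_krw": m.wtp_per_qaly * m.krw_per_usd,
            "krw_per_usd": m.krw_per_usd,
            "mild_handling_mode": m.mild_handling_mode,
            "cycle_correction": m.cycle_correction,
            "discount_timing": m.discount_timing,
        },
        "transitions": {
            "mild_interval_cycles": config.transition_models[
                "PPT"
            ].mild_row_interval_cycles,
        },
        "costs": {
            "PPT": {
                "medical_components": {
                    k: float(v) for k, v in config.ppt_medical_components.items()
                },
                "transport": float(
                    config.payoffs["PPT"].transport_cost_per_treated_cycle
                ),
                "time": {
                    "mean": float(config.payoffs["PPT"].time_cost_per_treated_cycle),
                    "se": float(config.time_cost_se["PPT"]),
                },
            },
            "PT": {
                "consultation": float(config.pt_mix.consultation),
                "scenarios": [
                    {
                        "cost": float(c),
                        "weight": float(w),
                        "beta": [float(a), float(b)],
                    }
                    for c, w, (a, b) in zip(
                        config.pt_mix.scenario_costs,
                        config.pt_mix.weights,
                        config.pt_mix.beta_params,
                    )
                ],
                "transport": float(
                    config.payoffs["PT"].transport_cost_per_treated_cycle
                ),
                "time": {
                    "mean": float(config.payoffs["PT"].time_cost_per_treated_cycle),
                    "se": float(config.time_cost_se["PT"]),
                },
            },
            "transport_se_fraction": config.transport_se_fraction,
        },
        "productivity_loss": {
            s: {
                "mean": float(
                    config.payoffs["PPT"].productivity_loss_per_cycle_by_state[i]
                ),
                "se": float(config.productivity_se[s]),
            }
            for i, s in enumerate(STATES)
        },
        "utilities": {
            s: {
                "value": float(config.payoffs["PPT"].utility_by_state[i]),
                "qaly_beta": [float(x) for x in config.utility_qaly_beta[s]],
            }
            for i, s in enumerate(STATES)
        },
        "psa": {
            "n_iterations": config.psa.n_iterations,
            "seed": config.psa.seed,
            "wtp_grid": [float(w) for w in config.psa.wtp_grid],
        },
    }
    for arm in ARMS:
        tm = config.transition_models[arm]
        out["transitions"][arm] = {
            s: {
                "probs": [float(x) for x in tm.rows[i]],
                "alphas": [float(x) for x in tm.dirichlet_alpha[i]],
            }
            for i, s in enumerate(STATES)
        }
    if config.trial is not None:
        t = config.trial
        out["trial"] = {
            "n_per_arm": t.n_per_arm,
            "baseline_distribution": {
                "moderate": float(t.baseline_distribution[0]),
                "severe": float(t.baseline_distribution[1]),
            },
            "utility_sd": float(t.utility_sd),
            "utility_noise": t.utility_noise,
            "seed": t.seed,
        }
    return out
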