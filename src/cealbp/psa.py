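"""Probabilistic sensitivity analysis.

Monte-Carlo resampling of every uncertain parameter: per-cycle QALY weights
and physiotherapy scenario weights from Beta distributions, cost parameters
from Gamma distributions (mean = base value, sd = stated standard error;
transportation uses an SE of 10% of its mean), and transition rows from
Dirichlet distributions.  Point ("fixed") parameters are never sampled.

Each iteration draws one full configuration and runs the deterministic base
case; summaries, probability-cost-effective and acceptability curves are
computed from the stored per-iteration draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .cea import PERSPECTIVES, run_base_case
from .model_core import ARMS, STATES, ValidationError

if TYPE_CHECKING:
    from .config import AnalysisConfig

FAMILIES = ("beta", "gamma", "dirichlet", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one uncertain parameter.

    ``params`` by family: beta -> (alpha, beta); gamma -> (mean, se), with
    shape = mean^2/se^2 and scale = se^2/mean; dirichlet -> concentration
    vector; fixed -> (value,).
    """

    parameter: str
    family: str
    params: tuple

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        p = np.asarray(self.params, dtype=float)
        if self.family == "beta" and (p.shape != (2,) or np.any(p <= 0)):
            raise ValidationError(f"{self.parameter}: beta needs two concentrations > 0")
        if self.family == "gamma" and (p.shape != (2,) or np.any(p <= 0)):
            raise ValidationError(f"{self.parameter}: gamma needs mean > 0 and se > 0")
        if self.family == "dirichlet" and (p.ndim != 1 or np.any(p <= 0)):
            raise ValidationError(
                f"{self.parameter}: dirichlet needs positive concentrations"
            )
        object.__setattr__(self, "params", tuple(np.atleast_1d(p)))

    def sample(self, rng: np.random.Generator):
        if self.family == "fixed":
            return self.params[0]
        if self.family == "beta":
            return rng.beta(*self.params)
        if self.family == "gamma":
            mean, se = self.params
            return rng.gamma(shape=(mean / se) ** 2, scale=se**2 / mean)
        return rng.dirichlet(np.asarray(self.params))


def _gamma_or_fixed(name: str, mean: float, se: float) -> DistributionSpec:
    if se <= 0 or mean <= 0:
        return DistributionSpec(name, "fixed", (mean,))
    return DistributionSpec(name, "gamma", (mean, se))


def default_distribution_specs(config: "AnalysisConfig") -> list[DistributionSpec]:
    """The uncertain-parameter set implied by the packaged inputs.

    Medical unit costs, the discount rate, the horizon and the initial
    severity split are point values and enter as ``fixed`` (never sampled).
    """
    specs: list[DistributionSpec] = []
    # Per-cycle QALY weights: printed Beta pairs whose means are the
    # utility x cycle-length values, so draws are used as QALY weights
    # directly and not re-scaled by cycle length.
    for state in STATES:
        a, b = config.utility_qaly_beta[state]
        specs.append(DistributionSpec(f"qaly_weight_{state}", "beta", (a, b)))
    # Scenario mix: marginal Betas, renormalized to the simplex after
    # sampling (see sample_parameters).
    for s, (a, b) in enumerate(config.pt_mix.beta_params):
        specs.append(DistributionSpec(f"pt_mix_scenario_{s + 1}", "beta", (a, b)))
    for arm in ARMS:
        p = config.payoffs[arm]
        specs.append(
            _gamma_or_fixed(
                f"transport_cost_{arm}",
                p.transport_cost_per_treated_cycle,
                config.transport_se_fraction * p.transport_cost_per_treated_cycle,
            )
        )
        specs.append(
            _gamma_or_fixed(
                f"time_cost_{arm}",
                p.time_cost_per_treated_cycle,
                config.time_cost_se[arm],
            )
        )
        specs.append(
            DistributionSpec(
                f"medical_cost_{arm}", "fixed", (p.medical_cost_per_treated_cycle,)
            )
        )
    for k, state in enumerate(STATES):
        specs.append(
            _gamma_or_fixed(
                f"productivity_loss_{state}",
                float(
                    config.payoffs["PPT"].productivity_loss_per_cycle_by_state[k]
                ),
                config.productivity_se[state],
            )
        )
    # Transition rows: the mild row is pooled across arms and sampled once.
    specs.append(
        DistributionSpec(
            "tp_row_mild",
            "dirichlet",
            tuple(config.transition_models["PPT"].dirichlet_alpha[0]),
        )
    )
    for arm in ARMS:
        for i, from_state in enumerate(STATES):
            if from_state == "mild":
                continue
            specs.append(
                DistributionSpec(
                    f"tp_row_{arm}_{from_state}",
                    "dirichlet",
                    tuple(config.transition_models[arm].dirichlet_alpha[i]),
                )
            )
    return specs


def fixed_distribution_specs(config: "AnalysisConfig") -> list[DistributionSpec]:
    """Degenerate spec set: every parameter pinned at its base value."""
    return [
        DistributionSpec(s.parameter, "fixed", (0.0,))
        for s in default_distribution_specs(config)
    ]


def sample_parameters(
    config: "AnalysisConfig",
    rng: np.random.Generator,
    specs: list[DistributionSpec] | None = None,
) -> "AnalysisConfig":
    """Draw one complete parameter configuration.

    ``fixed`` entries leave the base value untouched.  Draws are consumed in
    the order of ``specs`` so a given generator state maps to exactly one
    configuration.
    """
    from dataclasses import replace

    if specs is None:
        specs = default_distribution_specs(config)
    by_name = {s.parameter: s for s in specs}
    missing = [
        s.parameter
        for s in default_distribution_specs(config)
        if s.parameter not in by_name
    ]
    if missing:
        raise ValidationError(f"missing distributions for: {missing}")

    draws: dict[str, object] = {}
    for spec in specs:
        draws[spec.parameter] = None if spec.family == "fixed" else spec.sample(rng)

    dt = config.model.cycle_length_years
    payoffs = dict(config.payoffs)

    q_draws = [draws[f"qaly_weight_{s}"] for s in STATES]
    if any(v is not None for v in q_draws):
        for arm in ARMS:
            q = payoffs[arm].per_cycle_qaly_by_state.copy()
            for k, v in enumerate(q_draws):
                if v is not None:
                    q[k] = v
            payoffs[arm] = payoffs[arm].with_qaly_weights(q, dt)

    for arm in ARMS:
        kwargs = {}
        v = draws[f"transport_cost_{arm}"]
        if v is not None:
            kwargs["transport_cost_per_treated_cycle"] = v
        v = draws[f"time_cost_{arm}"]
        if v is not None:
            kwargs["time_cost_per_treated_cycle"] = v
        v = draws[f"medical_cost_{arm}"]
        if v is not None:
            kwargs["medical_cost_per_treated_cycle"] = v
        if kwargs:
            payoffs[arm] = replace(payoffs[arm], **kwargs)

    prod_draws = [draws[f"productivity_loss_{s}"] for s in STATES]
    if any(v is not None for v in prod_draws):
        for arm in ARMS:
            prod = payoffs[arm].productivity_loss_per_cycle_by_state.copy()
            for k, v in enumerate(prod_draws):
                if v is not None:
                    prod[k] = v
            payoffs[arm] = replace(
                payoffs[arm], productivity_loss_per_cycle_by_state=prod
            )

    out = config.with_payoffs(payoffs)

    w_draws = [draws[f"pt_mix_scenario_{s + 1}"] for s in range(4)]
    if any(v is not None for v in w_draws):
        w = config.pt_mix.weights.copy()
        for k, v in enumerate(w_draws):
            if v is not None:
                w[k] = v
        w = w / w.sum()  # restore the simplex constraint
        mix = config.pt_mix.with_weights(w)
        out = out.with_pt_mix(mix)
        pt = out.payoffs["PT"]
        from .cea import pt_cycle_cost

        out = out.with_payoffs(
            {
                **out.payoffs,
                "PT": replace(pt, medical_cost_per_treated_cycle=pt_cycle_cost(mix)),
            }
        )

    models = dict(out.transition_models)
    mild_row = draws["tp_row_mild"]
    changed = False
    new_rows = {arm: models[arm].rows.copy() for arm in ARMS}
    if mild_row is not None:
        changed = True
        for arm in ARMS:
            new_rows[arm][0] = mild_row
    for arm in ARMS:
        for i, from_state in enumerate(STATES):
            if from_state == "mild":
                continue
            v = draws.get(f"tp_row_{arm}_{from_state}")
            if v is not None:
                changed = True
                new_rows[arm][i] = v
    if changed:
        models = {arm: models[arm].with_rows(new_rows[arm]) for arm in ARMS}
        out = out.with_transition_models(models)
    return out


@dataclass
class PSAResults:
    """Per-iteration draws plus summary accessors."""

    n_iterations: int
    seed: int
    wtp_per_qaly: float
    draws: pd.DataFrame  # iteration, qaly_{arm}, cost_{arm}_{perspective}

    def incremental(self, perspective: str) -> tuple[np.ndarray, np.ndarray]:
        """(delta_cost, delta_qaly) arrays, PPT - PT."""
        if perspective not in PERSPECTIVES:
            raise ValidationError(f"unknown perspective {perspective!r}")
        d_cost = (
            self.draws[f"cost_PPT_{perspective}"].to_numpy()
            - self.draws[f"cost_PT_{perspective}"].to_numpy()
        )
        d_qaly = self.draws["qaly_PPT"].to_numpy() - self.draws["qaly_PT"].to_numpy()
        return d_cost, d_qaly

    def summary(self) -> pd.DataFrame:
        rows = []
        for arm in ARMS:
            row = {
                "arm": arm,
                "mean_qaly": self.draws[f"qaly_{arm}"].mean(),
                "sd_qaly": self.draws[f"qaly_{arm}"].std(ddof=1),
            }
            for perspective in PERSPECTIVES:
                col = f"cost_{arm}_{perspective}"
                row[f"mean_cost_{perspective}"] = self.draws[col].mean()
                row[f"sd_cost_{perspective}"] = self.draws[col].std(ddof=1)
            rows.append(row)
        return pd.DataFrame(rows)

    def ce_plane(self, perspective: str) -> pd.DataFrame:
        d_cost, d_qaly = self.incremental(perspective)
        return pd.DataFrame(
            {
                "iteration": self.draws["iteration"],
                "incremental_qaly": d_qaly,
                "incremental_cost": d_cost,
            }
        )


def run_psa(
    config: "AnalysisConfig",
    n_iterations: int | None = None,
    seed: int | None = None,
    specs: list[DistributionSpec] | None = None,
) -> PSAResults:
    """Monte-Carlo PSA storing all three perspectives per iteration.

    Reproducible for a fixed seed: each iteration uses an independent
    substream spawned from the master seed, so results do not depend on
    evaluation order.
    """
    n = config.psa.n_iterations if n_iterations is None else int(n_iterations)
    master = config.psa.seed if seed is None else int(seed)
    if n < 1:
        raise ValidationError("n_iterations must be >= 1")
    if specs is None:
        specs = default_distribution_specs(config)

    streams = np.random.SeedSequence(master).spawn(n)
    records = []
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        sampled = sample_parameters(config, rng, specs)
        results = run_base_case(sampled)
        rec = {"iteration": i}
        for arm in ARMS:
            rec[f"qaly_{arm}"] = results["healthcare"].total_qaly[arm]
            for perspective in PERSPECTIVES:
                rec[f"cost_{arm}_{perspective}"] = results[perspective].total_cost[arm]
        records.append(rec)
    draws = pd.DataFrame.from_records(records)
    if not np.isfinite(draws.to_numpy()).all():
        raise ValidationError("non-finite PSA draw encountered")
    return PSAResults(
        n_iterations=n,
        seed=master,
        wtp_per_qaly=config.model.wtp_per_qaly,
        draws=draws,
    )


def prob_cost_effective(
    results: PSAResults, wtp: float, perspective: str = "healthcare"
) -> float:
    """Fraction of iterations with positive NMB for PPT at the given WTP."""
    d_cost, d_qaly = results.incremental(perspective)
    return float(np.mean(wtp * d_qaly - d_cost > 0))


def ceac(
    results: PSAResults,
    wtp_grid: np.ndarray,
    perspective: str = "healthcare",
) -> pd.DataFrame:
    """Acceptability curve over a non-negative WTP grid."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("wtp_grid must be non-empty")
    if np.any(grid < 0):
        raise ValidationError("wtp_grid must be non-negative")
    d_cost, d_qaly = results.incremental(perspective)
    probs = [float(np.mean(w * d_qaly - d_cost > 0)) for w in grid]
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": probs})
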