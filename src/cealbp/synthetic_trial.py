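"""Synthetic patient-level trial generator and input re-estimation.

Generates RCT-like records (severity category at baseline, end of
treatment and 3-month follow-up; EQ-5D-style utilities; productivity
amounts) with known ground truth, and re-derives the model inputs from
them: transition counts -> probability rows and Dirichlet concentrations,
pooled state utilities with method-of-moments Beta fits, and trapezoidal
area-under-the-curve QALYs.  Used for parameter-recovery testing without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    ARMS,
    STATES,
    TransitionModel,
    ValidationError,
)

TIMEPOINTS = ("baseline", "end_of_treatment", "month3")

#: Weeks per modelled year used when converting AUC integrals; 52 weeks
#: makes a 13-week assessment interval exactly one 0.25-year cycle.
WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class PatientRecord:
    patient_id: int
    arm: str
    severity_at: dict  # timepoint -> state label
    eq5d_utility_at: dict  # timepoint -> utility in [0, 1]
    productivity_loss_per_cycle: float

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}")
        if self.severity_at["baseline"] == "mild":
            raise ValidationError("baseline severity must be moderate or severe")
        for tp, u in self.eq5d_utility_at.items():
            if not 0.0 <= u <= 1.0:
                raise ValidationError(f"utility at {tp} outside [0, 1]: {u}")


@dataclass(frozen=True)
class TrialSpec:
    n_per_arm: int
    true_transition_models: dict  # arm -> TransitionModel
    baseline_distribution: np.ndarray  # (moderate, severe)
    utility_means_by_state: np.ndarray  # (3,) ordered like STATES
    utility_sd: float
    seed: int
    utility_noise: str = "truncated_normal"  # or "beta"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "baseline_distribution", np.asarray(self.baseline_distribution, float)
        )
        object.__setattr__(
            self,
            "utility_means_by_state",
            np.asarray(self.utility_means_by_state, float),
        )
        errors = []
        if self.n_per_arm < 1:
            errors.append("n_per_arm must be >= 1")
        if abs(self.baseline_distribution.sum() - 1.0) > 1e-6:
            errors.append("baseline_distribution must sum to 1")
        if self.utility_sd < 0:
            errors.append("utility_sd must be non-negative")
        if self.utility_noise not in ("truncated_normal", "beta"):
            errors.append(f"unknown utility_noise {self.utility_noise!r}")
        if errors:
            raise ValidationError("; ".join(errors))


def _draw_utility(rng: np.random.Generator, mean: float, sd: float, noise: str) -> float:
    if sd == 0:
        return mean
    if noise == "beta":
        v = sd**2
        nu = mean * (1 - mean) / v - 1.0
        if nu <= 0:  # variance too large for a Beta; fall back to truncation
            noise = "truncated_normal"
        else:
            return float(rng.beta(mean * nu, (1 - mean) * nu))
    while True:  # truncated normal via rejection; acceptance is high here
        u = rng.normal(mean, sd)
        if 0.0 <= u <= 1.0:
            return float(u)


def simulate_trial(spec: TrialSpec, productivity_by_state=None) -> list[PatientRecord]:
    """Generate patient records, deterministic for a fixed seed.

    Each patient draws a baseline state (moderate/severe only), then makes
    one transition per follow-up interval using the arm's true per-cycle
    rows, with utilities drawn around the state means.
    """
    rng = np.random.default_rng(spec.seed)
    if productivity_by_state is None:
        productivity_by_state = np.zeros(3)
    productivity_by_state = np.asarray(productivity_by_state, float)

    records: list[PatientRecord] = []
    pid = 0
    for arm in ARMS:
        rows = spec.true_transition_models[arm].rows
        for _ in range(spec.n_per_arm):
            baseline = 1 + rng.choice(2, p=spec.baseline_distribution)
            path = [baseline]
            for _interval in range(2):
                path.append(rng.choice(3, p=rows[path[-1]]))
            severity = {tp: STATES[s] for tp, s in zip(TIMEPOINTS, path)}
            utilities = {
                tp: _draw_utility(
                    rng,
                    spec.utility_means_by_state[s],
                    spec.utility_sd,
                    spec.utility_noise,
                )
                for tp, s in zip(TIMEPOINTS, path)
            }
            records.append(
                PatientRecord(
                    patient_id=pid,
                    arm=arm,
                    severity_at=severity,
                    eq5d_utility_at=utilities,
                    productivity_loss_per_cycle=float(
                        productivity_by_state[path[-1]]
                    ),
                )
            )
            pid += 1
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """One row per patient-timepoint (the CSV interchange layout)."""
    rows = []
    for r in records:
        for tp in TIMEPOINTS:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "arm": r.arm,
                    "timepoint": tp,
                    "severity": r.severity_at[tp],
                    "eq5d_utility": r.eq5d_utility_at[tp],
                    "productivity_loss_per_cycle": r.productivity_loss_per_cycle,
                }
            )
    return pd.DataFrame(rows)


def records_from_frame(frame: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for pid, group in frame.groupby("patient_id", sort=True):
        by_tp = group.set_index("timepoint")
        records.append(
            PatientRecord(
                patient_id=int(pid),
                arm=str(by_tp["arm"].iloc[0]),
                severity_at={tp: by_tp.loc[tp, "severity"] for tp in TIMEPOINTS},
                eq5d_utility_at={
                    tp: float(by_tp.loc[tp, "eq5d_utility"]) for tp in TIMEPOINTS
                },
                productivity_loss_per_cycle=float(
                    by_tp["productivity_loss_per_cycle"].iloc[0]
                ),
            )
        )
    return records


def estimate_transitions(
    records: list[PatientRecord],
    arm: str,
    from_timepoint: str = "end_of_treatment",
    to_timepoint: str = "month3",
    pseudo_count: float = 0.0,
) -> dict:
    """Counts-based rows and Dirichlet alphas for one observed interval.

    Returns state -> {"probs": row or None, "alphas": counts + pseudo_count,
    "n": departures}.  A source state with no observed departures is flagged
    with ``probs=None`` rather than invented.
    """
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}")
    for tp in (from_timepoint, to_timepoint):
        if tp not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {tp!r}")
    counts = np.zeros((3, 3))
    for r in records:
        if r.arm != arm:
            continue
        i = STATES.index(r.severity_at[from_timepoint])
        j = STATES.index(r.severity_at[to_timepoint])
        counts[i, j] += 1
    out = {}
    for i, state in enumerate(STATES):
        n = counts[i].sum()
        out[state] = {
            "probs": counts[i] / n if n > 0 else None,
            "alphas": counts[i] + pseudo_count,
            "n": int(n),
        }
    return out


def auc_qaly(utilities_by_week: dict, weeks_per_year: float = WEEKS_PER_YEAR) -> float:
    """Trapezoidal area under the utility curve, in QALYs.

    ``utilities_by_week`` maps assessment time in weeks -> utility.  Times
    must be strictly increasing; at least two points are required.
    """
    items = sorted(utilities_by_week.items())
    if len(items) < 2:
        raise ValidationError("AUC QALY needs at least two timepoints")
    weeks = np.array([t for t, _ in items], dtype=float)
    values = np.array([u for _, u in items], dtype=float)
    if np.any(np.diff(weeks) <= 0):
        raise ValidationError("assessment times must be strictly increasing")
    return float(np.trapezoid(values, weeks / weeks_per_year))


def estimate_state_utilities(records: list[PatientRecord]) -> dict:
    """Pooled per-state utility means with method-of-moments Beta fits.

    Returns state -> {"mean", "var", "n", "beta"}; ``beta`` is None when the
    variance is zero (fixed value, no fit available).  The fit uses
    nu = m(1-m)/v - 1, alpha = m*nu, beta = (1-m)*nu.
    """
    samples: dict[str, list[float]] = {s: [] for s in STATES}
    for r in records:
        for tp in TIMEPOINTS:
            samples[r.severity_at[tp]].append(r.eq5d_utility_at[tp])
    out = {}
    for state in STATES:
        vals = np.asarray(samples[state], dtype=float)
        if vals.size < 2:
            raise ValidationError(
                f"state {state!r} observed {vals.size} time(s); need at least 2"
            )
        m = float(vals.mean())
        v = float(vals.var(ddof=1))
        if v < 1e-12:  # degenerate sample up to float round-off
            v = 0.0
        beta = None
        if v > 0:
            nu = m * (1 - m) / v - 1.0
            if nu > 0:
                beta = (m * nu, (1 - m) * nu)
        out[state] = {"mean": m, "var": v, "n": int(vals.size), "beta": beta}
    return out
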