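"""Three-state Markov cohort engine.

The disease model tracks a closed cohort over mild / moderate / severe pain
states on a fixed cycle grid.  The mild row of the transition table is a
two-cycle quantity, so the engine supports three ways of fitting it into the
per-cycle recursion (:func:`expand_mild_row`): a tunnel construction, a
matrix-root conversion, and direct per-cycle application.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg as sla
from scipy import optimize

logger = logging.getLogger(__name__)

STATES: tuple[str, str, str] = ("mild", "moderate", "severe")
ARMS: tuple[str, str] = ("PPT", "PT")

#: Half-open NRS intervals defining the severity states on the 0-10 scale.
NRS_CUTS: dict[str, tuple[float, float]] = {
    "mild": (0.0, 4.0),
    "moderate": (4.0, 7.0),
    "severe": (7.0, 10.0 + 1e-12),
}

MILD_MODES = ("tunnel", "matrix_root", "direct")
CYCLE_CORRECTIONS = ("none", "half_cycle")
DISCOUNT_TIMINGS = ("cycle_start", "cycle_end")

_ROW_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a model input violates its contract."""


@dataclass(frozen=True)
class HealthState:
    """One severity category with its defining NRS interval."""

    label: str
    nrs_low: float
    nrs_high: float

    def __post_init__(self) -> None:
        if self.label not in STATES:
            raise ValidationError(f"unknown state label {self.label!r}")

    def contains(self, nrs: float) -> bool:
        return self.nrs_low <= nrs < self.nrs_high


HEALTH_STATES: tuple[HealthState, ...] = tuple(
    HealthState(s, *NRS_CUTS[s]) for s in STATES
)


def classify_nrs(nrs: float) -> str:
    """Map a 0-10 numeric rating scale score to a severity label."""
    if not 0.0 <= nrs <= 10.0:
        raise ValidationError(f"NRS score {nrs} outside [0, 10]")
    if nrs < 4.0:
        return "mild"
    if nrs < 7.0:
        return "moderate"
    return "severe"


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic transition table for one arm.

    ``rows`` is ordered (mild, moderate, severe) -> probability vector over
    the same ordering.  The mild row is a 2-cycle quantity
    (``mild_row_interval_cycles == 2``); the other rows are per-cycle.
    ``dirichlet_alpha`` carries the concentration vectors used by the PSA.
    """

    arm: str
    rows: np.ndarray  # (3, 3)
    dirichlet_alpha: np.ndarray  # (3, 3)
    mild_row_interval_cycles: int = 2

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}")
        if self.mild_row_interval_cycles not in (1, 2):
            raise ValidationError(
                f"mild_row_interval_cycles must be 1 or 2, "
                f"got {self.mild_row_interval_cycles}"
            )
        _validate_rows(self.rows)
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=float))
        object.__setattr__(
            self, "dirichlet_alpha", np.asarray(self.dirichlet_alpha, dtype=float)
        )

    def row(self, state: str) -> np.ndarray:
        return self.rows[STATES.index(state)]

    def with_rows(self, rows: np.ndarray) -> "TransitionModel":
        return replace(self, rows=np.asarray(rows, dtype=float))


def _validate_rows(rows: np.ndarray) -> None:
    rows = np.asarray(rows, dtype=float)
    if rows.shape != (3, 3):
        raise ValidationError(f"expected a 3x3 transition table, got {rows.shape}")
    for i, state in enumerate(STATES):
        if np.any(rows[i] < 0):
            raise ValidationError(f"negative probability in {state!r} row: {rows[i]}")
        s = rows[i].sum()
        if abs(s - 1.0) > _ROW_SUM_TOL:
            raise ValidationError(
                f"{state!r} row sums to {s:.8f}, expected 1 within {_ROW_SUM_TOL}"
            )


def build_transition_model(
    rows,
    alphas,
    arm: str,
    *,
    renormalize: bool = False,
    mild_row_interval_cycles: int = 2,
) -> TransitionModel:
    """Validate and assemble a :class:`TransitionModel`.

    ``rows`` / ``alphas`` map state label -> length-3 vector, or are (3, 3)
    arrays ordered (mild, moderate, severe).  With ``renormalize=True`` rows
    are rescaled to sum to 1 before validation (rejecting rows off by more
    than 1e-6 otherwise).
    """
    row_mat = _as_row_matrix(rows, "rows")
    alpha_mat = _as_row_matrix(alphas, "alphas")
    if np.any(row_mat < 0):
        bad = STATES[int(np.where((row_mat < 0).any(axis=1))[0][0])]
        raise ValidationError(f"negative probability in {bad!r} row")
    if renormalize:
        sums = row_mat.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValidationError("cannot renormalize a zero row")
        row_mat = row_mat / sums
    return TransitionModel(
        arm=arm,
        rows=row_mat,
        dirichlet_alpha=alpha_mat,
        mild_row_interval_cycles=mild_row_interval_cycles,
    )


def _as_row_matrix(rows, what: str) -> np.ndarray:
    if isinstance(rows, dict):
        missing = [s for s in STATES if s not in rows]
        if missing:
            raise ValidationError(f"{what} missing states: {missing}")
        mat = np.array([rows[s] for s in STATES], dtype=float)
    else:
        mat = np.asarray(rows, dtype=float)
    if mat.shape != (3, 3):
        raise ValidationError(f"{what} must be 3 vectors of length 3, got {mat.shape}")
    return mat


@dataclass(frozen=True)
class ModelSpec:
    """Global run settings: grid, discounting, threshold and conventions."""

    cycle_length_years: float = 0.25
    horizon_cycles: int = 12
    annual_discount_rate: float = 0.045
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.12, 0.88])
    )
    wtp_per_qaly: float = 30_500_000 / 1_144.61
    krw_per_usd: float = 1_144.61
    mild_handling_mode: str = "direct"
    cycle_correction: str = "half_cycle"
    discount_timing: str = "cycle_start"

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "initial_distribution",
            np.asarray(self.initial_distribution, dtype=float),
        )
        errors = []
        pi0 = self.initial_distribution
        if pi0.shape != (3,):
            errors.append(f"initial_distribution must have length 3, got {pi0.shape}")
        else:
            if abs(pi0.sum() - 1.0) > _ROW_SUM_TOL:
                errors.append(f"initial_distribution sums to {pi0.sum():.8f}")
            if np.any(pi0 < 0):
                errors.append("initial_distribution has negative mass")
        if self.cycle_length_years <= 0:
            errors.append("cycle_length_years must be positive")
        if self.horizon_cycles < 1:
            errors.append("horizon_cycles must be >= 1")
        if self.annual_discount_rate < 0:
            errors.append("annual_discount_rate must be non-negative")
        if self.mild_handling_mode not in MILD_MODES:
            errors.append(
                f"mild_handling_mode must be one of {MILD_MODES}, "
                f"got {self.mild_handling_mode!r}"
            )
        if self.cycle_correction not in CYCLE_CORRECTIONS:
            errors.append(f"unknown cycle_correction {self.cycle_correction!r}")
        if self.discount_timing not in DISCOUNT_TIMINGS:
            errors.append(f"unknown discount_timing {self.discount_timing!r}")
        if errors:
            raise ValidationError("; ".join(errors))

    @property
    def horizon_years(self) -> float:
        return self.horizon_cycles * self.cycle_length_years

    def conventions(self) -> tuple[str, str, str]:
        return (self.mild_handling_mode, self.cycle_correction, self.discount_timing)


@dataclass(frozen=True)
class ExpandedMatrix:
    """Per-cycle transition matrix over a (possibly tunnel-expanded) space."""

    matrix: np.ndarray
    state_labels: tuple[str, ...]
    collapse_map: tuple[int, ...]  # expanded index -> index into STATES

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def collapse(self, occupancy: np.ndarray) -> np.ndarray:
        """Merge tunnel sub-states back onto the three clinical states."""
        occupancy = np.atleast_2d(occupancy)
        out = np.zeros((occupancy.shape[0], 3))
        for j, target in enumerate(self.collapse_map):
            out[:, target] += occupancy[:, j]
        return out

    def expand_initial(self, pi0: np.ndarray) -> np.ndarray:
        """Lift a 3-state initial distribution onto the expanded space.

        Mass entering mild from outside is placed in the first mild
        sub-state, mirroring what a transition into mild would do.
        """
        init = np.zeros(self.n_states)
        used = set()
        for s_idx in range(3):
            j = self.collapse_map.index(s_idx)
            used.add(j)
            init[j] = pi0[s_idx]
        return init


def expand_mild_row(model: TransitionModel, mode: str) -> ExpandedMatrix:
    """Turn the mixed-interval transition table into a per-cycle matrix.

    * ``tunnel`` -- mild splits into two sequential sub-states; entrants sit
      one cycle in ``mild_a``, then exit from ``mild_b`` using the printed
      2-cycle row.
    * ``matrix_root`` -- solves for a per-cycle mild row whose 2-step
      composition with the printed moderate/severe rows reproduces the
      printed 2-cycle mild row (principal square root as the seed, refined
      on the probability simplex).  Falls back to ``tunnel`` with a warning
      when no valid stochastic root exists.
    * ``direct`` -- applies the printed mild row every cycle as-is.
    """
    if mode not in MILD_MODES:
        raise ValidationError(f"unknown mild handling mode {mode!r}")
    mild, moderate, severe = model.rows

    if model.mild_row_interval_cycles == 1 or mode == "direct":
        return ExpandedMatrix(
            matrix=model.rows.copy(),
            state_labels=STATES,
            collapse_map=(0, 1, 2),
        )

    if mode == "matrix_root":
        row = _per_cycle_mild_row(mild, moderate, severe)
        if row is None:
            warnings.warn(
                "no valid stochastic per-cycle root for the mild row; "
                "falling back to tunnel mode",
                RuntimeWarning,
                stacklevel=2,
            )
            mode = "tunnel"
        else:
            return ExpandedMatrix(
                matrix=np.vstack([row, moderate, severe]),
                state_labels=STATES,
                collapse_map=(0, 1, 2),
            )

    # tunnel: states (mild_a, mild_b, moderate, severe); transitions into
    # mild land in mild_a, which feeds mild_b deterministically.
    mat = np.zeros((4, 4))
    mat[0, 1] = 1.0
    mat[1] = [mild[0], 0.0, mild[1], mild[2]]
    mat[2] = [moderate[0], 0.0, moderate[1], moderate[2]]
    mat[3] = [severe[0], 0.0, severe[1], severe[2]]
    return ExpandedMatrix(
        matrix=mat,
        state_labels=("mild_a", "mild_b", "moderate", "severe"),
        collapse_map=(0, 0, 1, 2),
    )


# Backwards-compatible alias used by early callers.
expand_mild_tunnel = expand_mild_row


def _per_cycle_mild_row(
    mild2: np.ndarray, moderate: np.ndarray, severe: np.ndarray
) -> np.ndarray | None:
    """Per-cycle mild row from the principal root of the 2-step matrix.

    The implied 2-step matrix stacks the printed 2-cycle mild row on top of
    the squared composition of the 1-cycle rows; its principal square root,
    clipped to [0, 1] and renormalized, supplies the per-cycle mild row.  A
    quadratic refinement on the simplex then minimises the residual of
    m[0]*m + m[1]*moderate + m[2]*severe against the printed 2-cycle row
    (with M = [m; moderate; severe], that expression is the 2-step mild
    row).  Returns None when no real root exists.

    For most real transition tables the system is only approximately
    solvable (the printed 2-cycle row need not lie in the cone reachable
    through the 1-cycle rows), so the returned row is a best
    approximation, not an exact root.
    """
    one_step = np.vstack([mild2, moderate, severe])
    two_step = one_step @ one_step
    two_step[0] = mild2
    root = sla.sqrtm(two_step.astype(complex))
    if np.max(np.abs(root.imag)) > 1e-8:
        return None
    seed = np.clip(root.real[0], 0.0, 1.0)
    if seed.sum() <= 0:
        return None
    seed = seed / seed.sum()

    def residual(m: np.ndarray) -> float:
        two = m[0] * m + m[1] * moderate + m[2] * severe
        return float(np.sum((two - mild2) ** 2))

    res = optimize.minimize(
        residual,
        seed,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * 3,
        constraints=[{"type": "eq", "fun": lambda m: m.sum() - 1.0}],
        options={"ftol": 1e-14, "maxiter": 200},
    )
    row = np.clip(res.x if res.success else seed, 0.0, 1.0)
    if row.sum() <= 0:
        return None
    return row / row.sum()


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle for one arm.

    ``occupancy`` has one row per cycle index 0..T over the expanded state
    space; ``collapsed_occupancy`` merges tunnel sub-states back onto
    (mild, moderate, severe).
    """

    arm: str
    occupancy: np.ndarray
    collapsed_occupancy: np.ndarray
    state_labels: tuple[str, ...]

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


def run_cohort(spec: ModelSpec, model: TransitionModel) -> CohortTrace:
    """Deterministic cohort simulation over ``spec.horizon_cycles`` cycles."""
    expanded = expand_mild_row(model, spec.mild_handling_mode)
    T = spec.horizon_cycles
    occ = np.zeros((T + 1, expanded.n_states))
    occ[0] = expanded.expand_initial(spec.initial_distribution)
    for t in range(T):
        occ[t + 1] = occ[t] @ expanded.matrix
    return CohortTrace(
        arm=model.arm,
        occupancy=occ,
        collapsed_occupancy=expanded.collapse(occ),
        state_labels=expanded.state_labels,
    )


def discount_factor(cycle_index: int, spec: ModelSpec) -> float:
    """Discount factor for an accrual in the given cycle.

    ``cycle_start`` timing discounts to the start of the cycle (cycle 0 is
    undiscounted); ``cycle_end`` discounts to its end.
    """
    if cycle_index < 0:
        raise ValidationError(f"cycle index must be non-negative, got {cycle_index}")
    t = cycle_index if spec.discount_timing == "cycle_start" else cycle_index + 1
    return float(
        (1.0 + spec.annual_discount_rate) ** (-t * spec.cycle_length_years)
    )


def trace_to_frame(trace: CohortTrace, spec: ModelSpec):
    """Tabulate a trace: cycle index, collapsed occupancy, discount factor."""
    import pandas as pd

    T = trace.n_cycles
    return pd.DataFrame(
        {
            "cycle": np.arange(T + 1),
            "mild": trace.collapsed_occupancy[:, 0],
            "moderate": trace.collapsed_occupancy[:, 1],
            "severe": trace.collapsed_occupancy[:, 2],
            "discount_factor": [
                discount_factor(min(t, T), spec) for t in range(T + 1)
            ],
        }
    )
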