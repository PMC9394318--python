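"""Discrete-time generalized-state Markov model of the PJI treatment course.

Five states, one step per month: ``PJI`` (waiting for PJI-related surgery),
``SECOND_STAGE`` (spacer in place, waiting for prosthesis installation),
``NON_PJI_OP`` (waiting for / undergoing surgery unrelated to PJI),
``OBSERVATION`` (no PJI), and absorbing ``DEATH``.  First PJI episodes and
relapses share the single ``PJI`` state.

Patient records are discretized into monthly state sequences anchored at the
manifestation date (fixed 30-day bins).  A month containing operations takes
the *waiting* state of its last operation; event-free months take the
post-operative ambient state (spacer-installing operations leave the patient
waiting for the second stage, every other operation returns the patient to
observation).  Operations therefore sit on the transition out of their
month, which is where their costs are charged: leaving ``PJI`` means the PJI
surgery happened, ``SECOND_STAGE → OBSERVATION`` is the second-stage
exchange, leaving ``NON_PJI_OP`` is the unrelated surgery.

Transition probabilities are estimated by pooled transition counting;
payoffs accrue per month of state occupancy (utility weights and monthly
stay costs) plus per-transition operation costs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .records import (
    OperationCategory,
    PatientRecord,
    SPACER_INSTALLING_LABELS,
    TreatmentMethod,
)
from .uncertainty import subsample_estimates, t_interval

__all__ = [
    "MarkovState",
    "Trajectory",
    "TransitionMatrix",
    "StatePayoffs",
    "discretize_to_months",
    "estimate_transitions",
    "simulate_trajectory",
    "simulate_states",
    "accumulate_payoffs",
    "mean_simulated_payoffs",
    "MarkovCEModel",
]


class MarkovState(IntEnum):
    PJI = 0
    SECOND_STAGE = 1
    NON_PJI_OP = 2
    OBSERVATION = 3
    DEATH = 4


N_STATES = len(MarkovState)


@dataclass(frozen=True)
class Trajectory:
    """Ordered monthly state sequence for one real or simulated patient."""

    states: tuple[MarkovState, ...]
    patient_id: str | None = None

    def __len__(self) -> int:
        return len(self.states)

    def occupancy(self) -> dict[MarkovState, int]:
        """Months spent in each state; values sum to the trajectory length."""
        occ = {s: 0 for s in MarkovState}
        for s in self.states:
            occ[s] += 1
        return occ


def _waiting_state(op) -> MarkovState:
    if op.op_type.is_second_stage:
        return MarkovState.SECOND_STAGE
    if op.op_type.category is OperationCategory.NO_PJI:
        return MarkovState.NON_PJI_OP
    return MarkovState.PJI


def _ambient_state(op) -> MarkovState:
    if op.op_type.label in SPACER_INSTALLING_LABELS:
        return MarkovState.SECOND_STAGE
    return MarkovState.OBSERVATION


def discretize_to_months(
    record: PatientRecord, horizon_months: int | None = None
) -> Trajectory:
    """Convert one record into its monthly state sequence.

    Month ``k`` covers days ``[30k, 30(k+1))`` after the manifestation date.
    The sequence runs to the censoring month (death months inclusive are
    ``DEATH``); ``horizon_months`` truncates it.
    """
    origin = record.manifestation_date

    def month_of(d) -> int:
        return (d - origin).days // 30

    end_month = month_of(record.censor_date)
    if record.death_date is not None:
        end_month = max(end_month, month_of(record.death_date))
    n_months = end_month + 1
    if horizon_months is not None:
        n_months = min(n_months, horizon_months)

    ops_by_month: dict[int, list] = {}
    for op in record.operations:
        ops_by_month.setdefault(month_of(op.date), []).append(op)

    death_month = month_of(record.death_date) if record.death_date is not None else None

    states: list[MarkovState] = []
    ambient = MarkovState.PJI  # waiting for the first PJI surgery
    for m in range(n_months):
        if death_month is not None and m >= death_month:
            states.append(MarkovState.DEATH)
            continue
        ops = ops_by_month.get(m)
        if ops:
            states.append(_waiting_state(ops[-1]))
            ambient = _ambient_state(ops[-1])
        else:
            states.append(ambient)
    return Trajectory(states=tuple(states), patient_id=record.id)


@dataclass
class TransitionMatrix:
    """Row-stochastic 5x5 monthly transition matrix with optional t-intervals."""

    probabilities: np.ndarray
    counts: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        p = self.probabilities
        if p.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected a {N_STATES}x{N_STATES} matrix, got {p.shape}")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        row_sums = p.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError(f"rows must sum to 1, got {row_sums}")
        death = p[MarkovState.DEATH]
        if not (death[MarkovState.DEATH] == 1.0 and death.sum() == 1.0):
            raise ValueError("DEATH must be absorbing")

    def to_frame(self) -> pd.DataFrame:
        names = [s.name for s in MarkovState]
        return pd.DataFrame(self.probabilities, index=names, columns=names)


def estimate_transitions(trajectories: Iterable[Trajectory]) -> TransitionMatrix:
    """Pooled transition counting: ``P[i, j] = count(i→j) / count(i→·)``.

    Rows with no observed transitions (small subgroups never visit every
    state) become unit self-loops with a warning; the DEATH row is forced
    absorbing.
    """
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    any_pair = False
    for traj in trajectories:
        s = traj.states
        for a, b in zip(s, s[1:]):
            counts[a, b] += 1
            any_pair = True
    if not any_pair:
        raise ValueError("need at least one trajectory with >= 2 months")

    probs = np.zeros((N_STATES, N_STATES), dtype=float)
    for i in range(N_STATES):
        total = counts[i].sum()
        if i == MarkovState.DEATH:
            probs[i, MarkovState.DEATH] = 1.0
            continue
        if total == 0:
            warnings.warn(
                f"no observed transitions out of {MarkovState(i).name}; "
                "using a unit self-loop",
                stacklevel=2,
            )
            probs[i, i] = 1.0
        else:
            probs[i] = counts[i] / total
    return TransitionMatrix(probabilities=probs, counts=counts)


def simulate_states(
    matrix: TransitionMatrix | np.ndarray,
    n_trajectories: int,
    horizon_months: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate ``n`` monthly trajectories; returns an (n, horizon) int array.

    Every trajectory starts in PJI; DEATH is absorbing.
    """
    p = matrix.probabilities if isinstance(matrix, TransitionMatrix) else np.asarray(matrix, float)
    if p.shape != (N_STATES, N_STATES) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("matrix must be row-stochastic 5x5")
    if horizon_months < 1:
        raise ValueError("horizon_months must be >= 1")
    rng = np.random.default_rng(rng)
    cum = np.cumsum(p, axis=1)
    states = np.empty((n_trajectories, horizon_months), dtype=np.int64)
    states[:, 0] = MarkovState.PJI
    for t in range(1, horizon_months):
        u = rng.random(n_trajectories)
        cur = states[:, t - 1]
        nxt = (cum[cur] < u[:, None]).sum(axis=1)
        states[:, t] = np.minimum(nxt, N_STATES - 1)
    return states


def simulate_trajectory(
    matrix: TransitionMatrix | np.ndarray,
    horizon_months: int,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Simulate a single monthly trajectory starting from PJI."""
    s = simulate_states(matrix, 1, horizon_months, rng)[0]
    return Trajectory(states=tuple(MarkovState(int(x)) for x in s))


_DEFAULT_UTILITIES: dict[MarkovState, float] = {
    MarkovState.PJI: 0.35,
    MarkovState.SECOND_STAGE: 0.7,
    MarkovState.NON_PJI_OP: 0.5,
    MarkovState.OBSERVATION: 0.85,
    MarkovState.DEATH: 0.0,
}

# Monthly stay costs (rubles/month): inpatient-level while waiting for PJI or
# non-PJI surgery, home care with a spacer in place, routine follow-up under
# observation.
_DEFAULT_MONTHLY_COSTS: dict[MarkovState, float] = {
    MarkovState.PJI: 40_000.0,
    MarkovState.SECOND_STAGE: 8_000.0,
    MarkovState.NON_PJI_OP: 30_000.0,
    MarkovState.OBSERVATION: 2_000.0,
    MarkovState.DEATH: 0.0,
}

# Transitions that imply a performed operation, with default operation costs
# (rubles): leaving PJI = the PJI surgery, SECOND_STAGE -> OBSERVATION = the
# second-stage prosthesis installation, leaving NON_PJI_OP = the unrelated
# surgery.
_DEFAULT_TRANSITION_COSTS: dict[tuple[MarkovState, MarkovState], float] = {
    (MarkovState.PJI, MarkovState.SECOND_STAGE): 90_000.0,
    (MarkovState.PJI, MarkovState.OBSERVATION): 90_000.0,
    (MarkovState.PJI, MarkovState.NON_PJI_OP): 90_000.0,
    (MarkovState.SECOND_STAGE, MarkovState.OBSERVATION): 130_000.0,
    (MarkovState.NON_PJI_OP, MarkovState.OBSERVATION): 35_000.0,
    (MarkovState.NON_PJI_OP, MarkovState.PJI): 35_000.0,
    (MarkovState.NON_PJI_OP, MarkovState.SECOND_STAGE): 35_000.0,
}


@dataclass
class StatePayoffs:
    """Per-state utility weights (annual QALY), monthly stay costs, and
    per-transition operation costs."""

    utility_per_state: dict[MarkovState, float] = field(
        default_factory=lambda: dict(_DEFAULT_UTILITIES)
    )
    monthly_cost_per_state: dict[MarkovState, float] = field(
        default_factory=lambda: dict(_DEFAULT_MONTHLY_COSTS)
    )
    operation_cost_per_transition: dict[tuple[MarkovState, MarkovState], float] = field(
        default_factory=lambda: dict(_DEFAULT_TRANSITION_COSTS)
    )

    def __post_init__(self):
        missing = [s.name for s in MarkovState if s not in self.utility_per_state]
        missing += [
            f"monthly_cost[{s.name}]"
            for s in MarkovState
            if s not in self.monthly_cost_per_state
        ]
        if missing:
            raise ValueError(f"missing payoff entries: {missing}")
        for s, u in self.utility_per_state.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility for {s.name} must be in [0, 1], got {u}")
        if self.utility_per_state[MarkovState.DEATH] != 0.0:
            raise ValueError("DEATH utility must be 0")
        if any(c < 0 for c in self.monthly_cost_per_state.values()) or any(
            c < 0 for c in self.operation_cost_per_transition.values()
        ):
            raise ValueError("costs must be non-negative")

    @classmethod
    def from_records(
        cls,
        records: Sequence[PatientRecord],
        utility_per_state: Mapping[MarkovState, float] | None = None,
        monthly_cost_per_state: Mapping[MarkovState, float] | None = None,
    ) -> "StatePayoffs":
        """Estimate per-transition operation costs as category means over the
        recorded operation costs (averaging all interventions attributable to
        each generalized state); stay costs and utilities keep their defaults
        unless overridden."""
        pji_costs, ss_costs, non_pji_costs = [], [], []
        for r in records:
            for op in r.operations:
                if op.op_type.is_second_stage:
                    ss_costs.append(op.cost)
                elif op.op_type.category is OperationCategory.NO_PJI:
                    non_pji_costs.append(op.cost)
                else:
                    pji_costs.append(op.cost)
        trans = dict(_DEFAULT_TRANSITION_COSTS)
        if pji_costs:
            m = float(np.mean(pji_costs))
            for to in (MarkovState.SECOND_STAGE, MarkovState.OBSERVATION, MarkovState.NON_PJI_OP):
                trans[(MarkovState.PJI, to)] = m
        if ss_costs:
            trans[(MarkovState.SECOND_STAGE, MarkovState.OBSERVATION)] = float(np.mean(ss_costs))
        if non_pji_costs:
            m = float(np.mean(non_pji_costs))
            for to in (MarkovState.OBSERVATION, MarkovState.PJI, MarkovState.SECOND_STAGE):
                trans[(MarkovState.NON_PJI_OP, to)] = m
        return cls(
            utility_per_state=dict(utility_per_state or _DEFAULT_UTILITIES),
            monthly_cost_per_state=dict(monthly_cost_per_state or _DEFAULT_MONTHLY_COSTS),
            operation_cost_per_transition=trans,
        )

    def utility_vector(self) -> np.ndarray:
        return np.array([self.utility_per_state[s] for s in MarkovState])

    def monthly_cost_vector(self) -> np.ndarray:
        return np.array([self.monthly_cost_per_state[s] for s in MarkovState])

    def transition_cost_matrix(self) -> np.ndarray:
        c = np.zeros((N_STATES, N_STATES))
        for (a, b), v in self.operation_cost_per_transition.items():
            c[a, b] = v
        return c


def accumulate_payoffs(
    trajectory: Trajectory,
    payoffs: StatePayoffs,
    annualize: bool = True,
    discount_rate: float = 0.0,
) -> tuple[float, float]:
    """Total (QALY, cost) of one trajectory.

    QALY = Σ months-in-state × utility, divided by 12 when ``annualize`` is
    set (utility weights are annual).  Cost = Σ months-in-state × monthly
    stay cost + operation costs over realized state changes that imply an
    operation.  ``discount_rate`` is an annual rate applied per month
    (default 0: no discounting).
    """
    u = payoffs.utility_per_state
    c = payoffs.monthly_cost_per_state
    scale = 1.0 / 12.0 if annualize else 1.0
    qaly = 0.0
    cost = 0.0
    for m, s in enumerate(trajectory.states):
        df = 1.0 if discount_rate == 0.0 else (1.0 + discount_rate) ** (-m / 12.0)
        qaly += u[s] * scale * df
        cost += c[s] * df
    for m, (a, b) in enumerate(zip(trajectory.states, trajectory.states[1:])):
        if a != b:
            op_cost = payoffs.operation_cost_per_transition.get((a, b))
            if op_cost is not None:
                df = 1.0 if discount_rate == 0.0 else (1.0 + discount_rate) ** (-(m + 1) / 12.0)
                cost += op_cost * df
    return qaly, cost


def mean_simulated_payoffs(
    states: np.ndarray, payoffs: StatePayoffs, annualize: bool = True
) -> tuple[float, float, float, float]:
    """Vectorized mean (QALY, cost) over an (n, horizon) state array, with
    standard errors: returns (qaly, cost, se_qaly, se_cost)."""
    u = payoffs.utility_vector()
    c = payoffs.monthly_cost_vector()
    tc = payoffs.transition_cost_matrix()
    scale = 1.0 / 12.0 if annualize else 1.0
    qalys = u[states].sum(axis=1) * scale
    costs = c[states].sum(axis=1)
    a, b = states[:, :-1], states[:, 1:]
    costs = costs + np.where(a != b, tc[a, b], 0.0).sum(axis=1)
    n = states.shape[0]
    return (
        float(qalys.mean()),
        float(costs.mean()),
        float(qalys.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        float(costs.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
    )


class MarkovCEModel(BaseEstimator):
    """Generalized-state monthly Markov cost-effectiveness model.

    Parameters
    ----------
    method
        Restrict fitting to records of one treatment method (None = all).
    horizon_months
        Analysis horizon; payoff totals accrue over this many months.
    payoffs
        StatePayoffs; when None, operation costs are estimated from the
        fitted records and defaults are used for stay costs and utilities.
    annualize
        Treat utility weights as annual (divide monthly accrual by 12).
    discount_rate
        Annual discount rate hook (default 0, i.e. none).
    bootstrap, n_subsamples, subsample_fraction, alpha
        Subsample-bootstrap settings for transition-probability intervals.
    random_state
        Seed for the bootstrap subsample draws.

    Attributes (after ``fit``)
    --------------------------
    trajectories_ : list[Trajectory]
    transition_matrix_ : TransitionMatrix (with lower/upper when bootstrapped)
    payoffs_ : StatePayoffs
    n_records_ : int
    """

    def __init__(
        self,
        method: TreatmentMethod | None = None,
        horizon_months: int = 30,
        payoffs: StatePayoffs | None = None,
        annualize: bool = True,
        discount_rate: float = 0.0,
        bootstrap: bool = False,
        n_subsamples: int = 10,
        subsample_fraction: float = 0.8,
        alpha: float = 0.05,
        random_state: int | None = None,
    ):
        self.method = method
        self.horizon_months = horizon_months
        self.payoffs = payoffs
        self.annualize = annualize
        self.discount_rate = discount_rate
        self.bootstrap = bootstrap
        self.n_subsamples = n_subsamples
        self.subsample_fraction = subsample_fraction
        self.alpha = alpha
        self.random_state = random_state

    def _select(self, records: Sequence[PatientRecord]) -> list[PatientRecord]:
        if self.method is None:
            return list(records)
        return [
            r
            for r in records
            if r.method is self.method and r.cohort is self.method.cohort
        ]

    def fit(self, X: Sequence[PatientRecord], y=None) -> "MarkovCEModel":
        records = self._select(X)
        if not records:
            name = self.method.label if self.method is not None else "<all>"
            raise ValueError(f"no records for treatment method {name}")
        self.n_records_ = len(records)
        self.trajectories_ = [
            discretize_to_months(r, horizon_months=self.horizon_months) for r in records
        ]
        self.transition_matrix_ = estimate_transitions(self.trajectories_)
        self.payoffs_ = (
            self.payoffs if self.payoffs is not None else StatePayoffs.from_records(records)
        )
        if self.bootstrap:
            self._bootstrap_intervals(records)
        return self

    def _bootstrap_intervals(self, records: list[PatientRecord]) -> None:
        rng = np.random.default_rng(self.random_state)
        estimates = np.full((self.n_subsamples, N_STATES, N_STATES), np.nan)

        k = 0

        def estimator(subset):
            nonlocal k
            trajs = [discretize_to_months(r, self.horizon_months) for r in subset]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                estimates[k] = estimate_transitions(trajs).probabilities
            k += 1
            return 0.0

        subsample_estimates(
            records,
            estimator,
            n_subsamples=self.n_subsamples,
            fraction=self.subsample_fraction,
            rng=rng,
        )
        lower = np.zeros((N_STATES, N_STATES))
        upper = np.zeros((N_STATES, N_STATES))
        for i in range(N_STATES):
            for j in range(N_STATES):
                ci = t_interval(estimates[:, i, j], alpha=self.alpha, clip=(0.0, 1.0))
                lower[i, j], upper[i, j] = ci.lower, ci.upper
        tm = self.transition_matrix_
        self.transition_matrix_ = TransitionMatrix(
            probabilities=tm.probabilities, counts=tm.counts, lower=lower, upper=upper
        )

    def simulate(
        self,
        n_trajectories: int,
        horizon_months: int | None = None,
        rng: np.random.Generator | int | None = None,
    ) -> np.ndarray:
        """Simulate fitted-model trajectories; (n, horizon) state-index array."""
        h = horizon_months or self.horizon_months
        return simulate_states(self.transition_matrix_, n_trajectories, h, rng)

    def expected_payoffs(self, horizon_months: int | None = None) -> tuple[float, float]:
        """Analytic expected (QALY, cost) over the horizon via occupancy
        propagation: o_{t+1} = o_t P, utilities and stay costs accrue per
        month of expected occupancy, operation costs per expected realized
        transition."""
        h = horizon_months or self.horizon_months
        if h < 1:
            return 0.0, 0.0
        p = self.transition_matrix_.probabilities
        u = self.payoffs_.utility_vector()
        c = self.payoffs_.monthly_cost_vector()
        tc = self.payoffs_.transition_cost_matrix()
        np.fill_diagonal(tc, 0.0)  # only realized state *changes* carry costs
        scale = 1.0 / 12.0 if self.annualize else 1.0
        occ = np.zeros(N_STATES)
        occ[MarkovState.PJI] = 1.0
        qaly = 0.0
        cost = 0.0
        for t in range(h):
            df = 1.0 if self.discount_rate == 0.0 else (1.0 + self.discount_rate) ** (-t / 12.0)
            qaly += float(occ @ u) * scale * df
            cost += float(occ @ c) * df
            if t < h - 1:
                dft = 1.0 if self.discount_rate == 0.0 else (1.0 + self.discount_rate) ** (-(t + 1) / 12.0)
                cost += float((occ[:, None] * p * tc).sum()) * dft
                occ = occ @ p
        return qaly, cost
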