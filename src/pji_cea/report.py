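"""Cost-effectiveness assembly: per-method QALY, cost, cost per QALY, ranks.

Each treatment method gets its own fitted model (decision tree over a
24-month horizon or Markov model over 30 months by default); the method's
total QALY and total cost over the horizon, with subsample-bootstrap
intervals, yield the cost of one QALY unit, and the methods are ranked by
ascending cost per QALY.  Values from the two model families are never
mixed in one table (their QALY and cost conventions differ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .decision_tree import DecisionTreeCEModel
from .markov import MarkovCEModel, StatePayoffs
from .records import PatientRecord, TreatmentMethod
from .uncertainty import IntervalEstimate, subsample_ci

__all__ = [
    "UndefinedRatioError",
    "MethodResult",
    "RankTable",
    "cost_per_qaly",
    "rank_methods",
    "run_comparison",
]

MODELS = ("decision_tree", "markov")


class UndefinedRatioError(ValueError):
    """Cost per QALY is undefined for non-positive QALY."""


def cost_per_qaly(cost: float, qaly: float) -> float:
    """Cost of one QALY unit, rounded half-up to 2 decimals for display."""
    if qaly <= 0:
        raise UndefinedRatioError(f"cost per QALY undefined for QALY = {qaly}")
    ratio = Decimal(repr(cost)) / Decimal(repr(qaly))
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MethodResult:
    method: TreatmentMethod
    model: str  # "decision_tree" | "markov"
    qaly: float
    cost: float
    horizon_months: int
    qaly_interval: IntervalEstimate | None = None
    cost_interval: IntervalEstimate | None = None
    rank: int | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")

    @property
    def cost_per_qaly(self) -> float:
        return cost_per_qaly(self.cost, self.qaly)


@dataclass
class RankTable:
    """Method results ordered by effectiveness rank (1 = lowest cost/QALY)."""

    results: list[MethodResult]
    model: str
    horizon_months: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": [r.method.label for r in self.results],
                "QALY": [r.qaly for r in self.results],
                "cost_rubles": [r.cost for r in self.results],
                "cost_per_qaly_rubles": [r.cost_per_qaly for r in self.results],
                "rank": [r.rank for r in self.results],
            }
        )

    def ranks_by_method(self) -> dict[TreatmentMethod, int]:
        return {r.method: r.rank for r in self.results}


def rank_methods(results: Sequence[MethodResult]) -> RankTable:
    """Rank by ascending cost per QALY; ties broken by higher QALY, then by
    method code.  All results must share one model family and horizon."""
    results = list(results)
    if not results:
        raise ValueError("no results to rank")
    models = {r.model for r in results}
    horizons = {r.horizon_months for r in results}
    if len(models) > 1:
        raise ValueError(
            f"cannot rank results from different model families in one table: {sorted(models)}"
        )
    if len(horizons) > 1:
        raise ValueError(f"results span several horizons: {sorted(horizons)}")
    ordered = sorted(
        results, key=lambda r: (r.cost_per_qaly, -r.qaly, r.method.name)
    )
    ranked = [replace(r, rank=i + 1) for i, r in enumerate(ordered)]
    return RankTable(results=ranked, model=models.pop(), horizon_months=horizons.pop())


def _tree_point(records, method, horizon, **kw) -> tuple[float, float]:
    m = DecisionTreeCEModel(method=method, horizon_months=horizon, **kw).fit(records)
    return m.expected_impact("QALY"), m.expected_impact("rubles")


def _markov_point(
    records, method, horizon, payoffs, annualize
) -> tuple[float, float]:
    m = MarkovCEModel(
        method=method, horizon_months=horizon, payoffs=payoffs, annualize=annualize
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m.fit(records)
    return m.expected_payoffs()


def run_comparison(
    records: Sequence[PatientRecord],
    model: str = "markov",
    methods: Sequence[TreatmentMethod] | None = None,
    horizon_months: int | None = None,
    payoffs: StatePayoffs | None = None,
    annualize: bool = True,
    n_subsamples: int = 10,
    fraction: float = 0.8,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> RankTable:
    """Fit the chosen model family per method and rank by cost per QALY.

    Point totals are analytic expectations over the horizon (tree: the
    probability-weighted path sum; Markov: occupancy propagation of the
    fitted chain); intervals come from the subsample bootstrap (n
    subsamples of ``fraction`` of the method's records).  Methods without
    records are skipped with a warning.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    horizon = horizon_months if horizon_months is not None else (
        24 if model == "decision_tree" else 30
    )
    if methods is None:
        present = {(r.method, r.cohort) for r in records}
        methods = [m for m in TreatmentMethod if (m, m.cohort) in present]

    rng = np.random.default_rng(seed)
    results: list[MethodResult] = []
    for method in methods:
        subset = [r for r in records if r.method is method and r.cohort is method.cohort]
        if not subset:
            warnings.warn(f"no records for method {method.label}; skipped", stacklevel=2)
            continue
        if horizon <= 0:
            results.append(
                MethodResult(method=method, model=model, qaly=0.0, cost=0.0,
                             horizon_months=horizon)
            )
            continue
        if model == "decision_tree":
            qaly, cost = _tree_point(records, method, horizon)

            def est_q(sub):
                return _tree_point(sub, method, horizon)[0]

            def est_c(sub):
                return _tree_point(sub, method, horizon)[1]

        else:
            qaly, cost = _markov_point(records, method, horizon, payoffs, annualize)

            def est_q(sub):
                return _markov_point(sub, method, horizon, payoffs, annualize)[0]

            def est_c(sub):
                return _markov_point(sub, method, horizon, payoffs, annualize)[1]

        qi = ci = None
        if n_subsamples >= 2 and len(subset) >= 2:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            qi = subsample_ci(
                subset, est_q, n_subsamples=n_subsamples, fraction=fraction,
                alpha=alpha, rng=sub_seed,
            )
            ci = subsample_ci(
                subset, est_c, n_subsamples=n_subsamples, fraction=fraction,
                alpha=alpha, rng=sub_seed,
            )
        results.append(
            MethodResult(
                method=method,
                model=model,
                qaly=qaly,
                cost=cost,
                horizon_months=horizon,
                qaly_interval=qi,
                cost_interval=ci,
            )
        )
    return rank_methods(results)
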