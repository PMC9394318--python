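"""Record-driven decision trees of PJI treatment courses.

For one treatment method, the tree's root is the method itself; the node at
depth ``i`` is the ``i``-th recorded intervention type, and every path ends
in an outcome leaf: ``Death`` (died with confirmed PJI), ``Failure`` (alive
with PJI at the end of observation), or ``Success`` (no PJI at the last
observation).  Edges carry occurrence-ratio probabilities (with subsample-
bootstrap intervals), mean operation costs, and mean inter-interval QALY
increments; the expected impact of a method in either unit is the
probability-weighted sum of per-path accumulated increments,

    C = Σ_i p_i · c_i ,

with the interval variant obtained by substituting the lower/upper
probability bounds into the same sum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .records import (
    OperationCategory,
    PatientRecord,
    TreatmentMethod,
    classify_operation,
)
from .uncertainty import t_interval

__all__ = [
    "Outcome",
    "DecisionTree",
    "DecisionTreeCEModel",
    "assign_outcome",
    "build_tree",
    "expected_impact",
    "sample_path",
]

ROOT = ()


class Outcome(Enum):
    SUCCESS = "Success"
    FAILURE = "Failure"
    DEATH = "Death"


def assign_outcome(record: PatientRecord) -> Outcome:
    """Label a record's terminal treatment outcome.

    Death is defined only for patients who died with confirmed PJI; a death
    with no PJI at the last observation counts as Success (the treatment
    eliminated the infection), flagged separately on the record's leaf.
    """
    if record.last_status == "NO_PJI":
        return Outcome.SUCCESS
    if record.death_date is not None:
        return Outcome.DEATH
    return Outcome.FAILURE


def died_without_pji(record: PatientRecord) -> bool:
    """True for the Success-with-death convention: the patient died, but
    PJI-free, so the course counts as a treatment success."""
    return record.death_date is not None and record.last_status == "NO_PJI"


# Fallback QALY increments per inter-operation interval when per-patient
# EQ-5D values are absent, keyed by the category of the operation the
# interval leads to; outcome edges cover the interval from the last
# operation to the end of observation.
_DEFAULT_CATEGORY_UTILITIES: dict[OperationCategory, float] = {
    OperationCategory.NO_PJI: 0.3,
    OperationCategory.PJI_FIRST_OR_RELAPSE: 0.1,
    OperationCategory.PJI_RELAPSE_ONLY: 0.1,
}
_DEFAULT_OUTCOME_UTILITIES: dict[Outcome, float] = {
    Outcome.SUCCESS: 1.7,
    Outcome.FAILURE: 0.7,
    Outcome.DEATH: 0.0,
}


@dataclass
class DecisionTree:
    """Rooted tree over a networkx DiGraph; node ids are label-path tuples."""

    method: TreatmentMethod
    graph: nx.DiGraph
    horizon_months: int

    @property
    def root(self) -> tuple:
        return ROOT

    def children(self, node: tuple) -> list[tuple]:
        return sorted(self.graph.successors(node))

    def edges(self):
        return self.graph.edges(data=True)

    def validate(self) -> None:
        if not nx.is_arborescence(self.graph):
            raise ValueError("decision tree must be a single-rooted arborescence")
        for node in self.graph.nodes:
            children = list(self.graph.successors(node))
            if not children:
                if self.graph.nodes[node]["label"] not in {o.value for o in Outcome}:
                    raise ValueError(f"non-outcome leaf {node}")
                continue
            total = sum(self.graph.edges[node, c]["probability"] for c in children)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"outgoing probabilities at {node} sum to {total}")

    def to_json(self) -> str:
        nodes = [
            {"id": list(n), "label": d["label"], "depth": d["depth"], "support": d["support"]}
            for n, d in self.graph.nodes(data=True)
        ]
        edges = [
            {
                "parent": list(a),
                "child": list(b),
                "probability": d["probability"],
                "lower": d.get("lower", d["probability"]),
                "upper": d.get("upper", d["probability"]),
                "cost": d["cost"],
                "utility": d["utility"],
                "support": d["support"],
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return json.dumps(
            {
                "method": self.method.label,
                "horizon_months": self.horizon_months,
                "nodes": nodes,
                "edges": edges,
            },
            indent=2,
        )

    def to_dot(self) -> str:
        lines = ["digraph decision_tree {", "  rankdir=LR;"]
        idx = {n: f"n{i}" for i, n in enumerate(self.graph.nodes)}
        for n, d in self.graph.nodes(data=True):
            label = d["label"].replace('"', "'")
            lines.append(f'  {idx[n]} [label="{label}\\n(n={d["support"]})"];')
        for a, b, d in self.graph.edges(data=True):
            lo, up = d.get("lower", d["probability"]), d.get("upper", d["probability"])
            lines.append(
                f'  {idx[a]} -> {idx[b]} [label="{d["probability"]:.3f} [{lo:.3f}, {up:.3f}]"];'
            )
        lines.append("}")
        return "\n".join(lines)


def _record_sequence(
    record: PatientRecord, horizon_months: int
) -> tuple[list, Outcome]:
    """Operations within the horizon (events within 30*h days of
    manifestation) and the terminal outcome."""
    cutoff_days = 30 * horizon_months
    ops = [
        op
        for op in record.operations
        if (op.date - record.manifestation_date).days < cutoff_days
    ]
    return ops, assign_outcome(record)


def build_tree(
    records: Sequence[PatientRecord],
    method: TreatmentMethod,
    horizon_months: int = 24,
    category_utilities: Mapping[OperationCategory, float] | None = None,
    outcome_utilities: Mapping[Outcome, float] | None = None,
) -> DecisionTree:
    """Build the decision tree for one method by recursive prefix grouping.

    At each node the children are exactly the distinct next-operation labels
    among the records sharing the node's prefix, plus outcome leaves where
    sequences end; edge probabilities are occurrence ratios.
    """
    cat_u = dict(_DEFAULT_CATEGORY_UTILITIES)
    cat_u.update(category_utilities or {})
    out_u = dict(_DEFAULT_OUTCOME_UTILITIES)
    out_u.update(outcome_utilities or {})

    subset = [r for r in records if r.method is method and r.cohort is method.cohort]
    if not subset:
        raise ValueError(f"no records for treatment method {method.label!r}")

    seqs = []
    for r in subset:
        ops, outcome = _record_sequence(r, horizon_months)
        seqs.append((r, ops, outcome))

    g = nx.DiGraph()
    g.add_node(ROOT, label=method.label, depth=0, support=len(seqs))

    def grow(node: tuple, items: list, depth: int) -> None:
        # partition by the next element of the sequence ("If Lk = ∅, break"
        # happens naturally when every sequence has ended)
        by_child: dict[str, list] = {}
        ended: dict[str, list] = {}
        for r, ops, outcome in items:
            if depth < len(ops):
                by_child.setdefault(ops[depth].op_type.label, []).append((r, ops, outcome))
            else:
                ended.setdefault(outcome.value, []).append((r, ops, outcome))
        total = len(items)
        for label in sorted(ended):
            sub = ended[label]
            child = node + (label,)
            g.add_node(child, label=label, depth=depth + 1, support=len(sub))
            g.add_edge(
                node,
                child,
                probability=len(sub) / total,
                cost=0.0,
                utility=out_u[Outcome(label)],
                support=len(sub),
            )
        for label in sorted(by_child):
            sub = by_child[label]
            child = node + (label,)
            costs = [ops[depth].cost for _, ops, _ in sub]
            # horizon truncation drops a date-sorted suffix, so ops is a
            # prefix of r.operations and index `depth` lines up with the
            # per-interval utility increments
            utils = [
                r.utility_increments[depth]
                for r, ops, _ in sub
                if r.utility_increments is not None
            ]
            if utils:
                utility = float(np.mean(utils))
            else:
                utility = cat_u[classify_operation(label).category]
            g.add_node(child, label=label, depth=depth + 1, support=len(sub))
            g.add_edge(
                node,
                child,
                probability=len(sub) / total,
                cost=float(np.mean(costs)),
                utility=utility,
                support=len(sub),
            )
            grow(child, sub, depth + 1)

    grow(ROOT, seqs, 0)
    tree = DecisionTree(method=method, graph=g, horizon_months=horizon_months)
    tree.validate()
    return tree


def expected_impact(
    tree: DecisionTree, unit: str = "rubles", bound: str = "point"
) -> float:
    """Probability-weighted accumulated edge increments over all paths.

    ``unit`` is ``"rubles"`` (edge costs) or ``"QALY"`` (edge utilities);
    ``bound`` substitutes the lower/upper probability estimates into the
    same sum for the interval assessment.
    """
    if unit not in ("rubles", "QALY"):
        raise ValueError(f"unit must be 'rubles' or 'QALY', got {unit!r}")
    attr = "cost" if unit == "rubles" else "utility"
    key = {"point": "probability", "lower": "lower", "upper": "upper"}[bound]

    def rec(node: tuple) -> float:
        total = 0.0
        for child in tree.graph.successors(node):
            d = tree.graph.edges[node, child]
            p = d.get(key, d["probability"])
            total += p * (d[attr] + rec(child))
        return total

    return rec(tree.root)


def sample_path(
    tree: DecisionTree, rng: np.random.Generator | int | None = None
) -> tuple[list[str], float, float]:
    """Draw one root-to-leaf path; returns (labels, total cost, total QALY)."""
    rng = np.random.default_rng(rng)
    node = tree.root
    labels: list[str] = [tree.graph.nodes[node]["label"]]
    cost = 0.0
    qaly = 0.0
    while True:
        children = tree.children(node)
        if not children:
            return labels, cost, qaly
        probs = np.array([tree.graph.edges[node, c]["probability"] for c in children])
        i = int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))
        i = min(i, len(children) - 1)
        child = children[i]
        d = tree.graph.edges[node, child]
        cost += d["cost"]
        qaly += d["utility"]
        labels.append(tree.graph.nodes[child]["label"])
        node = child


class DecisionTreeCEModel(BaseEstimator):
    """Decision-tree cost-effectiveness model for one treatment method.

    Fitting builds the tree from the records of ``method`` (operations
    truncated to ``horizon_months`` after manifestation) and, when
    ``bootstrap`` is set, attaches subsample-bootstrap t-intervals to every
    edge probability.

    Attributes (after ``fit``): ``tree_`` (DecisionTree), ``n_records_``.
    """

    def __init__(
        self,
        method: TreatmentMethod | None = None,
        horizon_months: int = 24,
        category_utilities: Mapping[OperationCategory, float] | None = None,
        outcome_utilities: Mapping[Outcome, float] | None = None,
        bootstrap: bool = False,
        n_subsamples: int = 10,
        subsample_fraction: float = 0.8,
        alpha: float = 0.05,
        random_state: int | None = None,
    ):
        self.method = method
        self.horizon_months = horizon_months
        self.category_utilities = category_utilities
        self.outcome_utilities = outcome_utilities
        self.bootstrap = bootstrap
        self.n_subsamples = n_subsamples
        self.subsample_fraction = subsample_fraction
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X: Sequence[PatientRecord], y=None) -> "DecisionTreeCEModel":
        if self.method is None:
            raise ValueError("method must be set before fitting")
        self.tree_ = build_tree(
            X,
            self.method,
            horizon_months=self.horizon_months,
            category_utilities=self.category_utilities,
            outcome_utilities=self.outcome_utilities,
        )
        self.n_records_ = self.tree_.graph.nodes[ROOT]["support"]
        if self.bootstrap:
            self._bootstrap_edge_intervals(X)
        return self

    def _bootstrap_edge_intervals(self, records: Sequence[PatientRecord]) -> None:
        subset = [
            r for r in records if r.method is self.method and r.cohort is self.method.cohort
        ]
        rng = np.random.default_rng(self.random_state)
        m = max(1, int(math.floor(self.subsample_fraction * len(subset))))
        edge_samples: dict[tuple, list[float]] = {
            (a, b): [] for a, b, _ in self.tree_.graph.edges(data=True)
        }
        for _ in range(self.n_subsamples):
            idx = rng.choice(len(subset), size=m, replace=False)
            sub = [subset[i] for i in idx]
            try:
                t = build_tree(
                    sub,
                    self.method,
                    horizon_months=self.horizon_months,
                    category_utilities=self.category_utilities,
                    outcome_utilities=self.outcome_utilities,
                )
            except ValueError:
                continue
            for (a, b), samples in edge_samples.items():
                if t.graph.has_edge(a, b):
                    samples.append(t.graph.edges[a, b]["probability"])
                elif t.graph.has_node(a):
                    samples.append(0.0)  # prefix reached, branch never taken
                else:
                    samples.append(float("nan"))  # prefix absent in subsample
        for (a, b), samples in edge_samples.items():
            d = self.tree_.graph.edges[a, b]
            finite = [s for s in samples if not math.isnan(s)]
            if len(finite) >= 2:
                ci = t_interval(finite, alpha=self.alpha, clip=(0.0, 1.0))
                d["lower"], d["upper"] = ci.lower, ci.upper
            else:
                d["lower"] = d["upper"] = d["probability"]

    def expected_impact(self, unit: str = "rubles", bound: str = "point") -> float:
        return expected_impact(self.tree_, unit=unit, bound=bound)

    def sample_path(self, rng: np.random.Generator | int | None = None):
        return sample_path(self.tree_, rng=rng)
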