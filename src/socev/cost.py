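"""Inference-cost estimation, budgeting, and budgeted evaluation.

Evaluating the normalized evidence of one node over ``L`` believed and
``K`` social relations takes one multiplication of two weighted sums, two
divisions, ``K + L`` multiplications inside the sums and ``2(K + L)``
additions across numerators and denominators:

    C = C_m + 2·C_d + (K+L)·C_m + 2·(K+L)·C_a

Relations whose evidence value is stored in the graph are terminal and
contribute a constant stored cost; relations that point at another node
are recursed exactly once each (non-recurrent inference), adding that
node's own estimate.  The same graph drives :func:`evaluate_with_budget`,
a depth-first evaluator that spends the budget node by node and falls back
on fresh-enough cached values — or a maximum-uncertainty default of 0.5 —
once the budget is exhausted.

Cost units are abstract: one tick of scheduler capacity processes
``capacity`` cost units, so budgets are wall-clock-agnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Optional

from .evidence import EvidenceEstimate, normalized_evidence

__all__ = [
    "OperationCosts",
    "CostEstimate",
    "InferenceTask",
    "EvaluationCache",
    "EvidenceRelation",
    "EvidenceNode",
    "EvidenceGraph",
    "terminal_cost",
    "recursive_cost",
    "schedule",
    "evaluate_with_budget",
    "NEUTRAL_VALUE",
    "DEFAULT_STALENESS_LIMIT",
]

logger = logging.getLogger(__name__)

#: Maximum-uncertainty midpoint used when neither budget nor cache can
#: produce a value.
NEUTRAL_VALUE = 0.5

DEFAULT_STALENESS_LIMIT = 100


@dataclass(frozen=True)
class OperationCosts:
    """Unit costs of the three arithmetic primitives."""

    multiply: float = 1.0
    divide: float = 1.0
    add: float = 1.0

    def __post_init__(self) -> None:
        for name in ("multiply", "divide", "add"):
            if getattr(self, name) <= 0:
                raise ValueError(f"operation cost {name!r} must be strictly positive")


@dataclass(frozen=True)
class CostEstimate:
    """Breakdown of a node's inference cost.

    ``total = terminal_part + Σ recursive_parts`` where ``recursive_parts``
    maps each child relation to its own (constant or recursed) cost.
    """

    total: float
    terminal_part: float
    recursive_parts: Mapping[tuple, float]


@dataclass(frozen=True)
class InferenceTask:
    root: tuple
    priority: float = 0.0
    budget: float = 0.0
    deadline_tick: int = 0
    created_tick: int = 0

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("task budget must be non-negative")
        if self.deadline_tick < self.created_tick:
            raise ValueError("deadline precedes task creation")


class EvaluationCache:
    """Timestamped value cache with a staleness horizon.

    Entries older than ``staleness_limit`` ticks are never returned as
    fresh; they are kept only so that inspection tools can see what was
    last known.
    """

    def __init__(self, staleness_limit: int = DEFAULT_STALENESS_LIMIT):
        if staleness_limit < 0:
            raise ValueError("staleness limit must be non-negative")
        self.staleness_limit = staleness_limit
        self._entries: dict[Hashable, tuple[float, int]] = {}

    def put(self, key: Hashable, value: float, timestamp: int) -> None:
        self._entries[key] = (float(value), int(timestamp))

    def get_fresh(self, key: Hashable, now: int) -> Optional[float]:
        entry = self._entries.get(key)
        if entry is None:
            return None
        value, stamp = entry
        if now - stamp > self.staleness_limit:
            return None
        return value

    def get_any(self, key: Hashable) -> Optional[float]:
        entry = self._entries.get(key)
        return None if entry is None else entry[0]

    def __len__(self) -> int:
        return len(self._entries)

    def to_dict(self) -> dict:
        return {
            "staleness_limit": self.staleness_limit,
            "entries": {repr(k): {"value": v, "timestamp": t} for k, (v, t) in self._entries.items()},
        }


@dataclass(frozen=True)
class EvidenceRelation:
    """One believed or social relation hanging off an evidence node.

    Exactly one of ``value`` (terminal, stored in the graph) or ``child``
    (reference to another node, recursed) is set.  ``cost`` is the stored
    constant cost of a terminal relation.
    """

    target_id: str
    weight: float
    value: Optional[float] = None
    child: Optional[tuple] = None
    cost: float = 0.0

    def __post_init__(self) -> None:
        if (self.value is None) == (self.child is None):
            raise ValueError("relation must carry either a stored value or a child reference")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("relation weight must lie in [0, 1]")
        if self.value is not None and not 0.0 <= self.value <= 1.0:
            raise ValueError("relation value must lie in [0, 1]")
        if self.cost < 0:
            raise ValueError("relation cost must be non-negative")

    @property
    def terminal(self) -> bool:
        return self.value is not None


@dataclass
class EvidenceNode:
    """Evidence context of one (agent, concept) pair."""

    believed: tuple = ()
    social: tuple = ()

    def __post_init__(self) -> None:
        # Deterministic depth-first order: believed children by item id
        # before social children by peer id.
        self.believed = tuple(sorted(self.believed, key=lambda r: r.target_id))
        self.social = tuple(sorted(self.social, key=lambda r: r.target_id))


class EvidenceGraph:
    """Nodes keyed by (agent_id, concept_id)."""

    def __init__(self, nodes: Mapping[tuple, EvidenceNode] | None = None):
        self.nodes: dict[tuple, EvidenceNode] = dict(nodes or {})

    def __contains__(self, key: tuple) -> bool:
        return key in self.nodes

    def __getitem__(self, key: tuple) -> EvidenceNode:
        try:
            return self.nodes[key]
        except KeyError:
            raise KeyError(f"node {key!r} not present in the evidence graph") from None

    def add(self, key: tuple, node: EvidenceNode) -> None:
        self.nodes[key] = node


def terminal_cost(K: int, L: int, costs: OperationCosts = OperationCosts()) -> float:
    """Cost of evaluating one node's own weighted-sum product.

    Linear in ``K + L``: ``C_m + 2·C_d + (K+L)·C_m + 2·(K+L)·C_a``.
    """
    if K < 0 or L < 0:
        raise ValueError("relation counts must be non-negative")
    n = K + L
    return costs.multiply + 2 * costs.divide + n * costs.multiply + 2 * n * costs.add


class CycleError(ValueError):
    pass


def recursive_cost(
    root: tuple,
    graph: EvidenceGraph,
    costs: OperationCosts = OperationCosts(),
    cache: Optional[EvaluationCache] = None,
) -> CostEstimate:
    """Full inference cost of evaluating ``root`` exhaustively.

    Terminal relations contribute their stored constant cost; child nodes
    are recursed exactly once each.  A cycle is an error unless the cache
    holds a value for the re-entered node (the evaluation would stop there).
    """
    return _recursive_cost(root, graph, costs, cache, chain=())


def _recursive_cost(key, graph, costs, cache, chain):
    if key in chain:
        if cache is not None and cache.get_any(key) is not None:
            return CostEstimate(total=0.0, terminal_part=0.0, recursive_parts={})
        cycle = " -> ".join(map(str, chain + (key,)))
        raise CycleError(f"unresolvable cycle with empty cache: {cycle}")
    node = graph[key]
    K, L = len(node.social), len(node.believed)
    term = terminal_cost(K, L, costs)
    parts: dict[tuple, float] = {}
    for kind, rels in (("believed", node.believed), ("social", node.social)):
        for rel in rels:
            if rel.terminal:
                parts[(kind, rel.target_id)] = rel.cost
            else:
                sub = _recursive_cost(rel.child, graph, costs, cache, chain + (key,))
                parts[(kind, rel.target_id)] = sub.total
    return CostEstimate(total=term + sum(parts.values()), terminal_part=term, recursive_parts=parts)


def schedule(
    tasks: list[InferenceTask],
    capacity: float,
    now: int = 0,
) -> list[tuple[InferenceTask, str]]:
    """Proactive cost-based plan for a set of inference tasks.

    A task whose budget cannot be spent by its deadline at the given
    capacity is marked ``skipped`` to free resources.  The rest are ordered
    by descending priority, ties broken by earlier deadline, then by
    smaller cost.
    """
    if capacity <= 0:
        raise ValueError("capacity must be strictly positive")
    plan = []
    runnable = []
    for task in tasks:
        achievable = capacity * max(0, task.deadline_tick - now)
        if task.budget > achievable:
            plan.append((task, "skipped"))
        else:
            runnable.append(task)
    runnable.sort(key=lambda t: (-t.priority, t.deadline_tick, t.budget))
    return [(t, "scheduled") for t in runnable] + plan


def evaluate_with_budget(
    root: tuple,
    graph: EvidenceGraph,
    budget: float = math.inf,
    cache: Optional[EvaluationCache] = None,
    costs: OperationCosts = OperationCosts(),
    now: int = 0,
) -> EvidenceEstimate:
    """Budgeted depth-first evaluation of normalized evidence at ``root``.

    Visiting a node deducts its terminal cost from the shared budget.
    When the remaining budget cannot cover a node, a fresh-enough cached
    value is substituted (provenance ``cached``); failing that, the neutral
    default 0.5 is used (provenance ``defaulted``).  With an unlimited
    budget the result equals exhaustive recursive evaluation.  Children are
    visited believed-first in relation-id order, so enlarging the budget
    never changes what a smaller budget already computed in full.
    """
    if budget < 0:
        raise ValueError("budget must be non-negative")
    if root not in graph:
        raise KeyError(f"root {root!r} not present in the evidence graph")
    state = {"remaining": float(budget)}
    value, provenance = _evaluate(root, graph, state, cache, costs, now, in_progress=set())
    return EvidenceEstimate(raw=value, normalized=value, timestamp=now, provenance=provenance)


def _fallback(key, cache, now):
    if cache is not None:
        hit = cache.get_fresh(key, now)
        if hit is not None:
            return hit, "cached"
    return NEUTRAL_VALUE, "defaulted"


def _evaluate(key, graph, state, cache, costs, now, in_progress):
    if key in in_progress:
        # Cyclic re-entry: reuse any cached value, else the neutral default.
        logger.warning("cyclic evaluation at %r broken via cache/default", key)
        if cache is not None:
            hit = cache.get_any(key)
            if hit is not None:
                return hit, "cached"
        return NEUTRAL_VALUE, "defaulted"
    if key not in graph:
        return _fallback(key, cache, now)
    node = graph[key]
    own = terminal_cost(len(node.social), len(node.believed), costs)
    if state["remaining"] < own:
        return _fallback(key, cache, now)
    state["remaining"] -= own
    in_progress.add(key)
    try:
        resolved = {}
        for kind, rels in (("believed", node.believed), ("social", node.social)):
            pairs = []
            for rel in rels:
                if rel.terminal:
                    pairs.append((rel.value, rel.weight))
                else:
                    child_value, _ = _evaluate(
                        rel.child, graph, state, cache, costs, now, in_progress
                    )
                    pairs.append((child_value, rel.weight))
            resolved[kind] = pairs
        estimate = normalized_evidence(resolved["believed"], resolved["social"], timestamp=now)
    finally:
        in_progress.discard(key)
    if cache is not None:
        cache.put(key, estimate.normalized, now)
    return estimate.normalized, "computed"
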