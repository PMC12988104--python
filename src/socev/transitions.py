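"""Transition-freedom metric and probability-threshold graph pruning.

The *transition freedom* (TF) of a state in a frequency-weighted
state-transition graph is its out-degree: the number of distinct next
states reachable from it.  Summed over all states it scores the overall
"freedom of transition" of the model; minimizing it compresses the model,
cutting both storage cost and the cost of evaluating options at each fork.

Pruning removes every transition whose conditional probability (its count
divided by the total outgoing count of its source, computed on the
pre-prune graph) falls strictly below a threshold.  Pruning is a single
pass: probabilities are not renormalized and re-pruned, so it is
idempotent at a fixed threshold, and thresholds nest — a higher threshold
removes a superset of what a lower one removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
__all__ = ["TransitionGraph", "transition_freedom", "prune_graph", "total_transition_freedom"]


@dataclass
class TransitionGraph:
    """States with frequency-weighted outgoing transitions.

    ``transitions[src][dst]`` holds the positive observation count of the
    ``src -> dst`` transition.  ``flagged`` collects states left
    unreachable by pruning; they are retained in the graph.
    """

    states: set = field(default_factory=set)
    transitions: dict = field(default_factory=dict)
    flagged: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.states = set(self.states)
        cleaned: dict[str, dict[str, float]] = {}
        for src, outgoing in self.transitions.items():
            cleaned[src] = {}
            for dst, count in outgoing.items():
                if count <= 0:
                    raise ValueError(f"transition {src!r}->{dst!r} has non-positive count {count!r}")
                cleaned[src][dst] = float(count)
            self.states.add(src)
            self.states.update(cleaned[src])
        self.transitions = cleaned

    def add_transition(self, src: str, dst: str, count: float = 1.0) -> None:
        if count <= 0:
            raise ValueError("transition count must be positive")
        self.states.add(src)
        self.states.add(dst)
        self.transitions.setdefault(src, {})
        self.transitions[src][dst] = self.transitions[src].get(dst, 0.0) + float(count)

    def conditional_probabilities(self, state: str) -> dict:
        """Per-target conditional probability of each outgoing transition."""
        if state not in self.states:
            raise KeyError(f"unknown state {state!r}")
        outgoing = self.transitions.get(state, {})
        total = sum(outgoing.values())
        return {dst: c / total for dst, c in outgoing.items()} if total else {}

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": sorted(self.states),
                "transitions": [
                    {"source": s, "target": t, "count": c}
                    for s in sorted(self.transitions)
                    for t, c in sorted(self.transitions[s].items())
                ],
                "flagged": sorted(self.flagged),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TransitionGraph":
        payload = json.loads(text)
        graph = cls(states=set(payload.get("states", [])))
        for rec in payload.get("transitions", []):
            graph.add_transition(rec["source"], rec["target"], rec["count"])
        graph.flagged = set(payload.get("flagged", []))
        return graph


def transition_freedom(graph: TransitionGraph, state: str) -> int:
    """Out-degree of a state: the number of its outgoing transitions."""
    if state not in graph.states:
        raise KeyError(f"unknown state {state!r}")
    return len(graph.transitions.get(state, {}))


def prune_graph(graph: TransitionGraph, prob_threshold: float) -> TransitionGraph:
    """Lossy compression: drop transitions below a conditional-probability threshold.

    Probabilities are taken from the pre-prune graph (single pass, no
    cascading renormalization).  States left without incoming transitions
    are retained but flagged as unreachable.
    """
    if not 0.0 <= prob_threshold <= 1.0:
        raise ValueError("probability threshold must lie in [0, 1]")
    pruned = TransitionGraph(states=set(graph.states))
    for src in graph.transitions:
        probs = graph.conditional_probabilities(src)
        for dst, count in graph.transitions[src].items():
            if probs[dst] >= prob_threshold:
                pruned.add_transition(src, dst, count)
    had_incoming = {dst for out in graph.transitions.values() for dst in out}
    has_incoming = {dst for out in pruned.transitions.values() for dst in out}
    pruned.flagged = set(graph.flagged) | (had_incoming - has_incoming)
    return pruned


def total_transition_freedom(graph: TransitionGraph) -> int:
    """Global freedom-of-transition score: TF summed over all states."""
    return sum(len(out) for out in graph.transitions.values())
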