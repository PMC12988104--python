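"""Budgeted recursive evidence evaluation with cost estimation and caching.

A two-level evidence graph: the root concept rests on one stored believed
relation and one social relation that itself must be inferred from a peer's
context.  We price the full evaluation, then run it with an unlimited
budget, with a budget that only covers the root (the unreached child falls
back to the maximum-uncertainty default 0.5), and with a zero budget after
caching (the cached value is reused).
"""

import math

from socev import (
    EvaluationCache,
    EvidenceGraph,
    EvidenceNode,
    EvidenceRelation,
    evaluate_with_budget,
    recursive_cost,
    terminal_cost,
)

graph = EvidenceGraph()
graph.add(
    ("me", "go_hiking"),
    EvidenceNode(
        believed=(EvidenceRelation("likes_outdoors", weight=1.0, value=0.9),),
        social=(EvidenceRelation("friend", weight=0.8, child=("friend", "go_hiking")),),
    ),
)
graph.add(
    ("friend", "go_hiking"),
    EvidenceNode(
        believed=(EvidenceRelation("likes_walking", weight=1.0, value=0.7),),
        social=(),
    ),
)

cost = recursive_cost(("me", "go_hiking"), graph)
print(f"estimated inference cost: {cost.total} (root alone: {cost.terminal_part})")

full = evaluate_with_budget(("me", "go_hiking"), graph, budget=math.inf)
print(f"unlimited budget:   {full.normalized:.4f} ({full.provenance})")

root_only = terminal_cost(K=1, L=1)
partial = evaluate_with_budget(("me", "go_hiking"), graph, budget=root_only)
print(f"root-only budget:   {partial.normalized:.4f} ({partial.provenance})")
# The friend's context was out of reach, so its approval defaulted to 0.5.

cache = EvaluationCache(staleness_limit=10)
evaluate_with_budget(("me", "go_hiking"), graph, budget=math.inf, cache=cache, now=0)
cached = evaluate_with_budget(("me", "go_hiking"), graph, budget=0.0, cache=cache, now=5)
print(f"zero budget, cache: {cached.normalized:.4f} ({cached.provenance})")
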