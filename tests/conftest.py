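"""Shared generators and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from socev.cost import EvidenceGraph, EvidenceNode, EvidenceRelation


def random_evidence_graph(rng: np.random.Generator, max_nodes: int = 30) -> tuple:
    """A random acyclic evidence graph plus its root key.

    Node ``i`` may only reference nodes with larger index, so the graph is
    acyclic by construction.  Every node carries at least one relation, and
    leaf references always resolve to nodes whose own relations are all
    terminal.
    """
    n = int(rng.integers(1, max_nodes + 1))
    keys = [("agent", f"c{i:02d}") for i in range(n)]
    graph = EvidenceGraph()
    for i in range(n):
        believed, social = [], []
        n_b = int(rng.integers(0, 4))
        n_s = int(rng.integers(0, 4))
        if n_b + n_s == 0:
            n_b = 1
        for kind, count, bucket in (("item", n_b, believed), ("peer", n_s, social)):
            for j in range(count):
                weight = float(rng.uniform(0.05, 1.0))
                # deeper references only; leaves are terminal values
                if i + 1 < n and rng.random() < 0.5:
                    child = keys[int(rng.integers(i + 1, n))]
                    bucket.append(
                        EvidenceRelation(target_id=f"{kind}{j}", weight=weight, child=child)
                    )
                else:
                    bucket.append(
                        EvidenceRelation(
                            target_id=f"{kind}{j}",
                            weight=weight,
                            value=float(rng.uniform(0.0, 1.0)),
                            cost=float(rng.uniform(0.0, 5.0)),
                        )
                    )
        graph.add(keys[i], EvidenceNode(believed=tuple(believed), social=tuple(social)))
    return graph, keys[0]


def exhaustive_evidence_oracle(graph: EvidenceGraph, key: tuple) -> float:
    """Independent brute-force evaluator of normalized believed-social evidence.

    Computes the product of attachment-weighted means directly, recursing
    into child references; a factor with no relations defaults to 1.
    """
    node = graph[key]
    factors = []
    for rels in (node.believed, node.social):
        num = den = 0.0
        for rel in rels:
            value = rel.value if rel.terminal else exhaustive_evidence_oracle(graph, rel.child)
            num += value * rel.weight
            den += rel.weight
        factors.append(num / den if den > 0 else 1.0)
    return factors[0] * factors[1]


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
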