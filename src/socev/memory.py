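"""Segmented hypergraph knowledge store with STM/LTM layers.

Knowledge lives in a generalized hypergraph whose links may join any
number of members and may themselves be members of other links.  Every
element belongs to one of four functional segments:

* ``foundation`` — unquestioned core beliefs and automated procedures;
* ``social`` — trust-weighted attachments to peers;
* ``evidence`` — raw incoming facts and executed or planned actions;
* ``imagination`` — uncertain knowledge inferred from the other three.

Elements also occupy a memory layer: the fast, low-capacity short-term
store (``stm``), the slow, high-capacity long-term store (``ltm``), or
``both`` when an LTM element is currently loaded into attention.  Three
processes move knowledge around under the capacity constraints:
*focusing* pulls the most relevant LTM elements into STM, *unfocusing*
evicts them (persisting novel STM-born knowledge to LTM first, so nothing
is lost silently), and *forgetting* compresses LTM by removing elements
unlikely to be used again — rarely used, long unused, or both.

When capacity forces a choice among elements, removal order follows the
pruning hierarchy: lowest reliability first; among equals, lowest social
evidence; among those, highest storage cost; finally ascending id for
determinism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

__all__ = [
    "SEGMENTS",
    "LAYERS",
    "KnowledgeNode",
    "KnowledgeLink",
    "OperationalContext",
    "MemoryStore",
]

SEGMENTS = ("foundation", "social", "evidence", "imagination")
LAYERS = ("stm", "ltm", "both")


@dataclass
class _Element:
    id: str
    segment: str = "evidence"
    social_flag: bool = False
    layer: str = "stm"
    reliability: float = 0.5
    storage_cost: float = 1.0
    social_evidence: float = 0.0
    last_used: int = 0
    use_count: int = 0

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}; expected one of {SEGMENTS}")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError("reliability must lie in [0, 1]")
        if self.storage_cost <= 0:
            raise ValueError("storage cost must be strictly positive")

    @property
    def in_stm(self) -> bool:
        return self.layer in ("stm", "both")

    @property
    def in_ltm(self) -> bool:
        return self.layer in ("ltm", "both")


@dataclass
class KnowledgeNode(_Element):
    label: str = ""


@dataclass
class KnowledgeLink(_Element):
    """A hyper-link over one or more nodes or links."""

    members: tuple = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.members) < 1:
            raise ValueError("a link must have at least one member")
        self.members = tuple(self.members)


@dataclass
class OperationalContext:
    """Current STM attention: focused ids plus their relevance scores."""

    focus: set = field(default_factory=set)
    relevance: dict = field(default_factory=dict)


def _removal_key(element: _Element):
    # Pruning order: probability (reliability proxy) first, then social
    # evidence, then cost (most expensive first), then id.
    return (element.reliability, element.social_evidence, -element.storage_cost, element.id)


class MemoryStore:
    """Capacity-bounded two-layer store of knowledge nodes and links."""

    def __init__(self, stm_capacity: int, ltm_capacity: int):
        if stm_capacity < 1 or ltm_capacity < 1:
            raise ValueError("capacities must be positive integers")
        self.stm_capacity = int(stm_capacity)
        self.ltm_capacity = int(ltm_capacity)
        self.clock = 0
        self.elements: dict[str, _Element] = {}
        self.context = OperationalContext()

    # -- bookkeeping ---------------------------------------------------

    def tick(self, n: int = 1) -> None:
        self.clock += n

    def stm_ids(self) -> list[str]:
        return sorted(i for i, e in self.elements.items() if e.in_stm)

    def ltm_ids(self) -> list[str]:
        return sorted(i for i, e in self.elements.items() if e.in_ltm)

    def _stm_count(self) -> int:
        return sum(1 for e in self.elements.values() if e.in_stm)

    def _ltm_count(self) -> int:
        return sum(1 for e in self.elements.values() if e.in_ltm)

    def add(self, element: _Element) -> None:
        """Insert a new element (links must reference existing members)."""
        if element.id in self.elements:
            raise ValueError(f"element {element.id!r} already present")
        if isinstance(element, KnowledgeLink):
            missing = [m for m in element.members if m not in self.elements]
            if missing:
                raise ValueError(f"link {element.id!r} references missing members {missing}")
        element.last_used = self.clock
        self.elements[element.id] = element
        if element.in_stm and self._stm_count() > self.stm_capacity:
            self._evict_stm(exclude={element.id})
        if element.in_ltm and self._ltm_count() > self.ltm_capacity:
            self._evict_ltm(exclude={element.id})

    # -- focusing ------------------------------------------------------

    def focus(self, relevance: Mapping[str, float]) -> "MemoryStore":
        """Load the most relevant LTM elements into STM attention.

        Candidates are ranked by descending relevance (ties to the lower
        id); the top ``stm_capacity`` among current STM members and newly
        relevant LTM elements stay in STM, the rest are unfocused.  An
        element already in STM is only refreshed, never duplicated.
        """
        for ident, score in relevance.items():
            if ident not in self.elements:
                raise KeyError(f"unknown element {ident!r} in context query")
            if score != score or score in (float("inf"), float("-inf")):
                raise ValueError("relevance values must be finite")
        if not relevance:
            return self
        self.context.relevance.update(relevance)
        rel = self.context.relevance
        candidates = {i for i, e in self.elements.items() if e.in_stm}
        candidates |= {i for i in relevance if self.elements[i].in_ltm}
        ranked = sorted(candidates, key=lambda i: (-rel.get(i, float("-inf")), i))
        keep = set(ranked[: self.stm_capacity])
        for ident in sorted(candidates - keep):
            if ident in self.elements and self.elements[ident].in_stm:
                self.unfocus([ident])
        for ident in sorted(keep):
            el = self.elements.get(ident)
            if el is None:  # displaced by an LTM eviction cascade
                continue
            if not el.in_stm:
                el.layer = "both"
                el.last_used = self.clock
                el.use_count += 1
            else:
                el.last_used = self.clock
        self.context.focus = {i for i in keep if i in self.elements and self.elements[i].in_stm}
        return self

    def unfocus(self, ids: Sequence[str]) -> "MemoryStore":
        """Move elements out of STM, persisting novel ones to LTM first."""
        for ident in ids:
            el = self.elements.get(ident)
            if el is None or not el.in_stm:
                raise KeyError(f"element {ident!r} is not in STM")
        for ident in ids:
            el = self.elements[ident]
            el.layer = "ltm"  # stm-only elements are written to LTM here
            self.context.focus.discard(ident)
        if self._ltm_count() > self.ltm_capacity:
            self._evict_ltm(exclude=set())
        return self

    def _evict_stm(self, exclude: set) -> None:
        while self._stm_count() > self.stm_capacity:
            rel = self.context.relevance
            victims = [i for i, e in self.elements.items() if e.in_stm and i not in exclude]
            victim = min(
                victims,
                key=lambda i: (rel.get(i, float("-inf")),) + tuple(_removal_key(self.elements[i])),
            )
            self.unfocus([victim])

    def _evict_ltm(self, exclude: set) -> None:
        while self._ltm_count() > self.ltm_capacity:
            victims = [i for i, e in self.elements.items() if e.in_ltm and i not in exclude]
            victim = min(victims, key=lambda i: _removal_key(self.elements[i]))
            self._remove(victim)

    # -- forgetting and consolidation ---------------------------------

    def forget(self, age_limit: int, min_use: int = 0) -> "MemoryStore":
        """Compress LTM by removing unlikely-to-be-used elements.

        An element is forgotten when ``use_count < min_use`` OR it has not
        been used for more than ``age_limit`` ticks.  Links referencing a
        removed element are removed with it.
        """
        if age_limit < 0 or min_use < 0:
            raise ValueError("forgetting policy thresholds must be non-negative")
        doomed = [
            e
            for e in self.elements.values()
            if e.in_ltm and (e.use_count < min_use or self.clock - e.last_used > age_limit)
        ]
        for el in sorted(doomed, key=_removal_key):
            if el.id in self.elements:
                self._remove(el.id)
        return self

    def consolidate(self, hardwire_threshold: float, forget_threshold: float) -> "MemoryStore":
        """Resolve uncertain imagination knowledge under resource pressure.

        Imagination elements whose reliability reaches ``hardwire_threshold``
        are hardwired into the foundation segment; those below
        ``forget_threshold`` are removed; the rest stay uncertain.
        """
        if not 0.0 <= forget_threshold <= hardwire_threshold <= 1.0:
            raise ValueError(
                "thresholds must satisfy 0 <= forget_threshold <= hardwire_threshold <= 1"
            )
        imag = [e for e in self.elements.values() if e.segment == "imagination"]
        for el in sorted(imag, key=_removal_key):
            if el.id not in self.elements:
                continue
            if el.reliability >= hardwire_threshold:
                el.segment = "foundation"
            elif el.reliability < forget_threshold:
                self._remove(el.id)
        return self

    def _remove(self, ident: str) -> None:
        """Remove an element and, transitively, any link referencing it."""
        self.elements.pop(ident, None)
        self.context.focus.discard(ident)
        self.context.relevance.pop(ident, None)
        while True:
            dangling = [
                i
                for i, e in self.elements.items()
                if isinstance(e, KnowledgeLink) and any(m not in self.elements for m in e.members)
            ]
            if not dangling:
                break
            for i in dangling:
                self.elements.pop(i, None)
                self.context.focus.discard(i)
                self.context.relevance.pop(i, None)

    # -- queries and serialization ------------------------------------

    def query_segment(self, segment: str, layer: str) -> list[str]:
        """Ids in a segment/layer, sorted; ``both`` matches either layer query."""
        if segment not in SEGMENTS:
            raise ValueError(f"unknown segment {segment!r}")
        if layer not in ("stm", "ltm"):
            raise ValueError(f"unknown layer {layer!r}; query with 'stm' or 'ltm'")
        return sorted(
            i
            for i, e in self.elements.items()
            if e.segment == segment and (e.in_stm if layer == "stm" else e.in_ltm)
        )

    def check_invariants(self) -> None:
        assert self._stm_count() <= self.stm_capacity, "STM capacity exceeded"
        assert self._ltm_count() <= self.ltm_capacity, "LTM capacity exceeded"
        for e in self.elements.values():
            if isinstance(e, KnowledgeLink):
                assert all(m in self.elements for m in e.members), f"dangling link {e.id}"

    def to_json(self) -> str:
        nodes = [asdict(e) for e in self.elements.values() if isinstance(e, KnowledgeNode)]
        links = [asdict(e) for e in self.elements.values() if isinstance(e, KnowledgeLink)]
        for rec in links:
            rec["members"] = list(rec["members"])
        payload = {
            "stm_capacity": self.stm_capacity,
            "ltm_capacity": self.ltm_capacity,
            "clock": self.clock,
            "nodes": sorted(nodes, key=lambda r: r["id"]),
            "links": sorted(links, key=lambda r: r["id"]),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MemoryStore":
        payload = json.loads(text)
        store = cls(payload["stm_capacity"], payload["ltm_capacity"])
        store.clock = payload.get("clock", 0)
        for rec in payload.get("nodes", []):
            store.elements[rec["id"]] = KnowledgeNode(**rec)
        for rec in payload.get("links", []):
            rec = dict(rec)
            rec["members"] = tuple(rec["members"])
            store.elements[rec["id"]] = KnowledgeLink(**rec)
        return store
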