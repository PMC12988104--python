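"""Focusing, unfocusing, forgetting and consolidation in the two-layer store.

A small store (STM capacity 2) holds five long-term elements.  Focusing on
a context pulls the two most relevant into attention; unfocusing a novel
STM-born hypothesis persists it to LTM; forgetting compresses LTM by age;
consolidation hardwires a reliable imagined concept into the foundation
segment and drops an unreliable one.
"""

from socev import KnowledgeNode, MemoryStore

store = MemoryStore(stm_capacity=2, ltm_capacity=10)
for i, rel in enumerate([0.9, 0.4, 0.7, 0.2, 0.6]):
    store.add(KnowledgeNode(id=f"fact{i}", layer="ltm", reliability=rel))

store.focus({"fact0": 0.9, "fact2": 0.8, "fact4": 0.3})
print("in attention after focus:", store.stm_ids())  # top-2 by relevance

store.tick(5)
hypo = KnowledgeNode(id="hypothesis", segment="imagination", layer="stm", reliability=0.95)
store.elements["hypothesis"] = hypo  # born in STM during inference
store.unfocus(["hypothesis"])
print("hypothesis persisted to LTM:", "hypothesis" in store.ltm_ids())

store.tick(100)
for kept in ("fact0", "hypothesis"):  # still in active use
    store.elements[kept].last_used = store.clock
store.forget(age_limit=50)
print("after forgetting stale knowledge:", sorted(store.elements))

store.consolidate(hardwire_threshold=0.9, forget_threshold=0.1)
print("hypothesis segment after consolidation:", store.elements["hypothesis"].segment)
# Reliability 0.95 cleared the hardwire threshold: the once-uncertain
# hypothesis is now part of the unquestioned foundation knowledge.
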