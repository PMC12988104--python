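# socev

Social-evidence belief dynamics under resource constraints.

`socev` is a cognitive-behavioral modeling toolkit for researchers studying
how belief systems form and change when agents weigh both their own core
beliefs and the opinions of socially trusted peers, while paying real
computational costs for every inference. It provides:

* an **evidence algebra** — believed and social evidence combined into a
  bounded reliability estimate, plus the revision rule for merging
  observations of differing confidence;
* a **cost model** — predictable per-inference costs, proactive task
  scheduling, and budgeted depth-first evaluation with staleness-aware
  caching;
* a **two-layer knowledge store** — a segmented hypergraph (foundation /
  social / evidence / imagination) split across short-term and long-term
  memory with focusing, unfocusing, forgetting and consolidation;
* **transition-freedom compression** — pruning of frequency-weighted
  state-transition graphs by conditional-probability thresholds;
* a **multi-agent simulator** — broadcast belief dynamics over a community,
  reproducing consensus formation, social polarization, and
  conformity-driven elimination of minority beliefs.

## The model

An agent *i* judges the reliability of a concept (or the preference for an
action) *j* as the product of two attachment-weighted means:

```
Ẽ_ij = ( Σ_l E^B_ijl · B_il / Σ_l B_il ) · ( Σ_k E^S_ijk · S_ik / Σ_k S_ik )
```

where `B_il ∈ [0,1]` is the agent's mental attachment to belief item *l*,
`E^B_ijl` the compatibility of *j* with that item, `S_ik` the social
attachment (trust) toward peer *k*, and `E^S_ijk` the peer's approval of
*j*. Observations of a generalized fact are merged by the revision rule
`F_rev = Σ f_j·D_j / Σ D_j`, with the evidence mass `D_j` derived from the
confidence `c_j` either directly (`D = c`) or as odds (`D = c/(1−c)`).

Evaluating one `Ẽ_ij` over `L` believed and `K` social relations costs

```
C̃_ij = C_m + 2·C_d + (K+L)·C_m + 2·(K+L)·C_a + Σ_l C^B_ijl + Σ_k C^S_ijk
```

which is linear in the size of the evidence bases and grows with the depth
of recursive inference — the basis for budgeting, caching, and for
cost-saving strategies that *shrink* `K` (ignore socially distant peers)
or `L` (forget weak beliefs). Those two strategies are exactly the
`peer_threshold` and `forgetting_threshold` of the community simulator.

## Worked example

`examples/polarization.py` runs three broadcast rounds of the built-in
five-agent community (agents 1–2 prefer activities {A,B}, agent 3 bridges
with {A,B,C,X}, agents 4–5 prefer {X,Y}+{Z}) under the four cost regimes:

```
peer=0.0 forgetting=0.0 -> 1 cluster(s) [{1, 2, 3, 4, 5}], belief spread 2.236 -> 0.008
peer=0.5 forgetting=0.0 -> 2 cluster(s) [{1, 2, 3}, {4, 5}], belief spread 2.236 -> 1.962
peer=0.0 forgetting=0.5 -> 2 cluster(s) [{1, 2, 3}, {4, 5}], belief spread 2.236 -> 1.547
peer=0.5 forgetting=0.5 -> 2 cluster(s) [{1, 2, 3}, {4, 5}], belief spread 2.236 -> 2.000
```

With open thresholds the community unifies (the maximum pairwise belief
distance collapses from 2.236 to 0.008). Restricting the social circle to
peers with cosine proximity ≥ 0.5 polarizes the community into the
{1,2,3} and {4,5} camps; adding forgetting makes the camps internally
identical and mutually isolated. The other example scripts demonstrate the
evidence algebra (`evidence_basics.py`), budgeted inference with caching
(`budgeted_inference.py`), the memory lifecycle (`memory_lifecycle.py`),
and transition-graph pruning (`graph_pruning.py`).

A thin CLI wraps the same library calls:

```
socev fixture                      # emit the five-agent community as JSON
socev simulate --out runs/demo     # run and export a trajectory as CSV
socev tf-prune --graph g.json --threshold 0.10 --out pruned.json
socev evaluate --graph e.json --root me:go_hiking --budget 50
```

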