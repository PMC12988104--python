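# Methods

## Evidence algebra

The core quantity is the normalized believed-social evidence of a concept
*j* for an agent *i*:

```
Ẽ_ij = ( Σ_l E^B_ijl · B_il / Σ_l B_il ) · ( Σ_k E^S_ijk · S_ik / Σ_k S_ik )
```

Each factor is a weighted mean of values in [0, 1], so `Ẽ ∈ [0, 1]`
whenever all inputs are, and each factor is invariant under positive
rescaling of its attachment vector. The un-normalized form
`E_ij = Σ(E^B·B) · Σ(E^S·S)` grows with the base sizes and is kept only
for diagnostic purposes.

**Zero-attachment factors.** When a factor's base is empty or carries zero
total attachment, the factor defaults to 1.0 and the estimate is marked
`defaulted`. Rationale: a solitary agent (no social attachments) should
still be able to evaluate evidence from its own beliefs rather than being
forced to `Ẽ = 0`; symmetrically for an agent with no belief base. If
*both* bases are empty there is nothing to evaluate and the call raises.
All evidence values below 1 are included in the sums; no floor cutoff is
applied.

**Revision and reliability.** Observations carry a strength *f* ∈ [0, 1]
and a confidence *c*; the evidence mass is `D = c` under the `strength`
convention or `D = c/(1−c)` under `frequency_odds` (undefined at c = 1,
which raises). The convention is a run-level configuration value with
default `strength`; both are exposed because both are established in the
literature on uncertain-inference frameworks. The revision rule
`F_rev = Σ f·D / Σ D` and the rule reliability `ν = Σ Φ·D / Σ D` are
weighted means and therefore stay inside the convex hull of their inputs
and are permutation-invariant. Satisfaction indicators Φ are admitted as
reals in [0, 1] so graded rule satisfaction is representable; booleans map
to 0/1.

**Validation is strict**: any weight or evidence value outside [0, 1]
raises instead of being clamped, because silent clamping hides data bugs.

## Cost model and budgeted inference

The cost of evaluating one node over `L` believed and `K` social relations
is `C_m + 2·C_d + (K+L)·C_m + 2·(K+L)·C_a` — one multiplication of two
weighted sums, two divisions, one multiplication per term, and additions
in both numerators and denominators. Costs of the three primitives default
to 1 each; units are abstract (one tick of scheduler capacity processes
`capacity` cost units), keeping budgets wall-clock-agnostic.

Relations stored in the graph are terminal and contribute a constant
stored cost; relations referencing another node are recursed exactly once
each (non-recurrent inference). The budgeted evaluator walks the graph
depth-first — believed children before social children, each in
lexicographic relation-id order — deducting each node's own cost from a
shared budget. The fixed order makes budget exhaustion deterministic and
gives prefix stability: enlarging the budget never changes a value that a
smaller budget already computed in full.

When a node cannot be afforded, a cached value no older than
`staleness_limit` ticks (default 100, configurable) is substituted;
failing that, the neutral default **0.5** — the maximum-uncertainty
midpoint — is used and marked `defaulted`. The same fallback breaks
cycles: a node re-entered within one evaluation returns its cached value
if any, else 0.5, and the event is logged. The scheduler drops tasks whose
budget cannot be spent by their deadline at the given capacity
(`skipped`), and orders the rest by priority, then earlier deadline, then
smaller cost. Skipped tasks are not re-queued.

## Knowledge store

Knowledge is a generalized hypergraph: links join one or more members and
may themselves be members of other links. Elements carry a functional
segment (foundation, social, evidence, imagination), a reliability, a
storage cost, a social-evidence score, and usage statistics. Capacities of
the short-term and long-term layers are measured in element counts, since
the model treats capacity abstractly; the `both` layer marks an LTM
element currently loaded into attention, so it need not be re-read on use.

Focusing ranks candidates by caller-supplied relevance (context matching
is deliberately left to the caller) and keeps the top `stm_capacity`;
unfocusing writes novel STM-born elements to LTM before eviction, so no
knowledge is lost silently. Forgetting removes LTM elements with
`use_count < min_use` **or** unused for more than `age_limit` ticks — the
two criteria are OR-combined because no blending weights are better
motivated — and sweeps away links whose members disappeared, transitively.
Consolidation hardwires imagination elements at or above a reliability
threshold into the foundation segment and removes those below a forget
threshold.

Whenever capacity forces a choice, removal order is total and
deterministic: ascending reliability (the proxy for probability of future
use), then ascending social evidence, then **descending** storage cost
(most expensive first), then ascending id. Ties everywhere resolve by
element id.

## Transition-freedom compression

The transition freedom (TF) of a state is its out-degree; the total over
all states scores the model's overall freedom of transition, and
minimizing it compresses the model. Pruning removes transitions whose
conditional probability — count over total outgoing count of the source,
computed on the **pre-prune** graph — is strictly below the threshold.
Single-pass semantics (no cascading renormalization) make pruning
idempotent at a fixed threshold and nested across thresholds. States left
unreachable are retained but flagged, since downstream consumers may still
hold references to them. Strictly-below removal matches the forgetting
semantics used elsewhere in the package.

## Community simulator

Agents hold belief vectors over a shared item universe; social proximity
is the cosine similarity of belief vectors (zero vectors are defined to
have proximity 0 — an agent with no beliefs is mentally adjacent to no
one). In each round every agent broadcasts once, in ascending-id
(`natural`) or descending (`reverse`) order. A receiver *i* whose
proximity to the sender *s* reaches `peer_threshold` updates every item as

```
b_i(j) ← ( b_i(j)·1 + b_s(j)·S_is ) / ( 1 + S_is )
```

— the `Ẽ` weighted average with the receiver's own belief as believed base
(self-weight 1) and the sender as the sole social source. Updates are
applied immediately, sender by sender, which is what makes communication
order observable. Proximities are recomputed once at round start (`rare`)
or after every broadcast (`frequent`); the peer threshold is compared
against whichever matrix is current. At the end of each round, belief
values strictly below `forgetting_threshold` are set to 0. Belief values
stay in [0, 1] by convexity of the update.

Cluster structure is operationalized as connected components of the
proximity graph at a configurable edge threshold (default 0.5;
proximity ≥ 0.99 is used for the "identical beliefs" check). Convergence
and consensus location are measured with Euclidean distance on belief
vectors; any monotone metric gives the same qualitative picture. The
consensus-bias measure compares the final community-mean belief vector
with each group's initial mean and returns the closer group, or a tie
within 1e−9.

**A known limitation**: under this update rule the self-weight of 1 caps
a single broadcast's pull at half the disagreement, so a community split
by per-round forgetting into unequal belief blocks (three agents against
two in the built-in fixture) settles on the majority block's beliefs
regardless of speaking order. A communication-order recency bias strong
enough to override the majority requires near-total adoption at high
proximity (self-weight `1−S` instead of 1), but that variant makes
frequent proximity recalculation *slow down* round-one convergence —
the early speakers capture the bridging agent and cut its ties to the
far group — contradicting the convergence-speed property this package
retains. The self-weight-1 rule was kept as the contract; the recency
direction of the consensus under forgetting is therefore not an emergent
property of this implementation.

## Synthetic data

`random_community(n_agents, n_items, density, seed)` draws each belief
independently as 1.0 with probability `density`, emulating the 0/1
preference vectors of the built-in community; it does not emulate graded
initial beliefs, correlated preferences, or pre-existing social structure
beyond what belief overlap induces. The random evidence graphs used in
testing are acyclic by construction (index-ordered references) with
branching up to 3+3 per node and depth bounded by node count; passing
tests on them show correctness of the evaluation and costing machinery,
not calibration against any empirical social data. The five-agent /
six-item community is the reference scenario for all emergent-behavior
checks and is built in.

## Numerical choices

Default three rounds per simulation; default thresholds 0.0; unit
operation costs; staleness limit 100 ticks; neutral default 0.5; tie
tolerance 1e−9 in consensus bias; oracle agreement asserted at 1e−12.
Problem sizes in the test suite (communities of ≤ 6 agents, evidence
graphs of ≤ 30 nodes, 10⁴-case fuzz for the evidence bounds and 10³
operation sequences for the store) were chosen so the full suite runs in
a few seconds while still exercising every branch of the contracts.
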