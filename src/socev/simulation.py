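"""Multi-agent broadcast simulator of belief dynamics.

A community of ``N`` agents holds belief vectors over a shared universe of
items, values in [0, 1].  Social proximity between two agents is the
cosine similarity of their belief vectors and plays the role of the social
attachment weight.  In each round every agent broadcasts its beliefs to
the whole community in turn; a receiver whose proximity to the sender
reaches ``peer_threshold`` absorbs the message as a weighted average with
its own belief (self-weight 1, sender weighted by proximity):

    b_i(j) <- (b_i(j) + b_s(j) * S_is) / (1 + S_is)

Receivers below the threshold ignore the message, which models the
cost-saving contraction of the agent's social reference base.  At the end
of each round every belief value strictly below ``forgetting_threshold``
is dropped to zero, modelling the contraction of the agent's personal
belief base.  Proximities are recomputed either once per round (``rare``)
or after every broadcast (``frequent``).

The five-agent fixture — two agents sharing {A, B}, two sharing {X, Y}
with one unique Z, and a bridging agent holding {A, B, C, X} — exhibits
the headline emergent phenomena: consensus formation when thresholds are
open, social polarization into two clusters under a peer threshold, and
conformity-driven elimination of minority items under forgetting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AgentState",
    "CommunityState",
    "SimulationConfig",
    "Trajectory",
    "cosine_proximity",
    "update_proximities",
    "broadcast",
    "apply_forgetting",
    "run_round",
    "run_simulation",
    "count_belief_clusters",
    "consensus_bias",
    "five_agent_fixture",
    "FIXTURE_ITEMS",
]

FIXTURE_ITEMS = ("A", "B", "C", "X", "Y", "Z")


@dataclass
class AgentState:
    """One agent's belief vector over the shared item universe."""

    agent_id: int
    beliefs: dict

    def __post_init__(self) -> None:
        for item, value in self.beliefs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"belief {item!r}={value!r} outside [0, 1]")

    def vector(self, items: Sequence[str]) -> np.ndarray:
        return np.array([self.beliefs.get(it, 0.0) for it in items], dtype=float)


@dataclass
class CommunityState:
    """Agents, their shared item universe, and the pairwise proximity matrix."""

    agents: list
    items: tuple
    proximity: np.ndarray = None  # type: ignore[assignment]
    round: int = 0

    def __post_init__(self) -> None:
        self.items = tuple(self.items)
        universe = set(self.items)
        for agent in self.agents:
            extra = set(agent.beliefs) - universe
            if extra:
                raise ValueError(f"agent {agent.agent_id} holds items outside the universe: {extra}")
        if self.proximity is None:
            self.proximity = _proximity_matrix(self)
        else:
            self.proximity = np.asarray(self.proximity, dtype=float)
            n = len(self.agents)
            if self.proximity.shape != (n, n):
                raise ValueError("proximity matrix shape does not match agent count")

    def belief_matrix(self) -> np.ndarray:
        return np.stack([a.vector(self.items) for a in self.agents])

    def agent_index(self, agent_id: int) -> int:
        for idx, agent in enumerate(self.agents):
            if agent.agent_id == agent_id:
                return idx
        raise KeyError(f"unknown agent id {agent_id!r}")

    def copy(self) -> "CommunityState":
        return CommunityState(
            agents=[AgentState(a.agent_id, dict(a.beliefs)) for a in self.agents],
            items=self.items,
            proximity=self.proximity.copy(),
            round=self.round,
        )


@dataclass(frozen=True)
class SimulationConfig:
    """The four experiment hyper-parameters plus the round count."""

    recalc_proximities: Literal["rare", "frequent"] = "rare"
    peer_threshold: float = 0.0
    forgetting_threshold: float = 0.0
    communication_order: Literal["natural", "reverse"] = "natural"
    n_rounds: int = 3

    def __post_init__(self) -> None:
        if self.recalc_proximities not in ("rare", "frequent"):
            raise ValueError("recalc_proximities must be 'rare' or 'frequent'")
        if self.communication_order not in ("natural", "reverse"):
            raise ValueError("communication_order must be 'natural' or 'reverse'")
        for name in ("peer_threshold", "forgetting_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be a positive integer")


@dataclass
class Trajectory:
    """Per-round snapshots of the community, snapshot 0 being the initial state."""

    snapshots: list
    config: SimulationConfig

    @property
    def initial(self) -> CommunityState:
        return self.snapshots[0]

    @property
    def final(self) -> CommunityState:
        return self.snapshots[-1]


def cosine_proximity(a: Mapping[str, float], b: Mapping[str, float], items: Sequence[str]) -> float:
    """Cosine similarity of two belief vectors; all-zero vectors yield 0.

    An agent with no beliefs has no mental overlap with anyone, so the
    zero vector is defined to be socially adjacent to no one.
    """
    extra = (set(a) | set(b)) - set(items)
    if extra:
        raise ValueError(f"belief items outside the shared universe: {sorted(extra)}")
    va = np.array([a.get(it, 0.0) for it in items], dtype=float)
    vb = np.array([b.get(it, 0.0) for it in items], dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(va @ vb / (na * nb))


def _proximity_matrix(community: CommunityState) -> np.ndarray:
    B = community.belief_matrix()
    norms = np.linalg.norm(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = (B @ B.T) / np.outer(norms, norms)
    P[~np.isfinite(P)] = 0.0
    P[norms == 0, :] = 0.0
    P[:, norms == 0] = 0.0
    np.fill_diagonal(P, 1.0)
    return np.clip(P, 0.0, 1.0)


def update_proximities(community: CommunityState) -> CommunityState:
    """Recompute the full symmetric proximity matrix from current beliefs."""
    community.proximity = _proximity_matrix(community)
    return community


def broadcast(sender_id: int, community: CommunityState, config: SimulationConfig) -> CommunityState:
    """One agent shares its beliefs; receivers above threshold absorb them.

    Every receiver ``i != sender`` with proximity ``S_is >= peer_threshold``
    updates every item as the attachment-weighted average of its own belief
    (weight 1) and the sender's (weight ``S_is``).  The sender is unchanged.
    With ``frequent`` recalculation the proximity matrix is refreshed after
    the broadcast.
    """
    s = community.agent_index(sender_id)
    sender_vec = community.agents[s].vector(community.items)
    for i, agent in enumerate(community.agents):
        if i == s:
            continue
        S = community.proximity[i, s]
        if S >= config.peer_threshold:
            own = agent.vector(community.items)
            updated = (own + sender_vec * S) / (1.0 + S)
            agent.beliefs = {it: float(v) for it, v in zip(community.items, updated)}
    if config.recalc_proximities == "frequent":
        update_proximities(community)
    return community


def apply_forgetting(agent: AgentState, threshold: float) -> AgentState:
    """Zero out belief values strictly below the forgetting threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("forgetting threshold must lie in [0, 1]")
    agent.beliefs = {it: (0.0 if v < threshold else v) for it, v in agent.beliefs.items()}
    return agent


def run_round(community: CommunityState, config: SimulationConfig) -> CommunityState:
    """One full round: every agent broadcasts once, then forgetting applies.

    With ``rare`` recalculation proximities are refreshed once at round
    start and held fixed for every broadcast of the round.
    """
    if config.recalc_proximities == "rare":
        update_proximities(community)
    order = sorted(a.agent_id for a in community.agents)
    if config.communication_order == "reverse":
        order = order[::-1]
    for sender_id in order:
        broadcast(sender_id, community, config)
    for agent in community.agents:
        apply_forgetting(agent, config.forgetting_threshold)
    if config.recalc_proximities == "frequent":
        update_proximities(community)
    community.round += 1
    return community


def run_simulation(initial: CommunityState, config: SimulationConfig) -> Trajectory:
    """Run ``n_rounds`` sequential rounds, recording every snapshot.

    The trajectory holds ``n_rounds + 1`` snapshots; snapshot 0 is the
    initial state with its proximity matrix refreshed from the initial
    beliefs.
    """
    state = initial.copy()
    update_proximities(state)
    snapshots = [state.copy()]
    for _ in range(config.n_rounds):
        state = run_round(state, config)
        snapshot = state.copy()
        update_proximities(snapshot)  # snapshots always carry current proximities
        snapshots.append(snapshot)
    return Trajectory(snapshots=snapshots, config=config)


def count_belief_clusters(community: CommunityState, edge_threshold: float = 0.5) -> int:
    """Connected components of the proximity graph at an edge threshold."""
    if not 0.0 <= edge_threshold <= 1.0:
        raise ValueError("edge threshold must lie in [0, 1]")
    g = nx.Graph()
    ids = [a.agent_id for a in community.agents]
    g.add_nodes_from(ids)
    P = community.proximity
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if P[i, j] >= edge_threshold:
                g.add_edge(ids[i], ids[j])
    return nx.number_connected_components(g)


def belief_clusters(community: CommunityState, edge_threshold: float = 0.5) -> list[set]:
    """The agent-id membership of each proximity cluster, sorted by minimum id."""
    g = nx.Graph()
    ids = [a.agent_id for a in community.agents]
    g.add_nodes_from(ids)
    P = community.proximity
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if P[i, j] >= edge_threshold:
                g.add_edge(ids[i], ids[j])
    return sorted(nx.connected_components(g), key=min)


def consensus_bias(
    trajectory: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    tolerance: float = 1e-9,
) -> str:
    """Which group's initial beliefs the final consensus sits closer to.

    Compares the Euclidean distance from the final community-mean belief
    vector to each group's initial mean vector.  Returns ``"a"``, ``"b"``,
    or ``"tie"`` when the distances agree within tolerance.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    initial, final = trajectory.initial, trajectory.final
    B0 = initial.belief_matrix()
    mean_final = final.belief_matrix().mean(axis=0)
    idx_a = [initial.agent_index(i) for i in group_a]
    idx_b = [initial.agent_index(i) for i in group_b]
    da = float(np.linalg.norm(mean_final - B0[idx_a].mean(axis=0)))
    db = float(np.linalg.norm(mean_final - B0[idx_b].mean(axis=0)))
    if abs(da - db) <= tolerance:
        return "tie"
    return "a" if da < db else "b"


def five_agent_fixture() -> CommunityState:
    """The built-in five-agent community over six recreational activities.

    Items A..Z; agents 1 and 2 prefer {A, B}, agent 3 bridges the groups
    with {A, B, C, X}, agent 4 prefers {X, Y}, and agent 5 {X, Y, Z} with
    Z unique to it.  Preferred activities carry attachment 1.0, all others
    0.0.
    """
    prefs = {1: "AB", 2: "AB", 3: "ABCX", 4: "XY", 5: "XYZ"}
    agents = [
        AgentState(aid, {it: (1.0 if it in chosen else 0.0) for it in FIXTURE_ITEMS})
        for aid, chosen in prefs.items()
    ]
    return CommunityState(agents=agents, items=FIXTURE_ITEMS)
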