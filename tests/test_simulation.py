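import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socev.config import random_community
from socev.simulation import (
    AgentState,
    CommunityState,
    SimulationConfig,
    apply_forgetting,
    belief_clusters,
    broadcast,
    consensus_bias,
    cosine_proximity,
    count_belief_clusters,
    five_agent_fixture,
    run_round,
    run_simulation,
    update_proximities,
)

ITEMS = ("A", "B", "C", "X", "Y", "Z")


def test_fixture_composition():
    community = five_agent_fixture()
    assert len(community.agents) == 5
    assert community.items == ITEMS
    held = {a.agent_id: {i for i, v in a.beliefs.items() if v == 1.0} for a in community.agents}
    assert held[1] == held[2] == {"A", "B"}
    assert held[3] == {"A", "B", "C", "X"}
    assert held[4] == {"X", "Y"}
    assert held[5] == {"X", "Y", "Z"}
    assert held[3] & held[1] == {"A", "B"} and held[3] & held[4] == {"X"}
    assert "Z" in held[5] and all("Z" not in held[a] for a in (1, 2, 3, 4))


def test_cosine_proximity_examples():
    fixture = five_agent_fixture()
    b = {a.agent_id: a.beliefs for a in fixture.agents}
    assert cosine_proximity(b[1], b[1], ITEMS) == pytest.approx(1.0)
    assert cosine_proximity(b[1], b[4], ITEMS) == pytest.approx(0.0)  # disjoint supports
    assert cosine_proximity(b[1], b[3], ITEMS) == pytest.approx(2 / (math.sqrt(2) * 2))
    assert cosine_proximity(b[4], b[5], ITEMS) == pytest.approx(2 / (math.sqrt(2) * math.sqrt(3)))
    assert cosine_proximity(b[3], b[4], ITEMS) == pytest.approx(1 / (2 * math.sqrt(2)))


def test_cosine_proximity_zero_vector_and_universe_mismatch():
    assert cosine_proximity({}, {"A": 1.0}, ITEMS) == 0.0
    with pytest.raises(ValueError, match="universe"):
        cosine_proximity({"Q": 1.0}, {"A": 1.0}, ITEMS)


def test_update_proximities_matrix_properties():
    community = five_agent_fixture()
    update_proximities(community)
    P = community.proximity
    assert np.allclose(P, P.T)
    assert np.allclose(np.diag(P), 1.0)
    assert P[3, 4] == pytest.approx(2 / (math.sqrt(2) * math.sqrt(3)))
    same = CommunityState(
        agents=[AgentState(i, {"A": 1.0}) for i in (1, 2, 3)], items=("A",)
    )
    assert np.allclose(same.proximity, 1.0)


def test_broadcast_update_rule():
    community = CommunityState(
        agents=[AgentState(1, {"A": 1.0, "B": 1.0}), AgentState(2, {"A": 1.0, "B": 0.0})],
        items=("A", "B"),
    )
    assert community.proximity[0, 1] == pytest.approx(1 / math.sqrt(2))
    community.proximity = np.array([[1.0, 1.0], [1.0, 1.0]])  # force S = 1
    broadcast(1, community, SimulationConfig())
    # receiver: (own*1 + sender*S)/(1+S) with S=1 halves the disagreement
    assert community.agents[1].beliefs["B"] == pytest.approx(0.5)
    assert community.agents[1].beliefs["A"] == pytest.approx(1.0)
    # sender untouched by its own broadcast
    assert community.agents[0].beliefs == {"A": 1.0, "B": 1.0}


def test_broadcast_below_threshold_ignored():
    community = five_agent_fixture()
    before = dict(community.agents[3].beliefs)  # agent 4, proximity 0 to agent 1
    broadcast(1, community, SimulationConfig(peer_threshold=0.5))
    assert community.agents[3].beliefs == before


def test_broadcast_unknown_sender_raises():
    with pytest.raises(KeyError):
        broadcast(42, five_agent_fixture(), SimulationConfig())


def test_apply_forgetting_strictly_below_semantics():
    agent = AgentState(1, {"A": 1.0, "C": 0.33, "X": 0.45})
    apply_forgetting(agent, 0.5)
    assert agent.beliefs == {"A": 1.0, "C": 0.0, "X": 0.0}
    agent = AgentState(1, {"A": 0.5})
    apply_forgetting(agent, 0.5)
    assert agent.beliefs["A"] == 0.5  # value exactly at threshold retained
    agent = AgentState(1, {"A": 0.2})
    apply_forgetting(agent, 0.0)
    assert agent.beliefs["A"] == 0.2


def test_run_round_fixed_points():
    # peer threshold above any off-diagonal proximity: nothing changes
    community = five_agent_fixture()
    before = [dict(a.beliefs) for a in community.agents]
    run_round(community, SimulationConfig(peer_threshold=0.99))
    assert [a.beliefs for a in community.agents] == before
    # single agent community
    solo = CommunityState(agents=[AgentState(1, {"A": 1.0})], items=("A",))
    run_round(solo, SimulationConfig())
    assert solo.agents[0].beliefs == {"A": 1.0}
    # identical agents are a fixed point of any round
    same = CommunityState(agents=[AgentState(i, {"A": 1.0, "B": 0.5}) for i in (1, 2, 3)], items=("A", "B"))
    run_round(same, SimulationConfig(recalc_proximities="frequent"))
    for agent in same.agents:
        assert agent.beliefs == pytest.approx({"A": 1.0, "B": 0.5})


def test_communication_order_changes_outcome():
    cfg_nat = SimulationConfig(communication_order="natural")
    cfg_rev = SimulationConfig(communication_order="reverse")
    nat = run_round(five_agent_fixture(), cfg_nat)
    rev = run_round(five_agent_fixture(), cfg_rev)
    assert not np.allclose(nat.belief_matrix(), rev.belief_matrix())


def test_trajectory_snapshot_contract():
    with pytest.raises(ValueError):
        SimulationConfig(n_rounds=0)
    traj = run_simulation(five_agent_fixture(), SimulationConfig(n_rounds=1))
    assert len(traj.snapshots) == 2
    assert np.allclose(traj.initial.belief_matrix(), five_agent_fixture().belief_matrix())
    traj3 = run_simulation(five_agent_fixture(), SimulationConfig())
    assert len(traj3.snapshots) == 4  # default three rounds plus the initial state


@given(
    seed=st.integers(0, 10_000),
    peer=st.sampled_from([0.0, 0.3, 0.5, 0.8]),
    forget=st.sampled_from([0.0, 0.3, 0.5]),
    recalc=st.sampled_from(["rare", "frequent"]),
    order=st.sampled_from(["natural", "reverse"]),
)
@settings(max_examples=40, deadline=None)
def test_beliefs_stay_in_unit_interval_and_proximity_well_formed(seed, peer, forget, recalc, order):
    """Convexity of the update rule keeps beliefs in [0, 1] for any config."""
    community = random_community(n_agents=4, n_items=5, density=0.5, seed=seed)
    cfg = SimulationConfig(
        recalc_proximities=recalc,
        peer_threshold=peer,
        forgetting_threshold=forget,
        communication_order=order,
        n_rounds=2,
    )
    traj = run_simulation(community, cfg)
    for snap in traj.snapshots:
        B = snap.belief_matrix()
        assert np.all((B >= 0.0) & (B <= 1.0))
        P = snap.proximity
        assert np.allclose(P, P.T) and np.allclose(np.diag(P), 1.0)
        assert np.all((P >= 0.0) & (P <= 1.0))


def test_count_belief_clusters_trivial_structures():
    community = CommunityState(agents=[AgentState(i, {"A": 1.0}) for i in (1, 2, 3)], items=("A",))
    assert count_belief_clusters(community, 0.5) == 1
    community.proximity = np.eye(3)
    assert count_belief_clusters(community, 0.5) == 3
    community.proximity = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
    assert count_belief_clusters(community, 0.5) == 2
    assert belief_clusters(community, 0.5) == [{1, 2}, {3}]


def test_consensus_bias_symmetric_community_ties():
    agents = [
        AgentState(1, {"A": 1.0, "B": 0.0}),
        AgentState(2, {"A": 0.0, "B": 1.0}),
    ]
    community = CommunityState(agents=agents, items=("A", "B"))
    traj = run_simulation(community, SimulationConfig(n_rounds=2))
    assert consensus_bias(traj, [1], [2]) == "tie"
    with pytest.raises(ValueError):
        consensus_bias(traj, [], [2])
    with pytest.raises(ValueError):
        consensus_bias(traj, [1], [1])


def test_consensus_bias_detects_closer_group():
    # three like-minded agents against one: consensus lands near the majority
    agents = [
        AgentState(1, {"A": 1.0, "B": 0.0}),
        AgentState(2, {"A": 1.0, "B": 0.0}),
        AgentState(3, {"A": 1.0, "B": 0.0}),
        AgentState(4, {"A": 0.0, "B": 1.0}),
    ]
    community = CommunityState(agents=agents, items=("A", "B"))
    traj = run_simulation(community, SimulationConfig(n_rounds=3))
    assert consensus_bias(traj, [1, 2, 3], [4]) == "a"


def test_polarization_components_match_expected_split():
    cfg = SimulationConfig(peer_threshold=0.5)
    traj = run_simulation(five_agent_fixture(), cfg)
    assert belief_clusters(traj.final, 0.5) == [{1, 2, 3}, {4, 5}]


def test_open_community_converges_monotonically():
    traj = run_simulation(five_agent_fixture(), SimulationConfig())
    def spread(snap):
        B = snap.belief_matrix()
        return max(
            np.linalg.norm(B[i] - B[j]) for i in range(len(B)) for j in range(len(B))
        )
    spreads = [spread(s) for s in traj.snapshots]
    assert all(b < a for a, b in zip(spreads, spreads[1:]))
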