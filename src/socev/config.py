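"""Run configuration, serialization, and seeded data generation.

All structured inputs are JSON (human-diffable), tabular outputs are CSV.
A run is fully reproducible from its config and seed; the manifest written
next to every exported trajectory suffices to replay it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cost import DEFAULT_STALENESS_LIMIT, OperationCosts
from .evidence import Convention
from .simulation import AgentState, CommunityState, SimulationConfig, Trajectory

__all__ = ["RunConfig", "load_config", "save_config", "export_trajectory", "random_community"]


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration for a reproducible run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    costs: OperationCosts = field(default_factory=OperationCosts)
    convention: Convention = Convention.STRENGTH
    staleness_limit: int = DEFAULT_STALENESS_LIMIT
    stm_capacity: int = 7
    ltm_capacity: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["convention"] = self.convention.value
        return d


_SIM_KEYS = {
    "recalc_proximities",
    "peer_threshold",
    "forgetting_threshold",
    "communication_order",
    "n_rounds",
}
_TOP_KEYS = {
    "simulation",
    "costs",
    "convention",
    "staleness_limit",
    "stm_capacity",
    "ltm_capacity",
    "seed",
}


def _build(payload: dict) -> RunConfig:
    bad = sorted(set(payload) - _TOP_KEYS)
    if bad:
        raise ValueError(f"unknown configuration keys: {bad}")
    sim_payload = dict(payload.get("simulation", {}))
    bad = sorted(set(sim_payload) - _SIM_KEYS)
    if bad:
        raise ValueError(f"unknown simulation keys: {bad}")
    cost_payload = dict(payload.get("costs", {}))
    bad = sorted(set(cost_payload) - {"multiply", "divide", "add"})
    if bad:
        raise ValueError(f"unknown cost keys: {bad}")
    try:
        return RunConfig(
            simulation=SimulationConfig(**sim_payload),
            costs=OperationCosts(**cost_payload),
            convention=Convention(payload.get("convention", "strength")),
            staleness_limit=int(payload.get("staleness_limit", DEFAULT_STALENESS_LIMIT)),
            stm_capacity=int(payload.get("stm_capacity", 7)),
            ltm_capacity=int(payload.get("ltm_capacity", 1000)),
            seed=int(payload.get("seed", 0)),
        )
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid configuration: {err}") from err


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run config, filling documented defaults."""
    text = Path(path).read_text()
    payload = json.loads(text)
    if not isinstance(payload, dict):
        raise ValueError("configuration root must be a JSON object")
    return _build(payload)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")


def community_to_dict(community: CommunityState) -> dict:
    return {
        "items": list(community.items),
        "agents": [{"agent_id": a.agent_id, "beliefs": dict(a.beliefs)} for a in community.agents],
    }


def community_from_dict(payload: dict) -> CommunityState:
    agents = [AgentState(rec["agent_id"], dict(rec["beliefs"])) for rec in payload["agents"]]
    return CommunityState(agents=agents, items=tuple(payload["items"]))


def export_trajectory(
    trajectory: Trajectory,
    directory: str | Path,
    config: RunConfig | None = None,
) -> list[Path]:
    """Write a trajectory as a long-format belief CSV plus per-round proximity CSVs.

    ``beliefs.csv`` holds one row per (round, agent, item); each snapshot's
    proximity matrix goes to ``proximity_round_<r>.csv``; ``manifest.json``
    records the config, seed and package version so the run can be replayed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for r, snap in enumerate(trajectory.snapshots):
        for agent in snap.agents:
            for item in snap.items:
                rows.append((r, agent.agent_id, item, agent.beliefs.get(item, 0.0)))
    beliefs = pd.DataFrame(rows, columns=["round", "agent_id", "item", "value"])
    beliefs_path = directory / "beliefs.csv"
    beliefs.to_csv(beliefs_path, index=False, float_format="%.12g")
    written.append(beliefs_path)

    for r, snap in enumerate(trajectory.snapshots):
        ids = [a.agent_id for a in snap.agents]
        frame = pd.DataFrame(snap.proximity, index=ids, columns=ids)
        path = directory / f"proximity_round_{r}.csv"
        frame.to_csv(path, float_format="%.12g")
        written.append(path)

    manifest = {
        "version": __version__,
        "numpy": np.__version__,
        "simulation": asdict(trajectory.config),
        "config": config.to_dict() if config is not None else None,
        "n_snapshots": len(trajectory.snapshots),
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written


def random_community(
    n_agents: int,
    n_items: int,
    density: float,
    seed: int = 0,
) -> CommunityState:
    """Seeded random community: each belief is 1.0 with probability ``density``."""
    if n_agents < 1 or n_items < 1:
        raise ValueError("need at least one agent and one item")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    items = tuple(f"item_{i}" for i in range(n_items))
    draws = rng.random((n_agents, n_items)) < density
    agents = [
        AgentState(aid + 1, {it: (1.0 if draws[aid, j] else 0.0) for j, it in enumerate(items)})
        for aid in range(n_agents)
    ]
    return CommunityState(agents=agents, items=items)
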