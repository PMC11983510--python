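"""Experiment presets, metrics, multi-seed runners and serialization.

Presets mirror the three benchmark protocols:

* ``mdt`` -- the two-stage decision task, 5 blocks of 1,000 episodes
  (500 at low transition uncertainty with the goal resampled every 125
  episodes, then 500 at high uncertainty), tabular agents by default or
  network-backed ones with ``backend='network'``.
* ``loca`` -- the gridworld adaptation benchmark: two blocks (one per
  uncertainty level) of three phases, each phase budgeted at 3% of a
  baseline episode count, repeated over independent runs.
* ``pong`` / ``pong-simcount`` -- the single-point stochastic Pong with
  its 1,000-decision goal/uncertainty schedule; the simcount preset
  sweeps the number of mental simulations at a fixed budget of real
  environment interactions.

Outputs: one episode-level CSV (``episodes.csv``) and a ``summary.json``
with per-agent means, across-seed dispersion, and Welch t-tests against
a reference agent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agents import AgentConfig, Transition, make_agent
from .environments import (
    GridWorldLoCA,
    MDTSchedule,
    PongSchedule,
    StochasticPong,
    TwoStageMDT,
    loca_schedule,
)
from .world_model import RolloutConfig

__all__ = [
    "EpisodeRecord",
    "choice_optimality",
    "nts",
    "mean_normalized_reward",
    "exponential_reward",
    "run_episode",
    "run_mdt",
    "run_loca",
    "run_pong",
    "run_pong_simcount",
    "run_experiment",
    "summarize",
]

PRESETS = ("mdt", "loca", "pong", "pong-simcount")


@dataclass
class EpisodeRecord:
    """One logged episode."""

    agent: str
    seed: int
    episode: int
    reward: float
    max_reward: float
    goal_kind: str
    p_intended: float
    steps: int
    phase: int = 0
    p_mb: float = float("nan")
    rel_mf: float = float("nan")
    rel_mb: float = float("nan")

    def __post_init__(self) -> None:
        if self.reward > self.max_reward + 1e-9:
            raise ValueError("episode reward exceeds the max achievable reward")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _rewards(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        if records.empty:
            raise ValueError("empty record list")
        return records["reward"].to_numpy(), records["max_reward"].to_numpy()
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    return (
        np.array([r.reward for r in records]),
        np.array([r.max_reward for r in records]),
    )


def choice_optimality(records) -> float:
    """Fraction of episodes achieving the maximum achievable reward."""
    r, m = _rewards(records)
    return float(np.mean(np.isclose(r, m)))


def nts(r_max: float, n_interactions: int) -> float:
    """Sample-efficiency index: best reward per environment interaction."""
    if n_interactions <= 0:
        raise ValueError("n_interactions must be positive")
    return r_max / n_interactions


def mean_normalized_reward(records) -> float:
    """Mean per-episode reward on the task's normalized scale."""
    r, m = _rewards(records)
    return float(np.mean(r / np.where(m > 0, m, 1.0)))


def exponential_reward(rewards: Sequence[float], smoothing: float = 0.99) -> float:
    """Exponentially weighted moving average of episode reward, final value.

    This is this package's reading of a smoothed end-of-training reward;
    the unsmoothed mean is always reported alongside it.
    """
    ewma = 0.0
    for i, r in enumerate(rewards):
        ewma = r if i == 0 else smoothing * ewma + (1.0 - smoothing) * r
    return float(ewma)


# ---------------------------------------------------------------------------
# Episode runner
# ---------------------------------------------------------------------------


def run_episode(agent, env) -> tuple[float, int, dict]:
    """Drive one episode; returns (total reward, steps, last step info)."""
    obs = env.reset()
    agent.start_episode(obs)
    total, steps, info = 0.0, 0, {}
    terminal = False
    while not terminal:
        a = agent.act(obs)
        res = env.step(a)
        tr = Transition(obs, a, res.reward, res.next_state, res.terminal)
        agent.observe(tr)
        total += res.reward
        steps += 1
        info = res.info
        terminal = res.terminal
        obs = res.next_state
    agent.end_episode()
    return total, steps, info


def trace_episode(agent, env) -> pd.DataFrame:
    """Run one episode and return a per-step trajectory table."""
    obs = env.reset()
    agent.start_episode(obs)
    rows, terminal, t = [], False, 0
    while not terminal:
        a = agent.act(obs)
        res = env.step(a)
        agent.observe(Transition(obs, a, res.reward, res.next_state, res.terminal))
        rows.append(
            {
                "t": t,
                "s": obs if np.isscalar(obs) else list(np.asarray(obs)),
                "a": a,
                "r": res.reward,
                "terminal": res.terminal,
                "goal_kind": res.info.get("goal_kind", ""),
                "uncertainty": res.info.get("p_intended", float("nan")),
            }
        )
        terminal, obs, t = res.terminal, res.next_state, t + 1
    agent.end_episode()
    return pd.DataFrame(rows)


def _arb_columns(agent) -> dict:
    if hasattr(agent, "arb"):
        st = agent.arb.state
        return {"p_mb": st.p_mb, "rel_mf": st.rel_mf, "rel_mb": st.rel_mb}
    return {}


def _onehot(n: int):
    eye = np.eye(n)

    def enc(s):
        return eye[int(s)] if np.isscalar(s) or isinstance(s, (int, np.integer)) else np.asarray(s, float)

    return enc


def _onehot_projector(n: int):
    eye = np.eye(n)

    def proj(x):
        return eye[int(np.argmax(np.asarray(x, float)))]

    return proj


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def run_mdt(
    agent_name: str,
    seed: int,
    n_episodes: int = 5000,
    backend: str = "table",
    config: AgentConfig | None = None,
) -> pd.DataFrame:
    """Run one agent for one seed on the full two-stage MDT schedule."""
    env = TwoStageMDT(seed=seed, schedule=MDTSchedule(seed))
    config = config if config is not None else AgentConfig()
    agent_seed = int(np.random.SeedSequence([seed, _name_key(agent_name)])
                     .generate_state(1)[0] % (2**31))
    if backend == "table":
        agent = make_agent(agent_name, n_states=env.n_states,
                           n_actions=env.n_actions, config=config,
                           seed=agent_seed)
    else:
        config = replace(
            config,
            rollout=replace(config.rollout,
                            state_projector=_onehot_projector(env.n_states),
                            horizon=3),
        )
        agent = make_agent(agent_name, obs_dim=env.n_states,
                           n_actions=env.n_actions, backend="network",
                           config=config, seed=agent_seed,
                           encoder=_onehot(env.n_states))
    rows = []
    for ep in range(n_episodes):
        total, steps, _ = run_episode(agent, env)
        rows.append(
            {
                "agent": agent_name,
                "seed": seed,
                "episode": ep,
                "reward": total,
                "max_reward": env.max_reward(),
                "goal_kind": env.goal.kind,
                "p_intended": env.uncertainty.p_intended,
                "steps": steps,
                "phase": ep // 125,
                **_arb_columns(agent),
            }
        )
    return pd.DataFrame(rows)


def run_loca(
    agent_name: str,
    seed: int,
    schedule=None,
    config: AgentConfig | None = None,
) -> pd.DataFrame:
    """One full gridworld adaptation run (2 blocks x 3 phases)."""
    schedule = schedule if schedule is not None else loca_schedule()
    config = config if config is not None else AgentConfig()
    agent_seed = int(np.random.SeedSequence([seed, _name_key(agent_name)])
                     .generate_state(1)[0] % (2**31))
    n_states = GridWorldLoCA(schedule.phases[0], seed=seed).n_states
    agent = make_agent(agent_name, n_states=n_states, n_actions=4,
                       config=config, seed=agent_seed)
    rows = []
    ep_global = 0
    for phase_idx, phase in enumerate(schedule.phases):
        env = GridWorldLoCA(phase, seed=int(np.random.SeedSequence(
            [seed, phase_idx]).generate_state(1)[0] % (2**31)))
        for _ in range(phase.n_episodes):
            total, steps, _ = run_episode(agent, env)
            rows.append(
                {
                    "agent": agent_name,
                    "seed": seed,
                    "episode": ep_global,
                    "reward": total,
                    "max_reward": env.max_reward(),
                    "goal_kind": "flexible",
                    "p_intended": phase.p_intended,
                    "steps": steps,
                    "phase": phase_idx,
                    **_arb_columns(agent),
                }
            )
            ep_global += 1
    return pd.DataFrame(rows)


def run_pong(
    agent_name: str,
    seed: int,
    n_episodes: int = 1000,
    config: AgentConfig | None = None,
    max_interactions: int | None = None,
) -> pd.DataFrame:
    """Run one network-backed agent on the scheduled stochastic Pong."""
    if config is None:
        config = AgentConfig(update_mode="step",
                             rollout=RolloutConfig(n_steps=5, horizon=5))
    env = StochasticPong(seed=seed, schedule=PongSchedule(seed))
    agent_seed = int(np.random.SeedSequence([seed, _name_key(agent_name)])
                     .generate_state(1)[0] % (2**31))
    agent = make_agent(agent_name, obs_dim=env.obs_dim,
                       n_actions=env.n_actions, backend="network",
                       config=config, seed=agent_seed)
    rows, interactions = [], 0
    for ep in range(n_episodes):
        total, steps, info = run_episode(agent, env)
        interactions += steps
        rows.append(
            {
                "agent": agent_name,
                "seed": seed,
                "episode": ep,
                "reward": total,
                "max_reward": 1.0,
                "goal_kind": info.get("goal_kind", ""),
                "p_intended": env.p_intended,
                "steps": steps,
                "phase": env.timestep // (env.schedule.period
                                          if env.schedule else 1000),
                "interactions": interactions,
                **_arb_columns(agent),
            }
        )
        if max_interactions is not None and interactions >= max_interactions:
            break
    return pd.DataFrame(rows)


def nts_from_records(df: pd.DataFrame) -> float:
    """NTS over a single run: best episode reward divided by the number of
    real interactions consumed when that best was first achieved."""
    r_max = df["reward"].max()
    first = df.loc[df["reward"] >= r_max, "interactions"].iloc[0]
    return nts(float(r_max), int(first))


def run_pong_simcount(
    seed: int,
    n_values: Sequence[int] = (10, 20, 50, 100),
    max_interactions: int = 8000,
    agents: Sequence[str] = ("meta-dyna", "dyna-q"),
    config: AgentConfig | None = None,
) -> pd.DataFrame:
    """Sweep the mental-simulation count at a fixed real-interaction budget."""
    frames = []
    for name in agents:
        for n in n_values:
            cfg = config if config is not None else AgentConfig(
                update_mode="step",
                rollout=RolloutConfig(n_steps=10, horizon=30))
            cfg = replace(cfg, planning_steps=n)
            df = run_pong(name, seed, n_episodes=10**6, config=cfg,
                          max_interactions=max_interactions)
            df["agent"] = f"{name}(n={n})"
            df["planning_steps"] = n
            df["base_agent"] = name
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Multi-seed driver, summaries, serialization
# ---------------------------------------------------------------------------


def _name_key(name: str) -> int:
    return int.from_bytes(name.encode()[:4].ljust(4, b"_"), "little") % (2**31)


def summarize(df: pd.DataFrame, reference: str = "meta-dyna") -> dict:
    """Per-agent metrics plus Welch t-tests of per-seed means vs a reference."""
    out: dict = {"agents": {}, "t_tests": {}}
    for name, g in df.groupby("agent"):
        per_seed = g.groupby("seed").apply(
            lambda x: mean_normalized_reward(x), include_groups=False
        )
        rewards_in_order = g.sort_values(["seed", "episode"])["reward"]
        out["agents"][str(name)] = {
            "mean_reward": mean_normalized_reward(g),
            "choice_optimality": choice_optimality(g),
            "per_seed_means": [float(v) for v in per_seed],
            "across_seed_std": float(per_seed.std(ddof=1))
            if len(per_seed) > 1 else 0.0,
            "across_seed_variance": float(per_seed.var(ddof=1))
            if len(per_seed) > 1 else 0.0,
            "exponential_reward": exponential_reward(rewards_in_order.tolist()),
            "n_episodes": int(len(g)),
        }
    ref = reference if reference in out["agents"] else next(iter(out["agents"]))
    ref_means = out["agents"][ref]["per_seed_means"]
    for name, entry in out["agents"].items():
        if name == ref or len(ref_means) < 2 or len(entry["per_seed_means"]) < 2:
            continue
        t, p = stats.ttest_ind(ref_means, entry["per_seed_means"],
                               equal_var=False)
        out["t_tests"][name] = {"reference": ref, "t": float(t), "p": float(p)}
    return out


def run_experiment(
    preset: str,
    agents: Sequence[str],
    seeds: int | Iterable[int] = 10,
    out_dir: str | Path | None = None,
    episodes: int | None = None,
    backend: str = "table",
    config: AgentConfig | None = None,
    reference: str = "meta-dyna",
) -> dict:
    """Execute a preset across agents and seeds; write CSV + JSON outputs."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; known: {PRESETS}")
    seed_list = list(range(seeds)) if isinstance(seeds, int) else list(seeds)
    frames = []
    for name in agents:
        for s in seed_list:
            if preset == "mdt":
                frames.append(run_mdt(name, s, episodes or 5000, backend, config))
            elif preset == "loca":
                frames.append(run_loca(name, s, config=config))
            elif preset == "pong":
                frames.append(run_pong(name, s, episodes or 1000, config))
            else:
                frames.append(run_pong_simcount(s, agents=[name], config=config))
    df = pd.concat(frames, ignore_index=True)
    summary = summarize(df, reference=reference)
    summary["preset"] = preset
    summary["seeds"] = seed_list
    if preset == "pong-simcount":
        summary["nts"] = {
            str(name): float(np.mean([nts_from_records(g1)
                                      for _, g1 in g.groupby("seed")]))
            for name, g in df.groupby("agent")
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "episodes.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    summary["records"] = df
    return summary


def recompute_summary(out_dir: str | Path, reference: str = "meta-dyna") -> dict:
    """Round-trip check: rebuild the summary from the episode CSV."""
    df = pd.read_csv(Path(out_dir) / "episodes.csv")
    return summarize(df, reference=reference)
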