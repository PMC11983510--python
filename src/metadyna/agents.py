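"""Agents: Meta-Dyna and its baselines.

All agents share a small episodic API driven by the experiment runner:

    obs = env.reset(); agent.start_episode(obs)
    a = agent.act(obs); ...; agent.observe(transition); agent.end_episode()

Tabular learners keep numpy Q-tables; network learners use small
feed-forward Q-networks (numpy, Adam).  The Meta-Dyna agent combines a
model-free learner (Q-learning on real experience), a model-based
learner (Q-learning on experience simulated by a world model), and the
reliability-based arbitration that weights them.  Buffer hygiene is
enforced: the model-free replay buffer only ever holds real transitions,
and the model-based Q-function is only ever trained on simulated ones.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .arbitration import (
    ArbitrationParams,
    Arbitrator,
    compute_rpe,
    compute_spe_discrete,
    compute_spe_from_gmm,
    integrate_q,
)
from .world_model import (
    MDNRNN,
    RolloutConfig,
    TabularModel,
    Transition,
    rollout,
    tabular_predict,
    tabular_update,
)

__all__ = [
    "Transition",
    "ReplayBuffer",
    "AgentConfig",
    "select_action",
    "qlearn_update",
    "sarsa_update",
    "forward_update",
    "value_iteration",
    "QLearningAgent",
    "SarsaAgent",
    "ForwardAgent",
    "DynaQAgent",
    "MetaDynaAgent",
    "HybridArbitrationAgent",
    "MLPQ",
    "DQNAgent",
    "DynaQNetAgent",
    "MetaDynaNetAgent",
    "AGENT_REGISTRY",
    "make_agent",
]


class ReplayBuffer:
    """Bounded FIFO of transitions; the MF buffer refuses simulated items."""

    def __init__(self, capacity: int = 10_000, role: str = "RB_MF"):
        if role not in ("RB_MF", "RB_MB"):
            raise ValueError(f"unknown buffer role {role!r}")
        self.role = role
        self._items: deque[Transition] = deque(maxlen=capacity)

    def add(self, tr: Transition) -> None:
        if self.role == "RB_MF" and tr.simulated:
            raise ValueError("RB_MF only accepts real (non-simulated) transitions")
        self._items.append(tr)

    def sample(self, n: int, rng: np.random.Generator) -> list[Transition]:
        idx = rng.integers(len(self._items), size=min(n, len(self._items)))
        return [self._items[i] for i in idx]

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)


@dataclass
class AgentConfig:
    """Hyperparameters shared across agents (tabular defaults)."""

    lr_mf: float = 0.1
    # the MB learner trains on abundant simulated data; its step-size is
    # matched to the world model's own step-size (gamma_t) so that value
    # adaptation keeps pace with model adaptation after reward changes
    lr_mb: float = 0.2
    gamma: float = 0.9
    epsilon: float = 0.1
    planning_steps: int = 10
    capacity: int = 10_000
    update_mode: Literal["episode", "step"] = "episode"
    arbitration: ArbitrationParams = field(default_factory=ArbitrationParams)
    rollout: RolloutConfig = field(default_factory=RolloutConfig)
    # arbitration tracker settings
    eta: float = 0.2
    rpe_max: float = 1.0
    dirichlet_prior: float = 1.0
    dirichlet_decay: float = 0.95
    p_mb_fixed: float | None = None
    # network settings
    hidden_size: int = 64
    lr_net: float = 5e-3
    batch_size: int = 32
    batches_per_episode: int = 4
    target_sync: int = 100
    wm_hidden: int = 64
    wm_components: int = 5
    wm_lr: float = 3e-3
    # planning engages only after this many world-model gradient updates:
    # rollouts from an unfit mixture model inject noise, not knowledge
    wm_warmup: int = 20
    wm_on_real_only: bool = False


# ---------------------------------------------------------------------------
# Primitive updates
# ---------------------------------------------------------------------------


def select_action(
    q_integrated: Callable[[object], np.ndarray] | np.ndarray,
    s,
    epsilon: float,
    rng: np.random.Generator,
) -> int:
    """Epsilon-greedy with uniform random tie-breaking (seeded)."""
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    q_vals = q_integrated(s) if callable(q_integrated) else q_integrated[s]
    q_vals = np.asarray(q_vals, dtype=float)
    if rng.random() < epsilon:
        return int(rng.integers(len(q_vals)))
    best = np.flatnonzero(q_vals == q_vals.max())
    return int(best[rng.integers(len(best))])


def qlearn_update(q: np.ndarray, tr: Transition, lr: float, gamma: float) -> np.ndarray:
    """Off-policy TD(0) backup toward r + gamma * max_a' Q(s', a')."""
    target = tr.r
    if not tr.terminal:
        target += gamma * q[tr.s_next].max()
    q[tr.s, tr.a] += lr * (target - q[tr.s, tr.a])
    return q


def sarsa_update(
    q: np.ndarray, tr: Transition, a_next: int | None, lr: float, gamma: float
) -> np.ndarray:
    """On-policy TD(0) backup toward r + gamma * Q(s', a_next)."""
    target = tr.r
    if not tr.terminal:
        target += gamma * q[tr.s_next, a_next]
    q[tr.s, tr.a] += lr * (target - q[tr.s, tr.a])
    return q


def value_iteration(
    model: TabularModel, gamma: float, sweeps: int = 1, q: np.ndarray | None = None
) -> np.ndarray:
    """Bellman optimality sweeps over the learned model.

    Only (s, a) pairs with at least one observed transition are backed
    up; unvisited entries keep their current values.  Terminal states
    have value zero.
    """
    if q is None:
        q = np.zeros((model.n_states, model.n_actions))
    visited = model.visit_counts.sum(axis=2) > 0
    terminal = np.zeros(model.n_states, dtype=bool)
    for s in model.terminal_states:
        terminal[s] = True
    for _ in range(sweeps):
        v = q.max(axis=1)
        v[terminal] = 0.0
        backup = model.r_est + gamma * model.t_est @ v
        q[visited] = backup[visited]
    return q


def forward_update(
    model: TabularModel, q_mb: np.ndarray, tr: Transition, gamma: float = 0.9
) -> tuple[TabularModel, np.ndarray]:
    """Pure model-based (FORWARD) step: model update + one VI sweep."""
    tabular_update(model, tr.s, tr.a, tr.s_next, tr.r, tr.terminal)
    q_mb = value_iteration(model, gamma, sweeps=1, q=q_mb)
    return model, q_mb


# ---------------------------------------------------------------------------
# Tabular agents
# ---------------------------------------------------------------------------


class BaseAgent:
    name = "base"

    def __init__(self, n_actions: int, config: AgentConfig, seed: int = 0):
        self.n_actions = n_actions
        self.cfg = config
        self.rng = np.random.default_rng(seed)

    # -- checkpointing ----------------------------------------------------

    def state_dict(self) -> dict:
        """Flat array snapshot of all learned parameters."""
        out: dict[str, np.ndarray] = {}
        for attr, val in vars(self).items():
            if isinstance(val, np.ndarray):
                out[attr] = val
            elif isinstance(val, MLPQ):
                for k, v in val.params.items():
                    out[f"{attr}.{k}"] = v
            elif isinstance(val, MDNRNN):
                for k, v in val.params.items():
                    out[f"{attr}.{k}"] = v
            elif isinstance(val, TabularModel):
                out[f"{attr}.t_est"] = val.t_est
                out[f"{attr}.r_est"] = val.r_est
                out[f"{attr}.visit_counts"] = val.visit_counts
        return out

    def save(self, path: str) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path: str) -> None:
        path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
        with np.load(path) as data:
            for key in data.files:
                attr, _, sub = key.partition(".")
                target = getattr(self, attr)
                if not sub:
                    setattr(self, attr, data[key])
                elif isinstance(target, (MLPQ, MDNRNN)):
                    target.params[sub] = data[key]
                elif isinstance(target, TabularModel):
                    setattr(target, sub, data[key])

    def start_episode(self, obs) -> None:  # pragma: no cover - trivial default
        pass

    def act(self, obs) -> int:
        raise NotImplementedError

    def observe(self, tr: Transition) -> None:
        raise NotImplementedError

    def end_episode(self) -> None:
        pass

    def q_values(self, obs) -> np.ndarray:
        raise NotImplementedError


class QLearningAgent(BaseAgent):
    """Plain model-free Q-learning with online per-step updates."""

    name = "q-learning"

    def __init__(self, n_states: int, n_actions: int, config: AgentConfig, seed=0):
        super().__init__(n_actions, config, seed)
        self.q = np.zeros((n_states, n_actions))

    def act(self, obs) -> int:
        return select_action(self.q, obs, self.cfg.epsilon, self.rng)

    def observe(self, tr: Transition) -> None:
        qlearn_update(self.q, tr, self.cfg.lr_mf, self.cfg.gamma)

    def q_values(self, obs) -> np.ndarray:
        return self.q[obs]


class SarsaAgent(BaseAgent):
    """On-policy SARSA; the update waits for the next chosen action."""

    name = "sarsa"

    def __init__(self, n_states: int, n_actions: int, config: AgentConfig, seed=0):
        super().__init__(n_actions, config, seed)
        self.q = np.zeros((n_states, n_actions))
        self._pending: Transition | None = None

    def start_episode(self, obs) -> None:
        self._pending = None

    def act(self, obs) -> int:
        a = select_action(self.q, obs, self.cfg.epsilon, self.rng)
        if self._pending is not None:
            sarsa_update(self.q, self._pending, a, self.cfg.lr_mf, self.cfg.gamma)
            self._pending = None
        return a

    def observe(self, tr: Transition) -> None:
        if tr.terminal:
            sarsa_update(self.q, tr, None, self.cfg.lr_mf, self.cfg.gamma)
        else:
            self._pending = tr

    def q_values(self, obs) -> np.ndarray:
        return self.q[obs]


class ForwardAgent(BaseAgent):
    """Pure model-based baseline: learned model + value-iteration sweeps."""

    name = "forward"

    def __init__(self, n_states: int, n_actions: int, config: AgentConfig, seed=0,
                 gamma_t: float = 0.2):
        super().__init__(n_actions, config, seed)
        self.model = TabularModel(n_states, n_actions, gamma_t=gamma_t)
        self.q = np.zeros((n_states, n_actions))

    def act(self, obs) -> int:
        return select_action(self.q, obs, self.cfg.epsilon, self.rng)

    def observe(self, tr: Transition) -> None:
        tabular_update(self.model, tr.s, tr.a, tr.s_next, tr.r, tr.terminal)

    def end_episode(self) -> None:
        if self.model.trained:
            value_iteration(self.model, self.cfg.gamma, sweeps=1, q=self.q)

    def q_values(self, obs) -> np.ndarray:
        return self.q[obs]


class DynaQAgent(BaseAgent):
    """Classical Dyna-Q: one Q-table plus n model-backed planning updates."""

    name = "dyna-q"

    def __init__(self, n_states: int, n_actions: int, config: AgentConfig, seed=0,
                 gamma_t: float = 0.2):
        super().__init__(n_actions, config, seed)
        self.q = np.zeros((n_states, n_actions))
        self.model = TabularModel(n_states, n_actions, gamma_t=gamma_t)
        self._visited: list[tuple[int, int]] = []
        self._visited_set: set[tuple[int, int]] = set()

    def act(self, obs) -> int:
        return select_action(self.q, obs, self.cfg.epsilon, self.rng)

    def observe(self, tr: Transition) -> None:
        qlearn_update(self.q, tr, self.cfg.lr_mf, self.cfg.gamma)
        tabular_update(self.model, tr.s, tr.a, tr.s_next, tr.r, tr.terminal)
        key = (tr.s, tr.a)
        if key not in self._visited_set:
            self._visited_set.add(key)
            self._visited.append(key)

    def end_episode(self) -> None:
        if not self._visited:
            return
        for _ in range(self.cfg.planning_steps):
            s, a = self._visited[self.rng.integers(len(self._visited))]
            probs, r, _ = tabular_predict(self.model, s, a)
            s_next = int(self.rng.choice(self.model.n_states, p=probs))
            sim = Transition(s, a, r, s_next,
                             terminal=s_next in self.model.terminal_states,
                             simulated=True)
            qlearn_update(self.q, sim, self.cfg.lr_mb, self.cfg.gamma)

    def q_values(self, obs) -> np.ndarray:
        return self.q[obs]


class MetaDynaAgent(BaseAgent):
    """Tabular Meta-Dyna: dual Q-tables, tabular world model, arbitration.

    Per episode (the default cadence): replay the episode through the
    model-free learner and the world model, recording the pre-update
    prediction errors; run ``planning_steps`` mental-simulation rollouts
    that train the model-based Q-table on simulated experience only;
    update the reliabilities and P_MB; act on the P_MB-weighted Q-values.
    ``p_mb_fixed`` pins the arbitration (0 reduces the agent to
    Q-learning, 1 to pure model-based control).
    """

    name = "meta-dyna"

    def __init__(self, n_states: int, n_actions: int, config: AgentConfig, seed=0,
                 gamma_t: float = 0.2):
        super().__init__(n_actions, config, seed)
        self.q_mf = np.zeros((n_states, n_actions))
        self.q_mb = np.zeros((n_states, n_actions))
        self.model = TabularModel(n_states, n_actions, gamma_t=gamma_t)
        self.arb = Arbitrator(
            params=config.arbitration,
            eta=config.eta,
            rpe_max=config.rpe_max,
            dirichlet_prior=config.dirichlet_prior,
            dirichlet_decay=config.dirichlet_decay,
        )
        if config.p_mb_fixed is not None:
            self.arb.state.p_mb = config.p_mb_fixed
        self.rb_mf = ReplayBuffer(config.capacity, "RB_MF")
        self.rb_mb = ReplayBuffer(config.capacity, "RB_MB")
        self._episode: list[Transition] = []
        self._start_state: int | None = None
        self._visited_states: list[int] = []
        self._visited_set: set[int] = set()

    @property
    def p_mb(self) -> float:
        return self.arb.state.p_mb

    def q_values(self, obs) -> np.ndarray:
        return integrate_q(self.q_mb[obs], self.q_mf[obs], self.p_mb)

    def act(self, obs) -> int:
        return select_action(lambda s: self.q_values(s), obs,
                             self.cfg.epsilon, self.rng)

    def start_episode(self, obs) -> None:
        self._episode = []
        self._start_state = obs

    def _process(self, tr: Transition) -> None:
        q_next = 0.0 if tr.terminal else float(self.q_mf[tr.s_next].max())
        tr.rpe = compute_rpe(tr.r, q_next, float(self.q_mf[tr.s, tr.a]),
                             self.cfg.gamma)
        tr.spe = compute_spe_discrete(float(self.model.t_est[tr.s, tr.a, tr.s_next]))
        qlearn_update(self.q_mf, tr, self.cfg.lr_mf, self.cfg.gamma)
        tabular_update(self.model, tr.s, tr.a, tr.s_next, tr.r, tr.terminal)
        self.arb.observe(tr.rpe, tr.spe)

    def observe(self, tr: Transition) -> None:
        self._episode.append(tr)
        self.rb_mf.add(tr)
        self.rb_mb.add(tr)
        if tr.s not in self._visited_set:
            self._visited_set.add(tr.s)
            self._visited_states.append(tr.s)
        if self.cfg.update_mode == "step":
            self._process(tr)

    def end_episode(self) -> None:
        if self.cfg.update_mode == "episode":
            for tr in self._episode:
                self._process(tr)
        if self.model.trained and self.cfg.planning_steps > 0:
            for _ in range(self.cfg.planning_steps):
                # mental simulations launch from a random previously
                # visited state (Dyna convention) for state coverage
                s0 = self._visited_states[
                    self.rng.integers(len(self._visited_states))]
                sims = rollout(self.model, lambda s: self.q_values(s),
                               s0, self.cfg.rollout, self.rng)
                for sim in sims:
                    self.rb_mb.add(sim)
                    qlearn_update(self.q_mb, sim, self.cfg.lr_mb, self.cfg.gamma)
        if self.cfg.p_mb_fixed is None:
            self.arb.update_p_mb()


class HybridArbitrationAgent(BaseAgent):
    """FORWARD (+VI) arbitrated against an on-line MF learner.

    ``mf_style`` selects the model-free component: 'sarsa' or
    'qlearning'.  The arbitration machinery is identical to Meta-Dyna's;
    only the component learners differ (no mental simulation -- the MB
    values come straight from value iteration over the learned model).
    """

    def __init__(self, n_states: int, n_actions: int, config: AgentConfig,
                 seed=0, mf_style: str = "sarsa", gamma_t: float = 0.2):
        super().__init__(n_actions, config, seed)
        if mf_style not in ("sarsa", "qlearning"):
            raise ValueError(f"unknown mf_style {mf_style!r}")
        self.mf_style = mf_style
        self.name = f"forward+{mf_style}"
        self.q_mf = np.zeros((n_states, n_actions))
        self.q_mb = np.zeros((n_states, n_actions))
        self.model = TabularModel(n_states, n_actions, gamma_t=gamma_t)
        self.arb = Arbitrator(
            params=config.arbitration, eta=config.eta, rpe_max=config.rpe_max,
            dirichlet_prior=config.dirichlet_prior,
            dirichlet_decay=config.dirichlet_decay,
        )
        self._pending: Transition | None = None

    @property
    def p_mb(self) -> float:
        return self.arb.state.p_mb

    def q_values(self, obs) -> np.ndarray:
        return integrate_q(self.q_mb[obs], self.q_mf[obs], self.p_mb)

    def start_episode(self, obs) -> None:
        self._pending = None

    def act(self, obs) -> int:
        a = select_action(lambda s: self.q_values(s), obs, self.cfg.epsilon,
                          self.rng)
        if self._pending is not None:
            sarsa_update(self.q_mf, self._pending, a, self.cfg.lr_mf,
                         self.cfg.gamma)
            self._pending = None
        return a

    def observe(self, tr: Transition) -> None:
        q_next = 0.0 if tr.terminal else float(self.q_mf[tr.s_next].max())
        rpe = compute_rpe(tr.r, q_next, float(self.q_mf[tr.s, tr.a]),
                          self.cfg.gamma)
        spe = compute_spe_discrete(float(self.model.t_est[tr.s, tr.a, tr.s_next]))
        if self.mf_style == "qlearning":
            qlearn_update(self.q_mf, tr, self.cfg.lr_mf, self.cfg.gamma)
        elif tr.terminal:
            sarsa_update(self.q_mf, tr, None, self.cfg.lr_mf, self.cfg.gamma)
        else:
            self._pending = tr
        forward_update(self.model, self.q_mb, tr, self.cfg.gamma)
        self.arb.observe(rpe, spe)

    def end_episode(self) -> None:
        self.arb.update_p_mb()


# ---------------------------------------------------------------------------
# Network backends and agents
# ---------------------------------------------------------------------------


class MLPQ:
    """One-hidden-layer ReLU Q-network trained with Adam on squared TD error."""

    def __init__(self, in_dim: int, n_actions: int, hidden: int = 64,
                 lr: float = 5e-3, seed: int | np.random.Generator = 0):
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        self.in_dim, self.n_actions, self.hidden = in_dim, n_actions, hidden
        self.lr = lr
        self.params = {
            "W1": rng.normal(0, np.sqrt(2.0 / in_dim), (hidden, in_dim)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0, np.sqrt(1.0 / hidden), (n_actions, hidden)),
            "b2": np.zeros(n_actions),
        }
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        h = np.maximum(p["W1"] @ x + p["b1"], 0.0)
        return p["W2"] @ h + p["b2"]

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        p = self.params
        H = np.maximum(X @ p["W1"].T + p["b1"], 0.0)
        return H @ p["W2"].T + p["b2"]

    def train_batch(self, X: np.ndarray, actions: np.ndarray,
                    targets: np.ndarray) -> float:
        """One Adam step on 0.5 * mean (Q(s,a) - y)^2 over the batch."""
        p = self.params
        B = len(X)
        H = np.maximum(X @ p["W1"].T + p["b1"], 0.0)
        Q = H @ p["W2"].T + p["b2"]
        qa = Q[np.arange(B), actions]
        err = qa - targets
        loss = 0.5 * float(np.mean(err**2))
        dQ = np.zeros_like(Q)
        dQ[np.arange(B), actions] = err / B
        grads = {
            "W2": dQ.T @ H,
            "b2": dQ.sum(axis=0),
        }
        dH = dQ @ p["W2"]
        dH[H <= 0] = 0.0
        grads["W1"] = dH.T @ X
        grads["b1"] = dH.sum(axis=0)
        self._t += 1
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self._m[k] = b1m * self._m[k] + (1 - b1m) * g
            self._v[k] = b2m * self._v[k] + (1 - b2m) * g**2
            mhat = self._m[k] / (1 - b1m**self._t)
            vhat = self._v[k] / (1 - b2m**self._t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def copy_from(self, other: "MLPQ") -> None:
        for k in self.params:
            self.params[k] = other.params[k].copy()


def _as_vec(obs, encoder: Callable | None) -> np.ndarray:
    return np.asarray(encoder(obs) if encoder is not None else obs, dtype=float)


class DQNAgent(BaseAgent):
    """Deep Q-learning with experience replay and a target network."""

    name = "dqn"

    def __init__(self, obs_dim: int, n_actions: int, config: AgentConfig,
                 seed=0, encoder: Callable | None = None):
        super().__init__(n_actions, config, seed)
        self.encoder = encoder
        self.q = MLPQ(obs_dim, n_actions, config.hidden_size, config.lr_net,
                      self.rng)
        self.target = MLPQ(obs_dim, n_actions, config.hidden_size,
                           config.lr_net, self.rng)
        self.target.copy_from(self.q)
        self.buffer = ReplayBuffer(config.capacity, "RB_MF")
        self._updates = 0

    def q_values(self, obs) -> np.ndarray:
        return self.q.forward(_as_vec(obs, self.encoder))

    def act(self, obs) -> int:
        return select_action(lambda s: self.q_values(s), obs,
                             self.cfg.epsilon, self.rng)

    def observe(self, tr: Transition) -> None:
        vec_tr = Transition(_as_vec(tr.s, self.encoder), tr.a, tr.r,
                            _as_vec(tr.s_next, self.encoder), tr.terminal)
        self.buffer.add(vec_tr)
        if self.cfg.update_mode == "step":
            self._train_batches(1)

    def _train_batches(self, n: int) -> None:
        if len(self.buffer) < self.cfg.batch_size:
            return
        for _ in range(n):
            batch = self.buffer.sample(self.cfg.batch_size, self.rng)
            X = np.stack([t.s for t in batch])
            Xn = np.stack([t.s_next for t in batch])
            acts = np.array([t.a for t in batch])
            rs = np.array([t.r for t in batch])
            terms = np.array([t.terminal for t in batch])
            qn = self.target.forward_batch(Xn).max(axis=1)
            targets = rs + self.cfg.gamma * qn * (~terms)
            self.q.train_batch(X, acts, targets)
            self._updates += 1
            if self._updates % self.cfg.target_sync == 0:
                self.target.copy_from(self.q)

    def end_episode(self) -> None:
        if self.cfg.update_mode == "episode":
            self._train_batches(self.cfg.batches_per_episode)


class DynaQNetAgent(DQNAgent):
    """Network Dyna-Q: DQN plus planning from a recurrent world model."""

    name = "dyna-q"

    def __init__(self, obs_dim: int, n_actions: int, config: AgentConfig,
                 seed=0, encoder: Callable | None = None):
        super().__init__(obs_dim, n_actions, config, seed, encoder)
        self.wm = MDNRNN(obs_dim, n_actions, config.wm_hidden,
                         config.wm_components, config.wm_lr, self.rng)
        self._episode: list[Transition] = []
        self._episodes: deque[list[Transition]] = deque(maxlen=256)
        self._start_obs = None

    def start_episode(self, obs) -> None:
        self._episode = []
        self._start_obs = _as_vec(obs, self.encoder)

    def observe(self, tr: Transition) -> None:
        vec_tr = Transition(_as_vec(tr.s, self.encoder), tr.a, tr.r,
                            _as_vec(tr.s_next, self.encoder), tr.terminal)
        self._episode.append(vec_tr)
        self.buffer.add(vec_tr)
        if self.cfg.update_mode == "step":
            self._train_batches(1)

    def _train_world_model(self) -> None:
        if self._episode:
            self._episodes.append(self._episode)
        if not self._episodes:
            return
        k = min(len(self._episodes), 8)
        idx = self.rng.choice(len(self._episodes), size=k, replace=False)
        self.wm.train_step([self._episodes[i] for i in idx])

    def _plan(self, q_fn: Callable, train_fn: Callable) -> None:
        if self.wm.n_updates < self.cfg.wm_warmup:
            return
        for _ in range(self.cfg.planning_steps):
            sims = rollout(self.wm, q_fn, self._start_obs, self.cfg.rollout,
                           self.rng)
            if sims:
                train_fn(sims)

    def _train_on_sims(self, sims: list[Transition]) -> None:
        X = np.stack([np.asarray(t.s, float) for t in sims])
        Xn = np.stack([np.asarray(t.s_next, float) for t in sims])
        acts = np.array([t.a for t in sims])
        rs = np.array([t.r for t in sims])
        terms = np.array([t.terminal for t in sims])
        qn = self.target.forward_batch(Xn).max(axis=1)
        targets = rs + self.cfg.gamma * qn * (~terms)
        self.q.train_batch(X, acts, targets)

    def end_episode(self) -> None:
        if self.cfg.update_mode == "episode":
            self._train_batches(self.cfg.batches_per_episode)
        self._train_world_model()
        self._plan(lambda s: self.q.forward(np.asarray(s, float)),
                   self._train_on_sims)
        self._episode = []


class MetaDynaNetAgent(BaseAgent):
    """Network Meta-Dyna: dual Q-networks, MDN-RNN world model, arbitration.

    The model-free network trains on real replay; the model-based network
    trains only on rollouts sampled from the world model; Q-values are
    integrated in output space with the arbitrated P_MB.  The SPE comes
    from the world model's mixture prediction (z-score mode), the RPE
    from the model-free TD error.
    """

    name = "meta-dyna"

    def __init__(self, obs_dim: int, n_actions: int, config: AgentConfig,
                 seed=0, encoder: Callable | None = None):
        super().__init__(n_actions, config, seed)
        self.encoder = encoder
        self.q_mf = MLPQ(obs_dim, n_actions, config.hidden_size,
                         config.lr_net, self.rng)
        self.q_mf_target = MLPQ(obs_dim, n_actions, config.hidden_size,
                                config.lr_net, self.rng)
        self.q_mf_target.copy_from(self.q_mf)
        self.q_mb = MLPQ(obs_dim, n_actions, config.hidden_size,
                         config.lr_net, self.rng)
        self.wm = MDNRNN(obs_dim, n_actions, config.wm_hidden,
                         config.wm_components, config.wm_lr, self.rng)
        self.arb = Arbitrator(
            params=config.arbitration, eta=config.eta, rpe_max=config.rpe_max,
            dirichlet_prior=config.dirichlet_prior,
            dirichlet_decay=config.dirichlet_decay,
        )
        if config.p_mb_fixed is not None:
            self.arb.state.p_mb = config.p_mb_fixed
        self.rb_mf = ReplayBuffer(config.capacity, "RB_MF")
        self.rb_mb = ReplayBuffer(config.capacity, "RB_MB")
        self._episode: list[Transition] = []
        self._episodes: deque[list[Transition]] = deque(maxlen=256)
        self._start_obs = None
        self._updates = 0

    @property
    def p_mb(self) -> float:
        return self.arb.state.p_mb

    def q_values(self, obs) -> np.ndarray:
        x = _as_vec(obs, self.encoder)
        return integrate_q(self.q_mb.forward(x), self.q_mf.forward(x), self.p_mb)

    def act(self, obs) -> int:
        return select_action(lambda s: self.q_values(s), obs,
                             self.cfg.epsilon, self.rng)

    def start_episode(self, obs) -> None:
        self._episode = []
        self._start_obs = _as_vec(obs, self.encoder)

    def observe(self, tr: Transition) -> None:
        vec_tr = Transition(_as_vec(tr.s, self.encoder), tr.a, tr.r,
                            _as_vec(tr.s_next, self.encoder), tr.terminal)
        self._episode.append(vec_tr)
        self.rb_mf.add(vec_tr)
        self.rb_mb.add(vec_tr)
        if self.cfg.update_mode == "step":
            self._train_q_mf(1)

    def _prediction_errors(self) -> None:
        """Annotate the episode with pre-training RPE/SPE and feed trackers."""
        h = self.wm.init_hidden()
        for tr in self._episode:
            q_sa = float(self.q_mf.forward(tr.s)[tr.a])
            q_next = 0.0 if tr.terminal else float(self.q_mf.forward(tr.s_next).max())
            tr.rpe = compute_rpe(tr.r, q_next, q_sa, self.cfg.gamma)
            if self.wm.trained:
                h, pred = self.wm.step(h, tr.s, tr.a, tr.spe, tr.rpe)
                tr.spe = compute_spe_from_gmm(np.asarray(tr.s_next, float), pred)
            else:
                tr.spe = 0.0
            self.arb.observe(tr.rpe, tr.spe)

    def _train_q_mf(self, n_batches: int | None = None) -> None:
        if len(self.rb_mf) < self.cfg.batch_size:
            return
        for _ in range(n_batches or self.cfg.batches_per_episode):
            batch = self.rb_mf.sample(self.cfg.batch_size, self.rng)
            X = np.stack([t.s for t in batch])
            Xn = np.stack([t.s_next for t in batch])
            acts = np.array([t.a for t in batch])
            rs = np.array([t.r for t in batch])
            terms = np.array([t.terminal for t in batch])
            qn = self.q_mf_target.forward_batch(Xn).max(axis=1)
            targets = rs + self.cfg.gamma * qn * (~terms)
            self.q_mf.train_batch(X, acts, targets)
            self._updates += 1
            if self._updates % self.cfg.target_sync == 0:
                self.q_mf_target.copy_from(self.q_mf)

    def _train_world_model(self) -> None:
        if self._episode:
            self._episodes.append(list(self._episode))
        if not self._episodes:
            return
        pool = self._episodes
        if self.cfg.wm_on_real_only:
            pool = [[t for t in ep if not t.simulated] for ep in pool]
            pool = [ep for ep in pool if ep]
        k = min(len(pool), 8)
        idx = self.rng.choice(len(pool), size=k, replace=False)
        self.wm.train_step([pool[i] for i in idx])

    def _plan(self) -> None:
        if not self.wm.trained:
            return
        for _ in range(self.cfg.planning_steps):
            sims = rollout(self.wm, lambda s: self.q_values(s),
                           self._start_obs, self.cfg.rollout, self.rng)
            if not sims:
                continue
            for sim in sims:
                self.rb_mb.add(sim)
            X = np.stack([np.asarray(t.s, float) for t in sims])
            Xn = np.stack([np.asarray(t.s_next, float) for t in sims])
            acts = np.array([t.a for t in sims])
            rs = np.array([t.r for t in sims])
            terms = np.array([t.terminal for t in sims])
            qn = self.q_mb.forward_batch(Xn).max(axis=1)
            targets = rs + self.cfg.gamma * qn * (~terms)
            self.q_mb.train_batch(X, acts, targets)

    def end_episode(self) -> None:
        self._prediction_errors()
        if self.cfg.update_mode == "episode":
            self._train_q_mf()
        self._train_world_model()
        if self.wm.n_updates >= self.cfg.wm_warmup:
            self._plan()
        if self.cfg.p_mb_fixed is None:
            self.arb.update_p_mb()
        self._episode = []


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

AGENT_REGISTRY = {
    "meta-dyna": (MetaDynaAgent, MetaDynaNetAgent),
    "dyna-q": (DynaQAgent, DynaQNetAgent),
    "q-learning": (QLearningAgent, DQNAgent),
    "sarsa": (SarsaAgent, None),
    "forward": (ForwardAgent, None),
    "dqn": (None, DQNAgent),
    "forward+sarsa": (HybridArbitrationAgent, None),
    "forward+qlearning": (HybridArbitrationAgent, None),
}


def make_agent(
    name: str,
    *,
    n_actions: int,
    n_states: int | None = None,
    obs_dim: int | None = None,
    backend: Literal["table", "network"] = "table",
    config: AgentConfig | None = None,
    seed: int = 0,
    encoder: Callable | None = None,
):
    """Instantiate a registered agent for a discrete or vector state space."""
    if name not in AGENT_REGISTRY:
        raise KeyError(f"unknown agent {name!r}; known: {sorted(AGENT_REGISTRY)}")
    tab_cls, net_cls = AGENT_REGISTRY[name]
    config = config if config is not None else AgentConfig()
    if backend == "table":
        if tab_cls is None:
            raise ValueError(f"agent {name!r} has no tabular backend")
        if n_states is None:
            raise ValueError("tabular agents need n_states")
        if name.startswith("forward+"):
            return tab_cls(n_states, n_actions, config, seed,
                           mf_style=name.split("+")[1])
        return tab_cls(n_states, n_actions, config, seed)
    if net_cls is None:
        raise ValueError(f"agent {name!r} has no network backend")
    if obs_dim is None:
        raise ValueError("network agents need obs_dim")
    return net_cls(obs_dim, n_actions, config, seed, encoder=encoder)
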