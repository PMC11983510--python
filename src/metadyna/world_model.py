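"""World models and mental simulation.

Two interchangeable environment models back the model-based system:

* :class:`TabularModel` -- per-(s, a, s') transition probabilities learned
  with a step-size update (observed successor pulled toward 1, the rest
  shrunk, row renormalised) plus a recency-weighted expected reward per
  (s, a).  Suited to the discrete tasks.
* :class:`MDNRNN` -- a single-layer gated recurrent network whose output
  layer parameterises a diagonal Gaussian mixture over the next state,
  a Gaussian over the reward, and a Bernoulli over episode termination.
  The network consumes (state, action, SPE, RPE) tuples each step and is
  trained by backpropagation through time on episode-ordered sequences.
  All gradients are derived by hand and verified against numerical
  differentiation in the test suite.

:func:`rollout` generates simulated transitions ("mental simulation")
from either model by chaining sampled successors under an epsilon-greedy
policy on the integrated Q-function; simulated transitions are tagged so
they can only ever feed the model-based replay buffer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Transition",
    "TabularModel",
    "GMMPrediction",
    "MDNRNN",
    "RolloutConfig",
    "tabular_update",
    "tabular_predict",
    "mdn_nll",
    "rollout",
    "train_world_model",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class Transition:
    """One (s, a, r, s') step, real or simulated.

    ``spe``/``rpe`` carry the prediction errors attached by the agent at
    storage time; the recurrent world model consumes them as inputs.
    """

    s: object
    a: int
    r: float
    s_next: object
    terminal: bool = False
    simulated: bool = False
    spe: float = 0.0
    rpe: float = 0.0


# ---------------------------------------------------------------------------
# Tabular model
# ---------------------------------------------------------------------------


class TabularModel:
    """Count-backed transition/reward model over discrete states.

    ``gamma_t`` is the model step-size: the observed successor's
    probability moves toward 1 by ``gamma_t * (1 - p)`` while all other
    successors shrink by the factor ``(1 - gamma_t)``; rows stay on the
    simplex.  The expected reward per (s, a) follows a recency-weighted
    running mean with the same step-size, so the model tracks
    non-stationary reward schedules.
    """

    def __init__(self, n_states: int, n_actions: int, gamma_t: float = 0.2):
        if not (0.0 <= gamma_t <= 1.0):
            raise ValueError(f"gamma_t must lie in [0, 1], got {gamma_t}")
        self.n_states = n_states
        self.n_actions = n_actions
        self.gamma_t = gamma_t
        self.t_est = np.full((n_states, n_actions, n_states), 1.0 / n_states)
        self.r_est = np.zeros((n_states, n_actions))
        self.visit_counts = np.zeros((n_states, n_actions, n_states), dtype=np.int64)
        self.terminal_states: set[int] = set()

    @property
    def trained(self) -> bool:
        return bool(self.visit_counts.sum() > 0)

    def visited(self, s: int, a: int) -> bool:
        return bool(self.visit_counts[s, a].sum() > 0)


def tabular_update(
    model: TabularModel,
    s: int,
    a: int,
    s_observed: int,
    r: float = 0.0,
    terminal: bool = False,
) -> TabularModel:
    """Apply one transition to the tabular model (mutates and returns it)."""
    S, A = model.n_states, model.n_actions
    if not (0 <= s < S and 0 <= s_observed < S):
        raise IndexError(f"state index out of range: {s} -> {s_observed}")
    if not (0 <= a < A):
        raise IndexError(f"action index out of range: {a}")
    g = model.gamma_t
    row = model.t_est[s, a]
    matched = row[s_observed]
    row *= 1.0 - g
    row[s_observed] = matched + g * (1.0 - matched)
    row /= row.sum()
    model.visit_counts[s, a, s_observed] += 1
    model.r_est[s, a] += g * (r - model.r_est[s, a])
    if terminal:
        model.terminal_states.add(s_observed)
    return model


def tabular_predict(model: TabularModel, s: int, a: int):
    """Return (successor distribution, expected reward, cold flag)."""
    if not (0 <= s < model.n_states and 0 <= a < model.n_actions):
        raise IndexError(f"state/action index out of range: ({s}, {a})")
    if not model.visited(s, a):
        return np.full(model.n_states, 1.0 / model.n_states), 0.0, True
    return model.t_est[s, a].copy(), float(model.r_est[s, a]), False


# ---------------------------------------------------------------------------
# Gaussian mixture predictions
# ---------------------------------------------------------------------------


@dataclass
class GMMPrediction:
    """Mixture parameters for the next state plus a Gaussian reward head."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, D)
    scales: np.ndarray  # (K, D), strictly positive
    reward_mean: float = 0.0
    reward_scale: float = 1.0
    terminal_prob: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.scales = np.atleast_2d(np.asarray(self.scales, dtype=float))
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        if np.any(self.scales <= 0) or self.reward_scale <= 0:
            raise ValueError("scales must be strictly positive")
        if self.means.shape != self.scales.shape:
            raise ValueError("means and scales must have matching shapes")


def mdn_nll(
    prediction: GMMPrediction,
    target_state: np.ndarray,
    target_reward: float | None = None,
) -> float:
    """Negative log-likelihood of a target under a diagonal Gaussian mixture.

    The reward term (Gaussian NLL under the reward head) is added when
    ``target_reward`` is given.
    """
    x = np.asarray(target_state, dtype=float)
    if x.shape != prediction.means.shape[1:]:
        raise ValueError(
            f"target shape {x.shape} does not match mean shape "
            f"{prediction.means.shape[1:]}"
        )
    z = (x - prediction.means) / prediction.scales
    log_comp = np.sum(
        -0.5 * z**2 - np.log(prediction.scales) - 0.5 * _LOG_2PI, axis=1
    )
    with np.errstate(divide="ignore"):
        log_w = np.log(prediction.weights)
    from scipy.special import logsumexp

    nll = -float(logsumexp(log_w + log_comp))
    if target_reward is not None:
        zr = (target_reward - prediction.reward_mean) / prediction.reward_scale
        nll += 0.5 * zr**2 + math.log(prediction.reward_scale) + 0.5 * _LOG_2PI
    return nll


# ---------------------------------------------------------------------------
# MDN-RNN
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class MDNRNN:
    """Single-layer gated recurrent mixture-density world model.

    Input per step: ``concat(state, one_hot(action), spe, rpe)``.
    Output heads: mixture logits (K), component means and log-scales
    (K x D), reward mean and log-scale, terminal logit.  Trained with
    Adam on the summed negative log-likelihood plus the terminal-head
    cross-entropy, backpropagated through time over whole episodes.

    With ``predict_delta`` (default) the mixture is fitted to the state
    *change* s' - s, which is the easier regression target for smooth
    dynamics; emitted :class:`GMMPrediction` means are always on the
    absolute next-state scale, so the external contract is unchanged.
    """

    LOGSIG_MIN, LOGSIG_MAX = -4.0, 4.0

    def __init__(
        self,
        state_dim: int,
        n_actions: int,
        hidden_size: int = 128,
        n_components: int = 5,
        lr: float = 3e-3,
        seed: int | np.random.Generator = 0,
        predict_delta: bool = True,
    ):
        self.predict_delta = predict_delta
        self.state_dim = state_dim
        self.n_actions = n_actions
        self.hidden_size = hidden_size
        self.n_components = n_components
        self.input_dim = state_dim + n_actions + 2
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        H, I, K, D = hidden_size, self.input_dim, n_components, state_dim

        def mat(rows, cols, scale=None):
            scale = scale if scale is not None else 1.0 / math.sqrt(cols)
            return rng.normal(0.0, scale, size=(rows, cols))

        p = {}
        for gate in ("z", "r", "h"):
            p[f"W{gate}"] = mat(H, I)
            p[f"U{gate}"] = mat(H, H)
            p[f"b{gate}"] = np.zeros(H)
        p["Wpi"], p["bpi"] = mat(K, H, 0.01), np.zeros(K)
        p["Wmu"], p["bmu"] = mat(K * D, H, 0.1), np.zeros(K * D)
        p["Wls"], p["bls"] = mat(K * D, H, 0.01), np.zeros(K * D)
        p["Wrm"], p["brm"] = mat(1, H, 0.1), np.zeros(1)
        p["Wrs"], p["brs"] = mat(1, H, 0.01), np.zeros(1)
        p["Wt"], p["bt"] = mat(1, H, 0.1), np.zeros(1)
        self.params = p
        self.lr = lr
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0
        self.n_updates = 0

    # -- forward -----------------------------------------------------------

    @property
    def trained(self) -> bool:
        return self.n_updates > 0

    def init_hidden(self) -> np.ndarray:
        return np.zeros(self.hidden_size)

    def make_input(
        self, state: np.ndarray, action: int, spe: float = 0.0, rpe: float = 0.0
    ) -> np.ndarray:
        onehot = np.zeros(self.n_actions)
        onehot[action] = 1.0
        return np.concatenate([np.asarray(state, float), onehot, [spe, rpe]])

    def _gru_step(self, h, x):
        p = self.params
        az = p["Wz"] @ x + p["Uz"] @ h + p["bz"]
        ar = p["Wr"] @ x + p["Ur"] @ h + p["br"]
        z, r = _sigmoid(az), _sigmoid(ar)
        ah = p["Wh"] @ x + p["Uh"] @ (r * h) + p["bh"]
        hc = np.tanh(ah)
        h_new = (1.0 - z) * h + z * hc
        cache = (h, x, z, r, hc)
        return h_new, cache

    def _heads(self, h) -> dict:
        p = self.params
        K, D = self.n_components, self.state_dim
        return {
            "pi_logits": p["Wpi"] @ h + p["bpi"],
            "mu": (p["Wmu"] @ h + p["bmu"]).reshape(K, D),
            "log_sigma": np.clip(
                (p["Wls"] @ h + p["bls"]).reshape(K, D),
                self.LOGSIG_MIN,
                self.LOGSIG_MAX,
            ),
            "rm": float((p["Wrm"] @ h + p["brm"])[0]),
            "rls": float(
                np.clip((p["Wrs"] @ h + p["brs"])[0], self.LOGSIG_MIN, self.LOGSIG_MAX)
            ),
            "tl": float((p["Wt"] @ h + p["bt"])[0]),
        }

    def step(self, h: np.ndarray, state, action: int, spe: float = 0.0,
             rpe: float = 0.0):
        """Advance the hidden state one step; return (h', GMMPrediction)."""
        x = self.make_input(state, action, spe, rpe)
        h_new, _ = self._gru_step(h, x)
        out = self._heads(h_new)
        logits = out["pi_logits"] - out["pi_logits"].max()
        w = np.exp(logits)
        w /= w.sum()
        mu = out["mu"]
        if self.predict_delta:
            mu = mu + np.asarray(state, float)[None, :]
        pred = GMMPrediction(
            weights=w,
            means=mu,
            scales=np.exp(out["log_sigma"]),
            reward_mean=out["rm"],
            reward_scale=float(np.exp(out["rls"])),
            terminal_prob=float(_sigmoid(np.array([out["tl"]]))[0]),
        )
        return h_new, pred

    def sample(self, pred: GMMPrediction, rng: np.random.Generator,
               temperature: float = 1.0):
        """Sample (next_state, reward, terminal) from a prediction."""
        logits = np.log(pred.weights + 1e-12) / temperature
        logits -= logits.max()
        w = np.exp(logits)
        w /= w.sum()
        k = rng.choice(len(w), p=w)
        sigma = pred.scales[k] * math.sqrt(temperature)
        s_next = pred.means[k] + sigma * rng.standard_normal(self.state_dim)
        # rewards enter planning as the head's prediction, not a draw:
        # sampling them would inject the head's residual scale as pure
        # noise into every simulated Bellman target
        terminal = bool(rng.random() < pred.terminal_prob)
        return s_next, float(pred.reward_mean), terminal

    # -- training ----------------------------------------------------------

    def loss_and_grads(self, episodes: Sequence[Sequence[Transition]]):
        """Mean per-step NLL (+ terminal BCE) and its parameter gradients."""
        p = self.params
        K, D, H = self.n_components, self.state_dim, self.hidden_size
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        total_loss, total_steps = 0.0, 0

        for episode in episodes:
            h = self.init_hidden()
            caches, dh_chain = [], []
            # forward
            for tr in episode:
                x = self.make_input(np.asarray(tr.s, float), tr.a, tr.spe, tr.rpe)
                h, gru_cache = self._gru_step(h, x)
                out = self._heads(h)
                target = np.asarray(tr.s_next, float)
                if self.predict_delta:
                    target = target - np.asarray(tr.s, float)

                mu, ls = out["mu"], out["log_sigma"]
                sig = np.exp(ls)
                z = (target - mu) / sig
                log_comp = np.sum(-0.5 * z**2 - ls - 0.5 * _LOG_2PI, axis=1)
                logits = out["pi_logits"]
                log_pi = logits - _logsumexp(logits)
                joint = log_pi + log_comp
                lse = _logsumexp(joint)
                resp = np.exp(joint - lse)  # responsibilities w_k
                nll_state = -lse

                zr = (tr.r - out["rm"]) / math.exp(out["rls"])
                nll_reward = 0.5 * zr**2 + out["rls"] + 0.5 * _LOG_2PI

                t_prob = _sigmoid(np.array([out["tl"]]))[0]
                y = 1.0 if tr.terminal else 0.0
                bce = -(y * math.log(t_prob + 1e-12)
                        + (1 - y) * math.log(1 - t_prob + 1e-12))

                total_loss += nll_state + nll_reward + bce
                total_steps += 1

                # gradients of this step's loss wrt head pre-activations
                d_logits = np.exp(log_pi) - resp  # (K,)
                d_mu = -(resp[:, None]) * z / sig  # (K, D)
                d_ls = resp[:, None] * (1.0 - z**2)  # (K, D)
                clip_mask = (ls > self.LOGSIG_MIN) & (ls < self.LOGSIG_MAX)
                d_ls = d_ls * clip_mask
                d_rm = -zr / math.exp(out["rls"])
                d_rls = 1.0 - zr**2
                if not (self.LOGSIG_MIN < out["rls"] < self.LOGSIG_MAX):
                    d_rls = 0.0
                d_tl = t_prob - y

                dh = (
                    p["Wpi"].T @ d_logits
                    + p["Wmu"].T @ d_mu.reshape(K * D)
                    + p["Wls"].T @ d_ls.reshape(K * D)
                    + p["Wrm"].T @ np.array([d_rm])
                    + p["Wrs"].T @ np.array([d_rls])
                    + p["Wt"].T @ np.array([d_tl])
                )
                grads["Wpi"] += np.outer(d_logits, h)
                grads["bpi"] += d_logits
                grads["Wmu"] += np.outer(d_mu.reshape(K * D), h)
                grads["bmu"] += d_mu.reshape(K * D)
                grads["Wls"] += np.outer(d_ls.reshape(K * D), h)
                grads["bls"] += d_ls.reshape(K * D)
                grads["Wrm"] += d_rm * h[None, :]
                grads["brm"] += [d_rm]
                grads["Wrs"] += d_rls * h[None, :]
                grads["brs"] += [d_rls]
                grads["Wt"] += d_tl * h[None, :]
                grads["bt"] += [d_tl]
                caches.append(gru_cache)
                dh_chain.append(dh)

            # backward through time
            dh_next = np.zeros(H)
            for t in range(len(caches) - 1, -1, -1):
                h_prev, x, z, r, hc = caches[t]
                dh = dh_chain[t] + dh_next
                dz = dh * (hc - h_prev)
                dhc = dh * z
                dh_prev = dh * (1.0 - z)
                dah = dhc * (1.0 - hc**2)
                grads["Wh"] += np.outer(dah, x)
                grads["Uh"] += np.outer(dah, r * h_prev)
                grads["bh"] += dah
                drh = p["Uh"].T @ dah
                dr = drh * h_prev
                dh_prev += drh * r
                dar = dr * r * (1.0 - r)
                grads["Wr"] += np.outer(dar, x)
                grads["Ur"] += np.outer(dar, h_prev)
                grads["br"] += dar
                daz = dz * z * (1.0 - z)
                grads["Wz"] += np.outer(daz, x)
                grads["Uz"] += np.outer(daz, h_prev)
                grads["bz"] += daz
                dh_next = dh_prev + p["Ur"].T @ dar + p["Uz"].T @ daz

        n = max(total_steps, 1)
        for k in grads:
            grads[k] /= n
        return total_loss / n, grads

    def save(self, path: str) -> None:
        """Write parameters to ``path`` (.npz) with a JSON config sidecar."""
        import json
        from pathlib import Path

        np.savez(path, **self.params)
        cfg = {
            "state_dim": self.state_dim,
            "n_actions": self.n_actions,
            "hidden_size": self.hidden_size,
            "n_components": self.n_components,
            "lr": self.lr,
            "predict_delta": self.predict_delta,
            "n_updates": self.n_updates,
        }
        Path(str(path) + ".json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, path: str) -> "MDNRNN":
        import json
        from pathlib import Path

        cfg = json.loads(Path(str(path) + ".json").read_text())
        n_updates = cfg.pop("n_updates")
        model = cls(**cfg)
        with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
            model.params = {k: data[k] for k in data.files}
        model.n_updates = n_updates
        return model

    def train_step(self, episodes: Sequence[Sequence[Transition]]) -> float:
        """One Adam step on a batch of episodes; returns the batch loss."""
        loss, grads = self.loss_and_grads(episodes)
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            np.clip(g, -5.0, 5.0, out=g)
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g**2
            mhat = self._adam_m[k] / (1 - b1**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2**self._adam_t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
        self.n_updates += 1
        return loss


def _logsumexp(x):
    m = x.max()
    return m + math.log(np.sum(np.exp(x - m)))


# ---------------------------------------------------------------------------
# Rollouts and training drivers
# ---------------------------------------------------------------------------


@dataclass
class RolloutConfig:
    """Mental-simulation settings.

    ``n_steps`` caps the number of simulated transitions per rollout,
    ``horizon`` the chain depth; the chain stops early at a predicted
    terminal.  ``state_projector`` optionally snaps sampled continuous
    states onto the task's valid state set (e.g. the nearest one-hot for
    categorical observations).
    """

    n_steps: int = 10
    temperature: float = 1.0
    horizon: int = 10
    # exploration inside mental simulation is cheap, so it is kept broader
    # than the behavioural epsilon to refresh rarely-taken actions
    epsilon: float = 0.3
    state_projector: Callable | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


def _epsilon_greedy(q_vals: np.ndarray, epsilon: float, rng: np.random.Generator):
    if rng.random() < epsilon:
        return int(rng.integers(len(q_vals)))
    best = np.flatnonzero(q_vals == q_vals.max())
    return int(best[rng.integers(len(best))])


def rollout(
    model,
    q_integrated: Callable,
    s0,
    cfg: RolloutConfig,
    rng: np.random.Generator,
) -> list[Transition]:
    """Simulate up to ``cfg.n_steps`` transitions from ``s0`` using the model.

    Actions are epsilon-greedy on ``q_integrated(state)``; successors are
    sampled from the model (categorical for tabular, tempered mixture
    sampling for the network).  A cold (never-trained) model yields an
    empty list -- simulated experience is never fabricated from an unfit
    model.  Every transition is tagged ``simulated=True``.
    """
    if not model.trained:
        return []
    out: list[Transition] = []
    if isinstance(model, TabularModel):
        s = int(s0)
        for _ in range(min(cfg.n_steps, cfg.horizon)):
            a = _epsilon_greedy(np.asarray(q_integrated(s), float), cfg.epsilon, rng)
            probs, r, _cold = tabular_predict(model, s, a)
            s_next = int(rng.choice(model.n_states, p=probs))
            terminal = s_next in model.terminal_states
            out.append(Transition(s, a, r, s_next, terminal, simulated=True))
            if terminal:
                break
            s = s_next
        return out

    # recurrent network model
    h = model.init_hidden()
    s = np.asarray(s0, float)
    for _ in range(min(cfg.n_steps, cfg.horizon)):
        a = _epsilon_greedy(np.asarray(q_integrated(s), float), cfg.epsilon, rng)
        h, pred = model.step(h, s, a)
        s_next, r, terminal = model.sample(pred, rng, cfg.temperature)
        if cfg.state_projector is not None:
            s_next = cfg.state_projector(s_next)
        out.append(Transition(s.copy(), a, r, s_next, terminal, simulated=True))
        if terminal:
            break
        s = np.asarray(s_next, float)
    return out


def split_episodes(buffer: Sequence[Transition]) -> list[list[Transition]]:
    """Split a transition buffer into episode-ordered sequences.

    Episodes end at terminal transitions.  Within an episode each
    transition's successor must be the next transition's state; shuffled
    sequences are rejected (the recurrent model's training contract).
    """
    episodes, current = [], []
    for tr in buffer:
        if current:
            prev = current[-1].s_next
            same = (
                np.array_equal(np.asarray(prev, float), np.asarray(tr.s, float))
                if not np.isscalar(prev)
                else prev == tr.s
            )
            if not same:
                raise ValueError(
                    "buffer is not episode-ordered: transition chain broken"
                )
        current.append(tr)
        if tr.terminal:
            episodes.append(current)
            current = []
    if current:
        episodes.append(current)
    return episodes


def train_world_model(
    model,
    buffer: Sequence[Transition],
    epochs: int = 1,
    rng: np.random.Generator | None = None,
    batch_episodes: int = 16,
) -> list[float]:
    """Fit a world model to a buffer of real experience; returns a loss trace.

    Tabular models replay the step-size update over the buffer (loss trace
    is empty).  The recurrent model takes ``epochs`` passes of minibatch
    Adam steps over episode-ordered sequences.
    """
    if len(buffer) == 0:
        raise ValueError("cannot train a world model on an empty buffer")
    if isinstance(model, TabularModel):
        for tr in buffer:
            tabular_update(model, tr.s, tr.a, tr.s_next, tr.r, tr.terminal)
        return []
    rng = rng if rng is not None else np.random.default_rng(0)
    episodes = split_episodes(buffer)
    trace = []
    for _ in range(epochs):
        order = rng.permutation(len(episodes))
        for start in range(0, len(order), batch_episodes):
            batch = [episodes[i] for i in order[start:start + batch_episodes]]
            trace.append(model.train_step(batch))
    return trace
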