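"""Arbitration between model-based and model-free control.

The meta-controller tracks the reliability of the two learning systems
through their characteristic prediction errors -- the reward prediction
error (RPE) for the model-free learner and the state prediction error
(SPE) for the model-based learner -- and evolves the probability of
model-based control ``P_MB`` with a pair of reliability-gated transition
rates.  The behavioural value function is the ``P_MB``-weighted convex
combination of the two systems' Q-values.

Conventions
-----------
* ``Rel_MF`` follows a Pearce--Hall associability: a recency-weighted
  mean of |RPE| mapped linearly onto [0, 1] (high associability = low
  reliability).
* ``Rel_MB`` is the posterior mean of the "zero prediction error"
  category of a Dirichlet over SPE categories {negative, zero, positive},
  with optional exponential forgetting of the pseudo-counts so the
  estimate can follow regime changes.
* ``P_MB`` dynamics: ``p' = p + alpha*(1-p) - beta*p`` with
  ``alpha = A_alpha / (1 + exp(B_alpha * Rel_MF))`` (a *less* reliable
  model-free system pushes control toward the model-based one) and
  symmetrically for ``beta``.  With the gains in (0, 1] the update can
  never leave the unit interval; values are clamped defensively anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ArbitrationParams",
    "PearceHallTracker",
    "DirichletTracker",
    "ArbitrationState",
    "Arbitrator",
    "compute_rpe",
    "compute_spe_discrete",
    "compute_spe_from_gmm",
    "classify_spe",
    "update_rel_mf",
    "update_rel_mb",
    "update_p_mb",
    "integrate_q",
]

SpeCategory = Literal["negative", "zero", "positive"]
_CATEGORY_INDEX = {"negative": 0, "zero": 1, "positive": 2}


@dataclass
class ArbitrationParams:
    """Rate parameters of the P_MB dynamics.

    A_alpha, A_beta : gains of the MF->MB / MB->MF transition rates,
        must lie in (0, 1] so P_MB cannot leave [0, 1].
    B_alpha, B_beta : slopes on Rel_MF / Rel_MB (>= 0 gives the
        intended "more reliable rival -> smaller escape rate" direction).
    omega : half-width of the zero band used to categorise SPEs.
    gamma : MDP discount factor used for the RPE.
    """

    A_alpha: float = 0.5
    B_alpha: float = 2.0
    A_beta: float = 0.5
    # Rel_MB is a calibrated zero-SPE frequency, so the MB->MF escape rate
    # can be steeply gated on it; Rel_MF's scale depends on the reward
    # variance (via rpe_max), so its slope is kept shallow.
    B_beta: float = 5.0
    omega: float = 0.25
    gamma: float = 0.9

    def __post_init__(self) -> None:
        for name in ("A_alpha", "A_beta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")


@dataclass
class PearceHallTracker:
    """Running associability of the model-free system.

    ``assoc`` tracks a recency-weighted mean of |RPE|; reliability is
    ``clamp(1 - assoc / rpe_max, 0, 1)``.
    """

    assoc: float = 0.0
    eta: float = 0.2
    rpe_max: float = 1.0

    def __post_init__(self) -> None:
        if self.rpe_max <= 0:
            raise ValueError(f"rpe_max must be > 0, got {self.rpe_max}")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError(f"eta must lie in (0, 1], got {self.eta}")

    @property
    def reliability(self) -> float:
        return float(np.clip(1.0 - self.assoc / self.rpe_max, 0.0, 1.0))


@dataclass
class DirichletTracker:
    """Dirichlet pseudo-counts over SPE categories (negative, zero, positive).

    ``decay`` applies exponential forgetting to the counts before each
    increment; ``decay=1.0`` is the pure conjugate update whose zero-category
    posterior mean converges to the empirical zero-SPE frequency.
    """

    counts: np.ndarray = field(default_factory=lambda: np.zeros(3))
    prior: float = 1.0
    decay: float = 0.95
    variance_penalty: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (3,) or np.any(self.counts < 0):
            raise ValueError("counts must be three non-negative numbers")
        if self.prior <= 0:
            raise ValueError(f"prior must be > 0, got {self.prior}")
        if not (0.0 < self.decay <= 1.0):
            raise ValueError(f"decay must lie in (0, 1], got {self.decay}")

    def posterior(self) -> np.ndarray:
        """Posterior category means E(Dir_i); sums to 1."""
        conc = self.counts + self.prior
        return conc / conc.sum()

    @property
    def reliability(self) -> float:
        conc = self.counts + self.prior
        total = conc.sum()
        mean_zero = conc[1] / total
        if not self.variance_penalty:
            return float(mean_zero)
        var_zero = conc[1] * (total - conc[1]) / (total**2 * (total + 1.0))
        return float(np.clip(mean_zero - math.sqrt(var_zero), 0.0, 1.0))


@dataclass
class ArbitrationState:
    """Live meta-control quantities, all kept in [0, 1]."""

    rel_mf: float = 1.0
    rel_mb: float = 1.0 / 3.0
    p_mb: float = 0.5


def compute_rpe(r: float, q_next: float, q_curr: float, gamma: float) -> float:
    """Temporal-difference reward prediction error r + gamma*q_next - q_curr."""
    if not (0.0 <= gamma < 1.0):
        raise ValueError(f"gamma must lie in [0, 1), got {gamma}")
    return r + gamma * q_next - q_curr


def compute_spe_discrete(t_val: float) -> float:
    """State prediction error 1 - T(s, a, s') for a discrete transition model."""
    if not (0.0 <= t_val <= 1.0):
        raise ValueError(f"transition probability must lie in [0, 1], got {t_val}")
    return 1.0 - t_val


def compute_spe_from_gmm(
    observation: np.ndarray,
    prediction: "GMMPrediction",
    mode: Literal["zscore", "mu_over_sigma"] = "zscore",
) -> float:
    """State prediction error from the world model's Gaussian mixture.

    ``zscore`` (default): absolute z-score of the observation under the
    highest-weight component, averaged over state dimensions -- zero for a
    perfect prediction, growing with surprise.  ``mu_over_sigma``: the
    literal ratio mu/sigma of that component (averaged over dimensions),
    kept as an alternative reading of the mixture-based error.
    """
    observation = np.asarray(observation, dtype=float)
    k_star = int(np.argmax(prediction.weights))
    mu = np.asarray(prediction.means[k_star], dtype=float)
    sigma = np.asarray(prediction.scales[k_star], dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("component scales must be strictly positive")
    if mode == "mu_over_sigma":
        return float(np.mean(mu / sigma))
    if observation.shape != mu.shape:
        raise ValueError(
            f"observation shape {observation.shape} does not match "
            f"prediction mean shape {mu.shape}"
        )
    return float(np.mean(np.abs(observation - mu) / sigma))


def classify_spe(spe: float, omega: float) -> SpeCategory:
    """Categorise a prediction error against the symmetric zero band |PE| <= omega."""
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    if spe > omega:
        return "positive"
    if spe < -omega:
        return "negative"
    return "zero"


def update_rel_mf(tracker: PearceHallTracker, rpe: float) -> float:
    """Advance the Pearce--Hall associability with |rpe|; return Rel_MF."""
    tracker.assoc = (1.0 - tracker.eta) * tracker.assoc + tracker.eta * abs(rpe)
    return tracker.reliability


def update_rel_mb(tracker: DirichletTracker, category: SpeCategory) -> float:
    """Record an SPE category event; return the zero-category posterior mean."""
    idx = _CATEGORY_INDEX[category]
    tracker.counts *= tracker.decay
    tracker.counts[idx] += 1.0
    return tracker.reliability


def update_p_mb(state: ArbitrationState, params: ArbitrationParams) -> float:
    """One step of the P_MB dynamics; mutates and returns state.p_mb."""
    alpha = params.A_alpha / (1.0 + math.exp(params.B_alpha * state.rel_mf))
    beta = params.A_beta / (1.0 + math.exp(params.B_beta * state.rel_mb))
    p = state.p_mb + alpha * (1.0 - state.p_mb) - beta * state.p_mb
    state.p_mb = float(np.clip(p, 0.0, 1.0))
    return state.p_mb


def integrate_q(q_mb, q_mf, p_mb: float):
    """Convex combination p_mb * Q_MB + (1 - p_mb) * Q_MF (elementwise)."""
    if not (0.0 <= p_mb <= 1.0):
        raise ValueError(f"p_mb must lie in [0, 1], got {p_mb}")
    return p_mb * np.asarray(q_mb, dtype=float) + (1.0 - p_mb) * np.asarray(
        q_mf, dtype=float
    )


class Arbitrator:
    """Stateful convenience wrapper used by the agents.

    Feeds each (RPE, SPE) pair through the two reliability trackers and
    advances P_MB once per :meth:`update_p_mb` call (the agents call it
    once per episode, after replaying the episode's prediction errors).
    """

    def __init__(
        self,
        params: ArbitrationParams | None = None,
        eta: float = 0.2,
        rpe_max: float = 1.0,
        dirichlet_prior: float = 1.0,
        dirichlet_decay: float = 0.95,
        variance_penalty: bool = False,
        p_mb_init: float = 0.5,
    ) -> None:
        self.params = params if params is not None else ArbitrationParams()
        self.ph = PearceHallTracker(eta=eta, rpe_max=rpe_max)
        self.dirichlet = DirichletTracker(
            prior=dirichlet_prior, decay=dirichlet_decay,
            variance_penalty=variance_penalty,
        )
        self.state = ArbitrationState(
            rel_mf=self.ph.reliability,
            rel_mb=self.dirichlet.reliability,
            p_mb=p_mb_init,
        )

    def observe(self, rpe: float, spe: float) -> None:
        """Record one step's prediction errors, refreshing both reliabilities."""
        self.state.rel_mf = update_rel_mf(self.ph, rpe)
        category = classify_spe(spe, self.params.omega)
        self.state.rel_mb = update_rel_mb(self.dirichlet, category)

    def update_p_mb(self) -> float:
        return update_p_mb(self.state, self.params)

    @property
    def p_mb(self) -> float:
        return self.state.p_mb
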