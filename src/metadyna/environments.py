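"""Benchmark environments with goal-condition and uncertainty schedules.

Three stochastic tasks probe the arbitration agent's adaptivity:

* :class:`TwoStageMDT` -- a two-stage binary decision tree with token
  outcomes.  Action slips occur at both stages (the intended branch is
  taken with probability ``p_intended``, the opposite branch otherwise).
  Goal conditions alternate between *specific* (binary reward for one
  target token) and *flexible* (token values 0, 1/4, 1/2, 1), resampled
  every 125 episodes; transition uncertainty alternates between low
  (0.9) and high (0.5) every 500 episodes within 1,000-episode blocks.
* :class:`GridWorldLoCA` -- an 8x8 gridworld with terminal reward bars
  at the left and right edges.  Three phases shift the start-state
  distribution and drop the high-reward zone's value so the optimal
  policy flips; a run traverses the three phases twice, once per
  uncertainty level.
* :class:`StochasticPong` -- a lightweight single-point Pong.  Specific
  goals reward contact on one quarter of the 20-pixel paddle and end the
  episode at first contact; flexible goals score +1/-1 on a miss by the
  opponent/agent.  The configuration alternates deterministic/stochastic
  and the goal is resampled every 1,000 agent decisions.

All environments are fully reproducible from (config, seed) and follow a
small gym-style ``reset()``/``step(action)`` API returning
:class:`StepResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GoalCondition",
    "UncertaintyLevel",
    "StepResult",
    "PhaseSchedule",
    "LocaPhase",
    "TwoStageMDT",
    "MDTSchedule",
    "GridWorldLoCA",
    "loca_schedule",
    "StochasticPong",
    "PongSchedule",
]


@dataclass(frozen=True)
class GoalCondition:
    """Active goal: specific (one rewarded outcome) or flexible (graded)."""

    kind: Literal["specific", "flexible"]
    target_token: int | None = None  # MDT token index 0..3, specific only
    target_segment: int | None = None  # Pong paddle quarter 0..3, specific only

    def __post_init__(self) -> None:
        has_target = self.target_token is not None or self.target_segment is not None
        if (self.kind == "specific") != has_target:
            raise ValueError("a target is set iff the goal kind is 'specific'")


@dataclass(frozen=True)
class UncertaintyLevel:
    """Probability that the intended action outcome occurs."""

    p_intended: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.p_intended <= 1.0):
            raise ValueError(f"p_intended must lie in (0, 1], got {self.p_intended}")


@dataclass
class StepResult:
    next_state: object
    reward: float
    terminal: bool
    info: dict = field(default_factory=dict)


@dataclass
class LocaPhase:
    n_episodes: int
    p_intended: float
    reward_left: float
    reward_right: float
    start_region: Literal["uniform", "near_right"]


@dataclass
class PhaseSchedule:
    phases: list[LocaPhase]

    def __post_init__(self) -> None:
        if any(p.n_episodes <= 0 for p in self.phases):
            raise ValueError("phase durations must be positive")


# ---------------------------------------------------------------------------
# Two-stage Markov decision task
# ---------------------------------------------------------------------------

LOW_UNCERTAINTY = UncertaintyLevel(0.9)
HIGH_UNCERTAINTY = UncertaintyLevel(0.5)


class MDTSchedule:
    """Goal/uncertainty schedule over episodes.

    Within each 1,000-episode block the first 500 episodes run at low
    transition uncertainty and the last 500 at high uncertainty; the
    goal condition is resampled uniformly (flexible, or specific with a
    uniform target token) at every multiple of ``segment_length``
    episodes, deterministically from the schedule seed.
    """

    def __init__(
        self,
        seed: int = 0,
        segment_length: int = 125,
        block_length: int = 1000,
        low: UncertaintyLevel = LOW_UNCERTAINTY,
        high: UncertaintyLevel = HIGH_UNCERTAINTY,
    ):
        self.seed = seed
        self.segment_length = segment_length
        self.block_length = block_length
        self.low = low
        self.high = high
        self._goals: dict[int, GoalCondition] = {}

    def _goal_for_segment(self, segment: int) -> GoalCondition:
        if segment not in self._goals:
            rng = np.random.default_rng([self.seed, segment])
            if rng.random() < 0.5:
                goal = GoalCondition("flexible")
            else:
                goal = GoalCondition("specific", target_token=int(rng.integers(4)))
            self._goals[segment] = goal
        return self._goals[segment]

    def __call__(self, episode_index: int) -> tuple[GoalCondition, UncertaintyLevel]:
        if episode_index < 0:
            raise ValueError("episode index must be >= 0")
        within = episode_index % self.block_length
        unc = self.low if within < self.block_length // 2 else self.high
        return self._goal_for_segment(episode_index // self.segment_length), unc


class TwoStageMDT:
    """Two-stage binary tree: root -> 2 intermediates -> 4 token outcomes.

    States: 0 root, 1-2 intermediates, 3-6 terminal tokens.  Token values
    under the flexible goal are (0, 1/2) below intermediate 1 and
    (1/4, 1) below intermediate 2, i.e. each intermediate holds one low
    and one high token.  Stage-1 steps yield reward 0; stage-2 steps
    yield the token reward and terminate the episode.
    """

    N_STATES = 7
    N_ACTIONS = 2
    TOKEN_VALUES = (0.0, 0.5, 0.25, 1.0)  # tokens 0..3 == states 3..6

    def __init__(self, seed: int = 0, schedule: MDTSchedule | None = None):
        self.rng = np.random.default_rng(seed)
        self.schedule = schedule if schedule is not None else MDTSchedule(seed)
        self.episode_index = -1
        self.state: int | None = None
        self.goal: GoalCondition = GoalCondition("flexible")
        self.uncertainty: UncertaintyLevel = LOW_UNCERTAINTY

    @property
    def n_states(self) -> int:
        return self.N_STATES

    @property
    def n_actions(self) -> int:
        return self.N_ACTIONS

    def max_reward(self) -> float:
        """Maximum attainable episode reward under the current goal."""
        return 1.0

    def reset(self) -> int:
        self.episode_index += 1
        self.goal, self.uncertainty = self.schedule(self.episode_index)
        self.state = 0
        return 0

    def step(self, action: int) -> StepResult:
        if self.state is None or self.state >= 3:
            raise RuntimeError("step() called on a terminated episode")
        if action not in (0, 1):
            raise ValueError(f"action must be 0 (left) or 1 (right), got {action}")
        slip = self.rng.random() >= self.uncertainty.p_intended
        eff = action ^ int(slip)
        info = {
            "goal_kind": self.goal.kind,
            "target_token": self.goal.target_token,
            "p_intended": self.uncertainty.p_intended,
            "intended": not slip,
        }
        if self.state == 0:
            self.state = 1 + eff
            return StepResult(self.state, 0.0, False, info)
        token = 2 * (self.state - 1) + eff  # token index 0..3
        if self.goal.kind == "flexible":
            reward = self.TOKEN_VALUES[token]
        else:
            reward = 1.0 if token == self.goal.target_token else 0.0
        info["token"] = token
        info["optimal"] = reward == self.max_reward()
        self.state = None
        return StepResult(3 + token, reward, True, info)


# ---------------------------------------------------------------------------
# GridWorldLoCA
# ---------------------------------------------------------------------------

_GRID_MOVES = {0: (-1, 0), 1: (1, 0), 2: (0, -1), 3: (0, 1)}  # up, down, left, right


def loca_schedule(
    baseline_episodes: int = 3000,
    phase_fraction: float = 0.03,
    reward_high: float = 4.0,
    reward_low: float = 2.0,
    reward_dropped: float = 1.0,
    block_uncertainties: Sequence[float] = (0.9, 0.5),
) -> PhaseSchedule:
    """Two blocks (one per uncertainty level) of the three adaptation phases.

    Phase 1: right zone pays ``reward_high``, starts anywhere.  Phase 2:
    the right zone's value drops to ``reward_dropped`` (so the left zone
    becomes optimal) but starts are confined next to the right zone,
    which only a model-based learner can exploit globally.  Phase 3:
    starts anywhere again, rewards as in phase 2.  Each phase gets
    ``phase_fraction`` of the baseline episode budget.
    """
    n = max(1, round(phase_fraction * baseline_episodes))
    phases = []
    for p in block_uncertainties:
        phases += [
            LocaPhase(n, p, reward_low, reward_high, "uniform"),
            LocaPhase(n, p, reward_low, reward_dropped, "near_right"),
            LocaPhase(n, p, reward_low, reward_dropped, "uniform"),
        ]
    return PhaseSchedule(phases)


class GridWorldLoCA:
    """8x8 grid with terminal reward bars occupying the edge columns.

    Movement succeeds in the intended direction with ``p_intended``,
    otherwise one of the other three directions is drawn uniformly;
    walls block (the agent stays put).  Entering an edge column ends the
    episode with that zone's reward; episodes are truncated at
    ``max_steps`` with reward 0.

    During ``near_right`` phases the agent is confined to the columns
    adjacent to the right-edge zone (the local-change training phase of
    the adaptation benchmark): it experiences the dropped reward there
    but cannot re-visit the rest of the grid, which is what separates
    learners that re-plan globally from a model from learners that need
    fresh experience everywhere.
    """

    def __init__(
        self,
        phase: LocaPhase,
        seed: int = 0,
        size: int = 8,
        max_steps: int = 40,
    ):
        self.size = size
        self.max_steps = max_steps
        self.rng = np.random.default_rng(seed)
        self.phase = phase
        self.pos: tuple[int, int] | None = None
        self._steps = 0

    @property
    def n_states(self) -> int:
        return self.size * self.size

    @property
    def n_actions(self) -> int:
        return 4

    def set_phase(self, phase: LocaPhase) -> None:
        self.phase = phase

    def max_reward(self) -> float:
        """Maximum reward reachable under the phase's start/confinement."""
        if self.phase.start_region == "near_right":
            return self.phase.reward_right
        return max(self.phase.reward_left, self.phase.reward_right)

    def _state_index(self, pos: tuple[int, int]) -> int:
        return pos[0] * self.size + pos[1]

    def reset(self) -> int:
        last = self.size - 1
        if self.phase.start_region == "near_right":
            cols = [last - 1]
        else:
            cols = list(range(1, last))
        row = int(self.rng.integers(self.size))
        col = int(self.rng.choice(cols))
        self.pos = (row, col)
        self._steps = 0
        return self._state_index(self.pos)

    def step(self, action: int) -> StepResult:
        if self.pos is None:
            raise RuntimeError("step() called on a terminated episode")
        if action not in _GRID_MOVES:
            raise ValueError(f"invalid action {action}")
        if self.rng.random() >= self.phase.p_intended:
            others = [a for a in range(4) if a != action]
            action = int(self.rng.choice(others))
        dr, dc = _GRID_MOVES[action]
        r, c = self.pos
        nr, nc = r + dr, c + dc
        if not (0 <= nr < self.size):
            nr = r  # wall
        nc = min(max(nc, 0), self.size - 1)
        if self.phase.start_region == "near_right" and nc < self.size - 3:
            nc = c  # confinement boundary of the local phase
        self.pos = (nr, nc)
        self._steps += 1
        info = {"p_intended": self.phase.p_intended}
        last = self.size - 1
        if nc == 0:
            reward, terminal = self.phase.reward_left, True
        elif nc == last:
            reward, terminal = self.phase.reward_right, True
        elif self._steps >= self.max_steps:
            reward, terminal = 0.0, True
            info["timeout"] = True
        else:
            reward, terminal = 0.0, False
        state = self._state_index(self.pos)
        if terminal:
            info["optimal"] = reward == self.max_reward()
            self.pos = None
        return StepResult(state, reward, terminal, info)


# ---------------------------------------------------------------------------
# Stochastic Pong
# ---------------------------------------------------------------------------


class PongSchedule:
    """Alternates deterministic/stochastic physics and resamples the goal
    every ``period`` agent decisions, deterministically from the seed."""

    def __init__(self, seed: int = 0, period: int = 1000):
        self.seed = seed
        self.period = period
        self._goals: dict[int, GoalCondition] = {}

    def __call__(self, timestep: int) -> tuple[GoalCondition, str]:
        if timestep < 0:
            raise ValueError("timestep must be >= 0")
        interval = timestep // self.period
        config = "deterministic" if interval % 2 == 0 else "stochastic"
        if interval not in self._goals:
            rng = np.random.default_rng([self.seed, interval])
            if rng.random() < 0.5:
                goal = GoalCondition("flexible")
            else:
                goal = GoalCondition("specific", target_segment=int(rng.integers(4)))
            self._goals[interval] = goal
        return self._goals[interval], config


class StochasticPong:
    """Single-point Pong on an 80x80 court (0-based pixels, y down).

    The agent's 20-pixel paddle sits at the right edge, a tracking
    opponent at the left.  Deterministic configuration: the paddle moves
    exactly as commanded and the reflection angle is a pure function of
    the contact offset.  Stochastic configuration: the commanded paddle
    displacement succeeds with probability ``p_intended`` (otherwise a
    uniformly drawn other displacement) and the reflected vertical speed
    receives uniform jitter (the +/-15 degree analogue).

    Specific goal: the episode terminates at first ball--paddle contact
    with reward 1 iff the contact lies in the scheduled 5-pixel quarter.
    Flexible goal: +1 when the opponent misses, -1 when the agent
    misses, terminal at the first point.
    """

    WIDTH = 80
    HEIGHT = 80
    PADDLE_HALF = 10  # 20-pixel paddle
    SEGMENTS = 4
    BALL_DX = 3.0
    MAX_DY = 3.0
    PADDLE_STEP = 4.0
    OPPONENT_SPEED = 2.0
    AGENT_X = 77.0
    OPP_X = 2.0

    def __init__(
        self,
        seed: int = 0,
        schedule: PongSchedule | None = None,
        goal: GoalCondition | None = None,
        config: str | None = None,
        p_intended: float = 0.9,
        max_steps: int = 500,
    ):
        self.rng = np.random.default_rng(seed)
        self.schedule = schedule
        self._fixed_goal = goal
        self._fixed_config = config
        self.p_intended = p_intended
        self.max_steps = max_steps
        self.timestep = 0  # global agent-decision counter across episodes
        self.goal = goal if goal is not None else GoalCondition("flexible")
        self.config = config if config is not None else "deterministic"
        self._active = False

    @property
    def n_actions(self) -> int:
        return 3  # up, down, stay

    @property
    def obs_dim(self) -> int:
        return 6

    def _apply_schedule(self) -> None:
        if self.schedule is not None:
            self.goal, self.config = self.schedule(self.timestep)
        else:
            if self._fixed_goal is not None:
                self.goal = self._fixed_goal
            if self._fixed_config is not None:
                self.config = self._fixed_config

    def _obs(self) -> np.ndarray:
        return np.array(
            [
                self.ball[0] / self.WIDTH,
                self.ball[1] / self.HEIGHT,
                self.vel[0] / self.BALL_DX,
                self.vel[1] / self.MAX_DY,
                self.paddle_y / self.HEIGHT,
                self.opp_y / self.HEIGHT,
            ]
        )

    def reset(self) -> np.ndarray:
        self._apply_schedule()
        self.ball = np.array([self.WIDTH / 2.0, float(self.rng.uniform(20, 60))])
        dy = float(self.rng.integers(-2, 3))
        self.vel = np.array([self.BALL_DX, dy])  # serve toward the agent
        self.paddle_y = self.HEIGHT / 2.0
        self.opp_y = self.HEIGHT / 2.0
        self._steps = 0
        self._active = True
        return self._obs()

    def _segment(self, offset: float) -> int:
        # offset in [-PADDLE_HALF, PADDLE_HALF] -> quarter 0..3 (top to bottom)
        idx = int((offset + self.PADDLE_HALF) // (2 * self.PADDLE_HALF / self.SEGMENTS))
        return min(max(idx, 0), self.SEGMENTS - 1)

    def step(self, action: int) -> StepResult:
        if not self._active:
            raise RuntimeError("step() called on a terminated episode")
        if action not in (0, 1, 2):
            raise ValueError(f"action must be 0 (up), 1 (down) or 2 (stay)")
        self.timestep += 1
        self._apply_schedule()
        self._steps += 1

        displ = {0: -self.PADDLE_STEP, 1: self.PADDLE_STEP, 2: 0.0}
        move = displ[action]
        if self.config == "stochastic" and self.rng.random() >= self.p_intended:
            others = [v for k, v in displ.items() if k != action]
            move = float(self.rng.choice(others))
        self.paddle_y = float(
            np.clip(self.paddle_y + move, self.PADDLE_HALF,
                    self.HEIGHT - self.PADDLE_HALF)
        )
        diff = self.ball[1] - self.opp_y
        self.opp_y = float(
            np.clip(
                self.opp_y + np.clip(diff, -self.OPPONENT_SPEED, self.OPPONENT_SPEED),
                self.PADDLE_HALF,
                self.HEIGHT - self.PADDLE_HALF,
            )
        )

        self.ball += self.vel
        if self.ball[1] < 0:
            self.ball[1] = -self.ball[1]
            self.vel[1] = -self.vel[1]
        elif self.ball[1] > self.HEIGHT - 1:
            self.ball[1] = 2 * (self.HEIGHT - 1) - self.ball[1]
            self.vel[1] = -self.vel[1]

        info = {
            "goal_kind": self.goal.kind,
            "target_segment": self.goal.target_segment,
            "config": self.config,
        }
        reward, terminal = 0.0, False

        if self.vel[0] > 0 and self.ball[0] >= self.AGENT_X:
            offset = self.ball[1] - self.paddle_y
            if abs(offset) <= self.PADDLE_HALF:  # contact
                if self.goal.kind == "specific":
                    seg = self._segment(offset)
                    info["contact_segment"] = seg
                    reward = 1.0 if seg == self.goal.target_segment else 0.0
                    terminal = True
                else:
                    dy = (offset / self.PADDLE_HALF) * self.MAX_DY
                    if self.config == "stochastic":
                        dy += float(self.rng.uniform(-1.0, 1.0))
                    self.vel = np.array(
                        [-self.BALL_DX, float(np.clip(dy, -self.MAX_DY, self.MAX_DY))]
                    )
                    self.ball[0] = self.AGENT_X - 1.0
            else:  # agent miss
                reward = -1.0 if self.goal.kind == "flexible" else 0.0
                terminal = True
                info["miss"] = "agent"
        elif self.vel[0] < 0 and self.ball[0] <= self.OPP_X:
            offset = self.ball[1] - self.opp_y
            if abs(offset) <= self.PADDLE_HALF:
                dy = (offset / self.PADDLE_HALF) * self.MAX_DY
                self.vel = np.array(
                    [self.BALL_DX, float(np.clip(dy, -self.MAX_DY, self.MAX_DY))]
                )
                self.ball[0] = self.OPP_X + 1.0
            else:
                reward = 1.0 if self.goal.kind == "flexible" else 0.0
                terminal = True
                info["miss"] = "opponent"

        if self._steps >= self.max_steps and not terminal:
            terminal = True
            info["timeout"] = True
        if terminal:
            info["optimal"] = reward >= 1.0
            self._active = False
        return StepResult(self._obs(), reward, terminal, info)

    def render(self, size: int = 84) -> np.ndarray:
        """Rasterise the court as a grayscale frame (for the CNN pathway)."""
        frame = np.zeros((size, size), dtype=np.float32)
        sx, sy = size / self.WIDTH, size / self.HEIGHT
        bx, by = int(self.ball[0] * sx), int(self.ball[1] * sy)
        frame[max(by - 1, 0):by + 2, max(bx - 1, 0):bx + 2] = 1.0
        for x, y in ((self.AGENT_X, self.paddle_y), (self.OPP_X, self.opp_y)):
            x0 = int(x * sx)
            y0 = int((y - self.PADDLE_HALF) * sy)
            y1 = int((y + self.PADDLE_HALF) * sy)
            frame[max(y0, 0):y1 + 1, max(x0 - 1, 0):x0 + 1] = 0.7
        return frame
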