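import numpy as np
import pytest

from metadyna.world_model import Transition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class FixedMDTSchedule:
    """Schedule stub holding one goal/uncertainty pair fixed."""

    def __init__(self, goal, uncertainty):
        self.goal = goal
        self.uncertainty = uncertainty

    def __call__(self, episode_index):
        return self.goal, self.uncertainty


@pytest.fixture
def fixed_schedule():
    return FixedMDTSchedule


class ChainMDP:
    """Tiny deterministic 4-state chain environment for oracle tests.

    s0 -a1-> s1 -a1-> s2 -a1-> s3 (terminal, reward 1); action 0 stays
    put with reward 0.  Exact Q-values are computable by value iteration
    on the known model.
    """

    n_states = 4
    n_actions = 2

    def __init__(self, seed=0):
        self.rng = np.random.default_rng(seed)
        self.state = 0

    def max_reward(self):
        return 1.0

    def reset(self):
        self.state = 0
        return 0

    def step(self, action):
        from metadyna.environments import StepResult

        s = self.state
        if action == 1:
            nxt = s + 1
        else:
            nxt = s
        terminal = nxt == 3
        reward = 1.0 if terminal else 0.0
        self.state = nxt
        return StepResult(nxt, reward, terminal, {"optimal": terminal})


@pytest.fixture
def chain_mdp():
    return ChainMDP


def chain_q_star(gamma=0.9):
    """Closed-form optimal Q for ChainMDP (hand-derived oracle)."""
    q = np.zeros((4, 2))
    # from s2: a1 -> terminal reward 1
    q[2, 1] = 1.0
    q[1, 1] = gamma * 1.0
    q[0, 1] = gamma**2
    q[2, 0] = gamma * q[2, 1]
    q[1, 0] = gamma * q[1, 1]
    q[0, 0] = gamma * q[0, 1]
    return q


@pytest.fixture
def chain_oracle():
    return chain_q_star


def make_transitions(pairs, terminal_last=True):
    """Build a chained transition list from (s, a, r, s') tuples."""
    out = []
    for i, (s, a, r, sn) in enumerate(pairs):
        out.append(
            Transition(s, a, r, sn, terminal=terminal_last and i == len(pairs) - 1)
        )
    return out
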