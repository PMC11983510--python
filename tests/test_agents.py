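"""Agent tests: update oracles, degenerate equivalences, buffer hygiene."""

import numpy as np
import pytest

from metadyna.agents import (
    AgentConfig,
    DQNAgent,
    DynaQAgent,
    ForwardAgent,
    HybridArbitrationAgent,
    MetaDynaAgent,
    MLPQ,
    QLearningAgent,
    ReplayBuffer,
    SarsaAgent,
    Transition,
    forward_update,
    make_agent,
    qlearn_update,
    sarsa_update,
    select_action,
    value_iteration,
)
from metadyna.environments import (
    GoalCondition,
    TwoStageMDT,
    UncertaintyLevel,
)
from metadyna.world_model import RolloutConfig, TabularModel, tabular_update
from tests.conftest import chain_q_star


def run_episodes(agent, env, n):
    from metadyna.experiments import run_episode

    return [run_episode(agent, env)[0] for _ in range(n)]


# ---------------------------------------------------------------------------
# Update primitives
# ---------------------------------------------------------------------------


def test_qlearn_terminal_full_step_update():
    q = np.zeros((2, 2))
    qlearn_update(q, Transition(0, 1, 1.0, 1, terminal=True), lr=1.0, gamma=0.9)
    assert q[0, 1] == 1.0


def test_qlearn_zero_learning_rate_is_identity():
    q = np.ones((2, 2))
    qlearn_update(q, Transition(0, 0, 5.0, 1), lr=0.0, gamma=0.9)
    assert np.all(q == 1.0)


def test_qlearn_converges_to_discounted_chain_values(chain_oracle):
    # sweep the known 4-state chain until the closed-form values appear
    q = np.zeros((4, 2))
    gamma = 0.9
    transitions = [
        Transition(0, 1, 0.0, 1), Transition(1, 1, 0.0, 2),
        Transition(2, 1, 1.0, 3, terminal=True),
        Transition(0, 0, 0.0, 0), Transition(1, 0, 0.0, 1),
        Transition(2, 0, 0.0, 2),
    ]
    for _ in range(2000):
        for tr in transitions:
            qlearn_update(q, tr, lr=0.2, gamma=gamma)
    assert np.allclose(q, chain_oracle(gamma), atol=1e-3)


def test_sarsa_terminal_matches_qlearning_terminal():
    q1, q2 = np.zeros((2, 2)), np.zeros((2, 2))
    tr = Transition(0, 0, 1.0, 1, terminal=True)
    qlearn_update(q1, tr, 0.5, 0.9)
    sarsa_update(q2, tr, None, 0.5, 0.9)
    assert np.array_equal(q1, q2)


def test_sarsa_with_greedy_next_action_equals_qlearning():
    q = np.array([[0.0, 0.0], [0.3, 0.9]])
    q1, q2 = q.copy(), q.copy()
    tr = Transition(0, 0, 0.5, 1)
    qlearn_update(q1, tr, 0.5, 0.9)
    sarsa_update(q2, tr, a_next=1, lr=0.5, gamma=0.9)  # 1 is the argmax
    assert np.allclose(q1, q2)


def test_sarsa_evaluates_fixed_soft_policy(rng):
    # policy-evaluation oracle on a 3-state chain with an eps-soft policy
    # states 0,1; 2 terminal. a1 advances, a0 stays (reward 0); reaching
    # 2 pays 1. pi(a1)=0.8 everywhere.
    gamma, p1 = 0.9, 0.8
    # exact Q^pi by solving the Bellman expectation equations by hand:
    # V(1) = p1*1 + (1-p1)*gamma*V(1)  => V(1)
    v1 = p1 * 1.0 / (1 - (1 - p1) * gamma)
    v0 = (p1 * gamma * v1) / (1 - (1 - p1) * gamma)
    q_oracle = np.array([
        [gamma * v0, gamma * v1],
        [gamma * v1, 1.0],
    ])
    q = np.zeros((3, 2))
    for _ in range(8000):
        s = 0
        a = 1 if rng.random() < p1 else 0
        while s != 2:
            s_next = (s + 1 if a == 1 else s)
            r = 1.0 if s_next == 2 else 0.0
            a_next = 1 if rng.random() < p1 else 0
            sarsa_update(q, Transition(s, a, r, s_next, terminal=s_next == 2),
                         a_next, lr=0.02, gamma=gamma)
            s, a = s_next, a_next
    assert np.allclose(q[:2], q_oracle, atol=0.05)


def test_forward_update_reaches_dp_values_on_deterministic_mdp(chain_oracle):
    model = TabularModel(4, 2, gamma_t=0.5)
    q = np.zeros((4, 2))
    transitions = [
        Transition(0, 1, 0.0, 1), Transition(1, 1, 0.0, 2),
        Transition(2, 1, 1.0, 3, terminal=True),
        Transition(0, 0, 0.0, 0), Transition(1, 0, 0.0, 1),
        Transition(2, 0, 0.0, 2),
    ]
    for _ in range(60):
        for tr in transitions:
            forward_update(model, q, tr, gamma=0.9)
    assert np.allclose(q[:3], chain_oracle(0.9)[:3], atol=1e-2)


def test_forward_reward_relocation_shifts_argmax_after_one_sweep():
    model = TabularModel(2, 2, gamma_t=1.0)
    tabular_update(model, 0, 0, 1, r=1.0, terminal=True)
    tabular_update(model, 0, 1, 1, r=0.0, terminal=True)
    q = value_iteration(model, 0.9, sweeps=2)
    assert q[0].argmax() == 0
    # relocate the reward with frozen transitions
    model.r_est[0] = [0.0, 1.0]
    q = value_iteration(model, 0.9, sweeps=1, q=q)
    assert q[0].argmax() == 1


def test_forward_update_with_empty_model_leaves_q_unchanged():
    model = TabularModel(3, 2)
    q = value_iteration(model, 0.9, sweeps=3)
    assert np.all(q == 0.0)


# ---------------------------------------------------------------------------
# Action selection
# ---------------------------------------------------------------------------


def test_select_action_greedy_unique_argmax(rng):
    q = np.array([[0.1, 0.9, 0.2]])
    assert all(select_action(q, 0, 0.0, rng) == 1 for _ in range(100))


def test_select_action_uniform_when_epsilon_one(rng):
    q = np.array([[0.0, 10.0, 0.0]])
    counts = np.bincount([select_action(q, 0, 1.0, rng) for _ in range(9000)],
                         minlength=3)
    assert np.allclose(counts / 9000, 1 / 3, atol=0.03)


def test_select_action_breaks_ties_uniformly(rng):
    q = np.array([[0.5, 0.5, 0.1]])
    counts = np.bincount([select_action(q, 0, 0.0, rng) for _ in range(10_000)],
                         minlength=3)
    assert counts[2] == 0
    assert counts[0] / 10_000 == pytest.approx(0.5, abs=0.02)


# ---------------------------------------------------------------------------
# Buffer hygiene and provenance
# ---------------------------------------------------------------------------


def test_replay_buffer_mf_rejects_simulated():
    rb = ReplayBuffer(10, "RB_MF")
    rb.add(Transition(0, 0, 0.0, 1))
    with pytest.raises(ValueError):
        rb.add(Transition(0, 0, 0.0, 1, simulated=True))
    rb_mb = ReplayBuffer(10, "RB_MB")
    rb_mb.add(Transition(0, 0, 0.0, 1, simulated=True))
    assert len(rb_mb) == 1


def test_replay_buffer_is_bounded_fifo():
    rb = ReplayBuffer(3, "RB_MF")
    for i in range(5):
        rb.add(Transition(i, 0, 0.0, i + 1))
    assert len(rb) == 3
    assert [tr.s for tr in rb] == [2, 3, 4]


def test_meta_dyna_buffer_and_qmb_provenance(fixed_schedule):
    env = TwoStageMDT(seed=0, schedule=fixed_schedule(
        GoalCondition("flexible"), UncertaintyLevel(0.9)))
    agent = MetaDynaAgent(env.n_states, env.n_actions, AgentConfig(), seed=1)
    run_episodes(agent, env, 50)
    assert all(not tr.simulated for tr in agent.rb_mf)
    assert any(tr.simulated for tr in agent.rb_mb)
    # with planning disabled, Q_MB is never touched by real transitions
    agent2 = MetaDynaAgent(env.n_states, env.n_actions,
                           AgentConfig(planning_steps=0), seed=1)
    run_episodes(agent2, env, 50)
    assert np.all(agent2.q_mb == 0.0)
    assert np.any(agent2.q_mf != 0.0)


# ---------------------------------------------------------------------------
# Degenerate equivalences
# ---------------------------------------------------------------------------


def test_p_mb_zero_reduces_to_qlearning_step_for_step(fixed_schedule):
    sched = fixed_schedule(GoalCondition("flexible"), UncertaintyLevel(0.9))
    env1 = TwoStageMDT(seed=4, schedule=sched)
    env2 = TwoStageMDT(seed=4, schedule=sched)
    ql = QLearningAgent(7, 2, AgentConfig(), seed=9)
    meta = MetaDynaAgent(7, 2, AgentConfig(p_mb_fixed=0.0, planning_steps=0,
                                           update_mode="step"), seed=9)

    from metadyna.experiments import run_episode

    for _ in range(200):
        r1, _, _ = run_episode(ql, env1)
        r2, _, _ = run_episode(meta, env2)
        assert r1 == r2
    assert np.array_equal(ql.q, meta.q_mf)


def test_p_mb_one_with_exact_model_matches_dp_policy(chain_mdp, chain_oracle):
    # pre-train the world model to the exact dynamics of the 4-state MDP
    cfg = AgentConfig(p_mb_fixed=1.0, planning_steps=20,
                      rollout=RolloutConfig(n_steps=10, horizon=10,
                                            epsilon=0.5))
    agent = MetaDynaAgent(4, 2, cfg, seed=3)
    agent.model.gamma_t = 1.0
    transitions = [(0, 1, 0.0, 1, False), (1, 1, 0.0, 2, False),
                   (2, 1, 1.0, 3, True), (0, 0, 0.0, 0, False),
                   (1, 0, 0.0, 1, False), (2, 0, 0.0, 2, False)]
    for s, a, r, sn, term in transitions:
        tabular_update(agent.model, s, a, sn, r, term)
    env = chain_mdp()
    run_episodes(agent, env, 150)
    oracle_policy = chain_oracle(0.9)[:3].argmax(axis=1)
    assert np.array_equal(agent.q_mb[:3].argmax(axis=1), oracle_policy)


def test_dyna_planning_with_exact_model_preserves_fixed_point(chain_oracle):
    agent = DynaQAgent(4, 2, AgentConfig(planning_steps=50), seed=0)
    agent.model.gamma_t = 1.0
    agent.q = chain_q = chain_oracle(0.9).copy()
    for s, a, r, sn, term in [(0, 1, 0.0, 1, False), (1, 1, 0.0, 2, False),
                              (2, 1, 1.0, 3, True), (0, 0, 0.0, 0, False),
                              (1, 0, 0.0, 1, False), (2, 0, 0.0, 2, False)]:
        tabular_update(agent.model, s, a, sn, r, term)
        agent._visited.append((s, a))
    before = agent.q.copy()
    agent.end_episode()  # planning only
    assert np.allclose(agent.q, before, atol=1e-9)


# ---------------------------------------------------------------------------
# Learning behaviour on stationary tasks
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("name", ["q-learning", "sarsa", "forward", "dyna-q",
                                  "meta-dyna", "forward+sarsa",
                                  "forward+qlearning"])
def test_agents_reach_optimal_policy_on_stationary_mdt(name, fixed_schedule):
    # deterministic stationary task: greedy policy must become optimal
    env = TwoStageMDT(seed=5, schedule=fixed_schedule(
        GoalCondition("flexible"), UncertaintyLevel(1.0)))
    agent = make_agent(name, n_states=7, n_actions=2, config=AgentConfig(),
                       seed=2)
    run_episodes(agent, env, 500)
    agent.cfg.epsilon = 0.0
    rewards = run_episodes(agent, env, 50)
    assert np.mean(rewards) == pytest.approx(1.0)


def test_dyna_planning_accelerates_learning_on_deterministic_grid():
    from metadyna.environments import GridWorldLoCA, LocaPhase
    from metadyna.experiments import run_episode

    def learn(n_planning, seed):
        # fraction of late episodes ending at the high-reward bar: a
        # policy-quality measure insensitive to the low bar's consolation
        phase = LocaPhase(80, 1.0, 2.0, 4.0, "uniform")
        env = GridWorldLoCA(phase, seed=seed)
        agent = DynaQAgent(64, 4, AgentConfig(planning_steps=n_planning),
                           seed=seed)
        rewards = [run_episode(agent, env)[0] for _ in range(80)]
        return np.mean([r == 4.0 for r in rewards[-40:]])

    slow = np.mean([learn(1, s) for s in range(8)])
    fast = np.mean([learn(20, s) for s in range(8)])
    assert fast > slow


def test_hybrid_agents_expose_arbitration_and_learn(fixed_schedule):
    env = TwoStageMDT(seed=6, schedule=fixed_schedule(
        GoalCondition("flexible"), UncertaintyLevel(0.9)))
    agent = HybridArbitrationAgent(7, 2, AgentConfig(), seed=1,
                                   mf_style="qlearning")
    rewards = run_episodes(agent, env, 300)
    assert 0.0 <= agent.p_mb <= 1.0
    # near-optimal late behaviour (epsilon-adjusted optimum is ~0.83)
    assert np.mean(rewards[-100:]) > 0.75


def test_seed_determinism_of_full_runs():
    from metadyna.experiments import run_mdt

    a = run_mdt("meta-dyna", seed=3, n_episodes=150)
    b = run_mdt("meta-dyna", seed=3, n_episodes=150)
    assert a.equals(b)


# ---------------------------------------------------------------------------
# Network backends
# ---------------------------------------------------------------------------


def test_mlpq_fits_a_small_regression_target(rng):
    net = MLPQ(3, 2, hidden=32, lr=1e-2, seed=0)
    X = rng.normal(size=(256, 3))
    y = X[:, 0] - 0.5 * X[:, 1]
    losses = []
    for _ in range(300):
        idx = rng.integers(256, size=32)
        losses.append(net.train_batch(X[idx], np.zeros(32, dtype=int), y[idx]))
    assert np.mean(losses[-20:]) < 0.05 * np.mean(losses[:20])


def test_dqn_target_sync_every_update_tracks_online_net(fixed_schedule):
    env = TwoStageMDT(seed=0, schedule=fixed_schedule(
        GoalCondition("flexible"), UncertaintyLevel(0.9)))
    enc = np.eye(7)
    agent = DQNAgent(7, 2, AgentConfig(update_mode="step", target_sync=1),
                     seed=0, encoder=lambda s: enc[int(s)])
    run_episodes(agent, env, 60)
    for k in agent.q.params:
        assert np.allclose(agent.q.params[k], agent.target.params[k])


def test_dqn_improves_on_stationary_mdt(fixed_schedule):
    env = TwoStageMDT(seed=1, schedule=fixed_schedule(
        GoalCondition("flexible"), UncertaintyLevel(0.9)))
    enc = np.eye(7)
    agent = DQNAgent(7, 2, AgentConfig(update_mode="step"), seed=1,
                     encoder=lambda s: enc[int(s)])
    rewards = run_episodes(agent, env, 500)
    assert np.mean(rewards[-100:]) > np.mean(rewards[:100])


@pytest.mark.parametrize("name,backend", [("meta-dyna", "table"),
                                          ("dyna-q", "table"),
                                          ("dqn", "network")])
def test_agent_checkpoint_round_trip(tmp_path, name, backend, fixed_schedule):
    env = TwoStageMDT(seed=2, schedule=fixed_schedule(
        GoalCondition("flexible"), UncertaintyLevel(0.9)))
    enc = np.eye(7)
    kwargs = (dict(n_states=7) if backend == "table"
              else dict(obs_dim=7, encoder=lambda s: enc[int(s)]))
    agent = make_agent(name, n_actions=2, backend=backend,
                       config=AgentConfig(update_mode="step"), seed=4, **kwargs)
    run_episodes(agent, env, 30)
    path = tmp_path / "ckpt.npz"
    agent.save(str(path))
    clone = make_agent(name, n_actions=2, backend=backend,
                       config=AgentConfig(), seed=99, **kwargs)
    clone.load(str(path))
    for k, v in agent.state_dict().items():
        assert np.array_equal(v, clone.state_dict()[k]), k


def test_registry_names_and_errors():
    with pytest.raises(KeyError):
        make_agent("nope", n_actions=2, n_states=3)
    with pytest.raises(ValueError):
        make_agent("dqn", n_actions=2, n_states=3)  # no tabular backend
    with pytest.raises(ValueError):
        make_agent("sarsa", n_actions=2, obs_dim=3, backend="network")
    agent = make_agent("forward+sarsa", n_actions=2, n_states=4)
    assert agent.mf_style == "sarsa"
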