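# Methods

## The model

`metadyna` implements a Dyna-style reinforcement-learning agent whose
behaviour is governed by a prefrontal-cortex-inspired meta-controller
that arbitrates between two value systems:

* a **model-free (MF)** learner — Q-learning on real experience, the
  computational analogue of habitual control, characterised by its
  reward prediction error `RPE = r + γ Q_MF(s',a') − Q_MF(s,a)`;
* a **model-based (MB)** learner — Q-learning on experience *simulated*
  from a learned world model ("mental simulation"), the analogue of
  goal-directed control, characterised by the state prediction error
  `SPE`: `1 − T(s,a,s')` for a discrete transition model, or the mean
  absolute z-score of the observation under the recurrent mixture
  model's dominant component in continuous spaces.

Reliability of each system is tracked from its prediction errors:

* `Rel_MF` via a Pearce–Hall associability — a recency-weighted mean of
  |RPE| (rate `eta`, default 0.2) mapped linearly to [0,1] through a
  normalisation bound `rpe_max` (default 1.0, the task's reward range);
* `Rel_MB` as the posterior mean of the *zero* category of a Dirichlet
  over SPE categories {negative, zero, positive}, with categories cut
  at a symmetric tolerance band |PE| ≤ ω. Pseudo-counts decay
  exponentially (default 0.95 per event ≈ a 20-event memory): without
  forgetting the posterior freezes and the controller cannot follow the
  tasks' 125-episode regime switches. `decay=1.0` recovers the textbook
  conjugate update, whose convergence to the empirical zero-frequency
  is property-tested.

The probability of model-based control evolves as

    α = A_α / (1 + exp(B_α · Rel_MF))
    β = A_β / (1 + exp(B_β · Rel_MB))
    P_MB ← P_MB + α (1 − P_MB) − β P_MB,

and behaviour is ε-greedy on the integrated values
`Q = P_MB · Q_MB + (1 − P_MB) · Q_MF` (output-space integration for the
network variant: averaging the *parameters* of independently trained
networks is ill-defined).

### Arbitration defaults and why

`A_α = A_β = 0.5` gives the P_MB dynamics a relaxation timescale of
roughly ten update calls — fast enough to track the benchmarks'
125-episode goal segments, slow enough not to chatter. `B_α = 2` and
`B_β = 5` are asymmetric on purpose: `Rel_MB` is a calibrated frequency
(a fraction of zero-surprise transitions), so the MB→MF escape rate can
be gated steeply on it, whereas `Rel_MF`'s scale depends on the task's
reward variance through `rpe_max`, so its slope is kept shallow.
`ω = 0.25` must exceed the true surprise level of a reliable model in
the low-uncertainty regime (SPE ≈ 0.1 when the intended branch occurs)
plus the transition-estimator's steady-state dispersion (≈ 0.1 at step
size 0.2); with ω below that sum a perfectly good model is
misclassified as surprising. These values were chosen by tracing the
mechanism (P_MB must rise in the low-uncertainty halves and fall in the
high-uncertainty halves), not by optimising task reward.

## World models

**Tabular.** Per-(s,a,s') transition probabilities updated with step
size `gamma_t` (default 0.2): the observed successor moves toward 1 by
`gamma_t·(1−p)`, all other successors shrink by `(1−gamma_t)`, and the
row is renormalised (it stays on the simplex analytically; the
renormalisation guards round-off). The expected reward per (s,a) is a
recency-weighted running mean with the same step size, so the model
tracks the tasks' non-stationary reward schedules; a count-based MLE is
kept alongside in `visit_counts`. `gamma_t` trades adaptation speed
against steady-state dispersion (sd ≈ √(γ_t/2 · p(1−p))); 0.2 adapts
within ~5 visits of a reward change, which the benchmarks' schedules
require.

**Recurrent mixture-density network.** A single-layer gated recurrent
unit (default 64 units for the desk-scale presets; 128 is the reference
width) consuming `(state, one-hot action, SPE, RPE)` per step, with
output heads parameterising a K-component diagonal Gaussian mixture
over the next state (K = 5), a Gaussian reward head, and a Bernoulli
terminal head. The network is written in numpy with hand-derived
backpropagation through time; the gradients are verified against
central-difference numerical differentiation in the test suite. By
default the mixture is fitted to the state *change* s' − s (the easier
target for smooth dynamics); emitted predictions are always on the
absolute next-state scale. Log-scales are clipped to [−4, 4] for
numerical stability, gradients to ±5, and optimisation uses Adam
(lr 3e-3).

**Mental simulation.** A rollout chains up to `n_steps` transitions
from a start state: ε-greedy action on the integrated Q (simulation
ε = 0.3 by default — exploration inside imagination is free and keeps
rarely-taken actions refreshed), successor sampled from the model
(categorical for tabular; tempered mixture sampling for the network),
stopping at a predicted terminal or the horizon. Rewards enter planning
as the reward head's *prediction*, not a draw — sampling them would
inject the head's residual scale into every simulated Bellman target as
pure noise. A model that has never been trained yields no rollouts, and
the network model additionally waits for `wm_warmup` (20) gradient
updates before planning engages. Simulated transitions are tagged and
may only enter the MB replay buffer; the MF buffer rejects them by
construction. Per episode the agent launches `planning_steps` (default
10) rollouts, each starting from a uniformly drawn previously-visited
state (the Dyna convention, for state coverage).

The MB learning rate defaults to 0.2, matched to `gamma_t`: with the
conventional 0.1 the simulated-experience learner measurably lags its
own model's reward estimates after a reward switch, making the MB
component strictly worse than value iteration on the same model.

## Environments (what the generator emulates, and what it does not)

**Two-stage decision task.** A binary tree: root → 2 intermediate
states → 4 token outcomes with flexible-goal values (0, ½) under one
intermediate and (¼, 1) under the other. Action slips occur at *both*
stages: the intended branch is taken with probability `p_intended`
(0.9 low / 0.5 high uncertainty). Goals alternate between *flexible*
(graded token values) and *specific* (1.0 for one uniformly drawn
target token), resampled every 125 episodes; uncertainty flips every
500 episodes inside 1,000-episode blocks, five blocks per run.

A consequence worth stating: at `p_intended = 0.5` both stages are
coin flips, so the high-uncertainty halves are policy-independent
(expected reward 0.4375 flexible, 0.25 specific, ≈ 0.344 mixed). The
protocol's full-run mean is therefore bounded by ≈ 0.59 for a perfect
player and ≈ 0.55 for a perfect ε = 0.1 player. Tabular agents measured
here land at 0.49–0.53, in the expected band, with the arbitration
agent statistically above plain Q-learning and at par with the best
single-system baselines.

**GridWorldLoCA.** 8×8 grid, terminal reward bars occupying the two
edge columns (right pays 4, left 2). Phase 1 starts anywhere; phase 2
drops the right bar's value to 1 *and confines the agent to the columns
adjacent to it* (the benchmark's local-change training phase — without
confinement this small grid lets model-free learners experience the
change everywhere and the probe discriminates nothing); phase 3 starts
anywhere again. The three phases run twice, once per uncertainty level
(movement slips 0.9/0.5), 3% of a 3,000-episode baseline per phase
(= 90 episodes), ten independent runs.

**Stochastic Pong.** A geometric single-point simulator (80×80 court,
20-pixel paddles, tracking opponent with capped speed), not an Atari
emulation: the experimental manipulations — single-point termination,
paddle-quarter goals, injected stochasticity — define the task.
Deterministic configuration: exact paddle motion, reflection angle a
pure function of contact offset. Stochastic configuration: commanded
paddle displacement succeeds with `p_intended` = 0.9 and the reflected
vertical speed takes uniform jitter (±1 px/step, the ±15° analogue).
Specific goal: terminal at first agent contact, +1 iff the contact lies
in the scheduled 5-pixel quarter; flexible: ±1 on a miss by
opponent/agent. Configuration and goal are resampled every 1,000 agent
decisions. An 84×84 grayscale rasteriser is provided for frame-based
pipelines, but all shipped presets use the 6-dimensional state vector.

None of the environments models perceptual noise, continuous time or
reaction latency; passing tests show that the arbitration mechanism
behaves as designed under the stated schedules, not that it would
survive raw-pixel or real-time conditions.

## Experiment presets and problem sizes

* `mdt`: 5,000 episodes per seed; 10 seeds tabular, 5 (network) in the
  reproduction script. The network preset one-hot-encodes states and
  snaps sampled rollout states to the nearest one-hot.
* `loca`: the 6-phase schedule above, 10 runs.
* `pong`: 1,000 episodes default; the test suite uses 400-episode /
  2-seed runs and a 4,000-interaction budget for the simulation-count
  sweep. These sizes were chosen as the package's desk-scale defaults.
* Welch's t-test is used for all pairwise comparisons; the
  "exponential reward" summary is an EWMA (smoothing 0.99) of episode
  reward reported at the last episode — this package's reading of a
  smoothed end-of-training reward — always alongside the plain mean.

The reproduction script (`scripts/acceptance.py`) recomputes the
headline quantities from scratch: the four tabular MDT means, the
network Meta-Dyna MDT mean, and the variance of Meta-Dyna's
per-(run, phase) average normalized returns on the gridworld benchmark.

## Numerical and design choices

* Transition-model update: the matched-successor branch is read as
  "observed successor equals the row successor"; the update's rate
  parameter is a model step-size (`gamma_t`) distinct from the MDP
  discount. The literal alternative (comparing two probabilities for
  equality) is degenerate.
* Episode-batch training cadence for the tabular Meta-Dyna (per-step
  mode available, and used by the Pong preset); prediction errors are
  computed *before* the corresponding update (surprise, not hindsight).
* ε-greedy ties are broken uniformly with the run's seeded generator;
  every run is reproducible from (config, seed), and the tabular
  experiment driver is byte-identical across re-runs.
* Degenerate configurations are preserved and tested: pinning P_MB to 0
  reproduces plain Q-learning step for step; pinning it to 1 with an
  exact model recovers the dynamic-programming policy.
* The variance-penalised reliability `E(Dir_zero) − √V(Dir_zero)` is
  available behind a flag; the default uses the posterior mean.

## Known limitations

* With both stages of the two-stage task subject to 0.5 action slips,
  no agent can exceed ≈ 0.59 mean normalized reward over the full
  protocol; reported reference values above that level are not
  reproducible under this protocol reading (see the ceiling argument
  above), and the package reports what it actually measures.
* The arbitration agent's advantage over Dyna-Q/FORWARD is small on
  these small discrete tasks, where a single well-tuned system already
  adapts within a goal segment; the mechanism's value shows mainly
  against plain model-free learning.
* The Pong benchmark at desk scale (hundreds of episodes) has large
  across-seed variance; orderings there should be read as trends.
* The recurrent world model is trained on the replay superset
  (real + simulated experience) as the architecture prescribes;
  a `wm_on_real_only` flag disables the self-training component.
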