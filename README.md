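# rpeacc

**Reward-prediction-error accumulation: actor-critic simulations and
neural encoding analysis.**

When an animal (or agent) makes a discrete goal-directed movement and the
expected reward does not arrive, it experiences a negative reward
prediction error (RPE), `delta = r - V(s)`.  Across a trial these errors
can accumulate — the n-th erroneous movement marks an *n-step error* —
and reinforcement-learning theory suggests that mixing accumulation
horizons improves learning.  `rpeacc` implements both sides of that
question as a reusable Python package:

* **Theory** (`rpeacc.rl_env`, `rpeacc.rl_agent`): a 2D arena task
  (centered reward zone, 256 discrete actions of which 75% are no-ops,
  direction-biased speeds) and a PPO-variant actor-critic (4x256 MLP)
  whose advantage is an n-step accumulation of non-bootstrapped RPEs,

      A_t(n) = delta_t + (gamma*lambda) delta_{t+1} + ...
               + (gamma*lambda)^(n-1) delta_{t+n-1},

  where `delta` is defined only at movement events (toward errors and
  goal entries; away-moves are reinitialization).  Three reward
  schedules — standard, randomly interleaved (50% omission) and split
  (low/high halves of the zone) — probe how RPEs follow reward
  expectation and state value.

* **Experiment-side analysis** (`rpeacc.behavior`,
  `rpeacc.encoding_glm`, `rpeacc.population`): stroke and
  toward/away-error detection from 10-ms object trajectories, n-step
  accumulation onsets `delta(n)` (n = 1..6), peri-error lick histograms,
  empirical state-value maps `E[gamma^(T-t)]`; elastic-net Poisson
  encoding GLMs on raised-cosine temporal bases (138 predictors:
  36 error + 48 + 48 velocity + 6 time) with held-out pseudo explained
  variance `1 - D(yhat)/D(ybar)`, block-shuffle significance, and
  conservative error-neuron classification with a single assigned
  accumulation level per neuron (argmax over n); population sequence
  analysis (onset-order slopes with permutation nulls), RPE-sign
  classification at trial offset, reward-evoked activity contrasts and
  region-level n-step code summaries.

* **Ground truth** (`rpeacc.synthetic`): a generator of trial-structured
  trajectory sessions (ballistic strokes, planted toward/away errors,
  expectation-scaled anticipatory licking) and neural populations drawn
  from the GLM's own generative form `Poisson(exp(X beta_true))`, so
  every stage of the pipeline is tested against known answers.

## Worked example

Train a small agent and inspect its RPE reorganization over learning:

```python
import numpy as np
from rpeacc import rl_agent, rl_env

arena = rl_env.ArenaConfig()                      # standard schedule
cfg = rl_agent.PpoConfig(n_step=8, episodes=800, seed=0)
record = rl_agent.train_agent(arena, cfg)
summary = rl_agent.summarize_rpes(record)
print({k: round(v, 2) for k, v in summary["naive"].items()})
print({k: round(v, 2) for k, v in summary["expert"].items()})
```

```
{'reward_evoked_rpe': 1.02, 'pre_goal_rpe': 0.03, 'steps_to_goal': 49.58, 'success_rate': 0.31}
{'reward_evoked_rpe': 0.45, 'pre_goal_rpe': -0.21, 'steps_to_goal': 36.58, 'success_rate': 0.66}
```

The naive agent expects nothing: reaching the reward zone evokes a full
positive RPE (~1.0) and erroneous movements evoke none (~0).  The expert
agent has learned the state value: rewards are partially expected
(reward-evoked RPE drops to ~0.4), the agent reaches the zone in fewer
steps, and movements toward the zone that miss it now produce negative
RPEs (~-0.2) — the error signal whose accumulation the encoding pipeline
looks for in neural data.

Generate a synthetic session with planted neurons and run the analysis
pipeline from the shell:

```bash
rpeacc simulate --profile expert --n-trials 20 --n-neurons 100 \
    --seed 1 --out data/
rpeacc analyze --data data/ --seed 1 --out results/
```

which writes a per-neuron classification table
(`neuron_classification.csv`: pseudo-E.V., task-related, error-related,
assigned n) and per-n error statistics.

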