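"""Actor-critic PPO variant with a non-bootstrapped RPE and n-step accumulation.

The agent is a multilayer perceptron (four hidden layers of 256 rectified
units, shared trunk) with a softmax policy head over the 256 discrete
actions and a scalar value head.  Two departures from canonical PPO define
the model:

* the single-step reward prediction error is ``delta = r - V(s)`` — the
  difference between the obtained reward and the estimated value of the
  *current* state, with no bootstrapped next-state value.  It mirrors the
  situation of an animal that expects a reward after every discrete
  movement ("stroke") toward the goal;
* the RPE sequence lives on movement events ("strokes"): toward errors
  and goal entries.  Moves away from the zone are reinitialization and
  are excluded; no-movement steps carry no RPE.  (Both exclusions are
  configurable — see ``PpoConfig.rpe_events``.)

Advantages accumulate up to ``n`` consecutive RPEs of the sequence with
weights ``(gamma*lambda)**k`` (generalized-advantage form), truncated at
trial end.  The critic regresses onto the accumulated estimate
``A_t(n) + V(s_t)``, so reward information propagates backward only over
the n-step horizon — the mechanism that makes learning depend on n (a
within-trial discounted empirical-return target is available as
``PpoConfig.value_target = "mc"``).

Everything runs on a single CPU thread in float32 numpy; training is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import rl_env
from .rl_env import ActionTable, ArenaConfig, TrialState

#: classes for which delta = r - V(s) is defined (away is excluded as
#: reinitialization; the training loop additionally drops "none" under
#: the default strokes-only event policy)
RPE_DEFINED_CLASSES = ("none", "toward_short", "lateral_miss", "goal")
TOWARD_ERROR_CLASSES = ("toward_short", "lateral_miss")


@dataclass(frozen=True)
class PpoConfig:
    """Hyperparameters of the PPO variant.

    Defaults follow the reference configuration: lr 1e-5, gamma 0.95,
    lambda 0.95, clip 0.2, gradient-norm cap 0.4, value-loss coefficient
    0.2, entropy coefficient 0.02, 10 update epochs, 4000 episodes.
    """

    n_step: int = 1
    learning_rate: float = 1e-5
    gamma: float = 0.95
    lam: float = 0.95
    clip_eps: float = 0.2
    max_grad_norm: float = 0.4
    value_loss_coef: float = 0.2
    entropy_coef: float = 0.02
    update_epochs: int = 10
    episodes: int = 4000
    value_target: str = "gae"  # "gae": A + V; "mc": discounted return
    #: which steps carry an RPE: "strokes" restricts the sequence to
    #: movement events (toward errors and goal), mirroring the behavioral
    #: stroke-locked RPEs; "all" also gives no-op steps delta = -V
    rpe_events: str = "strokes"
    #: "episode": one update over all RPE-carrying steps of the episode;
    #: "final_window": only the last n RPE-carrying steps are updated
    update_scope: str = "episode"
    hidden: int = 256
    n_hidden_layers: int = 4
    naive_episodes: int = 100
    expert_fraction: float = 0.1  # final fraction of episodes = expert window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_step < 1:
            raise ValueError("n_step must be >= 1")
        if not 0 < self.clip_eps < 1:
            raise ValueError("clip epsilon must lie in (0, 1)")
        for name in ("learning_rate", "gamma", "lam", "max_grad_norm",
                     "value_loss_coef", "entropy_coef"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


#: hyperparameter grid explored for robustness checks
SWEEP_GRID = {
    "learning_rate": (1e-4, 1e-5, 1e-6),
    "gamma": (0.95, 0.99, 1.0),
    "lam": (0.95, 1.0),
    "value_loss_coef": (0.0, 0.2, 0.4),
    "entropy_coef": (0.0, 0.02, 0.04),
}


def sweep_configs(base: "PpoConfig",
                  grid: Optional[Dict[str, Sequence[float]]] = None
                  ) -> List["PpoConfig"]:
    """One-factor-at-a-time sweep around ``base`` over the grid."""
    grid = grid if grid is not None else SWEEP_GRID
    out: List[PpoConfig] = []
    for key, values in grid.items():
        for v in values:
            if getattr(base, key) != v:
                out.append(replace(base, **{key: v}))
    return out


def single_step_rpe(reward: float, value: float,
                    movement_class: str) -> Optional[float]:
    """``r - V(s)``, or ``None`` for away moves (reinitialization).

    Class ``none`` (no displacement) returns a value here for callers
    that model idle steps; the training loop drops it under the default
    strokes-only event policy.
    """
    if movement_class not in rl_env.MOVEMENT_CLASSES:
        raise ValueError(f"unknown movement class {movement_class!r}")
    if not np.isfinite(value):
        raise ValueError("value estimate must be finite")
    if movement_class in RPE_DEFINED_CLASSES:
        return float(reward) - float(value)
    return None


def accumulate_advantage(deltas: Sequence[float], n: int, gamma: float,
                         lam: float) -> np.ndarray:
    """n-step accumulated advantage over a sequence of included RPEs.

    ``A_t = sum_{k=0}^{min(n-1, T-1-t)} (gamma*lam)**k * delta_{t+k}``,
    truncated at the end of the sequence (trial end).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    d = np.asarray(deltas, dtype=np.float64)
    if d.size == 0:
        raise ValueError("empty RPE trace")
    w = gamma * lam
    adv = np.zeros_like(d)
    for k in range(n):
        if k >= d.size:
            break
        adv[: d.size - k] += (w ** k) * d[k:]
    return adv


# ---------------------------------------------------------------------------
# network


class ActorCritic:
    """MLP with shared trunk, softmax policy head and scalar value head.

    Heads are initialized with small weights so that the initial policy is
    near-uniform and the initial value estimate near zero (a naive agent
    expects nothing).
    """

    def __init__(self, config: PpoConfig, rng: np.random.Generator,
                 n_inputs: int = 2, n_actions: int = rl_env.N_ACTIONS):
        h, L = config.hidden, config.n_hidden_layers
        sizes = [n_inputs] + [h] * L
        shapes = ([(sizes[i], sizes[i + 1]) for i in range(L)]
                  + [(sizes[i + 1],) for i in range(L)]
                  + [(h, n_actions), (n_actions,), (h, 1), (1,)])
        self._shapes = shapes
        self._n_layers = L
        n_total = sum(int(np.prod(s)) for s in shapes)
        # single contiguous parameter buffer; W/b/heads are views into it
        self.theta = np.zeros(n_total, dtype=np.float32)
        self._views = []
        off = 0
        for s in shapes:
            size = int(np.prod(s))
            self._views.append(self.theta[off:off + size].reshape(s))
            off += size
        self.W = self._views[:L]
        self.b = self._views[L:2 * L]
        self.Wp, self.bp, self.Wv, self.bv = self._views[2 * L:]
        for i in range(L):
            scale = np.sqrt(2.0 / sizes[i])  # He init for ReLU
            self.W[i][...] = rng.normal(0, scale, self.W[i].shape)
        head_scale = 0.01
        self.Wp[...] = rng.normal(0, head_scale, self.Wp.shape)
        self.Wv[...] = rng.normal(0, head_scale, self.Wv.shape)
        self._adam_m = np.zeros(n_total, dtype=np.float32)
        self._adam_v = np.zeros(n_total, dtype=np.float32)
        self._adam_t = 0

    def parameters(self) -> List[np.ndarray]:
        return list(self._views)

    def copy(self) -> "ActorCritic":
        import copy
        new = object.__new__(ActorCritic)
        new._shapes = self._shapes
        new._n_layers = self._n_layers
        new.theta = self.theta.copy()
        new._views = []
        off = 0
        for s in self._shapes:
            size = int(np.prod(s))
            new._views.append(new.theta[off:off + size].reshape(s))
            off += size
        L = self._n_layers
        new.W = new._views[:L]
        new.b = new._views[L:2 * L]
        new.Wp, new.bp, new.Wv, new.bv = new._views[2 * L:]
        new._adam_m = self._adam_m.copy()
        new._adam_v = self._adam_v.copy()
        new._adam_t = self._adam_t
        return new

    # forward ---------------------------------------------------------------

    def trunk(self, states: np.ndarray) -> List[np.ndarray]:
        """Hidden activations; last element is the final hidden layer."""
        x = np.asarray(states, dtype=np.float32)
        acts = []
        for W, b in zip(self.W, self.b):
            x = np.maximum(x @ W + b, 0.0)
            acts.append(x)
        return acts

    def forward(self, states: np.ndarray):
        """Return (log-probs, values, final-hidden activations)."""
        acts = self.trunk(np.atleast_2d(states))
        h = acts[-1]
        logits = h @ self.Wp + self.bp
        logits = logits - logits.max(axis=1, keepdims=True)
        logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        values = (h @ self.Wv + self.bv)[:, 0]
        return logp, values, h

    def policy_value(self, state: np.ndarray):
        logp, v, _ = self.forward(state[None, :])
        return logp[0], float(v[0])

    # update ----------------------------------------------------------------

    def _adam_step(self, grads: List[np.ndarray], lr: float,
                   max_norm: float) -> None:
        g = np.concatenate([np.ravel(a) for a in grads], dtype=np.float32)
        total = float(np.sqrt(np.vdot(g, g)))
        if max_norm > 0 and total > max_norm:
            g *= np.float32(max_norm / (total + 1e-12))
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        m, v = self._adam_m, self._adam_v
        m *= np.float32(b1)
        m += np.float32(1 - b1) * g
        v *= np.float32(b2)
        g *= g
        v += np.float32(1 - b2) * g
        buf = g  # reuse as scratch
        np.divide(v, np.float32(1 - b2 ** t), out=buf)
        np.sqrt(buf, out=buf)
        buf += np.float32(eps)
        np.divide(m, buf, out=buf)
        buf *= np.float32(lr / (1 - b1 ** t))
        self.theta -= buf

    def update(self, states: np.ndarray, actions: np.ndarray,
               logp_old: np.ndarray, advantages: np.ndarray,
               returns: np.ndarray, config: PpoConfig) -> Dict[str, float]:
        """One clipped-surrogate gradient step; returns the loss components."""
        B = states.shape[0]
        x = np.asarray(states, dtype=np.float32)
        actions = np.asarray(actions)
        logp_old = np.asarray(logp_old, dtype=np.float32)
        advantages = np.asarray(advantages, dtype=np.float32)
        returns = np.asarray(returns, dtype=np.float32)
        acts = []
        pre = []
        cur = x
        for W, b in zip(self.W, self.b):
            z = cur @ W + b
            pre.append(z)
            cur = np.maximum(z, 0.0)
            acts.append(cur)
        h = acts[-1]
        logits = h @ self.Wp + self.bp
        logits = logits - logits.max(axis=1, keepdims=True)
        lse = np.log(np.exp(logits).sum(axis=1, keepdims=True))
        logp = logits - lse
        p = np.exp(logp)
        values = (h @ self.Wv + self.bv)[:, 0]

        idx = np.arange(B)
        logp_a = logp[idx, actions]
        ratio = np.exp(logp_a - logp_old)
        eps = config.clip_eps
        t1 = ratio * advantages
        t2 = np.clip(ratio, 1 - eps, 1 + eps) * advantages
        policy_loss = -np.minimum(t1, t2).mean()

        value_err = values - returns
        value_loss = float((value_err ** 2).mean())
        H = -(p * logp).sum(axis=1)
        entropy = float(H.mean())
        total = (policy_loss + config.value_loss_coef * value_loss
                 - config.entropy_coef * entropy)
        if not np.isfinite(total):
            raise FloatingPointError("non-finite PPO loss")

        # gradient wrt logits: clipped surrogate + entropy bonus
        grad_r = np.where(t1 <= t2, advantages, 0.0) * (-1.0 / B)
        g_logp_a = grad_r * ratio
        gz = g_logp_a[:, None] * (-p)
        gz[idx, actions] += g_logp_a
        gz += (config.entropy_coef / B) * p * (logp + H[:, None])
        gz = gz.astype(np.float32)
        # gradient wrt value head
        gv = (config.value_loss_coef * 2.0 / B) * value_err
        gv = gv.astype(np.float32)[:, None]

        gWp = h.T @ gz
        gbp = gz.sum(axis=0)
        gWv = h.T @ gv
        gbv = gv.sum(axis=0)
        gh = gz @ self.Wp.T + gv @ self.Wv.T

        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gzi = gh * (pre[i] > 0)
            inp = x if i == 0 else acts[i - 1]
            gW[i] = inp.T @ gzi
            gb[i] = gzi.sum(axis=0)
            gh = gzi @ self.W[i].T
        grads = gW + gb + [gWp, gbp, gWv, gbv]
        self._adam_step(grads, config.learning_rate, config.max_grad_norm)
        return {"policy_loss": float(policy_loss),
                "value_loss": value_loss, "entropy": entropy,
                "total_loss": float(total)}


def ppo_update(agent: ActorCritic, batch: Dict[str, np.ndarray],
               config: PpoConfig) -> Dict[str, float]:
    """Run ``config.update_epochs`` clipped-surrogate steps on one batch."""
    losses: Dict[str, float] = {}
    for _ in range(config.update_epochs):
        losses = agent.update(batch["states"], batch["actions"],
                              batch["logp_old"], batch["advantages"],
                              batch["returns"], config)
    return losses


# ---------------------------------------------------------------------------
# rollout and training


def _sample_action(logp: np.ndarray, rng: np.random.Generator) -> int:
    p = np.exp(logp.astype(np.float64))
    cdf = np.cumsum(p)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))


@dataclass
class EpisodeResult:
    steps: int
    success: bool
    reward: float
    goal_rpe: float           # delta at the goal step (nan if never reached)
    goal_value: float         # V(s) at the state preceding the goal entry
    goal_side: str            # "high"/"low" under split, "" otherwise
    rewarded: bool            # interleaved reward assignment of this trial
    pre_goal_rpes: np.ndarray  # deltas at toward errors
    pre_goal_sides: List[str]  # arena half of each toward error (split)
    batch: Optional[Dict[str, np.ndarray]] = None


def run_episode(agent: ActorCritic, arena: ArenaConfig, table: ActionTable,
                config: PpoConfig, rng: np.random.Generator,
                collect: bool = True) -> EpisodeResult:
    trial = TrialState()
    pos = rl_env.reset(arena, rng, trial)
    inc_states: List[np.ndarray] = []
    inc_actions: List[int] = []
    inc_logp: List[float] = []
    inc_deltas: List[float] = []
    inc_values: List[float] = []
    inc_env_step: List[int] = []
    pre_goal: List[float] = []
    pre_sides: List[str] = []
    goal_rpe = np.nan
    goal_value = np.nan
    goal_side = ""
    terminal_reward = 0.0
    terminal_step = -1
    success = False
    t = 0
    while True:
        logp, value = agent.policy_value(pos.astype(np.float32))
        a = _sample_action(logp, rng)
        tr = rl_env.step(pos, a, arena, trial, table)
        delta = single_step_rpe(tr.reward, value, tr.movement_class)
        if (delta is not None and config.rpe_events == "strokes"
                and tr.movement_class == "none"):
            delta = None
        if delta is not None:
            inc_states.append(pos.copy())
            inc_actions.append(a)
            inc_logp.append(float(logp[a]))
            inc_deltas.append(delta)
            inc_values.append(value)
            inc_env_step.append(t)
            if tr.movement_class == "goal":
                goal_rpe = delta
                goal_value = value
                goal_side = "low" if tr.next_pos[0] < 0 else "high"
            elif tr.movement_class in TOWARD_ERROR_CLASSES:
                pre_goal.append(delta)
                pre_sides.append("low" if pos[0] < 0 else "high")
        pos = tr.next_pos
        t += 1
        if tr.terminal:
            success = tr.movement_class == "goal"
            terminal_reward = tr.reward
            terminal_step = t - 1
            break
    batch = None
    if collect and inc_deltas:
        if config.update_scope == "final_window":
            # only the last n RPE-carrying steps before termination are
            # updated: credit reaches back at most n steps per episode,
            # which is what makes learning speed depend on n
            lo = max(len(inc_deltas) - config.n_step, 0)
        else:
            lo = 0
        deltas = inc_deltas[lo:]
        adv = accumulate_advantage(deltas, config.n_step,
                                   config.gamma, config.lam)
        if config.value_target == "gae":
            returns = adv + np.asarray(inc_values[lo:], dtype=np.float64)
        else:  # within-trial discounted empirical (Monte Carlo) return
            env_steps = np.asarray(inc_env_step[lo:])
            returns = terminal_reward * config.gamma ** (
                terminal_step - env_steps)
        batch = {
            "states": np.asarray(inc_states[lo:], dtype=np.float32),
            "actions": np.asarray(inc_actions[lo:], dtype=np.int64),
            "logp_old": np.asarray(inc_logp[lo:], dtype=np.float64),
            "advantages": adv,
            "returns": returns.astype(np.float64),
        }
    return EpisodeResult(steps=t, success=success, reward=float(terminal_reward),
                         goal_rpe=float(goal_rpe), goal_value=float(goal_value),
                         goal_side=goal_side, rewarded=trial.rewarded,
                         pre_goal_rpes=np.asarray(pre_goal, dtype=np.float64),
                         pre_goal_sides=pre_sides, batch=batch)


@dataclass
class TrainingRecord:
    """Per-episode training history plus naive/expert snapshots."""

    arena: ArenaConfig
    config: PpoConfig
    steps: np.ndarray
    success: np.ndarray
    reward: np.ndarray
    goal_rpe: np.ndarray
    goal_value: np.ndarray
    goal_side: List[str]
    rewarded: np.ndarray
    pre_goal_rpe_mean: np.ndarray
    pre_goal_rpes: List[np.ndarray]
    pre_goal_sides: List[List[str]]
    naive: "TrainingRecord | None"
    naive_params: Optional[ActorCritic]
    final_params: Optional[ActorCritic]

    @property
    def expert_window(self) -> slice:
        n = len(self.steps)
        start = int(round(n * (1.0 - self.config.expert_fraction)))
        return slice(min(start, n - 1), n)


def _collect_record(arena, config, episodes_iter) -> Dict[str, list]:
    out = {k: [] for k in ("steps", "success", "reward", "goal_rpe",
                           "goal_value", "goal_side", "rewarded",
                           "pre_goal_rpe_mean", "pre_goal_rpes",
                           "pre_goal_sides")}
    for ep in episodes_iter:
        out["steps"].append(ep.steps)
        out["success"].append(ep.success)
        out["reward"].append(ep.reward)
        out["goal_rpe"].append(ep.goal_rpe)
        out["goal_value"].append(ep.goal_value)
        out["goal_side"].append(ep.goal_side)
        out["rewarded"].append(ep.rewarded)
        out["pre_goal_rpe_mean"].append(
            float(np.mean(ep.pre_goal_rpes)) if ep.pre_goal_rpes.size
            else np.nan)
        out["pre_goal_rpes"].append(ep.pre_goal_rpes)
        out["pre_goal_sides"].append(ep.pre_goal_sides)
    return out


def _finalize_record(arena, config, data, naive=None, naive_params=None,
                     final_params=None) -> TrainingRecord:
    return TrainingRecord(
        arena=arena, config=config,
        steps=np.asarray(data["steps"]),
        success=np.asarray(data["success"], dtype=bool),
        reward=np.asarray(data["reward"]),
        goal_rpe=np.asarray(data["goal_rpe"]),
        goal_value=np.asarray(data["goal_value"]),
        goal_side=data["goal_side"],
        rewarded=np.asarray(data["rewarded"], dtype=bool),
        pre_goal_rpe_mean=np.asarray(data["pre_goal_rpe_mean"]),
        pre_goal_rpes=data["pre_goal_rpes"],
        pre_goal_sides=data["pre_goal_sides"],
        naive=naive, naive_params=naive_params, final_params=final_params)


def train_agent(arena: ArenaConfig, config: PpoConfig,
                keep_params: bool = True) -> TrainingRecord:
    """Train one agent; returns the full per-episode record.

    The naive snapshot (``record.naive``) holds ``config.naive_episodes``
    evaluation episodes run with the initial parameters before any
    gradient step.
    """
    rng = np.random.default_rng(config.seed)
    table = rl_env.build_action_table()
    agent = ActorCritic(config, rng)
    naive_params = agent.copy() if keep_params else None

    naive_eps = [run_episode(agent, arena, table, config, rng, collect=False)
                 for _ in range(config.naive_episodes)]
    naive_rec = _finalize_record(arena, config,
                                 _collect_record(arena, config, naive_eps))

    def training_iter():
        for ep_idx in range(config.episodes):
            ep = run_episode(agent, arena, table, config, rng, collect=True)
            if ep.batch is not None:
                try:
                    ppo_update(agent, ep.batch, config)
                except FloatingPointError as exc:
                    raise FloatingPointError(
                        f"training diverged at episode {ep_idx}") from exc
            yield ep

    data = _collect_record(arena, config, training_iter())
    return _finalize_record(arena, config, data, naive=naive_rec,
                            naive_params=naive_params,
                            final_params=agent if keep_params else None)


# ---------------------------------------------------------------------------
# agent analysis


def value_map(agent: ActorCritic, n_samples: int = 100_000,
              rng: Optional[np.random.Generator] = None,
              bins: int = 40) -> Dict[str, np.ndarray]:
    """Mean critic output over uniformly sampled states, binned bins x bins.

    Empty bins are NaN (recorded as missing, not zero).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    states = rng.uniform(-1.0, 1.0, size=(n_samples, 2)).astype(np.float32)
    values = np.empty(n_samples)
    for i in range(0, n_samples, 8192):
        _, v, _ = agent.forward(states[i:i + 8192])
        values[i:i + 8192] = v
    edges = np.linspace(-1.0, 1.0, bins + 1)
    counts, _, _ = np.histogram2d(states[:, 0], states[:, 1], bins=[edges, edges])
    sums, _, _ = np.histogram2d(states[:, 0], states[:, 1], bins=[edges, edges],
                                weights=values)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return {"mean": mean, "counts": counts, "edges": edges}


def unit_tuning(agent: ActorCritic, arena: ArenaConfig,
                config: PpoConfig, rng: np.random.Generator,
                n_episodes: int = 20, bins: int = 40) -> Dict[str, np.ndarray]:
    """Spatial and direction tuning of final-hidden-layer units.

    Spatial maps evaluate each unit's activation on a bins x bins grid of
    states; direction profiles average the unit activity over rollout
    steps grouped by the direction of the sampled action (8 directions).
    """
    centers = (np.linspace(-1, 1, bins + 1)[:-1]
               + np.linspace(-1, 1, bins + 1)[1:]) / 2
    gx, gy = np.meshgrid(centers, centers, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(np.float32)
    _, _, h = agent.forward(grid)
    spatial = h.T.reshape(-1, bins, bins)

    table = rl_env.build_action_table()
    acts: List[np.ndarray] = []
    dirs: List[float] = []
    for _ in range(n_episodes):
        trial = TrialState()
        pos = rl_env.reset(arena, rng, trial)
        while True:
            logp, _, hh = agent.forward(pos[None, :].astype(np.float32))
            a = _sample_action(logp[0], rng)
            tr = rl_env.step(pos, a, arena, trial, table)
            if table.direction_deg[a] >= 0:
                acts.append(hh[0])
                dirs.append(table.direction_deg[a])
            pos = tr.next_pos
            if tr.terminal:
                break
    direction = np.full((spatial.shape[0], 8), np.nan)
    if acts:
        A = np.asarray(acts)
        D = np.asarray(dirs)
        for d, ang in enumerate(rl_env.DIRECTIONS_DEG):
            mask = D == ang
            if mask.any():
                direction[:, d] = A[mask].mean(axis=0)
    return {"spatial": spatial, "direction": direction}


def _nanmean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    return float(x[ok].mean()) if ok.any() else float("nan")


def _window_stats(rec: TrainingRecord, window: slice) -> Dict[str, float]:
    return {
        "reward_evoked_rpe": _nanmean(rec.goal_rpe[window]),
        "pre_goal_rpe": _nanmean(rec.pre_goal_rpe_mean[window]),
        "steps_to_goal": float(np.mean(rec.steps[window])),
        "success_rate": float(np.mean(rec.success[window])),
    }


def summarize_rpes(record: TrainingRecord) -> Dict[str, Dict[str, float]]:
    """Naive/expert RPE summaries, with schedule-specific breakdowns.

    For the interleaved schedule the expert summary separates rewarded
    (positive RPE) from omitted trials, where the omission RPE equals
    ``-V`` at the goal state.  For the split schedule RPEs are stratified
    by arena half.
    """
    if record.naive is None:
        raise ValueError("record has no naive snapshot")
    if not np.any(np.isfinite(record.goal_rpe)):
        return {"undefined": {"reason": float("nan")}}
    out = {
        "naive": _window_stats(record.naive, slice(None)),
        "expert": _window_stats(record, record.expert_window),
    }
    sched = record.arena.schedule
    w = record.expert_window
    if sched == "interleaved":
        goal = record.goal_rpe[w]
        rew = record.rewarded[w]
        finite = np.isfinite(goal)
        out["expert"]["rewarded_rpe"] = _nanmean(goal[finite & rew])
        out["expert"]["omission_rpe"] = _nanmean(goal[finite & ~rew])
        out["expert"]["omission_value"] = _nanmean(
            record.goal_value[w][finite & ~rew])
    if sched == "split":
        goal = record.goal_rpe[w]
        sides = np.asarray(record.goal_side[w], dtype=object)
        for side in ("high", "low"):
            mask = (sides == side) & np.isfinite(goal)
            out["expert"][f"reward_rpe_{side}"] = (
                float(goal[mask].mean()) if mask.any() else float("nan"))
        pre_vals = {"high": [], "low": []}
        for rpes, ss in zip(record.pre_goal_rpes[w],
                            record.pre_goal_sides[w]):
            for v, s in zip(rpes, ss):
                pre_vals[s].append(v)
        for side in ("high", "low"):
            vals = pre_vals[side]
            out["expert"][f"pre_goal_rpe_{side}"] = (
                float(np.mean(vals)) if vals else float("nan"))
    return out
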