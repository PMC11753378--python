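"""Synthetic behavioral sessions and neural populations with ground truth.

No public recording accompanies the mouse experiments, so every analysis
stage is exercised on generated data with planted structure:

* **sessions** — trial-structured 10-ms object/joystick trajectories made
  of ballistic stroke-like bursts (> 60 mm/s peak speed).  Each trial
  plants a configured number of toward errors (approaches stopping short
  of the reward zone), occasional away moves (reinitializations), and a
  final goal stroke; anticipatory lick bursts
  follow toward errors with a probability scaled by a reward-expectation
  parameter (naive-like low, expert-like high, interleaved intermediate);
* **neurons** — nonnegative deconvolved-style traces drawn as scaled
  Poisson counts with rate ``exp(offset + X beta_true)``, where X is the
  very design matrix the encoding stage builds from the session and
  ``beta_true`` is supported on one planted predictor group (an n-step
  error, a velocity direction, the time ramp) or empty (noise neurons).
  Reward/omission-tuned neurons get their event kernels injected directly
  at trial offsets.

Defaults mirror the study conditions: up to 60 trials per session (120
interleaved), 10-ms trajectory sampling, ~5.67 Hz imaging rate, arena
100 x 100 mm with a centered 40 x 40 mm reward zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import behavior, encoding_glm
from .behavior import ARENA_HALF, DT, ZONE_HALF, TrajectorySession
from .encoding_glm import FRAME_RATE


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one generated session."""

    schedule: str = "standard"
    n_trials: int = 60                  # 120 under the interleaved schedule
    mean_toward_errors: float = 4.0     # per-trial Poisson mean (naive ~4)
    mean_away_moves: float = 0.7
    completion_prob: float = 0.95
    reward_expectation: float = 0.8     # scales anticipatory lick probability
    lick_burst_rate: float = 8.0        # Hz within a burst
    inter_stroke_s: Tuple[float, float] = (0.6, 1.4)
    stroke_duration_s: Tuple[float, float] = (0.2, 0.4)
    reward_period_s: float = 4.0
    iti_s: float = 2.0
    position_jitter_mm: float = 0.08    # per-sample Gaussian noise
    frame_rate: float = FRAME_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.stroke_duration_s[0] <= 0:
            raise ValueError("stroke duration must be positive")
        if not 0 <= self.reward_expectation <= 1:
            raise ValueError("reward expectation must lie in [0, 1]")


def naive_config(**kw) -> SynthConfig:
    """Naive-like profile: frequent errors, weak reward expectation."""
    kw.setdefault("mean_toward_errors", 4.0)
    kw.setdefault("completion_prob", 0.6)
    kw.setdefault("reward_expectation", 0.2)
    return SynthConfig(**kw)


def expert_config(**kw) -> SynthConfig:
    """Expert-like profile: few errors, strong reward expectation."""
    kw.setdefault("mean_toward_errors", 1.2)
    kw.setdefault("completion_prob", 0.999)
    kw.setdefault("reward_expectation", 0.9)
    return SynthConfig(**kw)


def ir_config(**kw) -> SynthConfig:
    """Interleaved-reward profile: expert behavior, lower expectation."""
    kw.setdefault("schedule", "interleaved")
    kw.setdefault("n_trials", 120)
    kw.setdefault("mean_toward_errors", 1.2)
    kw.setdefault("completion_prob", 0.999)
    kw.setdefault("reward_expectation", 0.5)
    return SynthConfig(**kw)


def split_config(**kw) -> SynthConfig:
    kw.setdefault("schedule", "split")
    kw.setdefault("mean_toward_errors", 1.5)
    kw.setdefault("completion_prob", 0.999)
    kw.setdefault("reward_expectation", 0.9)
    return SynthConfig(**kw)


@dataclass
class GroundTruth:
    """Planted events and neuron identities of one synthetic dataset."""

    toward_times: pd.DataFrame          # trial, time, side, nth
    away_times: pd.DataFrame            # trial, time
    stroke_times: List[float]
    neuron_types: List[str] = field(default_factory=list)
    neuron_params: List[dict] = field(default_factory=list)
    true_beta: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# trajectory synthesis


def _smoothstep_profile(n: int) -> np.ndarray:
    """Bell-shaped normalized displacement increments over n samples."""
    x = np.linspace(0, np.pi, n)
    w = np.sin(x) ** 2
    return w / w.sum()


def _ballistic(p0: np.ndarray, p1: np.ndarray, duration_s: float,
               rng: np.random.Generator) -> np.ndarray:
    """Positions (excluding p0) of a smooth stroke from p0 to p1."""
    n = max(int(round(duration_s / DT)), 4)
    inc = _smoothstep_profile(n)[:, None] * (p1 - p0)[None, :]
    return p0 + np.cumsum(inc, axis=0)


def _random_outside_zone(rng: np.random.Generator,
                         min_margin: float = 18.0) -> np.ndarray:
    while True:
        p = rng.uniform(-ARENA_HALF + 2, ARENA_HALF - 2, size=2)
        if np.max(np.abs(p)) > ZONE_HALF + min_margin:
            return p


def _toward_stop_short(p0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Target strictly outside the zone along the ray to the center."""
    d0 = np.linalg.norm(p0)
    stop = ZONE_HALF * np.sqrt(2) + rng.uniform(4.0, 12.0)
    stop = min(stop, d0 - 8.0)  # radial excursion >= 8 mm, detectable
    if stop <= 0:
        stop = d0 * 0.5
    target = p0 * (stop / d0)
    # keep it outside the square zone
    if np.max(np.abs(target)) <= ZONE_HALF:
        target = target * (ZONE_HALF + 4.0) / max(np.max(np.abs(target)), 1e-6)
    return target


def _away_target(p0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    d0 = np.linalg.norm(p0)
    scale = rng.uniform(1.3, 1.8)
    target = p0 * scale
    return np.clip(target, -ARENA_HALF + 1, ARENA_HALF - 1)


def generate_session(config: SynthConfig
                     ) -> Tuple[TrajectorySession, GroundTruth]:
    """Generate one trial-structured session with planted events."""
    rng = np.random.default_rng(config.seed)
    traj_rows: List[np.ndarray] = []
    joy_rows: List[np.ndarray] = []
    trial_col: List[int] = []
    lick_times: List[float] = []
    trial_rows: List[dict] = []
    toward_rows: List[dict] = []
    away_rows: List[dict] = []
    strokes: List[float] = []

    t = 0.0
    for trial in range(config.n_trials):
        t_start = t
        pos = _random_outside_zone(rng)
        seg_positions: List[np.ndarray] = [pos.copy()]
        seg_events: List[Tuple[str, int, str]] = []  # (kind, sample idx, side)
        n_err = int(rng.poisson(config.mean_toward_errors))
        n_away = int(rng.poisson(config.mean_away_moves))
        completed = bool(rng.random() < config.completion_prob)
        moves: List[str] = ["toward"] * n_err + ["away"] * n_away
        rng.shuffle(moves)
        if completed:
            moves.append("goal")
        if not moves:
            moves = ["away"]  # a trial needs at least one movement
        for kind in moves:
            # stationary dwell before the stroke
            dwell = rng.uniform(*config.inter_stroke_s)
            n_dwell = int(round(dwell / DT))
            seg_positions.extend([pos.copy()] * n_dwell)
            dur = rng.uniform(*config.stroke_duration_s)
            if kind == "toward":
                target = _toward_stop_short(pos, rng)
            elif kind == "away":
                target = _away_target(pos, rng)
            else:
                jig = rng.uniform(-ZONE_HALF * 0.5, ZONE_HALF * 0.5, 2)
                if config.schedule == "split":
                    # aim at the side the trial will be rewarded on
                    side_x = rng.choice([-1.0, 1.0])
                    jig[0] = side_x * rng.uniform(2.0, ZONE_HALF * 0.6)
                target = jig
            # fast ballistic strokes: sharp radial-speed peaks well above
            # the 60 mm/s detection threshold, robust to positional noise
            radial_change = abs(np.linalg.norm(target)
                                - np.linalg.norm(pos))
            dur = float(np.clip(radial_change / 150.0, 0.05, 0.25))
            path = _ballistic(pos, target, dur, rng)
            seg_positions.extend(list(path))
            peak_idx = len(seg_positions) - len(path) // 2
            side = "high" if pos[0] >= 0 else "low"
            seg_events.append((kind, peak_idx, side))
            pos = target
            if kind == "toward":
                # slow sub-threshold glide back outward so the next stroke
                # again has a detectable radial excursion (peak < 60 mm/s)
                radius = float(np.linalg.norm(pos))
                out_r = rng.uniform(36.0, 46.0)
                if radius < out_r:
                    back = pos * (out_r / max(radius, 1e-6))
                    back = np.clip(back, -ARENA_HALF + 1, ARENA_HALF - 1)
                    dist = abs(np.linalg.norm(back) - radius)
                    glide = _ballistic(pos, back, max(dist / 15.0, 0.3), rng)
                    seg_positions.extend(list(glide))
                    pos = back
        xy = np.asarray(seg_positions)
        xy = xy + rng.normal(0, config.position_jitter_mm, xy.shape)
        times = t_start + np.arange(len(xy)) * DT
        count = 0
        for kind, idx, side in seg_events:
            ev_t = float(times[min(idx, len(times) - 1)])
            if kind == "toward":
                count += 1
                toward_rows.append({"trial": trial, "time": ev_t,
                                    "side": side, "nth": count})
                strokes.append(ev_t)
                if rng.random() < config.reward_expectation:
                    burst_t = ev_t + rng.uniform(0.1, 0.2)
                    n_licks = rng.integers(2, 6)
                    lick_times.extend(
                        burst_t + np.arange(n_licks) / config.lick_burst_rate)
            elif kind == "away":
                away_rows.append({"trial": trial, "time": ev_t})
                strokes.append(ev_t)
            else:
                strokes.append(ev_t)
        t_end = float(times[-1])
        rewarded = False
        reward_size = 0.0
        if completed:
            if config.schedule == "standard":
                rewarded, reward_size = True, 1.0
            elif config.schedule == "interleaved":
                rewarded = bool(rng.random() < 0.5)
                reward_size = 1.0 if rewarded else 0.0
            else:  # split: side of the final position
                rewarded = True
                reward_size = 1.25 if xy[-1, 0] >= 0 else 0.125
            if rewarded:
                lick_times.extend(t_end + 0.2
                                  + np.arange(6) / config.lick_burst_rate)
        trial_rows.append({"trial": trial, "t_start": t_start,
                           "t_end": t_end, "completed": completed,
                           "rewarded": rewarded, "reward_size": reward_size})
        traj_rows.append(xy)
        trial_col.extend([trial] * len(xy))
        # joystick mirrors the object with gain noise
        joy = xy * rng.uniform(0.9, 1.1) + rng.normal(
            0, config.position_jitter_mm, xy.shape)
        joy_rows.append(joy)
        # reward-consumption period + ITI: hold position (not part of trial)
        pause = config.reward_period_s + config.iti_s
        n_pause = int(round(pause / DT))
        hold = np.tile(xy[-1], (n_pause, 1)) + rng.normal(
            0, config.position_jitter_mm, (n_pause, 2))
        traj_rows.append(hold)
        joy_rows.append(hold.copy())
        trial_col.extend([-1] * n_pause)  # -1 marks the intertrial interval
        t = t_end + DT + pause * 1.0

    xy_all = np.concatenate(traj_rows)
    joy_all = np.concatenate(joy_rows)
    t_all = np.arange(len(xy_all)) * DT
    # re-anchor trial times onto the uniform grid
    trial_arr = np.asarray(trial_col)
    for row in trial_rows:
        mask = trial_arr == row["trial"]
        idx = np.where(mask)[0]
        row["t_start"], row["t_end"] = float(t_all[idx[0]]), float(t_all[idx[-1]])
    # planted event times were generated on the same running clock as the
    # concatenated grid (pauses included), so they match up to float error
    trajectory = pd.DataFrame({"t": t_all, "x": xy_all[:, 0],
                               "y": xy_all[:, 1], "trial": trial_arr})
    joystick = pd.DataFrame({"t": t_all, "x": joy_all[:, 0],
                             "y": joy_all[:, 1], "trial": trial_arr})
    session = TrajectorySession(
        trajectory=trajectory[trajectory["trial"] >= 0].reset_index(drop=True),
        joystick=joystick[joystick["trial"] >= 0].reset_index(drop=True),
        licks=np.asarray(sorted(lick_times)),
        trials=pd.DataFrame(trial_rows),
        schedule=config.schedule)
    truth = GroundTruth(
        toward_times=pd.DataFrame(toward_rows,
                                  columns=["trial", "time", "side", "nth"]),
        away_times=pd.DataFrame(away_rows, columns=["trial", "time"]),
        stroke_times=sorted(strokes))
    return session, truth


# ---------------------------------------------------------------------------
# neural populations


@dataclass(frozen=True)
class PopulationSpec:
    """Counts per planted neuron type and response magnitudes.

    The default composition totals 500 neurons: 240 error-tuned (40 per
    accumulation level), 120 velocity-tuned, 40 time-ramp, 100 noise.
    """

    n_per_error_step: int = 40     # per n = 1..6
    n_object_velocity: int = 60
    n_joystick_velocity: int = 60
    n_time: int = 40
    n_reward: int = 0              # direct reward-locked neurons
    n_omission: int = 0            # omission-locked (interleaved sessions)
    n_noise: int = 100
    kernel_gain: float = 2.0       # log-rate bump at the planted event
    baseline_rate: float = 1.0     # counts per frame
    trace_scale: float = 12.0      # deconvolved-units per count
    regions: Sequence[str] = ("M1", "M2", "S1", "PPC", "RSC")


def _planted_beta(dm: encoding_glm.DesignMatrix, group: str, gain: float,
                  rng: np.random.Generator) -> np.ndarray:
    """True coefficients on one group, shaped as a smooth causal kernel.

    The gain is expressed as the desired log-rate excursion at the event;
    coefficients are scaled by the column standard deviation implicitly
    (the design matrix is z-scored, so we normalize by each column's
    per-unit response)."""
    beta = np.zeros(dm.n_columns)
    cols = dm.columns_of(group)
    # weight the 6 bases with an asymmetric bump peaking just after 0
    w = np.array([0.05, 0.15, 0.5, 1.0, 0.45, 0.1])[: len(cols)]
    col_peak = np.abs(dm.X[:, cols]).max(axis=0)
    beta[cols] = gain * w / np.maximum(col_peak, 1e-3)
    return beta


def generate_neurons(session: TrajectorySession, spec: PopulationSpec,
                     config: SynthConfig,
                     dm: Optional[encoding_glm.DesignMatrix] = None
                     ) -> Tuple[np.ndarray, GroundTruth, encoding_glm.DesignMatrix]:
    """Draw a population of traces with rate ``exp(offset + X beta_true)``.

    Returns (traces (neurons x frames), ground truth, design matrix).
    """
    rng = np.random.default_rng(config.seed + 7919)
    if dm is None:
        ev = behavior.detect_errors(session)
        dm = encoding_glm.build_design_matrix(ev, session, variant=(
            "modified" if config.schedule == "split" else "standard"))
    F = dm.X.shape[0]
    types: List[str] = []
    betas: List[np.ndarray] = []
    extra: List[np.ndarray] = []  # direct log-rate injections (reward/omission)

    error_labels = sorted({g.split(":")[1] for g in dm.groups
                           if g.startswith("error:")})
    for lab in error_labels:
        for _ in range(spec.n_per_error_step):
            types.append(f"error_{lab}")
            betas.append(_planted_beta(dm, f"error:{lab}", spec.kernel_gain,
                                       rng))
            extra.append(np.zeros(F))
    for _ in range(spec.n_object_velocity):
        d = int(rng.integers(0, 8))
        types.append(f"object_velocity_d{d}")
        betas.append(_planted_beta(dm, f"object_velocity:d{d}",
                                   spec.kernel_gain, rng))
        extra.append(np.zeros(F))
    for _ in range(spec.n_joystick_velocity):
        d = int(rng.integers(0, 8))
        types.append(f"joystick_velocity_d{d}")
        betas.append(_planted_beta(dm, f"joystick_velocity:d{d}",
                                   spec.kernel_gain, rng))
        extra.append(np.zeros(F))
    for _ in range(spec.n_time):
        types.append("time")
        betas.append(_planted_beta(dm, "time", spec.kernel_gain * 0.5, rng))
        extra.append(np.zeros(F))

    def _event_injection(times: np.ndarray) -> np.ndarray:
        inj = np.zeros(F)
        kern = np.exp(-np.arange(0, 12) / 3.0)
        for ev_t in times:
            i = int(np.searchsorted(dm.frame_times, ev_t))
            hi = min(i + len(kern), F)
            if i < F:
                inj[i:hi] += spec.kernel_gain * kern[: hi - i]
        return inj

    offsets = session.trials.loc[session.trials["completed"], "t_end"]
    rewarded_off = session.trials.loc[
        session.trials["completed"] & session.trials["rewarded"], "t_end"]
    omitted_off = session.trials.loc[
        session.trials["completed"] & ~session.trials["rewarded"], "t_end"]
    for _ in range(spec.n_reward):
        types.append("reward")
        betas.append(np.zeros(dm.n_columns))
        extra.append(_event_injection(rewarded_off.to_numpy()))
    for _ in range(spec.n_omission):
        types.append("omission")
        betas.append(np.zeros(dm.n_columns))
        extra.append(_event_injection(omitted_off.to_numpy()))
    for _ in range(spec.n_noise):
        types.append("noise")
        betas.append(np.zeros(dm.n_columns))
        extra.append(np.zeros(F))

    N = len(types)
    B = np.stack(betas, axis=1)
    log_rate = (np.log(spec.baseline_rate) + dm.X @ B
                + np.stack(extra, axis=1))
    rate = np.exp(np.clip(log_rate, -10, 8))
    traces = rng.poisson(rate).astype(float) * spec.trace_scale
    truth = GroundTruth(toward_times=pd.DataFrame(
        columns=["trial", "time", "side", "nth"]),
        away_times=pd.DataFrame(columns=["trial", "time"]),
        stroke_times=[], neuron_types=types,
        neuron_params=[{"type": ty} for ty in types], true_beta=B)
    return traces.T, truth, dm


def assign_regions(types: Sequence[str], spec: PopulationSpec,
                   rng: np.random.Generator,
                   bias: Optional[Dict[str, str]] = None) -> List[str]:
    """Random region labels, optionally biasing a neuron type to a region."""
    regions = list(spec.regions)
    out = []
    for ty in types:
        if bias:
            for prefix, reg in bias.items():
                if ty.startswith(prefix) and rng.random() < 0.8:
                    out.append(reg)
                    break
            else:
                out.append(regions[int(rng.integers(0, len(regions)))])
        else:
            out.append(regions[int(rng.integers(0, len(regions)))])
    return out


def generate_sequence_population(n_neurons: int = 30, n_trials: int = 20,
                                 trial_len: int = 60,
                                 jitter_frames: int = 2,
                                 onset_spacing: int = 2,
                                 amplitude: float = 5.0,
                                 noise_sd: float = 0.05,
                                 shuffle_order: bool = False,
                                 seed: int = 0
                                 ) -> Tuple[np.ndarray, List[np.ndarray],
                                            np.ndarray]:
    """Population with a planted within-trial activation order.

    Neuron k activates ``onset_spacing`` frames after neuron k-1 in every
    trial (plus per-trial jitter); with ``shuffle_order`` the order is
    redrawn each trial (no consistent sequence — the null case).  Returns
    (activity (neurons x frames), per-trial frame indices, true order).
    """
    rng = np.random.default_rng(seed)
    frames = n_trials * trial_len
    act = np.zeros((n_neurons, frames))
    trial_frames = []
    order = np.arange(n_neurons)
    for tr in range(n_trials):
        base = tr * trial_len
        trial_frames.append(np.arange(base, base + trial_len))
        this_order = order.copy()
        if shuffle_order:
            rng.shuffle(this_order)
        for rank, neuron in enumerate(this_order):
            onset = 2 + rank * onset_spacing
            if jitter_frames:
                onset += int(rng.integers(-jitter_frames, jitter_frames + 1))
            onset = max(onset, 0)
            if onset < trial_len - 1:
                stop = min(onset + 3, trial_len)
                act[neuron, base + onset: base + stop] = amplitude
    act = np.abs(act + rng.normal(0, noise_sd, act.shape))
    return act, trial_frames, order


def make_fixture_suite(seed: int = 0) -> Dict[str, Tuple[TrajectorySession,
                                                         GroundTruth]]:
    """Deterministic miniature fixtures: one per schedule plus naive/expert."""
    return {
        "standard": generate_session(expert_config(n_trials=8, seed=seed)),
        "interleaved": generate_session(ir_config(n_trials=10, seed=seed + 1)),
        "split": generate_session(split_config(n_trials=8, seed=seed + 2)),
        "naive": generate_session(naive_config(n_trials=8, seed=seed + 3)),
        "expert": generate_session(expert_config(n_trials=8, seed=seed + 4)),
    }
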