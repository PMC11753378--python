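"""2D arena environment with a biased discrete action space.

The agent navigates a square arena ``[-1, 1] x [-1, 1]`` (arbitrary units)
toward a centered square reward zone of extent 0.4 x 0.4.  The action space
has 256 discrete actions of which 192 (75%) produce no displacement,
mimicking the idle periods of mice manipulating an object; the remaining 64
actions move the agent in one of eight directions at one of eight speeds.
Speeds carry a diagonal bias (one diagonal fast, the other slow), emulating
the movement statistics of mouse-driven object trajectories.

Three reward schedules are supported:

``standard``
    reward 1.0 on reaching the zone.
``interleaved``
    reward 1.0 on a randomly pre-assigned 50% of trials, 0 otherwise
    (reward omission despite success).
``split``
    the zone is split at x = 0; the left half pays 0.125 and the right
    half pays 1.25.

Every transition is classified by its relation to the reward zone
(``goal``, ``none``, ``toward_short``, ``lateral_miss``, ``away``); the
two toward classes operationalize the two erroneous-movement scenarios:
stopping short of the zone and aiming too laterally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

N_ACTIONS = 256
N_NOOP = 192
DIRECTIONS_DEG = np.arange(0, 360, 45)
#: per-direction (min, max) step magnitude, a.u.
SPEED_RANGES = {
    0: (0.216, 0.720),
    90: (0.216, 0.720),
    180: (0.216, 0.720),
    270: (0.216, 0.720),
    45: (0.072, 0.240),
    225: (0.072, 0.240),
    135: (0.360, 1.200),
    315: (0.360, 1.200),
}

MOVEMENT_CLASSES = ("none", "toward_short", "lateral_miss", "away", "goal")


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry, reward schedule and trial budget."""

    schedule: str = "standard"
    bound: float = 1.0
    zone_half: float = 0.2
    reward_standard: float = 1.0
    reward_interleaved_prob: float = 0.5
    reward_split_low: float = 0.125
    reward_split_high: float = 1.25
    max_steps: int = 60

    def __post_init__(self) -> None:
        if self.schedule not in ("standard", "interleaved", "split"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if not 0 < self.zone_half < self.bound:
            raise ValueError("reward zone must lie strictly inside the bounds")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if min(self.reward_standard, self.reward_split_low,
               self.reward_split_high) < 0:
            raise ValueError("rewards must be nonnegative")


@dataclass
class TrialState:
    """Mutable per-trial bookkeeping (step counter, reward assignment)."""

    steps_taken: int = 0
    rewarded: bool = True  # drawn per trial under the interleaved schedule


@dataclass(frozen=True)
class Transition:
    prev_pos: np.ndarray
    next_pos: np.ndarray
    action_id: int
    reward: float
    terminal: bool
    movement_class: str


@dataclass(frozen=True)
class ActionTable:
    """Displacement vectors for all 256 actions.

    ``displacements`` has shape (256, 2); rows 0..191 are zero.  Movement
    action ``192 + 8*d + s`` has direction ``DIRECTIONS_DEG[d]`` and the
    s-th of eight evenly spaced magnitudes spanning the direction's
    (min, max) range inclusively.
    """

    displacements: np.ndarray
    direction_deg: np.ndarray  # -1 for no-ops, else the direction in degrees
    magnitude: np.ndarray


def build_action_table() -> ActionTable:
    disp = np.zeros((N_ACTIONS, 2))
    dirs = np.full(N_ACTIONS, -1.0)
    mags = np.zeros(N_ACTIONS)
    for d, ang in enumerate(DIRECTIONS_DEG):
        lo, hi = SPEED_RANGES[int(ang)]
        speeds = np.linspace(lo, hi, 8)
        rad = np.deg2rad(ang)
        unit = np.array([np.cos(rad), np.sin(rad)])
        for s, mag in enumerate(speeds):
            a = N_NOOP + 8 * d + s
            disp[a] = mag * unit
            dirs[a] = ang
            mags[a] = mag
    return ActionTable(displacements=disp, direction_deg=dirs, magnitude=mags)


def in_zone(pos: np.ndarray, config: ArenaConfig) -> bool:
    """Closed-boundary membership test for the reward zone."""
    return bool(np.all(np.abs(pos) <= config.zone_half))


def reset(config: ArenaConfig, rng: np.random.Generator,
          trial_state: Optional[TrialState] = None) -> np.ndarray:
    """Draw a start position uniform over the arena minus the reward zone.

    If ``trial_state`` is given it is reinitialized in place (step counter
    zeroed; under the interleaved schedule the trial's reward assignment is
    drawn here).
    """
    while True:
        pos = rng.uniform(-config.bound, config.bound, size=2)
        if not in_zone(pos, config):
            break
    if trial_state is not None:
        trial_state.steps_taken = 0
        trial_state.rewarded = True
        if config.schedule == "interleaved":
            trial_state.rewarded = bool(
                rng.random() < config.reward_interleaved_prob)
    return pos


def _ray_hits_zone(origin: np.ndarray, direction: np.ndarray,
                   half: float) -> bool:
    """Slab test: does the ray origin + t*direction (t>=0) meet [-half, half]^2?"""
    t_lo, t_hi = 0.0, np.inf
    for k in range(2):
        if direction[k] == 0.0:
            if abs(origin[k]) > half:
                return False
        else:
            t1 = (-half - origin[k]) / direction[k]
            t2 = (half - origin[k]) / direction[k]
            if t1 > t2:
                t1, t2 = t2, t1
            t_lo = max(t_lo, t1)
            t_hi = min(t_hi, t2)
            if t_lo > t_hi:
                return False
    return t_hi >= 0.0


def classify_movement(prev_pos: np.ndarray, next_pos: np.ndarray,
                      config: ArenaConfig) -> str:
    """Assign the movement class of a realized displacement."""
    if in_zone(next_pos, config):
        return "goal"
    disp = next_pos - prev_pos
    if np.all(disp == 0.0):
        return "none"
    d0 = float(np.linalg.norm(prev_pos))
    d1 = float(np.linalg.norm(next_pos))
    if d1 >= d0:
        return "away"
    # moved closer but did not enter: short of the zone vs. lateral miss,
    # discriminated by whether the heading ray intersects the zone square
    if _ray_hits_zone(prev_pos, disp, config.zone_half):
        return "toward_short"
    return "lateral_miss"


def _goal_reward(next_pos: np.ndarray, config: ArenaConfig,
                 trial_state: TrialState) -> float:
    if config.schedule == "standard":
        return config.reward_standard
    if config.schedule == "interleaved":
        return config.reward_standard if trial_state.rewarded else 0.0
    # split: left half of the zone pays low, right half pays high
    return (config.reward_split_low if next_pos[0] < 0
            else config.reward_split_high)


def step(pos: np.ndarray, action_id: int, config: ArenaConfig,
         trial_state: TrialState, table: ActionTable) -> Transition:
    """Apply one action; clamp to bounds; classify and reward the move."""
    if not 0 <= action_id < N_ACTIONS:
        raise ValueError(f"action id {action_id} outside [0, {N_ACTIONS})")
    next_pos = np.clip(pos + table.displacements[action_id],
                       -config.bound, config.bound)
    cls = classify_movement(pos, next_pos, config)
    trial_state.steps_taken += 1
    reward = 0.0
    if cls == "goal":
        reward = _goal_reward(next_pos, config, trial_state)
    terminal = cls == "goal" or trial_state.steps_taken >= config.max_steps
    return Transition(prev_pos=np.asarray(pos, dtype=float),
                      next_pos=next_pos, action_id=int(action_id),
                      reward=float(reward), terminal=terminal,
                      movement_class=cls)
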