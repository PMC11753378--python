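"""Reading and writing sessions, activity and results.

Sessions travel as plain CSV (trajectory/joystick/licks/trials with a
documented column schema), neural activity and fits as ``.npz`` array
containers with a JSON sidecar of labels, and summary tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import TrajectorySession

TRAJ_COLUMNS = ["t", "x", "y", "trial"]
TRIAL_COLUMNS = ["trial", "t_start", "t_end", "completed", "rewarded",
                 "reward_size"]


def save_configs(path: str | Path, arena=None, ppo=None) -> Path:
    """Write arena/agent configuration to a YAML file."""
    import dataclasses

    import yaml

    doc = {}
    if arena is not None:
        doc["arena"] = dataclasses.asdict(arena)
    if ppo is not None:
        doc["ppo"] = dataclasses.asdict(ppo)
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_configs(path: str | Path):
    """Read (ArenaConfig, PpoConfig) from a YAML file; either may be None."""
    import yaml

    from .rl_agent import PpoConfig
    from .rl_env import ArenaConfig

    doc = yaml.safe_load(Path(path).read_text()) or {}
    arena = ArenaConfig(**doc["arena"]) if "arena" in doc else None
    ppo = PpoConfig(**doc["ppo"]) if "ppo" in doc else None
    return arena, ppo


def save_session(session: TrajectorySession, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.trajectory[TRAJ_COLUMNS].to_csv(out / "trajectory.csv",
                                            index=False)
    session.joystick[TRAJ_COLUMNS].to_csv(out / "joystick.csv", index=False)
    pd.DataFrame({"t": session.licks}).to_csv(out / "licks.csv", index=False)
    session.trials[TRIAL_COLUMNS].to_csv(out / "trials.csv", index=False)
    (out / "session.json").write_text(json.dumps(
        {"schedule": session.schedule}, indent=2))
    return out


def load_session(in_dir: str | Path) -> TrajectorySession:
    p = Path(in_dir)
    meta = json.loads((p / "session.json").read_text())
    return TrajectorySession(
        trajectory=pd.read_csv(p / "trajectory.csv"),
        joystick=pd.read_csv(p / "joystick.csv"),
        licks=pd.read_csv(p / "licks.csv")["t"].to_numpy(),
        trials=pd.read_csv(p / "trials.csv"),
        schedule=meta["schedule"])


def save_activity(traces: np.ndarray, out_dir: str | Path,
                  frame_times: Optional[np.ndarray] = None,
                  regions: Optional[Sequence[str]] = None,
                  neuron_types: Optional[Sequence[str]] = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays: Dict[str, np.ndarray] = {"traces": np.asarray(traces)}
    if frame_times is not None:
        arrays["frame_times"] = np.asarray(frame_times)
    np.savez(out / "activity.npz", **arrays)
    sidecar = {}
    if regions is not None:
        sidecar["regions"] = list(regions)
    if neuron_types is not None:
        sidecar["neuron_types"] = list(neuron_types)
    (out / "activity.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_activity(in_dir: str | Path) -> Dict[str, object]:
    p = Path(in_dir)
    data = np.load(p / "activity.npz")
    out: Dict[str, object] = {k: data[k] for k in data.files}
    sidecar = p / "activity.json"
    if sidecar.exists():
        out.update(json.loads(sidecar.read_text()))
    return out


def save_training_record(record, out_dir: str | Path) -> Path:
    """Serialize a TrainingRecord: per-episode log as CSV plus npz arrays."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "episode": np.arange(len(record.steps)),
        "steps": record.steps,
        "success": record.success.astype(int),
        "reward": record.reward,
        "goal_rpe": record.goal_rpe,
        "pre_goal_rpe_mean": record.pre_goal_rpe_mean,
        "rewarded": record.rewarded.astype(int),
    })
    df.to_csv(out / "episodes.csv", index=False)
    np.savez(out / "record.npz", steps=record.steps,
             success=record.success, goal_rpe=record.goal_rpe,
             goal_value=record.goal_value,
             pre_goal_rpe_mean=record.pre_goal_rpe_mean)
    meta = {"schedule": record.arena.schedule,
            "n_step": record.config.n_step,
            "episodes": record.config.episodes,
            "seed": record.config.seed}
    (out / "record.json").write_text(json.dumps(meta, indent=2))
    return out
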