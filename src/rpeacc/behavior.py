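"""Behavioral feature extraction from object-manipulation trajectories.

A session consists of trials in which a joystick-driven object moves
across a 100 x 100 mm arena toward a centered 40 x 40 mm reward zone,
sampled every 10 ms.  This module extracts:

* strokes — discrete object movements with peak speed > 60 mm/s,
  separated by at least 200 ms;
* erroneous movements — peaks of the radial speed (time-differenced
  distance to the arena center) above 60 mm/s, classified ``toward``
  (distance decreasing, zone not entered) or ``away`` (reinitialization);
* n-step error accumulation delta(n) — the n-th toward error within a
  trial, n = 1..6, reset across trials;
* peri-event lick histograms (100-ms bins, baseline-subtracted);
* the correct rate and the empirical spatial state-value map
  ``E[gamma**(T - t)]`` with gamma = 0.99 per 10-ms step, scaled by
  reward size.

Coordinates are in mm with the arena centered at the origin; times in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

DT = 0.01                 # trajectory sampling interval, s
ARENA_HALF = 50.0         # mm
ZONE_HALF = 20.0          # mm
SPEED_THRESHOLD = 60.0    # mm/s
MIN_SEPARATION = 0.2      # s
MAX_N = 6
GAMMA_BEHAVIOR = 0.99     # per 10-ms step discount for the empirical value

#: peri-event lick histogram normalization modes
LICK_NORM_MODES = ("toward_away", "expert_max", "one_step",
                   "first_quarter", "high_side")


@dataclass
class TrajectorySession:
    """Trial-structured behavioral session.

    ``trajectory`` and ``joystick`` are DataFrames with columns
    ``t, x, y, trial`` at 10-ms sampling; ``trials`` has columns
    ``trial, t_start, t_end, completed, rewarded, reward_size``;
    ``licks`` is an array of lick event times (s).
    """

    trajectory: pd.DataFrame
    joystick: pd.DataFrame
    licks: np.ndarray
    trials: pd.DataFrame
    schedule: str = "standard"

    def trial_slice(self, trial: int) -> pd.DataFrame:
        return self.trajectory[self.trajectory["trial"] == trial]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class StrokeEvent:
    time: float
    peak_speed: float
    trial: int


@dataclass
class ErrorEvents:
    """Per-trial toward/away error times and n-step accumulation onsets."""

    toward: pd.DataFrame   # columns: trial, time, side, nth (1-based count)
    away: pd.DataFrame     # columns: trial, time
    max_n: int = MAX_N

    def onset_times(self, n: int) -> np.ndarray:
        """Times at which the cumulative toward-error count reaches n."""
        if not 1 <= n <= self.max_n:
            raise ValueError(f"n must be in [1, {self.max_n}]")
        return self.toward.loc[self.toward["nth"] == n, "time"].to_numpy()

    def boxcar(self, n: int, times: np.ndarray,
               trials: pd.DataFrame) -> np.ndarray:
        """delta(n) boxcar on a time grid: 1 while the within-trial
        cumulative toward-error count equals n, 0 elsewhere."""
        out = np.zeros(len(times))
        for trial, grp in self.toward.groupby("trial"):
            tr = trials[trials["trial"] == trial].iloc[0]
            ts = grp["time"].to_numpy()
            if len(ts) < n:
                continue
            start = ts[n - 1]
            end = ts[n] if len(ts) > n else tr["t_end"]
            out[(times >= start) & (times < end)] = 1.0
        return out


def _speed(xy: np.ndarray) -> np.ndarray:
    """Speed (mm/s) from 10-ms displacements; length matches input,
    first sample 0."""
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1) / DT
    return np.concatenate([[0.0], d])


def detect_strokes(session: TrajectorySession) -> List[StrokeEvent]:
    """Object movements with speed > 60 mm/s, >= 200 ms apart."""
    events: List[StrokeEvent] = []
    sep = int(round(MIN_SEPARATION / DT))
    for trial, grp in session.trajectory.groupby("trial"):
        xy = grp[["x", "y"]].to_numpy()
        if len(xy) < 2:
            continue
        speed = _speed(xy)
        peaks, props = find_peaks(speed, height=SPEED_THRESHOLD, distance=sep)
        t = grp["t"].to_numpy()
        for p, h in zip(peaks, props["peak_heights"]):
            events.append(StrokeEvent(time=float(t[p]), peak_speed=float(h),
                                      trial=int(trial)))
    return events


def _zone_entry_mask(xy: np.ndarray) -> np.ndarray:
    return (np.abs(xy[:, 0]) <= ZONE_HALF) & (np.abs(xy[:, 1]) <= ZONE_HALF)


def detect_errors(session: TrajectorySession,
                  lookahead: float = MIN_SEPARATION) -> ErrorEvents:
    """Toward/away erroneous movements from radial-speed peaks.

    The distance of the object to the arena center is differenced over
    adjacent 10-ms samples; peaks of the resulting radial speed above
    60 mm/s with >= 200 ms separation (enforced within each class) are
    movement events.  A peak with decreasing distance is a ``toward``
    error unless the zone is entered within ``lookahead`` seconds (that
    movement is the goal approach, not an error); increasing distance is
    ``away`` (reinitialization).  Trials shorter than 200 ms are skipped.
    """
    sep = int(round(MIN_SEPARATION / DT))
    look = int(round(lookahead / DT))
    toward_rows: List[dict] = []
    away_rows: List[dict] = []
    for trial, grp in session.trajectory.groupby("trial"):
        xy = grp[["x", "y"]].to_numpy()
        t = grp["t"].to_numpy()
        if len(xy) < 2 or (t[-1] - t[0]) < MIN_SEPARATION:
            continue
        dist = np.linalg.norm(xy, axis=1)
        rv = np.concatenate([[0.0], np.diff(dist) / DT])  # signed, mm/s
        in_zone = _zone_entry_mask(xy)
        # toward: peaks of -rv (distance decreasing)
        pk_t, _ = find_peaks(-rv, height=SPEED_THRESHOLD, distance=sep)
        count = 0
        for p in pk_t:
            if in_zone[p: p + look + 1].any():
                continue  # this movement reaches the zone: goal, not error
            count += 1
            side = "high" if xy[p, 0] >= 0 else "low"
            toward_rows.append({"trial": int(trial), "time": float(t[p]),
                                "side": side, "nth": count})
        pk_a, _ = find_peaks(rv, height=SPEED_THRESHOLD, distance=sep)
        for p in pk_a:
            if in_zone[p]:
                continue  # reinitialization happens outside the zone
            away_rows.append({"trial": int(trial), "time": float(t[p])})
    toward = pd.DataFrame(toward_rows,
                          columns=["trial", "time", "side", "nth"])
    away = pd.DataFrame(away_rows, columns=["trial", "time"])
    return ErrorEvents(toward=toward, away=away)


def error_statistics(events: ErrorEvents,
                     trials: pd.DataFrame) -> pd.DataFrame:
    """Per-n trial-by-trial onset frequency and latency.

    Frequency is the fraction of trials whose cumulative toward-error
    count reaches n.  Latency is the time from the (n-1)-th to the n-th
    error; for n = 1 it is measured from trial start.  Latency is NaN for
    n never reached.
    """
    rows = []
    n_trials = len(trials)
    start_by_trial = dict(zip(trials["trial"], trials["t_start"]))
    for n in range(1, events.max_n + 1):
        hits = events.toward[events.toward["nth"] == n]
        freq = len(hits) / max(n_trials, 1)
        lat: List[float] = []
        for _, row in hits.iterrows():
            if n == 1:
                lat.append(row["time"] - start_by_trial[row["trial"]])
            else:
                prev = events.toward[
                    (events.toward["trial"] == row["trial"])
                    & (events.toward["nth"] == n - 1)]
                lat.append(row["time"] - prev["time"].iloc[0])
        rows.append({"n": n, "frequency": freq,
                     "latency": float(np.mean(lat)) if lat else np.nan,
                     "count": len(hits)})
    return pd.DataFrame(rows)


@dataclass
class LickHistogram:
    bin_centers: np.ndarray   # s, relative to the event
    values: np.ndarray        # baseline-subtracted (and optionally normalized)
    n_events: int
    comparison: float         # sum of the first five post-event bins

    def normalized(self, reference_max: float) -> "LickHistogram":
        if reference_max == 0:
            raise ValueError("normalization reference is zero")
        return LickHistogram(self.bin_centers, self.values / reference_max,
                             self.n_events, self.comparison / reference_max)


def peri_event_lick(session: TrajectorySession, event_times: Sequence[float],
                    window: float = 2.0, bin_width: float = 0.1,
                    reference_max: Optional[float] = None) -> LickHistogram:
    """Peri-event lick histogram: 10-ms lick raster averaged over events,
    binned every 100 ms, baseline (the bin at -50 ms) subtracted.

    ``reference_max`` optionally divides the histogram (the enumerated
    normalization modes all reduce to dividing by the maximum of a
    reference single-step histogram; callers pick the reference).
    """
    event_times = np.asarray(event_times, dtype=float)
    n_bins = int(round(2 * window / bin_width))
    edges = np.linspace(-window, window, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    hist = np.zeros(n_bins)
    licks = np.sort(np.asarray(session.licks, dtype=float))
    samples_per_bin = int(round(bin_width / DT))
    for ev in event_times:
        # 10-ms lick raster around the event, averaged within 100-ms bins
        grid = ev + np.arange(-window, window, DT)
        raster = np.zeros(len(grid))
        if licks.size:
            idx = np.searchsorted(licks, grid)
            has = (idx < len(licks)) & (np.abs(
                licks[np.minimum(idx, len(licks) - 1)] - grid) < DT)
            prev = (idx > 0) & (np.abs(licks[np.maximum(idx - 1, 0)] - grid)
                                < DT)
            raster[has | prev] = 1.0
        hist += raster[: n_bins * samples_per_bin].reshape(
            n_bins, samples_per_bin).mean(axis=1)
    if event_times.size:
        hist /= event_times.size
    baseline_bin = int(np.searchsorted(edges, -0.05) - 1)
    hist = hist - hist[baseline_bin]
    post = hist[np.searchsorted(edges, 0.0, side="right") - 1:][:5]
    out = LickHistogram(bin_centers=centers, values=hist,
                        n_events=int(event_times.size),
                        comparison=float(post.sum()))
    if reference_max is not None:
        out = out.normalized(reference_max)
    return out


def correct_rate(session: TrajectorySession) -> float:
    """Completed trials / total trials (reward delivery irrelevant)."""
    if session.n_trials < 1:
        raise ValueError("session has no trials")
    return float(session.trials["completed"].mean())


def empirical_state_value(sessions: Sequence[TrajectorySession],
                          gamma: float = GAMMA_BEHAVIOR,
                          bin_mm: float = 10.0) -> Dict[str, np.ndarray]:
    """Spatial map of ``E[reward_size * gamma**(T - t)]`` over rewarded trials.

    ``T - t`` counts 10-ms steps to the rewarded trial end.  Only trials
    ending in reward contribute; unvisited bins are NaN.
    """
    n_bins = int(round(2 * ARENA_HALF / bin_mm))
    edges = np.linspace(-ARENA_HALF, ARENA_HALF, n_bins + 1)
    sums = np.zeros((n_bins, n_bins))
    counts = np.zeros((n_bins, n_bins))
    for sess in sessions:
        rewarded = sess.trials[(sess.trials["completed"])
                               & (sess.trials["reward_size"] > 0)]
        for _, tr in rewarded.iterrows():
            grp = sess.trial_slice(int(tr["trial"]))
            xy = grp[["x", "y"]].to_numpy()
            t = grp["t"].to_numpy()
            steps_to_end = np.round((t[-1] - t) / DT).astype(int)
            w = float(tr["reward_size"]) * gamma ** steps_to_end
            ix = np.clip(np.digitize(xy[:, 0], edges) - 1, 0, n_bins - 1)
            iy = np.clip(np.digitize(xy[:, 1], edges) - 1, 0, n_bins - 1)
            np.add.at(sums, (ix, iy), w)
            np.add.at(counts, (ix, iy), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return {"mean": mean, "counts": counts, "edges": edges}
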