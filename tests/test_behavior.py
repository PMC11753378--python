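import numpy as np
import pandas as pd
import pytest

from rpeacc import behavior
from rpeacc.behavior import (DT, TrajectorySession, correct_rate,
                             detect_errors, detect_strokes,
                             empirical_state_value, error_statistics,
                             peri_event_lick)


def make_session(trial_xy, licks=(), schedule="standard", rewards=None):
    """Build a session from a list of per-trial (n_samples, 2) arrays."""
    rows, trial_rows = [], []
    t = 0.0
    for i, xy in enumerate(trial_xy):
        xy = np.asarray(xy, dtype=float)
        times = t + np.arange(len(xy)) * DT
        rows.append(pd.DataFrame({"t": times, "x": xy[:, 0],
                                  "y": xy[:, 1], "trial": i}))
        inside = (np.abs(xy[-1]) <= behavior.ZONE_HALF).all()
        size = rewards[i] if rewards is not None else (1.0 if inside else 0.0)
        trial_rows.append({"trial": i, "t_start": times[0],
                           "t_end": times[-1], "completed": bool(inside),
                           "rewarded": size > 0, "reward_size": size})
        t = times[-1] + 2.0  # ITI gap
    traj = pd.concat(rows, ignore_index=True)
    return TrajectorySession(trajectory=traj, joystick=traj.copy(),
                             licks=np.asarray(licks, dtype=float),
                             trials=pd.DataFrame(trial_rows),
                             schedule=schedule)


def burst_trajectory(start, stop, n_move=20, pad=60):
    """Hold at start, ballistic move to stop, hold at stop."""
    start, stop = np.asarray(start, float), np.asarray(stop, float)
    w = np.sin(np.linspace(0, np.pi, n_move)) ** 2
    inc = (w / w.sum())[:, None] * (stop - start)[None, :]
    path = start + np.cumsum(inc, axis=0)
    return np.vstack([np.tile(start, (pad, 1)), path,
                      np.tile(stop, (pad, 1))])


class TestStrokes:
    def test_single_burst_is_one_stroke(self):
        # 30 mm in 0.2 s: mean 150 mm/s, peak ~300 mm/s
        xy = burst_trajectory([45, 0], [15, 0])
        s = detect_strokes(make_session([xy]))
        assert len(s) == 1
        assert s[0].peak_speed > behavior.SPEED_THRESHOLD

    def test_constant_slow_drift_no_stroke(self):
        t = np.arange(300)
        xy = np.stack([45 - 0.5 * t * DT * 100, np.zeros_like(t)], axis=1)
        # 50 mm/s constant speed: below the 60 mm/s threshold
        xy = np.stack([45 - 50 * t * DT, np.zeros_like(t, dtype=float)],
                      axis=1)
        assert detect_strokes(make_session([xy])) == []

    def test_bursts_within_200ms_merge(self):
        xy1 = burst_trajectory([45, 0], [35, 0], n_move=8, pad=5)
        xy2 = burst_trajectory([35, 0], [25, 0], n_move=8, pad=5)
        xy = np.vstack([xy1, xy2])  # second burst ~130 ms after the first
        s = detect_strokes(make_session([xy]))
        assert len(s) == 1

    def test_bursts_beyond_200ms_distinct(self):
        xy1 = burst_trajectory([45, 0], [35, 0], n_move=8, pad=15)
        xy2 = burst_trajectory([35, 0], [25, 0], n_move=8, pad=15)
        s = detect_strokes(make_session([np.vstack([xy1, xy2])]))
        assert len(s) == 2


class TestErrors:
    def test_stop_short_is_toward_error(self):
        xy = burst_trajectory([45, 0], [30, 0])  # stops 10 mm outside zone
        ev = detect_errors(make_session([xy]))
        assert len(ev.toward) == 1
        assert ev.toward.iloc[0]["nth"] == 1
        assert len(ev.away) == 0

    def test_away_movement_is_reinitialization(self):
        xy = burst_trajectory([30, 0], [45, 0])
        ev = detect_errors(make_session([xy]))
        assert len(ev.toward) == 0
        assert len(ev.away) == 1

    def test_zone_entry_not_an_error(self):
        xy = burst_trajectory([45, 0], [10, 0])  # ends inside the zone
        ev = detect_errors(make_session([xy]))
        assert len(ev.toward) == 0

    def test_five_errors_give_single_fifth_onset(self, naive_session):
        session, truth = naive_session
        ev = detect_errors(session)
        per_trial = truth.toward_times.groupby("trial").size()
        trials5 = per_trial[per_trial == 5].index
        assert len(trials5) > 0
        for tr in trials5:
            onsets = ev.toward[(ev.toward["trial"] == tr)
                               & (ev.toward["nth"] == 5)]
            assert len(onsets) == 1

    def test_boxcar_onsets_ordered_and_reset(self, naive_session):
        session, _ = naive_session
        ev = detect_errors(session)
        for tr, grp in ev.toward.groupby("trial"):
            nth = grp.sort_values("time")["nth"].to_numpy()
            assert np.array_equal(nth, np.arange(1, len(nth) + 1))

    def test_translation_invariance(self):
        xy = burst_trajectory([45, 5], [28, 3])
        sess = make_session([xy])
        ev1 = detect_errors(sess)
        shifted = sess.trajectory.copy()
        shifted[["x", "y"]] += 1000.0
        sess2 = TrajectorySession(trajectory=shifted, joystick=shifted,
                                  licks=sess.licks, trials=sess.trials)
        # translation of the whole frame moves the arena center with it;
        # detection relative to the (session-implied) center is unchanged
        # when we translate coordinates back
        shifted[["x", "y"]] -= 1000.0
        ev2 = detect_errors(sess2)
        assert len(ev1.toward) == len(ev2.toward)

    def test_round_trip_sensitivity_precision(self, naive_session):
        session, truth = naive_session
        ev = detect_errors(session)
        planted = truth.toward_times
        detected = ev.toward
        tol = DT + 1e-9

        def match_rate(a, b):
            hits = 0
            for _, r in a.iterrows():
                cand = b[b["trial"] == r["trial"]]["time"].to_numpy()
                if cand.size and np.min(np.abs(cand - r["time"])) <= tol:
                    hits += 1
            return hits / max(len(a), 1)

        assert match_rate(planted, detected) >= 0.95  # sensitivity
        assert match_rate(detected, planted) >= 0.95  # precision


class TestErrorStatistics:
    def test_frequency_counts_onsets(self):
        toward = pd.DataFrame({"trial": [0, 0, 0], "time": [1.0, 2.5, 3.1],
                               "side": ["high"] * 3, "nth": [1, 2, 3]})
        ev = behavior.ErrorEvents(toward=toward,
                                  away=pd.DataFrame(columns=["trial", "time"]))
        trials = pd.DataFrame({"trial": [0], "t_start": [0.0],
                               "t_end": [5.0]})
        stats = error_statistics(ev, trials)
        assert list(stats["frequency"]) == [1, 1, 1, 0, 0, 0]

    def test_latency_between_consecutive_errors(self):
        toward = pd.DataFrame({"trial": [0, 0], "time": [1.0, 2.5],
                               "side": ["high"] * 2, "nth": [1, 2]})
        ev = behavior.ErrorEvents(toward=toward,
                                  away=pd.DataFrame(columns=["trial", "time"]))
        trials = pd.DataFrame({"trial": [0], "t_start": [0.0],
                               "t_end": [5.0]})
        stats = error_statistics(ev, trials)
        assert stats.loc[stats["n"] == 2, "latency"].iloc[0] == pytest.approx(1.5)
        assert stats.loc[stats["n"] == 1, "latency"].iloc[0] == pytest.approx(1.0)
        assert np.isnan(stats.loc[stats["n"] == 3, "latency"].iloc[0])

    def test_expert_fewer_errors_than_naive(self, naive_session,
                                            expert_session):
        nstats = error_statistics(detect_errors(naive_session[0]),
                                  naive_session[0].trials)
        estats = error_statistics(detect_errors(expert_session[0]),
                                  expert_session[0].trials)
        assert (estats["frequency"].sum() < nstats["frequency"].sum())


class TestPeriEventLick:
    def test_no_licks_zero_histogram(self):
        xy = burst_trajectory([45, 0], [30, 0])
        sess = make_session([xy])
        h = peri_event_lick(sess, [1.0])
        assert np.allclose(h.values, 0.0)
        assert h.comparison == 0.0

    def test_baseline_bin_zero_after_subtraction(self):
        xy = burst_trajectory([45, 0], [30, 0], pad=300)
        licks = np.arange(0.5, 5.0, 0.11)  # steady licking
        sess = make_session([xy], licks=licks)
        h = peri_event_lick(sess, [3.0])
        baseline_idx = np.argmin(np.abs(h.bin_centers - (-0.05)))
        assert h.values[baseline_idx] == pytest.approx(0.0, abs=1e-12)

    def test_toward_locked_licking_beats_away(self, expert_session):
        session, truth = expert_session
        ev = detect_errors(session)
        toward_h = peri_event_lick(session, ev.toward["time"])
        away_h = peri_event_lick(session, ev.away["time"])
        assert toward_h.comparison > away_h.comparison

    def test_normalization_scales_comparison(self):
        xy = burst_trajectory([45, 0], [30, 0], pad=300)
        licks = [3.1, 3.15, 3.2, 3.3]
        sess = make_session([xy], licks=licks)
        h = peri_event_lick(sess, [3.0])
        hn = peri_event_lick(sess, [3.0], reference_max=h.values.max())
        assert hn.values.max() == pytest.approx(1.0)


class TestCorrectRate:
    def test_all_completed(self):
        xy = burst_trajectory([45, 0], [10, 0])
        assert correct_rate(make_session([xy, xy])) == 1.0

    def test_half_completed(self):
        good = burst_trajectory([45, 0], [10, 0])
        bad = burst_trajectory([45, 0], [30, 0])
        assert correct_rate(make_session([good, bad])) == 0.5

    def test_interleaved_counts_unrewarded_completions(self):
        xy = burst_trajectory([45, 0], [10, 0])
        sess = make_session([xy, xy], schedule="interleaved",
                            rewards=[1.0, 0.0])
        sess.trials.loc[1, "rewarded"] = False
        sess.trials.loc[1, "completed"] = True
        assert correct_rate(sess) == 1.0


class TestEmpiricalStateValue:
    def test_closed_form_discounting(self):
        """A bin visited exactly k steps before reward scores gamma**k."""
        # hold 69 samples at one spot, then jump into the zone at the end
        pre = np.tile([45.0, 45.0], (69, 1))
        xy = np.vstack([pre, [[0.0, 0.0]]])
        sess = make_session([xy])
        vm = empirical_state_value([sess])
        edges = vm["edges"]
        ix = np.digitize(45.0, edges) - 1
        val = vm["mean"][ix, ix]
        # the first sample sits T-t = 69 steps before the rewarded end
        # and the bin averages the 69 held samples: mean of gamma^(1..69)
        expected = np.mean(0.99 ** np.arange(1, 70))
        assert val == pytest.approx(expected, abs=1e-12)
        # reward-time bin scores exactly the reward scale
        iz = np.digitize(0.0, edges) - 1
        assert vm["mean"][iz, iz] == pytest.approx(1.0, abs=1e-12)

    def test_incomplete_trials_excluded(self):
        bad = burst_trajectory([45, 0], [30, 0])
        sess = make_session([bad])
        vm = empirical_state_value([sess])
        assert np.all(~np.isfinite(vm["mean"]) | (vm["counts"] == 0))

    def test_split_reward_scaling(self):
        pre = np.tile([45.0, 45.0], (10, 1))
        xy = np.vstack([pre, [[10.0, 0.0]]])
        hi = make_session([xy], rewards=[1.25])
        lo = make_session([xy], rewards=[0.125])
        vh = empirical_state_value([hi])
        vl = empirical_state_value([lo])
        ok = np.isfinite(vh["mean"])
        assert np.allclose(vh["mean"][ok], 10 * vl["mean"][ok])
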