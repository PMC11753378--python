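import numpy as np
import pandas as pd
import pytest

from rpeacc import population
from rpeacc.population import (classify_rpe_sign, cross_environment_bins,
                               long_trial_control, onset_matrix,
                               region_code_summary, reward_evoked_change,
                               reward_evoked_response, sequential_slope)


def sequence_data(n_neurons=12, n_trials=16, trial_len=60, jitter=0,
                  seed=0, shuffle=False):
    """Neurons activating in a fixed order within each trial."""
    rng = np.random.default_rng(seed)
    frames = n_trials * trial_len
    act = np.zeros((n_neurons, frames))
    trial_frames = []
    for tr in range(n_trials):
        base = tr * trial_len
        trial_frames.append(np.arange(base, base + trial_len))
        order = np.arange(n_neurons)
        if shuffle:
            rng.shuffle(order)
        for rank, neuron in enumerate(order):
            onset = 3 + rank * 4
            if jitter:
                onset = max(0, onset + int(rng.integers(-jitter, jitter + 1)))
            if onset < trial_len:
                act[neuron, base + onset: base + min(onset + 3, trial_len)] = 5.0
    act += rng.normal(0, 0.05, act.shape)
    return np.abs(act), trial_frames


class TestOnsetMatrix:
    def test_onsets_detected_in_order(self):
        act, tf = sequence_data()
        on = onset_matrix(act, tf)
        assert on.shape == (16, 12)
        row = on[0]
        assert np.all(np.diff(row[np.isfinite(row)]) > 0)

    def test_silent_neuron_nan(self):
        act, tf = sequence_data()
        act[5] = 0.0
        on = onset_matrix(act, tf)
        assert np.all(~np.isfinite(on[:, 5]))


class TestSequentialSlope:
    def test_fixed_order_slope_near_one(self):
        act, tf = sequence_data(seed=1)
        res = sequential_slope(act, tf, np.random.default_rng(0),
                               n_permutations=200)
        assert res.slope > 0.9
        assert res.p_value < 0.01

    def test_jittered_order_still_significant(self):
        act, tf = sequence_data(jitter=8, seed=2)
        res = sequential_slope(act, tf, np.random.default_rng(0),
                               n_permutations=300)
        assert res.slope > 0.5
        assert res.p_value < 0.005

    def test_shuffled_data_null_consistent(self):
        act, tf = sequence_data(shuffle=True, seed=3)
        res = sequential_slope(act, tf, np.random.default_rng(0),
                               n_permutations=300)
        assert abs(res.slope) < 0.5
        assert res.p_value > 0.01

    def test_shuffled_p_roughly_uniform(self):
        """p-values over independently shuffled datasets span [0, 1]."""
        ps = []
        for seed in range(25):
            act, tf = sequence_data(shuffle=True, seed=100 + seed,
                                    n_neurons=8, n_trials=10)
            res = sequential_slope(act, tf, np.random.default_rng(seed),
                                   n_permutations=100)
            ps.append(res.p_value)
        ps = np.asarray(ps)
        # not concentrated at either extreme
        assert 0.1 < ps.mean() < 0.9
        assert (ps < 0.25).mean() < 0.7

    def test_reproducible_with_seed(self):
        act, tf = sequence_data(seed=4)
        r1 = sequential_slope(act, tf, np.random.default_rng(5),
                              n_permutations=100)
        r2 = sequential_slope(act, tf, np.random.default_rng(5),
                              n_permutations=100)
        assert r1.slope == r2.slope and r1.p_value == r2.p_value
        assert len(r1.null_slopes) <= 100

    def test_no_active_neurons_rejected(self):
        act = np.zeros((5, 100))
        tf = [np.arange(50), np.arange(50, 100)]
        with pytest.raises(ValueError):
            sequential_slope(act, tf, np.random.default_rng(0))


def peri_offset_data(kind, n_trials=40, n_frames=46, seed=0):
    """Trials x frames activity around trial offset at ~5.67 Hz.

    Frames span -4..+4 s; rewarded/nonrewarded trials alternate.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(-4, 4, n_frames)
    rewarded = np.arange(n_trials) % 2 == 0
    A = np.abs(rng.normal(0.05, 0.02, (n_trials, n_frames)))
    bump = np.exp(-0.5 * ((t - 0.8) / 0.5) ** 2) * 3.0
    if kind == "positive":
        A[rewarded] += bump
    elif kind == "negative":
        A[~rewarded] += bump
    return A, rewarded, t


class TestClassifyRpeSign:
    def test_reward_locked_neuron_positive(self):
        A, rewarded, t = peri_offset_data("positive")
        lab = classify_rpe_sign(A, rewarded, t, np.random.default_rng(0))
        assert lab.label == "positive"

    def test_omission_locked_neuron_negative(self):
        A, rewarded, t = peri_offset_data("negative")
        lab = classify_rpe_sign(A, rewarded, t, np.random.default_rng(0))
        assert lab.label == "negative"

    def test_flat_neuron_none(self):
        A, rewarded, t = peri_offset_data("flat")
        lab = classify_rpe_sign(A, rewarded, t, np.random.default_rng(0))
        assert lab.label == "none"

    def test_single_condition_rejected(self):
        A, rewarded, t = peri_offset_data("positive")
        with pytest.raises(ValueError):
            classify_rpe_sign(A, np.ones_like(rewarded, dtype=bool), t)

    def test_false_positive_rate_below_threshold(self):
        """Flat-noise neurons pass either label at most ~1% of the time."""
        hits = 0
        n = 120
        for seed in range(n):
            A, rewarded, t = peri_offset_data("flat", seed=seed)
            lab = classify_rpe_sign(A, rewarded, t,
                                    np.random.default_rng(seed),
                                    n_boot=300)
            hits += lab.label != "none"
        assert hits / n <= 0.03


class TestRewardEvoked:
    def test_zero_activity_zero_response(self):
        t = np.arange(0, 100, 1 / 5.67)
        resp = reward_evoked_response(np.zeros((3, len(t))), t, [50.0])
        assert np.allclose(resp, 0.0)

    def test_amplitude_difference_detected(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 200, 1 / 5.67)
        rewards = np.arange(20, 190, 10.0)

        def pop(amp):
            A = np.abs(rng.normal(0.05, 0.02, (30, len(t))))
            for rt in rewards:
                mask = (t >= rt) & (t < rt + 0.5)
                A[:, mask] += amp
            return reward_evoked_response(A, t, rewards)

        naive = pop(2.0)
        expert = pop(0.5)
        out = reward_evoked_change(naive, expert, np.random.default_rng(1))
        assert out["naive_mean"] > out["expert_mean"]
        assert out["p_naive_greater"] < 0.001


class TestLongTrialControl:
    def test_error_trials_dominate(self):
        rng = np.random.default_rng(0)
        n_trials, tl = 12, 50
        act = np.abs(rng.normal(0.01, 0.005, (6, n_trials * tl)))
        has_error = np.arange(n_trials) % 2 == 0
        tf = [np.arange(i * tl, (i + 1) * tl) for i in range(n_trials)]
        for i in range(n_trials):
            if has_error[i]:
                act[:, i * tl + 10: i * tl + 20] += 4.0
        durations = np.full(n_trials, 10.0)
        durations[: n_trials // 2] = 30.0  # long trials: first half
        out = long_trial_control(act, tf, durations, has_error)
        assert np.all(out["difference"] > 1.0)  # >10x on the log10 scale

    def test_identical_groups_zero_difference(self):
        act = np.full((4, 100), 2.0)
        tf = [np.arange(i * 25, (i + 1) * 25) for i in range(4)]
        durations = np.array([30.0, 30.0, 5.0, 5.0])
        has_error = np.array([True, False, True, False])
        out = long_trial_control(act, tf, durations, has_error)
        assert np.allclose(out["difference"], 0.0)

    def test_missing_group_rejected(self):
        act = np.ones((2, 100))
        tf = [np.arange(i * 25, (i + 1) * 25) for i in range(4)]
        durations = np.array([30.0, 30.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            long_trial_control(act, tf, durations,
                               np.array([True, True, False, False]))


def classification_table(rng, n_sessions=6, per_region=40,
                         boost=None):
    rows = []
    for s in range(n_sessions):
        for reg in ("M1", "M2", "S1", "PPC", "RSC"):
            for _ in range(per_region):
                task = rng.random() < 0.5
                err = bool(task and rng.random() < 0.3)
                n = None
                if err:
                    probs = np.ones(6)
                    if boost and reg == boost[0]:
                        probs[boost[1] - 1] = 8.0
                    probs /= probs.sum()
                    n = int(rng.choice(np.arange(1, 7), p=probs))
                rows.append({"region": reg, "session": s,
                             "task_related": task, "error_related": err,
                             "assigned_n": n})
    return pd.DataFrame(rows)


class TestRegionSummary:
    def test_single_region_all_normalized_to_one(self):
        rng = np.random.default_rng(0)
        tab = classification_table(rng)
        tab = tab[tab["region"] == "M2"]
        out = region_code_summary(tab, rng=np.random.default_rng(1),
                                  n_boot=20)
        present = out["normalized"]["fraction"]
        assert np.all((present == 1.0) | (present == 0.0))

    def test_planted_regional_bias_recovered(self):
        rng = np.random.default_rng(2)
        tab = classification_table(rng, boost=("RSC", 6))
        out = region_code_summary(tab, rng=np.random.default_rng(1),
                                  n_boot=20)
        norm = out["normalized"]
        n6 = norm[norm["n"] == 6].set_index("region")["fraction"]
        assert n6.idxmax() == "RSC"

    def test_sparse_region_omitted(self):
        rng = np.random.default_rng(3)
        tab = classification_table(rng)
        tab = pd.concat([tab[tab["region"] != "PPC"],
                         tab[tab["region"] == "PPC"].head(3)],
                        ignore_index=True)
        out = region_code_summary(tab, rng=np.random.default_rng(1),
                                  n_boot=10)
        assert "PPC" not in set(out["fractions"]["region"])

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        tab = classification_table(rng)
        out1 = region_code_summary(tab, rng=np.random.default_rng(1),
                                   n_boot=5)
        doubled = pd.concat([tab, tab], ignore_index=True)
        doubled["session"] = np.repeat(np.arange(2), len(tab)) * 100 + \
            np.tile(tab["session"], 2)
        out2 = region_code_summary(doubled, rng=np.random.default_rng(1),
                                   n_boot=5)
        m1 = out1["fractions"].set_index(["region", "n"])["fraction"]
        m2 = out2["fractions"].set_index(["region", "n"])["fraction"]
        assert np.allclose(m1.sort_index(), m2.sort_index())


class TestCrossEnvironmentBins:
    def test_bounds_exactly_zero_and_one(self):
        rng = np.random.default_rng(5)
        f1 = region_code_summary(classification_table(rng),
                                 rng=np.random.default_rng(1),
                                 n_boot=5)["fractions"]
        f2 = region_code_summary(classification_table(rng),
                                 rng=np.random.default_rng(2),
                                 n_boot=5)["fractions"]
        out = cross_environment_bins(f1, f2)
        for b in out["bin"].unique():
            vals = out.loc[out["bin"] == b, "value"]
            assert vals.min() == pytest.approx(0.0)
            assert vals.max() == pytest.approx(1.0)
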