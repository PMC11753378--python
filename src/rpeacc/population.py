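"""Population-level statistics for error-accumulation coding.

Four families of analyses operate on trial-structured activity:

* **sequential activity** — neurons are sorted by activity-onset order
  (session z-score > 2) in a training half of trials; a least-squares
  slope between that sorting index and the neurons' trial-averaged onset
  rank in the held-out half quantifies sequence consistency (1 = perfectly
  conserved order, 0 = none), with a within-trial across-neuron onset
  permutation null;
* **RPE-sign classification at trial offset** (interleaved-reward
  sessions) — neurons are labelled positive- or negative-RPE by epoch
  comparisons (reward epoch 0..2 s vs. baseline -4..-3.5 s; rewarded vs.
  nonrewarded; post- vs. pre-offset maxima), each via one-tailed trial
  bootstrap at p < 0.01;
* **reward-evoked activity** — baseline-subtracted post-reward means
  (0..0.5 s, baseline at -4 s) compared across groups (naive vs. expert,
  high vs. low reward);
* **region summaries** — per-region per-n coefficient profiles and
  normalized fractions of n-step error neurons, with session bootstraps.

All resampling is seeded and sized at 1000 draws by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

Z_ONSET_THRESHOLD = 2.0
N_PERMUTATIONS = 1000


# ---------------------------------------------------------------------------
# sequential activity


def onset_matrix(activity: np.ndarray, trial_frames: Sequence[np.ndarray],
                 z_threshold: float = Z_ONSET_THRESHOLD) -> np.ndarray:
    """Per-trial, per-neuron first frame (within trial) where the
    session-z-scored activity exceeds the threshold; NaN if never.

    Returns an array (n_trials, n_neurons) of within-trial frame indices.
    """
    act = np.asarray(activity, dtype=float)
    mu = act.mean(axis=1, keepdims=True)
    sd = act.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (act - mu) / sd
    n_neurons = act.shape[0]
    onsets = np.full((len(trial_frames), n_neurons), np.nan)
    for ti, frames in enumerate(trial_frames):
        zt = z[:, frames] > z_threshold
        any_on = zt.any(axis=1)
        first = zt.argmax(axis=1).astype(float)
        first[~any_on] = np.nan
        onsets[ti] = first
    return onsets


@dataclass
class SequentialSlopeResult:
    slope: float
    p_value: float
    null_slopes: np.ndarray
    sorting_index: np.ndarray
    test_rank: np.ndarray


def _mean_test_rank(onsets: np.ndarray) -> np.ndarray:
    """Trial-averaged onset rank per neuron (rank among neurons with an
    onset in that trial; ties broken by earlier frame index)."""
    n_trials, n_neurons = onsets.shape
    ranks = np.full_like(onsets, np.nan)
    for ti in range(n_trials):
        row = onsets[ti]
        active = np.where(np.isfinite(row))[0]
        if active.size < 2:
            continue
        order = active[np.argsort(row[active], kind="stable")]
        ranks[ti, order] = np.arange(1, active.size + 1)
    ok = np.isfinite(ranks)
    cnt = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, np.nansum(np.where(ok, ranks, 0.0), axis=0)
                        / np.maximum(cnt, 1), np.nan)


def _slope(sorting_index: np.ndarray, mean_rank: np.ndarray) -> float:
    ok = np.isfinite(mean_rank) & np.isfinite(sorting_index)
    if ok.sum() < 2:
        return np.nan
    res = stats.linregress(sorting_index[ok], mean_rank[ok])
    return float(res.slope)


def sequential_slope(activity: np.ndarray,
                     trial_frames: Sequence[np.ndarray],
                     rng: Optional[np.random.Generator] = None,
                     n_permutations: int = N_PERMUTATIONS,
                     z_threshold: float = Z_ONSET_THRESHOLD
                     ) -> SequentialSlopeResult:
    """Consistency of neuron activation order across trials.

    Trials are split into random halves; neurons are ranked by mean onset
    in the training half (the sorting index) and the slope is fitted
    between that index and the trial-averaged onset rank in the test
    half.  The permutation null shuffles onsets across neurons within
    each test trial.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    onsets = onset_matrix(activity, trial_frames, z_threshold)
    usable = np.where(np.sum(np.isfinite(onsets), axis=1) >= 2)[0]
    if usable.size < 2 or not np.isfinite(onsets).any():
        raise ValueError("not enough trials with >= 2 active neurons")
    perm = rng.permutation(usable)
    train_tr = perm[: usable.size // 2]
    test_tr = perm[usable.size // 2:]

    train_mean = _mean_test_rank(onsets[train_tr])
    # neurons without a training onset cannot be sorted; drop them
    keep = np.isfinite(train_mean)
    order = np.argsort(train_mean[keep], kind="stable")
    sorting_index = np.full(keep.sum(), np.nan)
    sorting_index[order] = np.arange(1, keep.sum() + 1)

    test_onsets = onsets[test_tr][:, keep]
    mean_rank = _mean_test_rank(test_onsets)
    slope = _slope(sorting_index, mean_rank)

    null = np.empty(n_permutations)
    for i in range(n_permutations):
        shuffled = test_onsets.copy()
        for ti in range(shuffled.shape[0]):
            rng.shuffle(shuffled[ti])
        null[i] = _slope(sorting_index, _mean_test_rank(shuffled))
    null = null[np.isfinite(null)]
    p = float((np.sum(null >= slope) + 1) / (null.size + 1))
    return SequentialSlopeResult(slope=slope, p_value=p, null_slopes=null,
                                 sorting_index=sorting_index,
                                 test_rank=mean_rank)


# ---------------------------------------------------------------------------
# RPE-sign classification at trial offset (interleaved reward)


@dataclass
class RpeClassLabel:
    label: str                     # "positive", "negative" or "none"
    p_values: Dict[str, float]
    epoch_means: Dict[str, float]


def _bootstrap_greater(x: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator, n_boot: int,
                       paired: bool) -> float:
    """One-tailed bootstrap p for mean(x) > mean(y) (resampling trials)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        d = x - y
        idx = rng.integers(0, len(d), size=(n_boot, len(d)))
        boot = d[idx].mean(axis=1)
        return float((np.sum(boot <= 0) + 1) / (n_boot + 1))
    bx = x[rng.integers(0, len(x), size=(n_boot, len(x)))].mean(axis=1)
    by = y[rng.integers(0, len(y), size=(n_boot, len(y)))].mean(axis=1)
    return float((np.sum(bx <= by) + 1) / (n_boot + 1))


def classify_rpe_sign(peri_offset: np.ndarray, rewarded: np.ndarray,
                      frame_times: np.ndarray,
                      rng: Optional[np.random.Generator] = None,
                      n_boot: int = N_PERMUTATIONS,
                      alpha: float = 0.01) -> RpeClassLabel:
    """Positive/negative RPE labelling of one neuron at trial offset.

    ``peri_offset``: trials x frames activity aligned to the trial
    offset; ``frame_times``: frame times (s) relative to the offset.
    Positive label: reward-epoch (0..2 s) mean > baseline (-4..-3.5 s),
    rewarded > nonrewarded, and post-offset max > pre-offset (-2..0 s)
    max on rewarded trials — each one-tailed bootstrap p < alpha.
    Negative label mirrors the conditions on nonrewarded trials.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rewarded = np.asarray(rewarded, dtype=bool)
    if rewarded.all() or (~rewarded).all():
        raise ValueError("need both rewarded and nonrewarded trials")
    A = np.asarray(peri_offset, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    ep_reward = (t >= 0) & (t < 2)
    ep_base = (t >= -4) & (t < -3.5)
    ep_pre = (t >= -2) & (t < 0)
    if not (ep_reward.any() and ep_base.any() and ep_pre.any()):
        raise ValueError("peri-offset window too short for the epochs")

    def label_for(cond: np.ndarray, other: np.ndarray) -> Tuple[bool, dict, dict]:
        mine = A[cond]
        rew_mean = mine[:, ep_reward].mean(axis=1)
        base_mean = mine[:, ep_base].mean(axis=1)
        p1 = _bootstrap_greater(rew_mean, base_mean, rng, n_boot, paired=True)
        p2 = _bootstrap_greater(rew_mean, A[other][:, ep_reward].mean(axis=1),
                                rng, n_boot, paired=False)
        post_max = mine[:, ep_reward].max(axis=1)
        pre_max = mine[:, ep_pre].max(axis=1)
        p3 = _bootstrap_greater(post_max, pre_max, rng, n_boot, paired=True)
        ps = {"epoch_vs_baseline": p1, "condition": p2, "post_vs_pre": p3}
        means = {"reward_epoch": float(rew_mean.mean()),
                 "baseline": float(base_mean.mean())}
        return all(p < alpha for p in ps.values()), ps, means

    pos, p_pos, m_pos = label_for(rewarded, ~rewarded)
    neg, p_neg, m_neg = label_for(~rewarded, rewarded)
    if pos and not neg:
        return RpeClassLabel("positive", p_pos, m_pos)
    if neg and not pos:
        return RpeClassLabel("negative", p_neg, m_neg)
    return RpeClassLabel("none", {**{f"pos_{k}": v for k, v in p_pos.items()},
                                  **{f"neg_{k}": v for k, v in p_neg.items()}},
                         m_pos)


# ---------------------------------------------------------------------------
# reward-evoked activity


def reward_evoked_response(activity: np.ndarray, frame_times: np.ndarray,
                           reward_times: Sequence[float],
                           post_window: Tuple[float, float] = (0.0, 0.5),
                           baseline_offset: float = -4.0) -> np.ndarray:
    """Per-neuron mean baseline-subtracted post-reward response.

    The baseline is the activity at ``baseline_offset`` s (nearest frame)
    relative to each reward; the response is the mean over
    ``post_window`` minus that baseline, averaged across rewards.
    """
    act = np.atleast_2d(np.asarray(activity, dtype=float))
    t = np.asarray(frame_times)
    out = np.zeros(act.shape[0])
    n_used = 0
    for rt in reward_times:
        post = (t >= rt + post_window[0]) & (t < rt + post_window[1])
        if not post.any():
            continue
        bi = int(np.argmin(np.abs(t - (rt + baseline_offset))))
        out += act[:, post].mean(axis=1) - act[:, bi]
        n_used += 1
    return out / max(n_used, 1)


def reward_evoked_change(naive_resp: np.ndarray, expert_resp: np.ndarray,
                         rng: Optional[np.random.Generator] = None,
                         n_boot: int = N_PERMUTATIONS) -> Dict[str, float]:
    """One-tailed bootstrap for naive > expert post-reward responses."""
    rng = rng if rng is not None else np.random.default_rng(0)
    p = _bootstrap_greater(np.asarray(naive_resp), np.asarray(expert_resp),
                           rng, n_boot, paired=False)
    return {"naive_mean": float(np.mean(naive_resp)),
            "expert_mean": float(np.mean(expert_resp)),
            "p_naive_greater": p}


# ---------------------------------------------------------------------------
# long-trial control


def long_trial_control(activity: np.ndarray,
                       trial_frames: Sequence[np.ndarray],
                       durations: np.ndarray,
                       has_error: np.ndarray,
                       floor: float = 1e-3) -> Dict[str, np.ndarray]:
    """Error-neuron activity in long trials with vs. without errors.

    Long trials are those above the mean duration; the per-neuron
    trial-averaged activity of the two groups is compared on a log10
    scale (a small floor guards empty traces).
    """
    durations = np.asarray(durations, dtype=float)
    has_error = np.asarray(has_error, dtype=bool)
    long_mask = durations > durations.mean()
    with_err = [f for f, l, e in zip(trial_frames, long_mask, has_error)
                if l and e]
    without_err = [f for f, l, e in zip(trial_frames, long_mask, has_error)
                   if l and not e]
    if not with_err or not without_err:
        raise ValueError("need long trials both with and without errors")
    act = np.atleast_2d(np.asarray(activity, dtype=float))

    def group_mean(frame_sets):
        per_trial = [act[:, f].mean(axis=1) for f in frame_sets]
        return np.mean(per_trial, axis=0)

    a = group_mean(with_err)
    b = group_mean(without_err)
    return {"log10_with_error": np.log10(a + floor),
            "log10_without_error": np.log10(b + floor),
            "difference": np.log10(a + floor) - np.log10(b + floor)}


# ---------------------------------------------------------------------------
# region summaries


N_BINS = ((1, 2), (3, 4), (5, 6))


def region_code_summary(table: pd.DataFrame,
                        coef_profiles: Optional[pd.DataFrame] = None,
                        rng: Optional[np.random.Generator] = None,
                        n_boot: int = N_PERMUTATIONS,
                        min_cells: int = 5) -> Dict[str, pd.DataFrame]:
    """Area-specific n-step code summary.

    ``table`` needs columns ``region, session, task_related,
    error_related, assigned_n``.  Returns per-region per-n fractions of
    error neurons (among error neurons), their across-region-normalized
    version (max per n = 1), and session-bootstrap standard deviations.
    Regions with <= ``min_cells`` task-related cells are omitted.
    ``coef_profiles`` (columns ``region, n, coef``) is summarized per
    region per n when given.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    regions = []
    for reg, grp in table.groupby("region"):
        if grp["task_related"].sum() > min_cells:
            regions.append(reg)
    if not regions:
        raise ValueError("no region has enough task-related cells")
    ns = sorted(int(n) for n in
                table.loc[table["error_related"] == True,  # noqa: E712
                          "assigned_n"].dropna().unique())
    if not ns:
        ns = [1]

    def fractions(tab: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for reg in regions:
            sub = tab[tab["region"] == reg]
            n_err = max(int(sub["error_related"].sum()), 1)
            for n in ns:
                cnt = int(((sub["error_related"] == True)  # noqa: E712
                           & (sub["assigned_n"] == n)).sum())
                rows.append({"region": reg, "n": n,
                             "fraction": cnt / n_err})
        return pd.DataFrame(rows)

    frac = fractions(table)
    norm = frac.copy()
    for n in ns:
        m = norm.loc[norm["n"] == n, "fraction"].max()
        norm.loc[norm["n"] == n, "fraction"] = (
            norm.loc[norm["n"] == n, "fraction"] / m if m > 0 else 0.0)

    sessions = table["session"].unique()
    boot = np.zeros((n_boot, len(regions), len(ns)))
    for b in range(n_boot):
        pick = rng.integers(0, len(sessions), size=len(sessions))
        resampled = pd.concat([table[table["session"] == sessions[i]]
                               for i in pick], ignore_index=True)
        fb = fractions(resampled)
        for ri, reg in enumerate(regions):
            for ni, n in enumerate(ns):
                sel = fb[(fb["region"] == reg) & (fb["n"] == n)]
                boot[b, ri, ni] = sel["fraction"].iloc[0] if len(sel) else 0.0
    boot_sd = pd.DataFrame(
        [{"region": reg, "n": n, "sd": float(boot[:, ri, ni].std())}
         for ri, reg in enumerate(regions) for ni, n in enumerate(ns)])

    out = {"fractions": frac, "normalized": norm, "bootstrap_sd": boot_sd}
    if coef_profiles is not None:
        prof = (coef_profiles[coef_profiles["region"].isin(regions)]
                .groupby(["region", "n"])["coef"].mean().reset_index())
        out["coef_profiles"] = prof
    return out


def cross_environment_bins(frac_env1: pd.DataFrame, frac_env2: pd.DataFrame,
                           bins: Sequence[Tuple[int, int]] = N_BINS
                           ) -> pd.DataFrame:
    """Min-max normalized n-bin error-neuron fractions across environments.

    n is pooled into bins (1-2, 3-4, 5-6); within each bin the counts are
    scaled so the minimum and maximum over all regions in both
    environments are exactly 0 and 1.
    """
    rows = []
    for env, frac in (("env1", frac_env1), ("env2", frac_env2)):
        for lo, hi in bins:
            pooled = (frac[(frac["n"] >= lo) & (frac["n"] <= hi)]
                      .groupby("region")["fraction"].sum().reset_index())
            for _, r in pooled.iterrows():
                rows.append({"environment": env, "bin": f"{lo}-{hi}",
                             "region": r["region"], "value": r["fraction"]})
    df = pd.DataFrame(rows)
    for b in df["bin"].unique():
        sel = df["bin"] == b
        lo, hi = df.loc[sel, "value"].min(), df.loc[sel, "value"].max()
        rng_ = hi - lo
        df.loc[sel, "value"] = ((df.loc[sel, "value"] - lo) / rng_
                                if rng_ > 0 else 0.0)
    return df
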