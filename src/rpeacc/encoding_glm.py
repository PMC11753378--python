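"""Encoding GLMs for deconvolved calcium activity.

Each neuron's nonnegative deconvolved trace (imaging rate ~5.67 Hz) is
modeled as an exponentiated weighted sum of task predictors — a Poisson
GLM with log link.  Task variables (n-step error onsets, object velocity,
joystick velocity, passage of time) are convolved with six raised-cosine
temporal basis functions spanning +/- 2 s and z-scored across the
session, giving the design-matrix variants:

========  ====================================================  =======
variant   error-type columns                                    total
========  ====================================================  =======
standard  n-step toward-error onsets, n = 1..6 (6 x 6 = 36)     138
control   away-movement accumulation onsets (36)                138
modified  high/low-side single-step error onsets (2 x 6 = 12)   114
modified_control  away single-step onsets (6)                   108
========  ====================================================  =======

(the velocity groups contribute 8 directions x 6 bases = 48 columns
each, and the within-trial time ramp 6).

Fitting uses elastic-net regularization (mixing 0.9 lasso / 0.1 ridge)
with a regularization path chosen by 5-fold cross-validation on a 70%
training block; goodness of fit is the deviance-based pseudo explained
variance (pseudo-E.V.) on the held-out 30%, against a mean-activity null.
The solver is a proximal-gradient (FISTA) Poisson elastic net fitted to
all neurons of a session simultaneously (they share the design matrix),
which keeps population-scale fitting tractable on one CPU.

Classification follows a conservative sequence: task-related (block-
shuffle significance of the pseudo-E.V. plus at least one contributing
variable), then error-related (error removal hurts, error coefficients
exceed both velocity and away-control coefficients, excitatory marginal
response), then a single assigned n per neuron by argmax of the per-n
coefficient summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import behavior
from .behavior import ErrorEvents, TrajectorySession

FRAME_RATE = 5.67          # Hz
BASIS_WINDOW = 2.0         # s, forward and backward
N_BASIS = 6
N_VELOCITY_BINS = 8
ACTIVITY_THRESHOLD = 20.0  # inclusion: activity must exceed this at least once

VARIANTS = ("standard", "control", "modified", "modified_control")
EXPECTED_COLUMNS = {"standard": 138, "control": 138,
                    "modified": 114, "modified_control": 108}


# ---------------------------------------------------------------------------
# temporal basis


@dataclass(frozen=True)
class BasisSet:
    """Six raised-cosine bumps tiling [-2 s, +2 s] on the frame grid."""

    lags_s: np.ndarray      # lag times of the sampled grid
    kernels: np.ndarray     # (n_lags, 6), each column one basis function
    centers: np.ndarray     # s

    @property
    def n_functions(self) -> int:
        return self.kernels.shape[1]


def raised_cosine_basis(frame_rate: float = FRAME_RATE,
                        window: float = BASIS_WINDOW,
                        n_functions: int = N_BASIS) -> BasisSet:
    """Evenly spaced raised cosines ``0.5*(1 + cos(pi*(t-c)/w))``.

    Centers span [-window, window]; the half-width ``w`` equals twice the
    center spacing so adjacent bumps overlap and the set has no coverage
    gaps on the open interval.  Peak value is 1.
    """
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    centers = np.linspace(-window, window, n_functions)
    w = 2 * (centers[1] - centers[0])
    max_lag = int(np.floor(window * frame_rate))
    lags = np.arange(-max_lag, max_lag + 1) / frame_rate
    K = np.zeros((len(lags), n_functions))
    for j, c in enumerate(centers):
        inside = np.abs(lags - c) <= w
        K[inside, j] = 0.5 * (1 + np.cos(np.pi * (lags[inside] - c) / w))
    return BasisSet(lags_s=lags, kernels=K, centers=centers)


def _convolve_basis(signal: np.ndarray, basis: BasisSet) -> np.ndarray:
    """Convolve one frame-rate signal with every basis function.

    The basis spans negative and positive lags, so column j at frame t
    reads ``sum_tau signal[t - tau] * k_j(tau)`` with tau in lag frames.
    """
    n = len(signal)
    half = (len(basis.lags_s) - 1) // 2
    out = np.empty((n, basis.n_functions))
    for j in range(basis.n_functions):
        full = np.convolve(signal, basis.kernels[:, j], mode="full")
        out[:, j] = full[half: half + n]
    return out


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    X: np.ndarray                    # frames x columns, z-scored
    groups: List[str]                # per-column group label
    variant: str
    frame_times: np.ndarray
    basis: BasisSet

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def columns_of(self, group_prefix: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups)
                         if g.startswith(group_prefix)], dtype=int)

    @property
    def top_groups(self) -> List[str]:
        """Task-variable groups at the granularity of the contribution
        tests: the error family, the two velocity families, and time."""
        tops = []
        for g in self.groups:
            top = g.split(":")[0]
            if top not in tops:
                tops.append(top)
        return tops


def frame_grid(session: TrajectorySession,
               frame_rate: float = FRAME_RATE) -> np.ndarray:
    t0 = float(session.trajectory["t"].iloc[0])
    t1 = float(session.trajectory["t"].iloc[-1])
    return np.arange(t0, t1, 1.0 / frame_rate)


def _impulses(times: Sequence[float], frame_times: np.ndarray) -> np.ndarray:
    """Single-frame unit impulses at the frames nearest the event times."""
    sig = np.zeros(len(frame_times))
    if len(frame_times) < 2:
        return sig
    dt = frame_times[1] - frame_times[0]
    for ev in np.asarray(times, dtype=float):
        i = int(np.searchsorted(frame_times, ev))
        for cand in (i - 1, i):
            if 0 <= cand < len(sig) and abs(frame_times[cand] - ev) <= dt:
                sig[cand] = 1.0
                break
    return sig


def _velocity_channels(df: pd.DataFrame, frame_times: np.ndarray) -> np.ndarray:
    """Speed-carrying time series for 8 direction bins at the frame rate.

    The 10-ms velocity is averaged within each frame bin; its angle picks
    one of eight equally spaced direction bins (centered on 0, 45, ...,
    315 degrees) and the channel carries the movement speed.
    """
    xy = df[["x", "y"]].to_numpy()
    t = df["t"].to_numpy()
    vel = np.diff(xy, axis=0) / behavior.DT
    tv = t[1:]
    n = len(frame_times)
    channels = np.zeros((n, N_VELOCITY_BINS))
    frame_idx = np.searchsorted(frame_times, tv, side="right") - 1
    ok = (frame_idx >= 0) & (frame_idx < n)
    speed = np.linalg.norm(vel, axis=1)
    ang = np.degrees(np.arctan2(vel[:, 1], vel[:, 0])) % 360.0
    bins = (np.round(ang / 45.0).astype(int)) % N_VELOCITY_BINS
    counts = np.zeros((n, N_VELOCITY_BINS))
    np.add.at(channels, (frame_idx[ok], bins[ok]), speed[ok])
    np.add.at(counts, (frame_idx[ok], bins[ok]), 1)
    with np.errstate(invalid="ignore"):
        channels = np.where(counts > 0, channels / np.maximum(counts, 1), 0.0)
    return channels


def _time_ramp(session: TrajectorySession,
               frame_times: np.ndarray) -> np.ndarray:
    """Monotonic within-trial frame counter (0 outside trials)."""
    ramp = np.zeros(len(frame_times))
    for _, tr in session.trials.iterrows():
        mask = (frame_times >= tr["t_start"]) & (frame_times <= tr["t_end"])
        ramp[mask] = np.arange(1, mask.sum() + 1)
    return ramp


def _away_accumulation_times(events: ErrorEvents, max_n: int) -> Dict[int, np.ndarray]:
    """Onset times of the n-th away movement per trial (control predictors)."""
    out = {n: [] for n in range(1, max_n + 1)}
    for trial, grp in events.away.groupby("trial"):
        ts = grp["time"].to_numpy()
        for n in range(1, min(len(ts), max_n) + 1):
            out[n].append(ts[n - 1])
    return {n: np.asarray(v) for n, v in out.items()}


def build_design_matrix(events: ErrorEvents, session: TrajectorySession,
                        frame_times: Optional[np.ndarray] = None,
                        variant: str = "standard",
                        basis: Optional[BasisSet] = None) -> DesignMatrix:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if frame_times is None:
        frame_times = frame_grid(session)
    if basis is None:
        frame_rate = 1.0 / float(frame_times[1] - frame_times[0])
        basis = raised_cosine_basis(frame_rate)

    blocks: List[np.ndarray] = []
    groups: List[str] = []

    def add(signal: np.ndarray, label: str) -> None:
        conv = _convolve_basis(signal, basis)
        blocks.append(conv)
        groups.extend([f"{label}:b{j}" for j in range(basis.n_functions)])

    if variant == "standard":
        for n in range(1, events.max_n + 1):
            add(_impulses(events.onset_times(n), frame_times), f"error:n{n}")
    elif variant == "control":
        away = _away_accumulation_times(events, events.max_n)
        for n in range(1, events.max_n + 1):
            add(_impulses(away[n], frame_times), f"away:n{n}")
    elif variant == "modified":
        toward = events.toward
        if "side" not in toward.columns or toward["side"].isna().any():
            raise ValueError("modified variant requires side labels")
        for side in ("high", "low"):
            times = toward.loc[toward["side"] == side, "time"].to_numpy()
            add(_impulses(times, frame_times), f"error:{side}")
    else:  # modified_control: single-step away movements
        away_first = _away_accumulation_times(events, 1)[1]
        add(_impulses(away_first, frame_times), "away:n1")

    add_velocity = _velocity_channels(session.trajectory, frame_times)
    for d in range(N_VELOCITY_BINS):
        add(add_velocity[:, d], f"object_velocity:d{d}")
    joy = _velocity_channels(session.joystick, frame_times)
    for d in range(N_VELOCITY_BINS):
        add(joy[:, d], f"joystick_velocity:d{d}")
    add(_time_ramp(session, frame_times), "time")

    X = np.concatenate(blocks, axis=1)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    dm = DesignMatrix(X=X, groups=groups, variant=variant,
                      frame_times=frame_times, basis=basis)
    if dm.n_columns != EXPECTED_COLUMNS[variant]:
        raise AssertionError(
            f"{variant} design matrix has {dm.n_columns} columns, "
            f"expected {EXPECTED_COLUMNS[variant]}")
    return dm


# ---------------------------------------------------------------------------
# deviance and pseudo explained variance


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Deviance vs. the saturated model: ``2*sum(y*log(y/mu) - (y - mu))``.

    Valid for nonnegative real-valued y (quasi-Poisson form); the
    ``y log y`` term is 0 at y = 0.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0) or np.any((mu == 0) & (y > 0)):
        raise ValueError("predicted rates must be positive where y > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / np.where(mu > 0, mu, 1.0)),
                        0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def pseudo_ev(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Deviance-based pseudo explained variance vs. a mean-activity null.

    ``1 - D(y_hat) / D(y_bar)``; undefined (raises) for constant y.
    """
    y = np.asarray(y, dtype=float)
    ybar = float(y.mean())
    if ybar <= 0 or np.allclose(y, ybar):
        raise ValueError("pseudo-E.V. undefined for constant activity")
    d_null = poisson_deviance(y, np.full_like(y, ybar))
    if d_null == 0:
        raise ValueError("null deviance is zero")
    return 1.0 - poisson_deviance(y, y_hat) / d_null


# ---------------------------------------------------------------------------
# elastic-net Poisson solver (all neurons at once)


def _poisson_enet_path(X: np.ndarray, Y: np.ndarray, alphas: np.ndarray,
                       l1_ratio: float = 0.9, max_iter: int = 200,
                       tol: float = 1e-6) -> Tuple[np.ndarray, np.ndarray]:
    """FISTA proximal-gradient Poisson elastic net along a penalty path.

    X: (F, P) standardized predictors; Y: (F, N) nonnegative traces.
    Returns (betas (len(alphas), P, N), intercepts (len(alphas), N)).
    The intercept is unpenalized.  Warm starts descend the path.
    """
    F, P = X.shape
    N = Y.shape[1]
    ybar = Y.mean(axis=0)
    B = np.zeros((P, N))
    b0 = np.log(np.maximum(ybar, 1e-8))
    betas = np.empty((len(alphas), P, N))
    intercepts = np.empty((len(alphas), N))
    # Lipschitz proxy for the step size: largest eigenvalue of X'X/F times
    # a cap on the rate; refreshed via backtracking below.
    XtX_norm = np.linalg.norm(X, ord=2) ** 2 / F
    for ai, alpha in enumerate(alphas):
        l1 = alpha * l1_ratio
        l2 = alpha * (1 - l1_ratio)
        Z = B.copy()
        z0 = b0.copy()
        t_mom = 1.0
        step = 1.0 / (XtX_norm * max(float(ybar.max()), 1.0) * 4.0)
        prev_obj = np.inf
        for it in range(max_iter):
            eta = np.clip(X @ Z + z0, -30.0, 30.0)
            mu = np.exp(eta)
            G = X.T @ (mu - Y) / F
            g0 = (mu - Y).mean(axis=0)
            B_new = Z - step * (G + l2 * Z)
            thr = step * l1
            B_new = np.sign(B_new) * np.maximum(np.abs(B_new) - thr, 0.0)
            b0_new = z0 - step * g0
            t_new = 0.5 * (1 + np.sqrt(1 + 4 * t_mom ** 2))
            Z = B_new + ((t_mom - 1) / t_new) * (B_new - B)
            z0 = b0_new + ((t_mom - 1) / t_new) * (b0_new - b0)
            delta = max(float(np.abs(B_new - B).max()),
                        float(np.abs(b0_new - b0).max()))
            B, b0, t_mom = B_new, b0_new, t_new
            if it % 20 == 19:
                eta = np.clip(X @ B + b0, -30.0, 30.0)
                obj = float((np.exp(eta) - Y * eta).mean()
                            + l1 * np.abs(B).mean() + 0.5 * l2 * (B ** 2).mean())
                if not np.isfinite(obj) or obj > prev_obj * 1.5:
                    # diverging: halve the step and restart momentum
                    step *= 0.5
                    Z, z0, t_mom = B.copy(), b0.copy(), 1.0
                prev_obj = min(prev_obj, obj)
            if delta < tol:
                break
        betas[ai] = B
        intercepts[ai] = b0
    return betas, intercepts


def _alpha_grid(X: np.ndarray, Y: np.ndarray, l1_ratio: float,
                n_alphas: int) -> np.ndarray:
    F = X.shape[0]
    ybar = Y.mean(axis=0)
    grad0 = np.abs(X.T @ (Y - ybar)) / F
    a_max = float(grad0.max()) / max(l1_ratio, 1e-3)
    a_max = max(a_max, 1e-4)
    return np.geomspace(a_max, a_max * 1e-3, n_alphas)


@dataclass(frozen=True)
class GlmConfig:
    l1_ratio: float = 0.9          # elastic-net mixing (lasso share)
    train_fraction: float = 0.7
    n_folds: int = 5
    n_alphas: int = 8
    n_shuffles: int = 1000
    shuffle_block_s: float = 2.0
    alpha_level: float = 0.05
    activity_threshold: float = ACTIVITY_THRESHOLD
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.l1_ratio <= 1:
            raise ValueError("l1_ratio must lie in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class NeuronFit:
    """Elastic-net GLM fit and classification state for one neuron."""

    intercept: float
    coef: np.ndarray
    groups: List[str]
    alpha: float
    pseudo_ev: float
    variant: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    shuffle_null: Optional[np.ndarray] = None
    contributions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    task_related: Optional[bool] = None
    error_related: Optional[bool] = None
    excluded_by_velocity: bool = False
    excluded_by_control: bool = False
    assigned_n: Optional[int] = None

    def group_max_coef(self, prefix: str) -> float:
        idx = [i for i, g in enumerate(self.groups) if g.startswith(prefix)]
        if not idx:
            return np.nan
        return float(np.max(self.coef[idx]))

    def per_n_coef(self) -> Dict[str, float]:
        """Per-error-type maximum coefficient (the pre-argmax summary)."""
        labels = sorted({g.split(":")[1] for g in self.groups
                         if g.startswith("error:")})
        return {lab: self.group_max_coef(f"error:{lab}") for lab in labels}


def train_test_split_frames(n_frames: int, train_fraction: float,
                            rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Contiguous 70/30 split: the test block starts at a random frame
    (wrapping around), so basis-width leakage is limited to two borders."""
    n_test = int(round(n_frames * (1 - train_fraction)))
    start = int(rng.integers(0, n_frames))
    test = (start + np.arange(n_test)) % n_frames
    mask = np.ones(n_frames, dtype=bool)
    mask[test] = False
    return np.where(mask)[0], np.sort(test)


def fit_population(Y: np.ndarray, dm: DesignMatrix, config: GlmConfig,
                   rng: Optional[np.random.Generator] = None,
                   per_neuron_alpha: Optional[np.ndarray] = None
                   ) -> List[NeuronFit]:
    """Fit elastic-net Poisson GLMs to every column of Y (frames x neurons).

    All neurons share the design matrix, the train/test split, the CV
    folds and the penalty path; the per-neuron penalty is the path value
    minimizing that neuron's mean CV deviance.  ``per_neuron_alpha``
    skips the CV and fits each neuron at the given penalty — used for
    control-variant fits at the penalty matched to the main fit.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != dm.X.shape[0]:
        Y = Y.T
    F, N = Y.shape
    if np.any(Y < 0):
        raise ValueError("activity traces must be nonnegative")
    if np.any(Y.max(axis=0) == 0):
        raise ValueError("all-zero activity trace: fit rejected")
    train_idx, test_idx = train_test_split_frames(
        F, config.train_fraction, rng)
    Xtr, Ytr = dm.X[train_idx], Y[train_idx]
    if per_neuron_alpha is not None:
        alphas = np.unique(np.asarray(per_neuron_alpha, dtype=float))[::-1]
        best_ai = np.array([int(np.where(alphas == a)[0][0])
                            for a in per_neuron_alpha])
    else:
        alphas = _alpha_grid(Xtr, Ytr, config.l1_ratio, config.n_alphas)
        # 5-fold CV on contiguous training blocks
        folds = np.array_split(np.arange(len(train_idx)), config.n_folds)
        cv_dev = np.zeros((len(alphas), N))
        for fold in folds:
            mask = np.ones(len(train_idx), dtype=bool)
            mask[fold] = False
            betas, b0s = _poisson_enet_path(Xtr[mask], Ytr[mask], alphas,
                                            config.l1_ratio, config.max_iter)
            Xv, Yv = Xtr[fold], Ytr[fold]
            for ai in range(len(alphas)):
                mu = np.exp(np.clip(Xv @ betas[ai] + b0s[ai], -30, 30))
                dev = 2.0 * (np.where(Yv > 0, Yv * np.log(
                    np.where(Yv > 0, Yv, 1.0) / mu), 0.0) - (Yv - mu))
                cv_dev[ai] += dev.sum(axis=0)
        best_ai = cv_dev.argmin(axis=0)

    betas, b0s = _poisson_enet_path(Xtr, Ytr, alphas, config.l1_ratio,
                                    config.max_iter)
    fits: List[NeuronFit] = []
    for j in range(N):
        ai = int(best_ai[j])
        beta = betas[ai, :, j]
        b0 = float(b0s[ai, j])
        mu_test = np.exp(np.clip(dm.X[test_idx] @ beta + b0, -30, 30))
        ev = pseudo_ev(Y[test_idx, j], mu_test)
        fits.append(NeuronFit(intercept=b0, coef=beta.copy(),
                              groups=list(dm.groups), alpha=float(alphas[ai]),
                              pseudo_ev=float(ev), variant=dm.variant,
                              train_idx=train_idx, test_idx=test_idx))
    return fits


def fit_glm(activity: np.ndarray, dm: DesignMatrix, config: GlmConfig,
            rng: Optional[np.random.Generator] = None) -> NeuronFit:
    """Single-neuron convenience wrapper around :func:`fit_population`."""
    return fit_population(activity[:, None], dm, config, rng)[0]


# ---------------------------------------------------------------------------
# classification


def _block_shifts(n: int, block: int, n_shuffles: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Random circular row rotations by whole blocks (autocorrelation kept)."""
    n_blocks = max(n // block, 1)
    return (rng.integers(1, n_blocks, size=n_shuffles) * block) % n


def classify_task_related(fit: NeuronFit, dm: DesignMatrix, y: np.ndarray,
                          config: GlmConfig,
                          rng: Optional[np.random.Generator] = None) -> NeuronFit:
    """Block-shuffle test of the held-out pseudo-E.V. plus per-variable
    contribution tests.

    The neuron is task-related iff its pseudo-E.V. is positive, exceeds
    the (1 - alpha) quantile of 1000 block-shuffled pseudo-E.V.s
    (predictor rows circularly rotated by random multiples of the 2-s
    block), and at least one task variable contributes: its isolated
    pseudo-E.V. is positive and shuffling only its columns drops the
    model pseudo-E.V. significantly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    Xte = dm.X[fit.test_idx]
    yte = y[fit.test_idx]
    F = len(fit.test_idx)
    block = max(int(round(config.shuffle_block_s
                          / (dm.frame_times[1] - dm.frame_times[0]))), 1)
    shifts = _block_shifts(F, block, config.n_shuffles, rng)
    beta, b0 = fit.coef, fit.intercept

    # circular row rotation commutes with X @ beta, so every shuffle is a
    # rotation of the linear predictor — no matrix products in the loop
    roll_idx = (np.arange(F)[None, :] - shifts[:, None]) % F
    ylog = np.where(yte > 0, yte * np.log(np.where(yte > 0, yte, 1.0)), 0.0)
    d_null_model = poisson_deviance(yte, np.full(F, max(yte.mean(), 1e-12)))

    def evs_of_etas(etas: np.ndarray) -> np.ndarray:
        """Pseudo-E.V. for each row of linear predictors (+ intercept)."""
        mu = np.exp(np.clip(etas + b0, -30.0, 30.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2.0 * ((ylog - yte * np.log(mu)).sum(axis=1)
                         - (yte.sum() - mu.sum(axis=1)))
        return 1.0 - dev / d_null_model

    eta = Xte @ beta
    null = evs_of_etas(eta[roll_idx])
    fit.shuffle_null = null
    p_model = float(np.mean(null >= fit.pseudo_ev))

    contributions: Dict[str, Dict[str, float]] = {}
    any_contributing = False
    for top in dm.top_groups:
        cols = dm.columns_of(top)
        eta_g = Xte[:, cols] @ beta[cols]
        # isolated pseudo-E.V.: only this group's contribution + intercept
        own_ev = float(evs_of_etas(eta_g[None, :])[0])
        # removal: shuffle only this group's columns, keep the rest
        drops = evs_of_etas((eta - eta_g)[None, :] + eta_g[roll_idx])
        p_removal = float(np.mean(drops >= fit.pseudo_ev))
        contributing = (own_ev > 0) and (p_removal < config.alpha_level)
        contributions[top] = {"own_ev": own_ev, "p_removal": p_removal,
                              "contributing": float(contributing)}
        any_contributing = any_contributing or contributing
    fit.contributions = contributions
    fit.task_related = bool(fit.pseudo_ev > 0
                            and p_model < config.alpha_level
                            and any_contributing)
    return fit


def marginal_response(fit: NeuronFit, group_prefix: str,
                      basis: BasisSet) -> np.ndarray:
    """Model-derived per-event response of one predictor group.

    Exponentiated temporal kernel ``exp(sum_j beta_j k_j(tau))`` of the
    group's basis coefficients; other variables are marginalized out
    (their multiplicative factors dropped).  Flat profile of value 1 for
    all-zero coefficients.
    """
    idx = [i for i, g in enumerate(fit.groups) if g.startswith(group_prefix)]
    if not idx:
        raise ValueError(f"no columns match {group_prefix!r}")
    kernel = basis.kernels @ fit.coef[idx]
    return np.exp(kernel)


def group_contribution(fit: NeuronFit, dm: DesignMatrix,
                       group_prefix: str) -> np.ndarray:
    """Frame-wise multiplicative contribution ``exp(X_g beta_g)``; the
    product over all top groups times ``exp(intercept)`` recovers the
    full model prediction."""
    cols = dm.columns_of(group_prefix)
    return np.exp(np.clip(dm.X[:, cols] @ fit.coef[cols], -30, 30))


def classify_error_neuron(fit: NeuronFit, control_fit: NeuronFit,
                          basis: Optional[BasisSet] = None) -> NeuronFit:
    """Error-neuron test against movement and reinitialization covariates.

    Requires: task-related; the error family contributes (removal hurts);
    the maximum error coefficient exceeds the maximum object- and
    joystick-velocity coefficients and the maximum away-control
    coefficient (from the control-variant fit); and the assigned n-step
    marginal response is excitatory.  ``assigned_n`` is the argmax over n
    of the per-n maximum coefficient.
    """
    if fit.task_related is None:
        raise ValueError("run classify_task_related first")
    fit.error_related = False
    fit.assigned_n = None
    if not fit.task_related:
        return fit
    err_contrib = fit.contributions.get("error", {})
    if not err_contrib.get("contributing", 0.0):
        return fit
    err_max = fit.group_max_coef("error")
    if not (err_max > fit.group_max_coef("object_velocity")
            and err_max > fit.group_max_coef("joystick_velocity")):
        fit.excluded_by_velocity = True
        return fit
    if not err_max > control_fit.group_max_coef("away"):
        fit.excluded_by_control = True
        return fit
    per_n = fit.per_n_coef()
    best = max(per_n, key=lambda k: per_n[k])
    if per_n[best] <= 0:
        return fit  # only excitatory modulation counts
    if basis is not None:
        prof = marginal_response(fit, f"error:{best}", basis)
        if prof.max() <= 1.0:
            return fit
    fit.error_related = True
    fit.assigned_n = int(best[1:]) if best.startswith("n") else best
    return fit


def fits_table(fits: Sequence[NeuronFit],
               regions: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-neuron classification table (CSV-ready)."""
    rows = []
    for i, f in enumerate(fits):
        rows.append({
            "neuron": i,
            "region": regions[i] if regions is not None else "",
            "pseudo_ev": f.pseudo_ev,
            "task_related": bool(f.task_related) if f.task_related is not None
            else None,
            "error_related": bool(f.error_related)
            if f.error_related is not None else None,
            "assigned_n": f.assigned_n,
        })
    return pd.DataFrame(rows)
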