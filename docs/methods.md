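# Methods

`rpeacc` couples a deep reinforcement-learning simulator of
reward-prediction-error (RPE) accumulation with a behavioral and neural
encoding-analysis pipeline, plus a synthetic-data generator that supplies
ground-truthed inputs for every stage.  This note documents the models,
the defaults and the reasoning behind the open design choices.

## 1. The RL model (`rl_env`, `rl_agent`)

### Environment

A point agent navigates the square arena `[-1, 1]^2` (arbitrary units)
toward a centered reward zone of extent `0.4 x 0.4`.  Trials start from a
uniform random position outside the zone (rejection sampling) and end on
zone entry or after 60 steps.  The 256 discrete actions comprise 192
no-ops (75%) and 64 movements — 8 directions x 8 speeds, with the speed
range depending on direction (cardinal 0.216–0.720; the slow diagonal
45°/225° 0.072–0.240; the fast diagonal 135°/315° 0.360–1.200 a.u. per
step), a diagonal bias patterned on mouse-driven object kinematics.  The
eight speeds per direction are evenly spaced inclusive of the printed
endpoints — the simplest scheme consistent with "varying speeds".
Positions are clamped to the arena; a clamped move is classified by its
realized displacement.

Reward schedules: `standard` pays 1.0 on zone entry; `interleaved` pays
1.0 on a randomly pre-assigned half of trials (omission on the rest);
`split` divides the zone at x = 0 into a low (0.125, left) and high
(1.25, right) half.

Every transition gets exactly one movement class: `goal` (zone entered),
`none` (no displacement), `away` (Euclidean distance to the zone center
increased), and otherwise `toward_short` or `lateral_miss`, split by
whether the infinite ray along the displacement would eventually cross
the zone square.  The last two operationalize the two erroneous-movement
scenarios (stopping short; aiming too laterally) without extra
parameters.

### Agent and learning rule

The actor-critic is a shared multilayer perceptron (four hidden layers of
256 rectified-linear units) with a softmax policy head over the 256
actions and a linear scalar value head, written directly in numpy with
explicit backpropagation and an Adam optimizer; training is single-thread
deterministic for a fixed seed.  Heads are initialized at small scale
(sd 0.01) so a naive agent starts with a near-uniform policy and
near-zero value estimates.

The single-step RPE is non-bootstrapped:

    delta_t = r_t - V(s_t)

— the difference between the obtained reward and the value of the
*current* state, with no discounted next-state value.  It models an agent
(like a trained mouse) that expects the reward to be attainable with a
single discrete movement.  The RPE sequence lives on movement events
("strokes"): toward errors and goal entries.  Moves away from the zone
are reinitialization and excluded; no-op steps carry no RPE — like the
stroke-locked reward expectation of the animal, prediction errors occur
when something is attempted.

Advantages accumulate n single-step RPEs with generalized-advantage
weights:

    A_t(n) = sum_{k=0}^{min(n-1, T-t)} (gamma*lambda)^k delta_{t+k}

with `gamma = lambda = 0.95`, truncated at trial end, computed for every
event in the sequence (sliding window).  The critic regresses onto the
accumulated estimate `A_t(n) + V(s_t)` — the standard target paired with
generalized advantage estimation.  Both choices matter scientifically,
and the package keeps the alternatives switchable
(`PpoConfig.rpe_events`, `PpoConfig.value_target`, `PpoConfig.update_scope`)
because the empirical differences are instructive:

* putting no-op steps into the RPE sequence (`rpe_events="all"`) lets a
  sliding n-step advantage credit idle steps that happen to precede a
  goal; large-n agents then learn to idle and n = 1 outperforms n = 8 —
  the opposite of the learning-with-n effect;
* Monte-Carlo critic targets (`value_target="mc"`, the within-trial
  discounted empirical return `gamma^(T-t) r`) hand the critic
  full-horizon reward information for every n, washing out the
  n-dependence; with the strokes-only sequence they additionally
  destabilize learning (toward-error punishments dominate the clipped
  updates and movement collapses);
* with the default pairing — stroke events plus GAE targets — reward
  information propagates backward only over the n-step event horizon,
  and learning speed, expert reward-evoked RPEs and expert pre-goal
  RPEs all depend on n as described.

Updates are clipped-surrogate PPO: probability ratios clipped to
`[1-eps, 1+eps]` with `eps = 0.2`, value-loss coefficient 0.2, entropy
bonus 0.02, gradient norm capped at 0.4, learning rate 1e-5, ten update
epochs per episode batch (all included steps of the episode).  The
per-window phrasing of the update schedule ("after n steps ... computed
for the update") is realized at episode end: advantages are identical,
and the episode batch simply concatenates the windows.

Naive agents are snapshots before the first gradient step (summaries use
100 evaluation episodes with frozen initial parameters); expert summaries
average the final 10% of training episodes (episodes 3600–4000 at the
full 4000-episode scale).  Evaluation always samples from the softmax
(stochastic policy), never argmax.

### Agent analyses

* value maps: mean critic output over 100,000 uniform states binned
  40 x 40 (empty bins are missing, not zero);
* unit tuning: final-hidden-layer activations on a 40 x 40 state grid
  (spatial) and averaged over rollout steps grouped by the direction of
  the sampled action (direction, 8 bins);
* RPE summaries: reward-evoked RPE = `delta` at the goal step; pre-goal
  RPEs = `delta` at toward errors; under the interleaved schedule
  rewarded and omitted goals are separated (the omission RPE equals `-V`
  at the goal state identically); under the split schedule RPEs are
  stratified by arena half.

### Problem sizes for the packaged checks

The packaged tests train at 1500 episodes with 5 seeds per n for the
standard-schedule comparisons and one seed each for the interleaved and
split schedules; the acceptance script uses 1000 episodes with 2 seeds
per n.  These sizes (rather than 10 agents x 4000 episodes) were chosen
so the full suite completes on a laptop-class single core while the
qualitative orderings (learning with n, naive-to-expert RPE changes,
interleaved and split contrasts) are already stable.

A property of this variant worth knowing: steps-to-goal typically peaks
mid-training and partially regresses before settling.  Once the critic
assigns value to states along the approach, every erroneous stroke is
punished by `-V`, and training settles into an equilibrium where error
punishment balances goal reinforcement.  Larger n delays and softens
this regression (goal RPEs reach further back through the accumulated
advantage), which is also visible in the final-performance ordering
across n.

## 2. Behavioral analysis (`behavior`)

Sessions hold object and joystick trajectories at 10-ms sampling in a
100 x 100 mm arena with a centered 40 x 40 mm reward zone, lick times,
and a trial table.  Strokes are object movements whose speed exceeds
60 mm/s, at least 200 ms apart (peak detection on the displacement-based
speed; the threshold is applied as peak height, with peak prominence the
documented alternative).  Erroneous movements are peaks of the
time-differenced distance to the arena center (radial speed) above
60 mm/s and 200 ms apart, `toward` when distance decreases without zone
entry by that movement (entry within 200 ms marks the goal approach
instead), `away` when it increases; the 200-ms separation is enforced
within each class.  The n-th toward error of a trial defines the
accumulation onset `delta(n)`, n = 1..6, reset at the intertrial
interval; trials shorter than 200 ms are skipped.

Latency for n = 1 is measured from trial start (the definition between
consecutive errors leaves the first error without a predecessor).
Peri-event lick histograms average a 10-ms lick raster over events in a
±2 s window (matching the encoding-model basis span), bin it at 100 ms,
subtract the bin at −50 ms, and optionally divide by the maximum of a
caller-chosen reference histogram (the five enumerated normalization
modes all reduce to this); the comparison scalar sums the first five
post-event bins.

The empirical state value is the spatial map of
`E[reward_size * 0.99^(T-t)]` over rewarded trials only (10-ms steps, T
the rewarded trial end); incomplete trials contribute nothing, and the
reward sizes 1.25/0.125 reproduce the high/low split-zone scaling.

## 3. Encoding models (`encoding_glm`)

Six raised cosines `0.5*(1 + cos(pi (t-c)/w))` with centers evenly
spaced on [-2 s, 2 s] and half-width `w` twice the center spacing tile
the window with no coverage gaps; each peaks at 1.  Predictors: error
onsets (single-frame impulses at each `delta(n)` onset), object and
joystick velocity split into 8 direction bins carrying speed, and a
monotonic within-trial time ramp — all convolved with the basis and
z-scored across the session.  Column counts are fixed by construction:
138 (standard), 138 (away-accumulation control), 114 (split-task variant
with high/low single-step errors), 108 (its away control).  The
behavioral accumulation signal is a boxcar, but the model predictors use
onset impulses; both forms appear in the source descriptions and the
impulse-plus-basis form is the one appropriate for kernel estimation.

The GLM is Poisson with log link — the description fixes the log link
(activity as an exponentiated weighted sum), and the Poisson deviance is
its standard companion, valid for the nonnegative real-valued
deconvolved traces (quasi-Poisson reading).  Goodness of fit is the
deviance-based pseudo explained variance `1 - D(yhat)/D(ybar)` on a
held-out 30% of frames against the mean-activity null.  The train/test
split is a contiguous random-start block (wrapping), so leakage through
the ±2-s basis is limited to two block borders; the 5 CV folds on the
training block are contiguous for the same reason.

Fitting is elastic net (0.9 lasso / 0.1 ridge) along an 8-value
geometric penalty path from the data-derived maximum, warm-started, by
proximal-gradient (FISTA) descent with backtracking — written in-house
because the per-neuron fit had to scale to populations: all neurons of a
session share the design matrix, so the solver fits every neuron
simultaneously as one matrix-valued problem (a ~50x wall-clock saving
over per-neuron library fits; the solver is cross-checked against
statsmodels' penalized Poisson GLM in the test suite).  Only neurons
whose activity exceeds 20 (trace units) at least once are fitted.

Classification:

* **task-related** — held-out pseudo-E.V. positive, above the 95th
  percentile of 1000 block-shuffle nulls (predictor rows circularly
  rotated by random multiples of a 2-s block, preserving
  autocorrelation), and at least one task variable contributing
  (isolated pseudo-E.V. positive and a significant drop when only that
  variable's columns are shuffled — the removal statistic is the shuffle
  percentile of the full-model pseudo-E.V.);
* **error-related** — task-related, error family contributing, maximum
  error coefficient above both velocity maxima and above the
  away-control fit's maximum coefficient, and excitatory marginal
  response.  Group comparisons use the maximum coefficient within the
  group, chosen as the summary because the basis spreads one kernel over
  6 coefficients and the peak is scale-matched across groups;
* **assigned n** — argmax over n of the per-n maximum coefficient.

Marginalized response profiles exponentiate one group's kernel
(`exp(sum_j beta_j k_j(tau))`); the product over groups times
`exp(intercept)` recovers the full prediction exactly.

## 4. Population statistics (`population`)

Activity onsets are the first within-trial frame where session-z-scored
activity exceeds 2.  For sequence analysis, trials are split into random
halves (the odd/even alternative is a one-line change); neurons are
ranked by mean onset in the training half and a least-squares slope is
fitted between that sorting index and the trial-averaged onset rank in
the held-out half (rank among neurons active in that trial, ties to the
earlier frame).  The permutation null (1000 draws) shuffles onsets
across neurons within each test trial.

RPE-sign classification at the trial offset of interleaved sessions uses
the three epoch conditions (reward epoch 0–2 s vs. baseline −4 to
−3.5 s; rewarded vs. nonrewarded; post- vs. pre-offset maximum), each at
a one-tailed trial bootstrap p < 0.01 (1000 draws; epoch-comparison
bootstrap counts match the other resampling procedures, whose sizes are
stated).  Positive and negative labels are mutually exclusive by
construction.  Reward-evoked responses are post-reward means (0–0.5 s)
minus the single-frame baseline at −4 s.  The long-trial control splits
above-mean-duration trials by error content and compares per-neuron
trial-averaged activity on a log10 scale (floor 1e-3 guards silent
traces).  Region summaries require more than five task-related cells per
region, normalize per-n error-neuron fractions to the across-region
maximum, and min-max normalize pooled n-bins (1–2, 3–4, 5–6 — the
"4–6" variant that appears once in the source is read as a typo for
5–6) to exactly [0, 1] across regions and environments; uncertainty
comes from 1000 session resamples with replacement.

## 5. Synthetic data (`synthetic`)

The generator emulates the task structure, not mouse biomechanics:
trials are sequences of ballistic strokes (squared-sine speed profiles,
peak well above the 60 mm/s threshold) with Gaussian positional jitter
(0.08 mm per 10-ms sample).  Toward errors approach the zone center and
stop at least 8 mm short; after each, the object glides back outward
below the detection threshold so the next planted stroke is again
detectable — a device for ground-truth cleanliness, not a claim about
mouse kinematics.  Away moves scale the radial position outward.
Completed trials end with a stroke into the zone, followed by a 4-s
reward period and 2-s intertrial interval.  Lick bursts follow toward
errors with probability proportional to the reward-expectation
parameter (naive 0.2, expert 0.9, interleaved 0.5), plus consumption
licking after rewards.  Profiles: naive ~4 toward errors per trial and
60% completion; expert ~1.2 and >99%; interleaved doubles trials to 120.

Neurons draw Poisson counts on `exp(offset + X beta_true)` — the exact
generative form the encoding model assumes — scaled by 12 trace units
per count so planted neurons clear the inclusion threshold; `beta_true`
concentrates on one predictor group with a smooth asymmetric
basis-weight bump.  Reward/omission neurons are injected directly as
exponential-decay kernels at trial offsets (reward delivery is not a GLM
predictor).  What passing recovery tests show is therefore internal
consistency of the pipeline (identifiability at realistic event counts
and rates), not robustness to the violations real data bring:
non-Poisson noise, slow drifts, correlated populations, imperfect
deconvolution.  The noise defaults are chosen for testability and are
config-exposed.

## 6. Numerical choices and degenerate inputs

* FISTA step size from the spectral norm of X with divergence-triggered
  halving; log-rates clipped at ±30 before exponentiation.
* Pseudo-E.V. is undefined (raises) for constant traces; all-zero traces
  are rejected before fitting.
* Peak detection ties and sub-sample timing follow scipy's `find_peaks`;
  radial-speed sign at the peak decides toward/away.
* Zone membership uses closed boundaries (a boundary hit counts as
  inside).
* Empty value-map bins are NaN; sequence analysis requires at least two
  trials with two active neurons and raises otherwise.
* All resampling (shuffles, bootstraps, permutations) flows from
  explicit `numpy.random.Generator` seeds; results are bit-reproducible.

## 7. Known limitations

* The RL agent is a single-thread float32 implementation; its learning
  curves match the described variant qualitatively but are not expected
  to be numerically identical to a GPU/PyTorch run.
* The critic-target choice (GAE target vs. empirical return) is the one
  genuinely open modeling decision; both are implemented, the default is
  justified above by its n-dependence.
* The generator's trajectories are piecewise-ballistic idealizations;
  detection thresholds tuned on them transfer to real data only insofar
  as real strokes are comparably fast and separated.
* No hierarchical pooling across sessions/animals beyond resampling; no
  spike inference; region labels are consumed as given.
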