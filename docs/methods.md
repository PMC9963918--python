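# Methods

## Task model

The task interleaves two independent environments ("worlds").  Each world
has two *equivalent* start states: the two options available in either start
state lead deterministically onto the same two non-branching three-state
paths, which end in 0–9 reward points multiplied by a cued stake (1× or 5×).
Twelve path states are decodable; start-state cues are not part of the
sequence analyses.  Defaults follow the study design this task family uses:
6 blocks × 24 trials (144 trials), worlds and start states drawn with equal
marginal probability.

Generator choices where the design leaves freedom (all configurable):

- **Reward drift** — per-path Gaussian random walk, SD 2 points/trial,
  *reflected* at 0 and 9.  Reflection keeps the printed bounds while
  preserving enough drift for model-free and model-based expectations to
  diverge; the long-run marginal is approximately uniform, hence symmetric
  about the 4.5 midpoint.  Initial rewards are uniform on [0, 9].
- **Pseudorandomization** — world runs capped at 3 consecutive repeats;
  stakes i.i.d. equiprobable.
- **Reaction times** — lognormal around 0.7 s (σ ≈ 0.15 s) plus a 9-ms
  additive cost on start-state-change trials, the planning-cost signature
  the RT regression is built to detect.

## Reinforcement-learning controllers

Model-free values Q[start, option] and model-based path values V[path] both
learn by the delta rule with a single shared rate α; the hybrid decision
value is w·V + (1−w)·Q passed through a softmax with inverse temperature β
(per-point scale).  Choices on the 0–9 point scale mean β ≈ 2–3 already
produces near-deterministic choice for value gaps of a couple of points.
Decisions taken here:

- **Initialization** at the reward midpoint 4.5 for both stores, avoiding
  first-trial optimism or pessimism.
- **Stakes do not scale learning**: the stores track raw points; stakes
  affect earnings only.
- **Perseveration** (a log-odds bonus for repeating the last same-world
  path choice) is implemented but off by default.
- **Fitting** — bounded L-BFGS-B from ≥ 5 random starts (default 10), w
  fitted directly on its [0, 1] box rather than through a logistic
  transform; with multiple starts the box-constrained search recovers
  boundary and interior generating values with |median bias| < 0.1 at the
  default data size (see the acceptance suite).  AIC and BIC are both
  reported.
- The **replay-modulated** variant adds β_high/β_low applied on world-change
  choices preceded by high/low feedback replay; the high/low split is a
  within-participant median split (ties to "low") of backward other-world
  feedback sequenceness on trials preceding a world change.

The **rarity** tracker applies the same delta rule to world appearance
indicators at rate 0.10 (a deliberately slow experience memory), initialized
at 0.5 per world; rarity is 1 − frequency, and the series exposed to
regressions is the *pre-trial* value.

## Behavioral regressions

The stay regression is a multilevel logistic model of stay on previous
same-world reward (z-scored within participant) × same-start, fitted by
variational Bayes with a random intercept and a random reward slope per
participant; on failure it falls back to a random-intercept model and then
to a pooled logit with cluster-robust (participant) covariance, the engine
used being recorded on the result.  The model-free signature is a positive
reward × same-start interaction; the model-based signature is a null
interaction, supported by a TOST equivalence test.  The default TOST bound
maps a medium standardized effect d = 0.5 to log-odds as d·π/√3 ≈ 0.907
(times the regressor SD, 1 after z-scoring).  The RT model is a linear
mixed model with a random intercept; memory probes count as correct only
when all three stages are correct, with participant-level bootstrap CIs.

## Sequenceness (TDLM)

Stage 1 regresses each state's reactivation series on the Δt-lagged series
of all 12 states jointly, with an intercept; rank-deficient designs fall
back to the minimum-norm solution with a warning, so flat (all-zero) series
yield zero matrices.  Stage 2 regresses the vectorized empirical matrix on
[T_F, T_B, T_cons, T_auto] without an additional intercept: T_cons (ones
off the diagonal) and T_auto (identity) jointly absorb the matrix mean and
the diagonal, so the diagonal informs only the autocorrelation control and
the four regressors remain linearly independent.  Exact linear combinations
of the four matrices are recovered to machine precision.

Aggregation is per-trial stage-1 matrices averaged within participant, then
stage 2 per lag, then the participant mean (a concatenated-samples variant
was considered and rejected as it conflates between-trial baseline shifts
with transitions).  The lag grid is 10–600 ms in 10-ms steps (60 lags);
analysis lags of 70 ms (forward) and 40 ms (backward) are configuration,
not inference — localization is re-runnable.

**Permutation threshold.**  The null reassigns the 12 states to the 4 × 3
path-position grid (uniform over unique non-identity permutations, default
500 draws); because stage 1 is invariant to the assignment, only the cheap
stage 2 is recomputed per permutation.  The threshold is the 95th
percentile of the across-lag absolute maximum of the group-mean curve, per
direction.  Trial-wise scores restrict T_F/T_B to a path subset (current or
other world) while keeping the controls global.

## Decoding

One-vs-rest lasso-regularized logistic classifiers are trained on the
sensor pattern at a single 200-ms post-stimulus latency, with the penalty
chosen by stratified 5-fold CV over a log-spaced grid (10⁻³–10³).
Applied to a window they yield per-time, per-state sigmoid probabilities
with no cross-state renormalization.  Reactivation significance compares
the mean per-timepoint *peak* probability against classifiers re-trained on
permuted labels: permuted classifiers do not align with patterns in
held-out windows, so their peak evidence stays near the base rate, whereas
a grand mean over all states is insensitive by construction (the true
state's gain is offset by the others' loss).  A null-class augmentation and
cross-state renormalization are deliberately not defaults.

## Replay–behavior linking

Trial-wise sequenceness is z-scored within participant, and continuous
regressors (e.g. rarity) are z-scored within participant as well, so
linking coefficients are on an approximately standardized scale and the
TOST bound of 0.5 (a medium effect in score-SD units) applies uniformly;
binary indicators stay 0/1.  The linking engine is a linear mixed model
with a random intercept (random slope optional), falling back to
cluster-robust OLS.  One-tailed z tests compare coefficients between
current/other world and planning/feedback cells; the across-participant
planning-vs-rarity trade-off is a Pearson correlation.

## Synthetic neural data

Reactivation series are Beta(1, 10) i.i.d. baseline (low, positive, bounded
— mimicking one-vs-rest classifier output off-state) plus injected events:
a bump of height *fidelity* on a path's three states at offsets
(0, Δt, 2Δt), order reversed for backward events, event counts Poisson with
the configured rate, onsets uniform where the triple fits; values clipped
to [0, 1].  The planning window is 2.34 s (2.5 s minus the first 160 ms)
and the feedback window 3.5 s (the latter part of a 5-s period), both on
the 10-ms grid.  The double-dissociation cohort couples the planning event
rate to the start-state-change indicator (+2 events) and the feedback event
rate to other-world rarity (gain 4 events per unit rarity) at fidelity 0.6
— a signal-to-noise regime where single-dataset localization is reliable
but trial-wise scores remain noisy, as in real decoding.

What the generator does *not* emulate: sensor-level autocorrelation and
shared noise across states (classifier cross-talk), event-duration jitter,
non-stationary baselines, eye-movement or motor confounds, and any
relationship between decodability and behavior.  Passing tests therefore
validate the estimators and their calibration under the stated noise model,
not the physiological claims themselves.

## Problem sizes and numerical choices

The validation suite uses 24 participants × 144 trials for behavioral
recovery, 24 × 40 trials for lag localization, 200 null datasets of 6 × 12
trials (100 permutations each) for threshold calibration, and 10 cohorts of
12 × 60 trials for the double dissociation — sizes at which each check's
statistic is stable across seeds.  Stage-1 regressions are solved by
batched normal equations (with a least-squares fallback on singular
designs) and verified against an explicit pseudoinverse oracle to 1e-8.
Ties at the replay median split go to "low"; constant regressors are
dropped with a log message; nonpositive RTs are dropped with a logged
count.

## Known limitations

- The variational-Bayes mixed logistic engine gives approximate posterior
  SDs; the cluster-robust fallback is exact but population-averaged.
- The replay-modulated model's β_high/β_low are weakly identified from few
  labeled trials per participant; only their ordering (and the paired
  signed-rank test across participants) is a stable quantity.
- Trial-wise sequenceness from a single short window is noisy by design;
  inferences are made at the cohort level, never per trial.
- The permutation null assumes exchangeability of state-to-position
  assignments, which holds for the synthetic generator and for decoders
  trained on a balanced localizer.
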