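# Methods

This note records the modelling assumptions, default parameters, numerical
choices, and known limitations of the package. Everything quantitative
stated here is computed by the test suite or the example scripts; nothing
is asserted that the code does not measure.

## Game dynamics

Play happens in normalized screen coordinates [−1, 1] × [−1, 1], x
rightward, y upward. The puck starts at (−0.75, 0) and moves right at
constant speed `v_p` per step; its vertical step is `v_p · u` for joystick
input u ∈ [−1, 1]. The goal line is at x = 0.77 and the bar guards it at
x = 0.75. A trial spans `n_steps = ceil(1.52 / v_p)` steps; the default
`v_p = 1.52/95 = 0.016` makes trials last 95 steps, the middle of the
94–96-step range the simulator is meant to emulate, at 1.5 s per trial
(`dt = 1.5/95 s` for any time conversion). The puck's horizontal position
is computed from the step index (`x_t = x_0 + t·v_p`) so the linear law
holds exactly, with no floating-point drift.

The bar moves only vertically, at `(2/3)·θ·v_p·u`. Holding a near-maximal
input (|u| ≥ 0.8) in one direction for three consecutive steps engages
acceleration: θ increases by 0.85 on the third qualifying step and on each
qualifying step thereafter, and resets to 1 whenever the push weakens or
reverses. Both avatars are clamped onscreen (the puck by its radius, 1/64
of the screen height; the bar by its half-height, default 0.15).

The outcome rule is a one-dimensional interval overlap at the first step
where the puck reaches the bar's plane: the shot is blocked iff
`|puck_y − bar_y| ≤ bar_half_height + puck_radius` there; otherwise the
puck crosses the goal line and the shooter wins. The original task never
needed to publish its collision test or frame rate; these are package
choices, and all of them (`v_p`, radius, bar height, thresholds) are
configurable through `GameConfig`.

## Agents

**Goalie.** A track-then-guess heuristic: during tracking, the bar is
driven toward the puck's vertical position as observed `reaction_lag`
steps earlier (input = `gain · error`, clipped to ±1, gain 25 by default —
effectively bang-bang, so the bar accelerates whenever it is meaningfully
off target); from a per-trial random onset late in the trial it commits to
a full-speed guess in a random direction. Defaults: lag ~ U{3..12} steps,
onset ~ U(0.88, 0.96) of the trial, guess direction fair. The onset window
was calibrated once against the win-rate range the task is known to
produce (shooters winning roughly 40–75%): with the bar's acceleration
rule, onsets much earlier than ~0.85 make the guess overshoot the entire
screen and the shooter wins nearly always. The ω = 1 opponent (the "human"
condition) is a second parameterization of the same heuristic (lag
U{1..6}, onset U(0.88, 0.97)); no attempt is made to model real human
goalkeeping beyond that.

**Hazard shooter.** The work-horse synthetic participant. It always emits
|u| = 1 and reverses direction with probability Φ(f_true), where f_true is
*linear* in (nominally standardized) state predictors plus an opponent
shift — the simplest family whose gradients are known exactly, so that
gradient and sensitivity estimators can be tested against closed-form
truth. Defaults: base logit −3.9, weight 3.4 on time-since-last-change,
0.7 on own vertical position, 0.5 on opponent identity, zero elsewhere.
These were calibrated once so that (a) change points occupy ≈ 4–5% of
timesteps, the sparse regime the framework is designed for, and (b) the
policy is strongly state-driven (Bayes-optimal AUC ≈ 0.95), comparable to
the high predictability observed in real players. The default cohort
generator varies the base rate and the opponent effect across
participants, the two traits that dominate individual differences here.

**Skill variants.** `TimedShooter` makes the *final* reversal a
deliberately timed shot: with probability `skill` it turns against the
goalie's guess one step after the goalie commits (jinking if it already
points the right way, so a final change point is always recorded);
otherwise the final move happens at a uniformly random time. Before the
final move it follows a low-rate background hazard (2%/step); after it,
it holds course. The H2 ("timing skill") cohort is a bimodal split of
skill 0 and skill 1 players facing identical goalies. The H1
("positioning skill") cohort holds timing uniform for everyone and varies
the *tracking pressure* instead: half the cohort faces a sharp tracker,
half a sluggish low-gain one that lets the puck build persistent vertical
separation. This is deliberate: the advantage must be visible in the
state variables themselves (puck and bar positions), because the
final-move value model is a pooled function of state — an advantage
living only in the opponent's future behavior (e.g. an earlier guess
onset) is invisible to any state-conditioned value function.

## Design construction

A change point is a sign reversal of the shooter's joystick input with
both magnitudes at or above a dead zone of 0.2 (reversals through the
neutral zone are jitter, not decisions; the threshold is configurable).
Each timestep t ≥ 1 of a trial becomes one row: the seven state
predictors, ω, the binary action (reversal at this step), and the trial's
outcome. Velocities are first differences of recorded positions (the
joystick series is not assumed observable in real data); time since the
last change point is normalized by trial length and resets the row after
a reversal; opponent experience is the per-opponent trial ordinal scaled
to [0, 1]. Continuous predictors are standardized per participant for
per-participant models — necessary for comparable ARD length scales — and
globally (one scaler for the cohort) for models that pool participants,
such as the per-opponent final-move value fits; mixing the two
conventions silently is the main foot-gun this API shape prevents.

Train/test splits are uniform at the timepoint level (default 80/20).
Rows within a trial are correlated, so timepoint-level splits lean on the
modelling assumption that actions are independent given state; this
matches how the models are specified and keeps the evaluation simple.

## Sparse variational GP classifier

Probit-link GP classification with the ARD-RBF kernel
`σ² exp(−Σ d²/(2λ²))`, fitted by stochastic variational inference with M
inducing points (Hensman-style SVGP): q(u) = N(m, S) with S = L Lᵀ
parameterized by a lower-triangular L (log diagonal), inducing locations
initialized by k-means and optimized jointly with all hyperparameters
(empirical Bayes). The Bernoulli expectation uses 20-point Gauss–Hermite
quadrature; predictive class probabilities use the exact probit-Gaussian
integral Φ(μ/√(1+v)). All ELBO gradients are analytic; the test suite
checks every parameter block against central finite differences, which is
the package's strongest single correctness guarantee.

Numerical choices: jitter 1e−6 on K_zz; latent variances floored at
1e−12; Adam with default learning rate 0.05 (long runs prefer 0.02–0.03),
minibatch 512, 5000 iterations by default — recovery experiments in the
tests use 2000–10000 depending on problem size, and fits of ~20k
timepoints with M = 50 take tens of seconds on one CPU. A NaN ELBO aborts
with a diagnostic rather than continuing silently. The variational
parameterization is unwhitened; for the data sizes here that converges
fine and keeps the gradient algebra transparent.

The posterior over ∇f is Gaussian with analytic moments (first and second
kernel derivatives); far from data its covariance reverts to the prior
value diag(σ²/λᵢ²), a limit the tests verify exactly.

## Sensitivity indices

νᵢ squares the posterior-mean gradient normalized by the posterior sd of
the gradient — latent-function uncertainty only, with no likelihood-noise
term, which is the construction under which the χ²(1) null holds. The
combined opponent-action index ς whitens the (bar position, bar velocity)
gradient block by the Cholesky factor of its 2×2 posterior covariance;
this equals the equal-weighted PCA construction identically, and the
tests confirm the identity to 1e−10. Credible intervals use the
noncentral χ²(1, ν̂) distribution. Early/late trial phases, where used,
split at half the trial; the split point is configurable and nothing
downstream depends on its exact value.

Note an asymmetry the tests make explicit: for an input the agent truly
ignores, the *posterior-mean* gradient shrinks toward zero faster than
its sd, so empirical ν values sit well below the χ²(1) null rather than
on it — the χ²(1) law is exact for prior draws and conservative for
fitted irrelevant inputs.

## Variance decomposition

Method-of-moments with group-size weights: participant component =
size-weighted variance of participant means about the grand mean; trial
component = size-weighted variance of trial means about their participant
means; residual = within-trial variance. The three sums of squares add to
the total sum of squares *exactly* (law of total variance), so the
proportions sum to one to machine precision and the total is invariant
under permutation — the properties the permutation test relies on. The
price of exact additivity is a degrees-of-freedom floor: under label
shuffles the expected trial-level proportion is (n_cells −
n_participants)/(n − 1), about 1.1% for 20 × 50 × 90 data, and the
participant level about 0.02%. Any unbiased (df-corrected) estimator
would center the null at zero but break exact additivity; this package
keeps additivity and reports the floor honestly.

The permutation null jointly reassigns the (participant, trial) label
pair across data points (implemented as permuting the values against the
fixed label structure), 1000 shuffles by default; p-values use the
(1 + #{null ≥ obs})/(n_perm + 1) convention.

## Value models and timing

The empirical action value is the same classifier over (state, ω, action)
predicting the trial outcome — a value under *both* players' realized
strategies. The final-move value conditions on commitment: it is trained
only on the final change point of each trial, one GP per opponent, pooled
across participants — after the final move the shooter's strategy is
trivial (hold course), so the value is a property of state and opponent,
not of the shooter. Trials with no change point at all are excluded from
value fitting (counted and reported) but kept in win-rate denominators.

The EV curve of a trial evaluates the fitted value at every timestep's
state ("what if the final move were now"); t_opt is its argmax with ties
broken to the earliest step; the timing deviation is |t_move − t_opt|
normalized by trial length. The positioning-vs-timing report contrasts
the top and bottom scorers with two statistics: the late-trial (final
quarter) EV offset between them, and the gap in mean timing deviation.
Both are always reported; generative control cohorts in the acceptance
tests confirm that each statistic responds to its own mechanism and not
the other's.

## Problem sizes used by the test suite

Synthetic experiments are sized to what the estimators need, not more:
the main policy-recovery fit uses one participant × 216 trials (~20k
timepoints, M = 50 inducing points, 6000 Adam iterations); the
hyperparameter–sensitivity correlation uses six participants × 60 trials
each at M = 24; the timing cohorts use eight participants × 80–120 trials
with M = 30 value fits; the permutation-null experiment uses the full
20 × 50 × 90 layout with 1000 shuffles. The whole suite runs in a few
minutes on one CPU.

## What the synthetic data do and do not establish

The generator produces sparse change points, heterogeneous participants,
two opponent regimes, and skill differences with known mechanisms, so
passing tests establish that the estimators recover *known* structure:
policies (AUC, calibration, ARD relevance ordering), gradients (exact
oracles), distributional laws (χ², noncentral-χ² coverage), variance
structure, and the sign-level behavioral findings. They do not establish
that real human players satisfy the modelling assumptions: real policies
need not be linear-latent (the GP does not require it, but the recovery
margins observed here were measured under it), real change points may be
graded rather than bang-bang (the dead zone matters more there), within-
trial dependence may exceed what state conditioning captures, and the
"human opponent" condition here is just a second heuristic
parameterization. Ingesting real trajectory data requires only the CSV
schema of `penaltyshot.engine` plus a column mapping.

## Known limitations

* The SVGP is single-output, RBF-only, and unwhitened by design; very
  large datasets or kernels with structure (periodicity, linear trends)
  are out of scope.
* Sensitivities are reported for the policy model; the same machinery
  applies to the value models but is not separately surfaced.
* The simulator integrates inputs zero-order-hold at the frame level;
  there is no sub-step physics, rendering, or hardware input path.
* The variance decomposition treats participant and trial as nested
  strata; crossed designs (e.g. opponent as a third stratum) are not
  supported.
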