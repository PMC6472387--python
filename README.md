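# penaltyshot

Gaussian-process models of instantaneous strategy in a continuous,
competitive two-player game.

## The problem

In a penalty-shot video game, a shooter steers a puck that travels
rightward at constant horizontal speed while controlling only its vertical
velocity; a goalie controls a vertical bar that can accelerate when pushed
hard in one direction, and tries to intercept the puck at the goal line.
Both players act simultaneously and continuously, so classical
discrete-choice game analysis does not apply. The key observation making
the problem tractable is that shooter trajectories decompose into
straight-line segments at near-maximal velocity separated by *change
points* — moments at which the joystick reverses sign. Each instant of
play then becomes a binary decision ("reverse now or keep going"), and a
player's strategy becomes a *policy*: the probability of reversing as a
function of the game state.

This package provides, end to end:

* a **simulator** of the game dynamics (`penaltyshot.engine`) and a family
  of **synthetic agents** with known ground-truth policies
  (`penaltyshot.agents`), so that every estimator in the package can be
  validated against exact generative truth;
* **change-point extraction and design construction**
  (`penaltyshot.design`);
* a hand-rolled **sparse variational GP classifier** with probit link and
  ARD-RBF kernel (`penaltyshot.svgp`), used by all models;
* statsmodels-style **model/results classes**: the change-point policy,
  the empirical action value, and the final-move expected value
  (`penaltyshot.models`, `penaltyshot.value`);
* gradient-based **sensitivity indices** with chi-squared uncertainty
  (`penaltyshot.sensitivity`) and a **variance decomposition** with a
  permutation null (`penaltyshot.vardecomp`);
* a **CLI pipeline** (`penaltyshot simulate | extract | fit-policy |
  sensitivity | decompose | fit-value | report | run`).

## The models

The policy is a GP probit classifier. With state **s** (puck x/y, bar y,
both vertical velocities, normalized time since the last change point, and
an opponent-experience index) and opponent identity ω ∈ {0, 1}:

    a ~ Bernoulli(π(s, ω)),      Φ⁻¹(π) = f(s, ω) ~ GP(0, k),

    k(x, x') = σ² exp( − Σᵢ (xᵢ − xᵢ')² / (2 λᵢ²) ),

with one ARD length scale λᵢ per input: a large λᵢ means input i barely
influences the policy. Inference is sparse variational (inducing points,
Adam on the ELBO, Gauss–Hermite quadrature for the Bernoulli expectation);
hyperparameters are learned by empirical Bayes.

Because f is a GP with a smooth kernel, its gradient is a GP with analytic
posterior moments, which yields per-timepoint sensitivity indices

    νᵢ(x) = ( ∇ᵢ f(x) / σᵢ(x) )²,        ς(x) = ‖ L⁻¹ ∇_x̃ f(x) ‖²,

where σᵢ is the posterior sd of ∇ᵢ f, x̃ = (bar position, bar velocity)
and L Lᵀ is the posterior covariance of ∇_x̃ f. Under the null of no
dependence, νᵢ is χ²(1); credible intervals come from the noncentral χ².
Each index's variance splits exactly into participant, trial and residual
fractions (law of total variance), with a label-shuffling permutation
null.

Action values use the same GP classifier: the empirical value Q(a | s, ω)
predicts the trial's outcome from state, opponent and current action; the
final-move value treats the trial as a stopping problem — the win
probability of reversing *now* and running straight — trained on the final
change point of each trial, one GP per opponent. From its per-trial EV
curves the package derives the optimal move time t_opt, the timing
deviation |t_move − t_opt|, and a contrast between "advantageous
positioning" and "advantageous timing" explanations of skill.

## Worked example

```python
import numpy as np
from penaltyshot import (SyntheticShooterParams, generate_dataset,
                         build_design, ChangePointPolicy)

trials, truth = generate_dataset(
    n_participants=1, n_trials_per_opponent=50, seed=7,
    participant_params=[SyntheticShooterParams()],
)
design = build_design(trials)
print(f"{len(trials)} trials, {len(design)} timepoints, "
      f"change-point rate {design.a.mean():.3f}")

result = ChangePointPolicy(design).fit(n_inducing=40, n_iter=4000, seed=0,
                                       learning_rate=0.03)
print(result.summary())

table = result.sensitivity_table(rows=np.arange(500))
print(table[["nu_time_since_cp", "nu_omega", "varsigma"]].mean().round(3))
```

prints

```
100 trials, 9361 timepoints, change-point rate 0.049
Policy (sparse variational GP, probit link)
====================================================
observations:     9361    inducing points: 40
held-out AUC:      0.953    kernel variance: 10.782
----------------------------------------------------
ARD length scales (large = weak influence):
  time_since_cp         3.075
  omega                 6.187
  puck_y                6.670
  bar_vy               45.955
  puck_vy              89.140
  puck_x              128.994
  bar_y               131.920
  opp_experience      150.994
====================================================
nu_time_since_cp    57.638
nu_omega            10.143
varsigma             1.706
```

The generating shooter switched direction at a hazard driven mainly by the
time since its last reversal (plus its own vertical position and the
opponent's identity), at a base rate near 5% of timesteps. The fit
recovers exactly that structure: held-out AUC 0.95, short length scales —
and large mean sensitivities — for the driving inputs, and length scales
one to two orders of magnitude larger for the inputs the shooter ignored
(e.g. the bar's position and velocity, hence the small combined opponent
sensitivity ς).

The full pipeline runs from the shell:

```
penaltyshot run --seed 0 --out runs/demo
```

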