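"""Opponent and shooter policies, and batch dataset generation.

The goalie follows a track-then-guess heuristic: it drives the bar toward
the puck's vertical position as observed ``reaction_lag`` steps earlier,
then, from a randomly drawn onset late in the trial, commits to a full-speed
guess in a random direction for the remainder of the trial.

Shooters emit near-maximal vertical input (|u| = 1) and differ only in when
they reverse direction. The basic :class:`HazardShooter` reverses with
probability ``Phi(f_true)`` where ``f_true`` is a *linear* latent in the
seven state predictors plus opponent identity — a ground truth whose
gradients are known exactly, used throughout for recovery tests. Two
further variants encode distinct kinds of skill for the timing analyses:
:class:`TimedShooter` (skill = timing the final reversal to the moment the
goalie commits to its guess) and :class:`PositioningShooter` (skill =
building vertical separation early in the trial).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .engine import GameConfig, GameState, Trial, run_trial

__all__ = [
    "GoalieHeuristicParams",
    "SyntheticShooterParams",
    "HeuristicGoalie",
    "HazardShooter",
    "TimedShooter",
    "goalie_policy",
    "synthetic_shooter_policy",
    "generate_dataset",
    "default_cohort_params",
    "h1_positioning_cohort",
    "h2_timing_cohort",
    "STATE_FEATURES",
]

#: the seven state predictors, in canonical order (omega is appended last)
STATE_FEATURES = (
    "puck_x",
    "puck_y",
    "bar_y",
    "puck_vy",
    "bar_vy",
    "time_since_cp",
    "opp_experience",
)

#: nominal (center, scale) used to express the synthetic ground-truth latent
#: in roughly standardized units during simulation (the model-side design
#: matrix is standardized empirically per participant; these are fixed
#: generator-side constants so that ground-truth weights stay interpretable).
NOMINAL_CENTER = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.10, 0.5])
NOMINAL_SCALE = np.array([0.45, 0.35, 0.35, 0.016, 0.011, 0.10, 0.29])


@dataclass(frozen=True)
class GoalieHeuristicParams:
    """Track-then-guess goalie. Lags are in steps; onsets in trial fraction."""

    reaction_lag_range: tuple[int, int] = (3, 12)
    guess_onset_range: tuple[float, float] = (0.88, 0.96)
    guess_direction_prob: float = 0.5
    tracking_gain: float = 25.0

    def __post_init__(self) -> None:
        if self.reaction_lag_range[0] < 0:
            raise ValueError("reaction lag must be >= 0")
        lo, hi = self.guess_onset_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("guess onset range must lie in (0, 1]")
        if not 0 <= self.guess_direction_prob <= 1:
            raise ValueError("guess_direction_prob must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticShooterParams:
    """Ground truth of a hazard shooter's switching policy.

    ``state_weights`` are coefficients on the 7 nominally standardized state
    predictors; ``opponent_effect`` shifts the latent when facing the human
    opponent (omega = 1); ``base_switch_logit`` sets the baseline hazard on
    the probit scale. ``skill`` is the timing precision of the final move
    (used by :class:`TimedShooter`; ignored by the plain hazard shooter).
    """

    base_switch_logit: float = -3.9
    state_weights: tuple[float, ...] = (0.0, 0.7, 0.0, 0.0, 0.0, 3.4, 0.0)
    opponent_effect: float = 0.5
    skill: float = 0.0

    def __post_init__(self) -> None:
        if len(self.state_weights) != len(STATE_FEATURES):
            raise ValueError(
                f"state_weights must have {len(STATE_FEATURES)} entries"
            )

    def latent(self, features: np.ndarray, omega: float) -> float:
        """Ground-truth latent f_true(s, omega) on the probit scale."""
        z = (np.asarray(features) - NOMINAL_CENTER) / NOMINAL_SCALE
        return float(
            self.base_switch_logit
            + np.dot(self.state_weights, z)
            + self.opponent_effect * omega
        )

    def latent_gradient_raw(self) -> np.ndarray:
        """d f_true / d(raw feature): exact, for gradient-oracle tests."""
        return np.asarray(self.state_weights) / NOMINAL_SCALE


class HeuristicGoalie:
    """Stateful policy object implementing the track-then-guess heuristic."""

    def __init__(self, params: GoalieHeuristicParams | None = None):
        self.params = params or GoalieHeuristicParams()
        self._lag = 0
        self._onset_step = np.inf
        self._guess_dir = 1.0
        self._history: list[float] = []

    def reset(self, cfg: GameConfig, rng: np.random.Generator) -> None:
        p = self.params
        lo, hi = p.reaction_lag_range
        self._lag = int(rng.integers(lo, hi + 1))
        onset_frac = rng.uniform(*p.guess_onset_range)
        self._onset_step = int(round(onset_frac * cfg.n_steps))
        self._guess_dir = 1.0 if rng.random() < p.guess_direction_prob else -1.0
        self._history = []

    def __call__(self, state: GameState, rng: np.random.Generator) -> float:
        self._history.append(state.puck_y)
        if state.t >= self._onset_step:
            return self._guess_dir
        target = self._history[max(0, len(self._history) - 1 - self._lag)]
        return float(
            np.clip(self.params.tracking_gain * (target - state.bar_y), -1.0, 1.0)
        )


def goalie_policy(
    state: GameState, params: GoalieHeuristicParams, rng: np.random.Generator
) -> float:
    """Stateless convenience wrapper (tracking phase only, zero lag)."""
    return float(np.clip(params.tracking_gain * (state.puck_y - state.bar_y), -1, 1))


class _ShooterBase:
    """Shared bookkeeping: direction, time since last reversal, experience."""

    def __init__(self, params: SyntheticShooterParams, omega: int = 0,
                 opp_experience: float = 0.0):
        self.params = params
        self.omega = float(omega)
        self.opp_experience = float(opp_experience)
        self._dir = 1.0
        self._last_switch = 0
        self._n_steps = 95
        self._v_p = 0.016
        self.switch_steps: list[int] = []

    def reset(self, cfg: GameConfig, rng: np.random.Generator) -> None:
        self._dir = 1.0 if rng.random() < 0.5 else -1.0
        self._last_switch = 0
        self._n_steps = cfg.n_steps
        self._v_p = cfg.puck_speed
        self.switch_steps = []

    def _features(self, state: GameState) -> np.ndarray:
        tslc = (state.t - self._last_switch) / self._n_steps
        # velocities as recorded first differences of position: v_p * u_prev
        return np.array(
            [
                state.puck_x,
                state.puck_y,
                state.bar_y,
                state.puck_u * self._v_p,
                state.bar_u * self._v_p * (2.0 / 3.0) * state.theta,
                tslc,
                self.opp_experience,
            ]
        )

    def _switch(self, t: int) -> None:
        self._dir = -self._dir
        self._last_switch = t
        self.switch_steps.append(t)


class HazardShooter(_ShooterBase):
    """Reverses direction with probability Phi(f_true(s, omega)) each step."""

    def __call__(self, state: GameState, rng: np.random.Generator) -> float:
        if state.t > 0:
            p = ndtr(self.params.latent(self._features(state), self.omega))
            if rng.random() < p:
                self._switch(state.t)
        return self._dir


class TimedShooter(_ShooterBase):
    """Hazard shooter whose *final* reversal is a deliberately timed shot.

    With probability ``skill`` the shooter executes an informed final move:
    a couple of steps after the goalie commits to its guess, it turns away
    from the guessed direction and holds course. Otherwise the final move
    occurs at a uniformly random time in the second half of the trial with
    an uninformed (reversal) direction. Before the final move the shooter
    follows a low-rate hazard policy; after it, no further reversals.
    """

    #: per-step reversal probability before the planned final move
    background_hazard = 0.02

    def __init__(self, params, omega=0, opp_experience=0.0,
                 goalie: HeuristicGoalie | None = None, delay: int = 2):
        super().__init__(params, omega, opp_experience)
        self.goalie = goalie
        self.delay = delay
        self._informed = False
        self._t_final = np.inf
        self._committed = False
        self._pending_jink = False

    def reset(self, cfg: GameConfig, rng: np.random.Generator) -> None:
        super().reset(cfg, rng)
        self._committed = False
        self._pending_jink = False
        self._informed = rng.random() < self.params.skill
        if (self._informed and self.goalie is not None
                and np.isfinite(self.goalie._onset_step)):
            self._t_final = min(
                self.goalie._onset_step + self.delay, cfg.n_steps - 3
            )
        else:
            self._informed = False
            # uninformed final moves: uniform over most of the trial
            self._t_final = int(
                rng.integers(int(0.25 * cfg.n_steps), cfg.n_steps - 5)
            )

    def __call__(self, state: GameState, rng: np.random.Generator) -> float:
        if self._committed:
            if self._pending_jink:
                # second half of a jink: reverse once more, away from the
                # goalie's guess, so a final change point is always recorded
                self._switch(state.t)
                self._pending_jink = False
            return self._dir
        if state.t >= self._t_final:
            if self._informed and self.goalie is not None:
                new_dir = -self.goalie._guess_dir
                if new_dir != self._dir:
                    self._switch(state.t)
                else:
                    # already heading away: jink toward then back so the
                    # timed final move leaves a change point near t_final
                    self._switch(state.t)
                    self._pending_jink = True
            else:
                self._switch(state.t)
            self._committed = True
            return self._dir
        if state.t > 0:
            # low-rate background hazard so pre-final behavior is plausible
            if rng.random() < self.background_hazard:
                self._switch(state.t)
        return self._dir


def h2_timing_cohort(
    n_participants: int = 8,
    n_trials_per_opponent: int = 40,
    cfg: GameConfig | None = None,
    seed: int = 0,
):
    """Cohort in which skill is purely *timing* of the final move.

    Every participant faces identical goalies and experiences the same EV
    landscape; they differ only in how precisely the final reversal is
    timed to the goalie's commitment (``skill`` grades from 0 to 1), so
    the final-move distribution — not the EV curve — separates scorers.
    """
    # bimodal skills: a clearly unskilled and a clearly skilled half
    skills = (np.arange(n_participants) >= n_participants / 2).astype(float)
    params = [SyntheticShooterParams(skill=float(s)) for s in skills]
    factory = lambda p, omega, exp, goalie: TimedShooter(
        p, omega, exp, goalie=goalie, delay=1
    )
    # a goalie that commits a little earlier than the default leaves the
    # informed final move enough remaining steps to convert reliably,
    # sharpening the payoff of timing skill (identically for everyone)
    goalies = {
        0: GoalieHeuristicParams(guess_onset_range=(0.85, 0.91)),
        1: GoalieHeuristicParams(
            reaction_lag_range=(1, 6), guess_onset_range=(0.85, 0.91)
        ),
    }
    return generate_dataset(
        n_participants,
        n_trials_per_opponent,
        cfg,
        seed=seed,
        participant_params=params,
        shooter_factory=factory,
        goalie_params=goalies,
    )


def h1_positioning_cohort(
    n_participants: int = 8,
    n_trials_per_opponent: int = 40,
    cfg: GameConfig | None = None,
    seed: int = 0,
):
    """Cohort in which skill is *positioning*: better late-trial states.

    All participants time their final moves uniformly (TimedShooter with
    skill 0). What varies is the tracking pressure they are under: half
    the cohort faces a sharp tracker (high gain), half a sluggish one
    (low gain) that lets the puck build persistent vertical separation —
    an advantage that is visible in the state variables (puck and bar
    positions), so the pooled EV model sees vertically shifted EV curves
    while final-move timing stays exchangeable across participants.
    """
    params = [SyntheticShooterParams(skill=0.0) for _ in range(n_participants)]
    gains = np.where(np.arange(n_participants) < n_participants / 2, 25.0, 1.2)

    def goalie_for(i: int) -> dict[int, GoalieHeuristicParams]:
        g = float(gains[i])
        return {
            0: GoalieHeuristicParams(tracking_gain=g),
            1: GoalieHeuristicParams(
                reaction_lag_range=(1, 6),
                guess_onset_range=(0.88, 0.97),
                tracking_gain=g,
            ),
        }

    factory = lambda p, omega, exp, goalie: TimedShooter(
        p, omega, exp, goalie=goalie, delay=1
    )
    return generate_dataset(
        n_participants,
        n_trials_per_opponent,
        cfg,
        seed=seed,
        participant_params=params,
        shooter_factory=factory,
        goalie_params=goalie_for,
    )


def synthetic_shooter_policy(
    state: GameState,
    params: SyntheticShooterParams,
    rng: np.random.Generator,
    shooter: HazardShooter | None = None,
) -> float:
    """Functional facade over :class:`HazardShooter` for one-off calls."""
    if shooter is None:
        shooter = HazardShooter(params)
        shooter._n_steps = 95
    return shooter(state, rng)


def default_cohort_params(
    n_participants: int, rng: np.random.Generator
) -> list[SyntheticShooterParams]:
    """Heterogeneous cohort emulating across-participant strategy variation.

    Baseline switching rate and opponent effect vary across participants
    (the traits the study population varied in most); state weights receive
    mild jitter.
    """
    base = SyntheticShooterParams()
    out = []
    for _ in range(n_participants):
        w = np.asarray(base.state_weights) + rng.normal(0, 0.08, len(STATE_FEATURES))
        out.append(
            SyntheticShooterParams(
                base_switch_logit=base.base_switch_logit + rng.normal(0, 0.15),
                state_weights=tuple(np.round(w, 4)),
                opponent_effect=float(
                    np.clip(rng.normal(0.5, 0.3), 0.0, 1.4)
                ),
            )
        )
    return out


def generate_dataset(
    n_participants: int,
    n_trials_per_opponent: int,
    cfg: GameConfig | None = None,
    seed: int = 0,
    participant_params: Sequence[SyntheticShooterParams] | None = None,
    shooter_factory=None,
    goalie_params=None,
) -> tuple[list[Trial], dict]:
    """Simulate a full synthetic cohort.

    Each participant plays ``n_trials_per_opponent`` trials against each of
    two opponents (omega = 0: computer goalie; omega = 1: a second goalie
    parameterization standing in for the human opponent), in randomized
    order, with the per-opponent trial ordinal recorded for the experience
    predictor. Returns the trials and a ground-truth sidecar dict.
    """
    if n_participants < 1 or n_trials_per_opponent < 1:
        raise ValueError("counts must be >= 1")
    cfg = cfg or GameConfig()
    root = np.random.default_rng(seed)
    if participant_params is None:
        participant_params = default_cohort_params(n_participants, root)
    default_goalies = {
        0: GoalieHeuristicParams(),
        1: GoalieHeuristicParams(
            reaction_lag_range=(1, 6), guess_onset_range=(0.88, 0.97)
        ),
    }
    trials: list[Trial] = []
    truth: dict = {"participants": {}}
    for i in range(n_participants):
        pid = f"p{i:03d}"
        params = participant_params[i]
        if goalie_params is None:
            gparams = default_goalies
        elif callable(goalie_params):
            gparams = goalie_params(i)
        else:
            gparams = goalie_params
        prng = np.random.default_rng(root.integers(2**31 - 1))
        order = np.repeat([0, 1], n_trials_per_opponent)
        prng.shuffle(order)
        counters = {0: 0, 1: 0}
        denom = max(n_trials_per_opponent - 1, 1)
        switch_steps: dict[str, list[int]] = {}
        for omega in order:
            idx = counters[int(omega)]
            counters[int(omega)] += 1
            goalie = HeuristicGoalie(gparams[int(omega)])
            if shooter_factory is None:
                shooter = HazardShooter(
                    params, omega=int(omega), opp_experience=idx / denom
                )
            else:
                shooter = shooter_factory(
                    params, int(omega), idx / denom, goalie
                )
            tr = run_trial(
                shooter,
                goalie,
                cfg,
                seed=prng,
                participant_id=pid,
                opponent_id=int(omega),
                trial_index=idx,
            )
            trials.append(tr)
            switch_steps[f"{int(omega)}:{idx}"] = list(map(int, shooter.switch_steps))
        truth["participants"][pid] = {
            "params": asdict(params),
            "switch_steps": switch_steps,
        }
    truth["config"] = {"n_trials_per_opponent": n_trials_per_opponent, "seed": seed}
    return trials, truth


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
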