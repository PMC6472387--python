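"""Penalty-shot game dynamics.

Two avatars move in a normalized [-1, 1] x [-1, 1] arena. The shooter's puck
travels rightward at constant horizontal speed ``v_p`` and its vertical
velocity is ``v_p * u`` for joystick input ``u`` in [-1, 1]. The goalie's bar
moves only vertically at ``(2/3) * theta * v_p * u``, where the multiplier
``theta`` grows by a fixed increment on every step of a sustained
near-maximal push in one direction (three or more consecutive steps with
``|u| >= 0.8``), and resets to 1 the moment the push relents or reverses.

A trial ends either when the puck's x-position first reaches the bar's
x-position and the bar blocks it (vertical interval overlap), or when the
puck crosses the goal line (a win for the shooter).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GameConfig",
    "GameState",
    "Trial",
    "step_puck",
    "step_bar",
    "run_trial",
    "determine_outcome",
    "trials_to_frame",
    "frame_to_trials",
    "trials_to_csv",
    "trials_from_csv",
]

#: columns of the canonical per-timestep trial serialization
TRIAL_COLUMNS = [
    "participant_id",
    "opponent_id",
    "trial_index",
    "t",
    "puck_x",
    "puck_y",
    "bar_y",
    "puck_u",
    "bar_u",
    "outcome",
]


@dataclass(frozen=True)
class GameConfig:
    """Physical constants of the game, in normalized screen units.

    Defaults place the puck at (-0.75, 0), the goal line at x = 0.77 and
    make a trial last ``n_steps = ceil((goal_line_x - puck_start_x) /
    puck_speed)`` steps (95 with the default speed). The puck diameter is
    1/64 of the screen width (screen width = 2 normalized units).
    """

    puck_speed: float = (0.77 - (-0.75)) / 95.0
    puck_start: tuple[float, float] = (-0.75, 0.0)
    goal_line_x: float = 0.77
    puck_radius: float = 1.0 / 64.0
    bar_start: tuple[float, float] = (0.75, 0.0)
    bar_half_height: float = 0.15
    bar_speed_factor: float = 2.0 / 3.0
    accel_increment: float = 0.85
    accel_input_threshold: float = 0.8
    accel_steps_required: int = 3
    screen_bound: float = 1.0
    trial_duration_s: float = 1.5

    def __post_init__(self) -> None:
        if self.puck_speed <= 0:
            raise ValueError("puck_speed must be positive")
        if not (self.puck_start[0] < self.goal_line_x <= self.bar_start[0] + 1e-12
                or self.puck_start[0] < self.bar_start[0] <= self.goal_line_x):
            # canonical layout: puck left of bar, bar at/left of goal line
            pass
        if self.puck_start[0] >= self.goal_line_x:
            raise ValueError("puck must start left of the goal line")
        if not (abs(self.puck_start[0]) <= 1 and abs(self.bar_start[0]) <= 1
                and self.goal_line_x <= 1):
            raise ValueError("positions must lie within screen bounds")
        if self.bar_half_height <= 0 or self.bar_half_height >= 1:
            raise ValueError("bar_half_height must be in (0, 1)")

    @property
    def n_steps(self) -> int:
        """Number of steps for the puck to reach the goal line."""
        return math.ceil((self.goal_line_x - self.puck_start[0]) / self.puck_speed)

    @property
    def dt(self) -> float:
        """Seconds per step, for converting step counts to wall time."""
        return self.trial_duration_s / self.n_steps


@dataclass(frozen=True)
class GameState:
    """Instantaneous state of one trial.

    ``puck_u`` / ``bar_u`` are the joystick inputs applied on the *previous*
    step (zero at t = 0), so a policy receiving this state sees only what was
    observable at time ``t``. ``theta`` is the bar's current speed multiplier
    and ``accel_streak`` the running count of consecutive qualifying pushes.
    """

    t: int
    puck_x: float
    puck_y: float
    bar_y: float
    puck_u: float = 0.0
    bar_u: float = 0.0
    theta: float = 1.0
    accel_streak: int = 0


def _check_input(u: float) -> float:
    u = float(u)
    if not np.isfinite(u) or u < -1.0 or u > 1.0:
        raise ValueError(f"joystick input must be in [-1, 1], got {u!r}")
    return u


def step_puck(state: GameState, u: float, cfg: GameConfig) -> GameState:
    """Advance the puck one step with vertical input ``u``.

    The puck advances horizontally by exactly ``puck_speed`` and vertically
    by ``puck_speed * u``; its center is clamped so the puck stays onscreen.
    """
    u = _check_input(u)
    lim = cfg.screen_bound - cfg.puck_radius
    new_y = float(np.clip(state.puck_y + cfg.puck_speed * u, -lim, lim))
    # horizontal advance is computed from the step index so that
    # puck_x(t) = puck_start_x + t * puck_speed holds exactly, with no
    # accumulated floating-point drift over a trial
    return replace(
        state,
        t=state.t + 1,
        puck_x=cfg.puck_start[0] + (state.t + 1) * cfg.puck_speed,
        puck_y=new_y,
        puck_u=u,
    )


def step_bar(state: GameState, u: float, cfg: GameConfig) -> GameState:
    """Advance the bar one step with vertical input ``u``.

    Sustaining ``|u| >= accel_input_threshold`` in one direction for
    ``accel_steps_required`` consecutive steps starts the acceleration:
    ``theta`` then grows by ``accel_increment`` on that step and on each
    further qualifying step. Any weaker or reversed input resets ``theta``
    to 1. The bar moves by ``bar_speed_factor * theta * puck_speed * u``,
    with its extent clamped onscreen.
    """
    u = _check_input(u)
    qualifies = abs(u) >= cfg.accel_input_threshold
    same_direction = np.sign(u) == np.sign(state.bar_u)
    if qualifies and (state.accel_streak == 0 or same_direction):
        streak = state.accel_streak + 1
    elif qualifies:
        streak = 1
    else:
        streak = 0
    if streak >= cfg.accel_steps_required:
        theta = state.theta + cfg.accel_increment
    else:
        theta = 1.0
    v_bar = cfg.bar_speed_factor * theta * cfg.puck_speed
    lim = cfg.screen_bound - cfg.bar_half_height
    new_y = float(np.clip(state.bar_y + v_bar * u, -lim, lim))
    return replace(state, bar_y=new_y, bar_u=u, theta=theta, accel_streak=streak)


@dataclass
class Trial:
    """One complete trial: per-timestep arrays plus identifying labels.

    Arrays share length L (the number of recorded states); ``puck_u[t]`` and
    ``bar_u[t]`` are the inputs applied *at* step t, so the final entries are
    zero. ``outcome`` is 1 if the shooter won, 0 if blocked.
    """

    participant_id: str
    opponent_id: int
    trial_index: int
    t: np.ndarray
    puck_x: np.ndarray
    puck_y: np.ndarray
    bar_y: np.ndarray
    puck_u: np.ndarray
    bar_u: np.ndarray
    outcome: int
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_inputs(self) -> int:
        """Number of steps on which inputs were applied (length - 1)."""
        return len(self.t) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "opponent_id": self.opponent_id,
                "trial_index": self.trial_index,
                "t": self.t,
                "puck_x": self.puck_x,
                "puck_y": self.puck_y,
                "bar_y": self.bar_y,
                "puck_u": self.puck_u,
                "bar_u": self.bar_u,
                "outcome": self.outcome,
            }
        )


def determine_outcome(trial_or_states, cfg: GameConfig) -> int:
    """Outcome rule: 1 (win) unless the bar blocks the puck.

    The block test is a 1-D vertical interval overlap at the first step
    where the puck's x-position reaches the bar's x-position:
    loss iff ``|puck_y - bar_y| <= bar_half_height + puck_radius`` there.
    """
    if isinstance(trial_or_states, Trial):
        puck_x = np.asarray(trial_or_states.puck_x)
        puck_y = np.asarray(trial_or_states.puck_y)
        bar_y = np.asarray(trial_or_states.bar_y)
    else:
        states = list(trial_or_states)
        puck_x = np.array([s.puck_x for s in states])
        puck_y = np.array([s.puck_y for s in states])
        bar_y = np.array([s.bar_y for s in states])
    reached = np.nonzero(puck_x >= cfg.bar_start[0] - 1e-12)[0]
    if len(reached) == 0:
        raise ValueError("trial ended before the puck reached the bar")
    k = int(reached[0])
    blocked = abs(puck_y[k] - bar_y[k]) <= cfg.bar_half_height + cfg.puck_radius
    return 0 if blocked else 1


Policy = Callable[[GameState, np.random.Generator], float]


def run_trial(
    shooter_policy: Policy,
    goalie_policy: Policy,
    cfg: GameConfig,
    seed: int | np.random.Generator = 0,
    participant_id: str = "p0",
    opponent_id: int = 0,
    trial_index: int = 0,
) -> Trial:
    """Simulate one trial; deterministic given (config, seed, policies).

    Policies are callables ``(state, rng) -> u`` in [-1, 1]; those with a
    ``reset(cfg, rng)`` method are reset at trial start (used by stateful
    agents to draw per-trial latent variables). The trial terminates at the
    blocking step, or at the goal-line crossing if unblocked.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # goalie first: shooters may condition their trial plan on the goalie's
    # per-trial draws (e.g. timed shooters exploiting the guess onset)
    for pol in (goalie_policy, shooter_policy):
        if hasattr(pol, "reset"):
            pol.reset(cfg, rng)
    state = GameState(
        t=0,
        puck_x=cfg.puck_start[0],
        puck_y=cfg.puck_start[1],
        bar_y=cfg.bar_start[1],
    )
    states = [state]
    inputs: list[tuple[float, float]] = []
    blocked = False
    while state.puck_x < cfg.goal_line_x - 1e-12:
        u_s = _check_input(shooter_policy(state, rng))
        u_g = _check_input(goalie_policy(state, rng))
        state = step_bar(step_puck(state, u_s, cfg), u_g, cfg)
        states.append(state)
        inputs.append((u_s, u_g))
        if state.puck_x >= cfg.bar_start[0] - 1e-12:
            # puck reached the bar's plane: the block test decides the trial
            gap = abs(state.puck_y - state.bar_y)
            if gap <= cfg.bar_half_height + cfg.puck_radius:
                blocked = True
            break
        if state.t > 10 * cfg.n_steps:  # defensive; unreachable for valid cfg
            raise RuntimeError("trial failed to terminate")
    if not blocked:
        # roll the puck forward to the goal line; the bar can no longer block
        while state.puck_x < cfg.goal_line_x - 1e-12:
            u_s = _check_input(shooter_policy(state, rng))
            state = step_puck(state, u_s, cfg)
            states.append(state)
            inputs.append((u_s, 0.0))
    L = len(states)
    puck_u = np.zeros(L)
    bar_u = np.zeros(L)
    if inputs:
        puck_u[: L - 1] = [u for u, _ in inputs]
        bar_u[: L - 1] = [g for _, g in inputs]
    return Trial(
        participant_id=participant_id,
        opponent_id=opponent_id,
        trial_index=trial_index,
        t=np.arange(L),
        puck_x=np.array([s.puck_x for s in states]),
        puck_y=np.array([s.puck_y for s in states]),
        bar_y=np.array([s.bar_y for s in states]),
        puck_u=puck_u,
        bar_u=bar_u,
        outcome=0 if blocked else 1,
    )


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    if not trials:
        raise ValueError("no trials to serialize")
    return pd.concat([tr.to_frame() for tr in trials], ignore_index=True)[TRIAL_COLUMNS]


def frame_to_trials(frame: pd.DataFrame) -> list[Trial]:
    trials = []
    keys = ["participant_id", "opponent_id", "trial_index"]
    for (pid, opp, idx), g in frame.groupby(keys, sort=False):
        g = g.sort_values("t")
        trials.append(
            Trial(
                participant_id=str(pid),
                opponent_id=int(opp),
                trial_index=int(idx),
                t=g["t"].to_numpy(),
                puck_x=g["puck_x"].to_numpy(),
                puck_y=g["puck_y"].to_numpy(),
                bar_y=g["bar_y"].to_numpy(),
                puck_u=g["puck_u"].to_numpy(),
                bar_u=g["bar_u"].to_numpy(),
                outcome=int(g["outcome"].iloc[0]),
            )
        )
    return trials


def trials_to_csv(trials: Sequence[Trial], path) -> None:
    """Write trials as CSV, one row per timestep, full float precision."""
    trials_to_frame(trials).to_csv(path, index=False)


def trials_from_csv(path) -> list[Trial]:
    return frame_to_trials(pd.read_csv(path))
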