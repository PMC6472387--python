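"""Change-point extraction and model-input construction from trajectories.

Each trajectory is reduced to a sequence of straight-line segments separated
by change points (sign reversals of the shooter's vertical joystick input).
Every timestep then becomes one classification row: the binary action (did
the shooter reverse direction at this step) against a state vector of seven
predictors plus opponent identity:

``puck_x, puck_y, bar_y, puck_vy, bar_vy, time_since_cp, opp_experience, omega``

Velocities are first differences of recorded positions; ``time_since_cp``
is the time since the last change point as a fraction of trial length and
resets at every change point; ``opp_experience`` is the per-opponent trial
ordinal scaled to [0, 1]. Continuous predictors are standardized per
participant; omega is carried through unscaled as a {0, 1} input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import Trial

__all__ = [
    "INPUT_COLUMNS",
    "STATE_COLUMNS",
    "OPP_ACTION_COLUMNS",
    "Design",
    "extract_changepoints",
    "build_design",
    "split_train_test",
]

STATE_COLUMNS = [
    "puck_x",
    "puck_y",
    "bar_y",
    "puck_vy",
    "bar_vy",
    "time_since_cp",
    "opp_experience",
]
INPUT_COLUMNS = STATE_COLUMNS + ["omega"]
#: the opponent-action block (position, velocity) used by the combined
#: opponent sensitivity index
OPP_ACTION_COLUMNS = ["bar_y", "bar_vy"]

#: joystick magnitudes below this dead zone do not define a direction
DEFAULT_DEAD_ZONE = 0.2


def extract_changepoints(trial: Trial, dead_zone: float = DEFAULT_DEAD_ZONE) -> np.ndarray:
    """Steps at which the shooter's joystick input reversed sign.

    A change point at step t means sign(u_t) != sign(u_{t-1}) with both
    magnitudes at or above ``dead_zone``; the first step is never a change
    point. Accepts a :class:`Trial` or a raw input series.
    """
    u = np.asarray(trial.puck_u if isinstance(trial, Trial) else trial, dtype=float)
    if isinstance(trial, Trial):
        u = u[: max(len(u) - 1, 0)]  # last state has no applied input
    if len(u) and np.all(u == 0):
        warnings.warn("all-zero input series: no change points defined")
        return np.array([], dtype=int)
    strong = np.abs(u) >= dead_zone
    flips = np.sign(u[1:]) != np.sign(u[:-1])
    cp = np.nonzero(flips & strong[1:] & strong[:-1])[0] + 1
    return cp


@dataclass
class Design:
    """A labeled per-timepoint design matrix plus its standardization.

    ``frame`` has one row per usable timepoint with raw and standardized
    predictors; ``X`` is the standardized input matrix in INPUT_COLUMNS
    order, ``a`` the change-point labels, ``w`` the trial outcomes.
    """

    frame: pd.DataFrame
    scalers: dict = field(default_factory=dict)

    @property
    def X(self) -> np.ndarray:
        return self.frame[[f"z_{c}" for c in STATE_COLUMNS] + ["omega"]].to_numpy()

    @property
    def a(self) -> np.ndarray:
        return self.frame["a"].to_numpy()

    @property
    def w(self) -> np.ndarray:
        return self.frame["w"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def for_participant(self, pid: str) -> "Design":
        sub = self.frame[self.frame["participant_id"] == pid].reset_index(drop=True)
        return Design(sub, {pid: self.scalers.get(pid)})

    def destandardize_gradient(self, pid: str, grad_z: np.ndarray) -> np.ndarray:
        """Map a gradient taken in standardized units back to raw units."""
        mean, sd = self.scalers[pid]
        scale = np.append(sd, 1.0)  # omega unscaled
        return grad_z / scale


def _trial_rows(trial: Trial, n_trials_per_opponent: int | None,
                dead_zone: float) -> pd.DataFrame | None:
    L = len(trial)
    if L < 3:
        raise ValueError("trials with fewer than 2 input steps are rejected")
    cps = extract_changepoints(trial, dead_zone)
    # rows at t = 1 .. L-2: velocities need t-1, labels need input at t
    ts = np.arange(1, L - 1)
    n_len = trial.n_inputs  # trial length in input steps
    tslc = np.empty(len(ts), dtype=float)
    last = 0
    cpset = set(int(c) for c in cps)
    a = np.zeros(len(ts), dtype=int)
    for j, t in enumerate(ts):
        if t in cpset:
            a[j] = 1
        tslc[j] = (t - last) / n_len
        if t in cpset:  # resets *after* this row: next row sees 1/length
            last = t
    puck_vy = trial.puck_y[ts] - trial.puck_y[ts - 1]
    bar_vy = trial.bar_y[ts] - trial.bar_y[ts - 1]
    if n_trials_per_opponent is not None and n_trials_per_opponent > 1:
        exp = trial.trial_index / (n_trials_per_opponent - 1)
    else:
        exp = 0.0
    return pd.DataFrame(
        {
            "participant_id": trial.participant_id,
            "omega": float(trial.opponent_id),
            "trial_index": trial.trial_index,
            "t": ts,
            "trial_len": n_len,
            "puck_x": trial.puck_x[ts],
            "puck_y": trial.puck_y[ts],
            "bar_y": trial.bar_y[ts],
            "puck_vy": puck_vy,
            "bar_vy": bar_vy,
            "time_since_cp": tslc,
            "opp_experience": exp,
            "a": a,
            "w": trial.outcome,
        }
    )


def build_design(
    trials: Sequence[Trial],
    dead_zone: float = DEFAULT_DEAD_ZONE,
    standardize: bool | str = True,
) -> Design:
    """Assemble the labeled per-timepoint design matrix for a trial set.

    The per-opponent experience index is inferred from the largest
    trial_index observed per (participant, opponent) stratum so that it
    spans 0 (first trial) to 1 (last trial).

    ``standardize`` may be True (per participant — the right scaling for
    per-participant policy models), ``"global"`` (one scaler for the whole
    cohort — required when a single model pools participants, e.g. the
    per-opponent final-move EV fits), or False (raw units).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials given")
    # per (participant, opponent) trial counts for the experience predictor
    counts: dict[tuple[str, int], int] = {}
    for tr in trials:
        key = (tr.participant_id, tr.opponent_id)
        counts[key] = max(counts.get(key, 0), tr.trial_index + 1)
    parts = []
    for k, tr in enumerate(trials):
        df = _trial_rows(tr, counts[(tr.participant_id, tr.opponent_id)], dead_zone)
        df.insert(0, "trial_id", k)
        parts.append(df)
    frame = pd.concat(parts, ignore_index=True)
    scalers: dict = {}
    for c in STATE_COLUMNS:
        frame[f"z_{c}"] = frame[c]
    if standardize == "global":
        mean = frame[STATE_COLUMNS].mean().to_numpy()
        sd = frame[STATE_COLUMNS].std(ddof=0).to_numpy()
        sd = np.where(sd > 0, sd, 1.0)
        frame[[f"z_{c}" for c in STATE_COLUMNS]] = (
            (frame[STATE_COLUMNS].to_numpy() - mean) / sd
        )
        for pid in frame["participant_id"].unique():
            scalers[pid] = (mean, sd)
    elif standardize:
        for pid, g in frame.groupby("participant_id"):
            mean = g[STATE_COLUMNS].mean().to_numpy()
            sd = g[STATE_COLUMNS].std(ddof=0).to_numpy()
            sd = np.where(sd > 0, sd, 1.0)
            scalers[pid] = (mean, sd)
            idx = g.index
            frame.loc[idx, [f"z_{c}" for c in STATE_COLUMNS]] = (
                (g[STATE_COLUMNS].to_numpy() - mean) / sd
            )
    else:
        for pid in frame["participant_id"].unique():
            scalers[pid] = (
                np.zeros(len(STATE_COLUMNS)),
                np.ones(len(STATE_COLUMNS)),
            )
    return Design(frame, scalers)


def split_train_test(
    n_or_design, fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random timepoint-level split into train/test index arrays.

    ``fraction`` is the training share, strictly inside (0, 1); the split is
    exact (``round(n * fraction)`` training rows), disjoint and exhaustive.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly between 0 and 1")
    n = n_or_design if isinstance(n_or_design, (int, np.integer)) else len(n_or_design)
    n = int(n)
    n_train = int(round(n * fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(f"degenerate split: n={n}, fraction={fraction}")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
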