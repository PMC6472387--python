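"""Final-move timing analysis and the positioning-vs-timing comparison.

Treating the trial as a stopping problem, the final-move expected value
model gives, at every timestep of every trial, the counterfactual win
probability of changing direction *now* and holding course. For each trial
this yields an EV curve over time; the optimal final-move time ``t_opt`` is
its argmax (earliest step on ties) and the timing deviation is
``|t_move - t_opt|`` in normalized time, where ``t_move`` is the observed
final change point. Skilled timing shows up as small deviations and high
win rates.

Two competing explanations of skill are contrasted between the top and
bottom scorers: under an advantageous-positioning hypothesis the better
player's EV curve is vertically shifted upward late in the trial; under an
advantageous-timing hypothesis the EV curves match but the better player's
final moves concentrate near the EV peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Design
from .models import EmpiricalQ, EmpiricalQResults, FinalMoveEV, FinalMoveEVResults

__all__ = [
    "fit_empirical_q",
    "fit_final_move_ev",
    "timing_analysis",
    "TimingResult",
    "hypothesis_comparison",
    "HypothesisReport",
]


def fit_empirical_q(
    design: Design, n_inducing: int = 50, n_iter: int = 5000, seed: int = 0, **kw
) -> EmpiricalQResults:
    """Fit the empirical action-value GP Q(a | s, omega) -> P(win)."""
    return EmpiricalQ(design).fit(n_inducing=n_inducing, n_iter=n_iter, seed=seed, **kw)


def fit_final_move_ev(
    design: Design, n_inducing: int = 30, n_iter: int = 2000, seed: int = 0, **kw
) -> FinalMoveEVResults:
    """Fit the per-opponent final-move expected-value GPs."""
    return FinalMoveEV(design).fit(n_inducing=n_inducing, n_iter=n_iter, seed=seed, **kw)


@dataclass
class TimingResult:
    """Per-trial timing metrics and per-participant aggregates.

    ``trials`` has one row per trial with a final change point: t_move,
    t_opt (steps), their normalized deviation, the trial EV curve summary
    and outcome. ``participants`` aggregates mean deviation and win rate
    (win rates count all trials, including those without change points).
    """

    trials: pd.DataFrame
    participants: pd.DataFrame
    ev_curves: dict = field(default_factory=dict)


def timing_analysis(results: FinalMoveEVResults, design: Design) -> TimingResult:
    """Evaluate EV curves, optimal move times, and timing deviations."""
    frame = design.frame
    X = design.X
    rows = []
    curves = {}
    final_rows = set(results.model.final_rows)
    for trial_id, g in frame.groupby("trial_id", sort=True):
        omega = float(g["omega"].iloc[0])
        idx = g.index.to_numpy()
        ev = results.ev(X[idx], omega)
        ts = g["t"].to_numpy()
        t_opt = int(ts[np.argmax(ev)])  # earliest step on exact ties
        curves[int(trial_id)] = pd.DataFrame(
            {"t": ts, "ev": ev, "omega": omega,
             "participant_id": g["participant_id"].iloc[0]}
        )
        fin = [i for i in idx if i in final_rows]
        n_len = int(g["trial_len"].iloc[0])
        rec = {
            "trial_id": trial_id,
            "participant_id": g["participant_id"].iloc[0],
            "omega": omega,
            "w": int(g["w"].iloc[0]),
            "t_opt": t_opt,
            "ev_max": float(np.max(ev)),
            "ev_mean": float(np.mean(ev)),
            "trial_len": n_len,
        }
        if fin:
            t_move = int(frame.loc[fin[0], "t"])
            rec["t_move"] = t_move
            rec["ev_at_move"] = float(ev[list(ts).index(t_move)])
            rec["deviation"] = abs(t_move - t_opt) / n_len
        rows.append(rec)
    trials = pd.DataFrame(rows)
    agg = trials.groupby("participant_id").agg(
        mean_deviation=("deviation", "mean"),
        win_rate=("w", "mean"),
        mean_ev_at_move=("ev_at_move", "mean"),
        n_trials=("w", "size"),
    ).reset_index()
    return TimingResult(trials, agg, curves)


@dataclass
class HypothesisReport:
    """Top-vs-bottom scorer contrast of EV offset vs timing concentration.

    ``ev_offset_late`` (positioning): mean late-trial EV of the top scorer
    minus the bottom scorer — large if skill is carrying better states.
    ``timing_gap`` (timing): mean normalized |t_move - t_opt| of the bottom
    scorer minus the top scorer — large if skill is timing concentration.
    Both are reported so the data decide.
    """

    top: str
    bottom: str
    ev_offset_late: float
    timing_gap: float
    table: pd.DataFrame

    def decisive_factor(self, scale_ev: float = 1.0, scale_timing: float = 1.0) -> str:
        a = abs(self.ev_offset_late) / scale_ev
        b = abs(self.timing_gap) / scale_timing
        return "positioning" if a > b else "timing"


def hypothesis_comparison(
    timing: TimingResult, late_fraction: float = 0.75
) -> HypothesisReport:
    """Contrast the highest and lowest scorers' EV curves and timing."""
    parts = timing.participants
    if len(parts) < 2:
        raise ValueError("need at least 2 participants")
    if parts["win_rate"].nunique() == 1:
        top = parts["participant_id"].iloc[0]
        bottom = parts["participant_id"].iloc[-1]
    else:
        top = parts.loc[parts["win_rate"].idxmax(), "participant_id"]
        bottom = parts.loc[parts["win_rate"].idxmin(), "participant_id"]

    def late_ev(pid: str) -> float:
        vals = []
        for tid, c in timing.ev_curves.items():
            if c["participant_id"].iloc[0] != pid:
                continue
            cut = c["t"] >= late_fraction * c["t"].max()
            # average the curve within trial first, then across trials
            vals.append(c.loc[cut, "ev"].mean())
        return float(np.mean(vals))

    dev = parts.set_index("participant_id")["mean_deviation"]
    report = HypothesisReport(
        top=str(top),
        bottom=str(bottom),
        ev_offset_late=late_ev(top) - late_ev(bottom),
        timing_gap=float(dev[bottom] - dev[top]),
        table=parts.sort_values("win_rate", ascending=False).reset_index(drop=True),
    )
    return report
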