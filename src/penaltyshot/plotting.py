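"""Regenerable figures: trajectories, change-point overlays, EV/timing curves."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .design import Design
from .svgp import probit_average

__all__ = [
    "plot_trajectories",
    "plot_changepoint_overlay",
    "plot_switch_probability",
    "plot_ev_and_final_moves",
]

_OPP_COLORS = {0.0: "tab:green", 1.0: "tab:blue"}


def plot_trajectories(trials, ax=None, max_trials: int | None = None):
    """All puck trajectories of one participant, colored by opponent."""
    ax = ax or plt.subplots(figsize=(5, 4))[1]
    for tr in trials[:max_trials]:
        ax.plot(tr.puck_x, tr.puck_y, color=_OPP_COLORS.get(float(tr.opponent_id)),
                lw=0.6, alpha=0.4)
    ax.set_xlabel("puck x")
    ax.set_ylabel("puck y")
    ax.set_ylim(-1, 1)
    return ax


def plot_changepoint_overlay(trials, changepoints, ax=None):
    """Trajectories with observed change points marked."""
    ax = plot_trajectories(trials, ax=ax)
    for tr, cps in zip(trials, changepoints):
        if len(cps):
            ax.plot(tr.puck_x[cps], tr.puck_y[cps], "k.", ms=3)
    return ax


def plot_switch_probability(results, design: Design, ax=None):
    """Mean change probability vs time, averaged on the probit scale."""
    ax = ax or plt.subplots(figsize=(5, 3))[1]
    frame = design.frame
    p = results.predict_proba(design.X)
    for omega in sorted(frame["omega"].unique()):
        mask = frame["omega"].to_numpy() == omega
        sub = frame[mask]
        probs = p[mask]
        ts = np.sort(sub["t"].unique())
        curve = [probit_average(probs[sub["t"].to_numpy() == t]) for t in ts]
        ax.plot(ts, curve, color=_OPP_COLORS.get(float(omega)),
                label=f"opponent {omega:g}")
    ax.set_xlabel("timestep")
    ax.set_ylabel("P(change point)")
    ax.legend(frameon=False)
    return ax


def plot_ev_and_final_moves(timing, pid: str, ax=None, bins: int = 20):
    """Final-move EV over time with the final change-point distribution."""
    ax = ax or plt.subplots(figsize=(5, 3))[1]
    curves = [c for c in timing.ev_curves.values()
              if c["participant_id"].iloc[0] == pid]
    ts = np.sort(np.unique(np.concatenate([c["t"].to_numpy() for c in curves])))
    mean_ev = np.full(len(ts), np.nan)
    for j, t in enumerate(ts):
        vals = [c.loc[c["t"] == t, "ev"].mean() for c in curves
                if (c["t"] == t).any()]
        mean_ev[j] = np.mean(vals)
    ax.plot(ts, mean_ev, color="tab:red", label="final-move EV")
    moves = timing.trials.query("participant_id == @pid")["t_move"].dropna()
    if len(moves):
        ax2 = ax.twinx()
        ax2.hist(moves, bins=bins, color="tab:blue", alpha=0.35, density=True)
        ax2.set_ylabel("final move density")
    ax.set_xlabel("timestep")
    ax.set_ylabel("EV")
    ax.set_title(pid)
    return ax
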