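"""Gradient-based sensitivity indices of the latent policy GP.

Because the latent f is a GP with a smooth kernel, its gradient is a GP as
well, with analytic posterior mean and covariance at any input point. Each
input dimension i gets an uncertainty-normalized squared-gradient index

    nu_i(x) = ( grad_i f(x) / sigma_i(x) )^2,

where sigma_i is the posterior standard deviation of grad_i f at x; under
the null (no real dependence on input i) nu_i is chi-squared with one
degree of freedom. The combined opponent-action sensitivity whitens the
(opponent position, opponent velocity) gradient block by the Cholesky
factor of its posterior covariance,

    varsigma(x) = || L^-1 grad_xt f(x) ||^2,   L L^T = Sigma_xt,

equivalently a PCA of the two coordinates with every principal component
weighted equally. Given the observed index, the sampling distribution of
the underlying squared standardized gradient is noncentral chi-squared,
which provides per-timepoint credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.stats import ncx2

from .design import Design, INPUT_COLUMNS, OPP_ACTION_COLUMNS

__all__ = [
    "GradientPosterior",
    "latent_gradient",
    "sensitivity_index",
    "opponent_action_sensitivity",
    "credible_interval",
    "sensitivity_table",
    "aggregate_sensitivity",
    "opponent_phase_difference",
]

#: indices of the opponent position/velocity block within INPUT_COLUMNS
OPP_BLOCK = tuple(INPUT_COLUMNS.index(c) for c in OPP_ACTION_COLUMNS)


@dataclass
class GradientPosterior:
    """Posterior of grad f at a batch of points: mean (n, D), cov (n, D, D)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(self.mean)
        if self.cov.ndim == 2:
            self.cov = self.cov[None, :, :]

    @property
    def sd(self) -> np.ndarray:
        d = np.einsum("ndd->nd", self.cov)
        return np.sqrt(np.maximum(d, 0.0))


def latent_gradient(model, X: np.ndarray) -> GradientPosterior:
    """Analytic posterior of the latent gradient of a fitted SVGP at X."""
    mean, cov = model.latent_gradient(np.atleast_2d(X))
    return GradientPosterior(mean, cov)


def sensitivity_index(grad: GradientPosterior, i: int | None = None) -> np.ndarray:
    """nu_i = (grad_i f / sd_i)^2 per point; all dimensions if i is None."""
    sd = grad.sd
    if np.any(sd <= 0):
        raise ValueError("degenerate gradient posterior: zero standard deviation")
    nu = (grad.mean / sd) ** 2
    return nu if i is None else nu[:, i]


def opponent_action_sensitivity(
    grad: GradientPosterior, block: tuple[int, int] = OPP_BLOCK
) -> np.ndarray:
    """Whitened squared norm of the opponent position/velocity gradient.

    varsigma = g^T Sigma^-1 g for the 2x2 posterior covariance block Sigma;
    raises if the block is numerically singular (with its condition number).
    """
    b = list(block)
    g = grad.mean[:, b]
    Sig = grad.cov[:, b][:, :, b]
    out = np.empty(len(g))
    for k in range(len(g)):
        try:
            L = cholesky(Sig[k], lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError(
                f"singular opponent-block covariance at point {k}; "
                f"condition number {np.linalg.cond(Sig[k]):.3g}"
            ) from exc
        whitened = solve_triangular(L, g[k], lower=True)
        out[k] = whitened @ whitened
    return out


def credible_interval(nu: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Noncentral-chi2(1, nu) interval for the underlying squared gradient."""
    nu = np.asarray(nu, float)
    a = (1.0 - level) / 2.0
    lo = ncx2.ppf(a, df=1, nc=nu)
    hi = ncx2.ppf(1.0 - a, df=1, nc=nu)
    return np.stack([lo, hi], axis=-1)


def sensitivity_table(
    model, design: Design, rows: np.ndarray | None = None, level: float = 0.95
) -> pd.DataFrame:
    """Per-timepoint table of the 8 nu indices, varsigma, and intervals.

    ``rows`` optionally restricts to an index subset of the design frame.
    Keyed by participant, trial, opponent and timestep.
    """
    frame = design.frame if rows is None else design.frame.iloc[rows]
    X = design.X if rows is None else design.X[rows]
    grad = latent_gradient(model, X)
    nu = sensitivity_index(grad)
    vs = opponent_action_sensitivity(grad)
    out = frame[["participant_id", "trial_id", "trial_index", "omega", "t",
                 "trial_len"]].reset_index(drop=True)
    for j, c in enumerate(INPUT_COLUMNS):
        out[f"nu_{c}"] = nu[:, j]
        ci = credible_interval(nu[:, j], level)
        out[f"nu_{c}_lo"] = ci[:, 0]
        out[f"nu_{c}_hi"] = ci[:, 1]
    out["varsigma"] = vs
    ci = credible_interval(vs, level)
    out["varsigma_lo"] = ci[:, 0]
    out["varsigma_hi"] = ci[:, 1]
    return out


def aggregate_sensitivity(table: pd.DataFrame, level: str = "participant") -> pd.DataFrame:
    """Mean indices at trial or participant granularity."""
    cols = [c for c in table.columns if c.startswith("nu_") or c == "varsigma"]
    cols = [c for c in cols if not c.endswith(("_lo", "_hi"))]
    if level == "timepoint":
        return table[cols]
    if level == "trial":
        keys = ["participant_id", "trial_id", "omega"]
    elif level == "participant":
        keys = ["participant_id"]
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    grouped = table.groupby(keys, sort=True)[cols].mean()
    if grouped.isna().any().any() or any(n == 0 for n in grouped.count(1)):
        raise ValueError("empty aggregation group")
    return grouped.reset_index()


def opponent_phase_difference(
    table: pd.DataFrame, index: str = "varsigma", split: float = 0.5
) -> pd.DataFrame:
    """Per-participant opponent differences in log sensitivity, by phase.

    For each participant and each trial phase (early = first ``split``
    fraction of the trial, late = remainder) the statistic is

        mean log(index | omega = 1) - mean log(index | omega = 0),

    positive when the participant is more sensitive against the human
    opponent in that phase.
    """
    t = table.copy()
    t["phase"] = np.where(t["t"] < split * t["trial_len"], "early", "late")
    t["log_idx"] = np.log(np.maximum(t[index], 1e-300))
    rows = []
    for pid, g in t.groupby("participant_id"):
        rec = {"participant_id": pid}
        for phase in ("early", "late"):
            gp = g[g["phase"] == phase]
            m1 = gp.loc[gp["omega"] == 1.0, "log_idx"].mean()
            m0 = gp.loc[gp["omega"] == 0.0, "log_idx"].mean()
            rec[phase] = m1 - m0
        rows.append(rec)
    return pd.DataFrame(rows)
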