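"""Model / Results classes for the policy and value GPs.

Follows the fit-and-results convention of statistical modelling packages:
a model object is built from data (here, a :class:`~penaltyshot.design.Design`
assembled from trials), ``fit()`` runs sparse variational inference and
returns a results object carrying the fitted kernel hyperparameters, the
variational state, held-out performance, and analysis methods (prediction,
latent gradients, sensitivity tables, summaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Design, INPUT_COLUMNS, build_design, split_train_test
from .svgp import SVGPClassifier

__all__ = [
    "ChangePointPolicy",
    "PolicyResults",
    "EmpiricalQ",
    "EmpiricalQResults",
    "FinalMoveEV",
    "FinalMoveEVResults",
]


def _fit_classifier(X, y, n_inducing, n_iter, seed, **kw) -> SVGPClassifier:
    model = SVGPClassifier(n_inducing=n_inducing, n_iter=n_iter, seed=seed, **kw)
    return model.fit(X, y)


class _GPModelBase:
    """Shared fit plumbing over a labeled design matrix."""

    #: label column predicted by the subclass
    label = "a"

    def __init__(self, design: Design):
        self.design = design

    @classmethod
    def from_trials(cls, trials, **design_kw):
        return cls(build_design(trials, **design_kw))

    def _inputs(self) -> np.ndarray:
        return self.design.X

    def _labels(self) -> np.ndarray:
        return self.design.frame[self.label].to_numpy()

    def fit(
        self,
        n_inducing: int = 50,
        n_iter: int = 5000,
        test_fraction: float = 0.2,
        seed: int = 0,
        **svgp_kw,
    ):
        X = self._inputs()
        y = self._labels()
        train, test = split_train_test(len(X), 1.0 - test_fraction, seed=seed)
        gp = _fit_classifier(X[train], y[train], n_inducing, n_iter, seed, **svgp_kw)
        auc = gp.score_auc(X[test], y[test])
        return self._results_cls(self, gp, train, test, auc)


@dataclass
class _ResultsBase:
    model: _GPModelBase
    gp: SVGPClassifier
    train_idx: np.ndarray
    test_idx: np.ndarray
    auc_: float

    @property
    def input_names(self) -> list[str]:
        return list(INPUT_COLUMNS)

    @property
    def lengthscales(self) -> pd.Series:
        return pd.Series(self.gp.kernel_.lengthscales, index=self.input_names)

    @property
    def kernel_variance(self) -> float:
        return self.gp.kernel_.variance

    @property
    def elbo_trace(self) -> list:
        return self.gp.elbo_trace_

    def predict_proba(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.model._inputs() if X is None else X
        return self.gp.predict_proba(X)

    def latent(self, X: np.ndarray | None = None):
        X = self.model._inputs() if X is None else X
        return self.gp.latent(X)

    def latent_gradient(self, X: np.ndarray | None = None):
        from .sensitivity import latent_gradient

        X = self.model._inputs() if X is None else X
        return latent_gradient(self.gp, X)

    def summary(self) -> str:
        name = type(self).__name__.replace("Results", "")
        ls = self.lengthscales
        lines = [
            f"{name} (sparse variational GP, probit link)",
            "=" * 52,
            f"observations: {len(self.model.design):>8d}"
            f"    inducing points: {len(self.gp.q_mu_)}",
            f"held-out AUC: {self.auc_:>10.3f}"
            f"    kernel variance: {self.kernel_variance:.3f}",
            "-" * 52,
            "ARD length scales (large = weak influence):",
        ]
        for k, v in ls.sort_values().items():
            lines.append(f"  {k:<16s} {v:>10.3f}")
        lines.append("=" * 52)
        return "\n".join(lines)


class PolicyResults(_ResultsBase):
    """Fitted change-point policy pi(s, omega) = Phi(f)."""

    def sensitivity_table(self, rows: np.ndarray | None = None) -> pd.DataFrame:
        from .sensitivity import sensitivity_table

        return sensitivity_table(self.gp, self.model.design, rows)


class ChangePointPolicy(_GPModelBase):
    """GP probit model of the probability of reversing direction next step."""

    label = "a"
    _results_cls = PolicyResults


class EmpiricalQResults(_ResultsBase):
    """Fitted empirical action value Q(a | s, omega): P(win | state, action)."""

    @property
    def input_names(self) -> list[str]:
        return list(INPUT_COLUMNS) + ["a"]

    def q_values(self, X_state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(Q(a=0 | s), Q(a=1 | s)) for a batch of state inputs."""
        n = len(X_state)
        q = []
        for a in (0.0, 1.0):
            q.append(
                self.gp.predict_proba(
                    np.column_stack([X_state, np.full(n, a)])
                )
            )
        return q[0], q[1]


class EmpiricalQ(_GPModelBase):
    """GP probit model of trial outcome from state, opponent and action."""

    label = "w"
    _results_cls = EmpiricalQResults

    def _inputs(self) -> np.ndarray:
        return np.column_stack(
            [self.design.X, self.design.frame["a"].to_numpy(float)]
        )


@dataclass
class FinalMoveEVResults:
    """Per-opponent GPs giving the win probability of a final move now."""

    model: "FinalMoveEV"
    gps: dict
    aucs: dict
    n_excluded: int

    def ev(self, X: np.ndarray, omega: float) -> np.ndarray:
        """Final-move expected value at states X against opponent omega."""
        key = float(omega)
        if key not in self.gps:
            raise KeyError(f"no model for opponent {omega!r}")
        return self.gps[key].predict_proba(X)

    def summary(self) -> str:
        lines = ["FinalMoveEV (one GP per opponent)", "=" * 52]
        for k, gp in sorted(self.gps.items()):
            lines.append(
                f"opponent {k:g}: n_train={gp._n_train}, "
                f"train AUC={self.aucs[k]:.3f}"
            )
        lines.append(f"trials without any change point excluded: {self.n_excluded}")
        return "\n".join(lines)


class FinalMoveEV:
    """Model of the value of making one's *final* direction change now.

    Trained only on the final change point of each trial (state -> win),
    one GP per opponent: once the shooter has committed to a straight-line
    finish, strategy is trivial and the outcome depends only on the state
    at commitment and the opponent's counter-strategy, so trials pool
    across participants within an opponent.
    """

    def __init__(self, design: Design):
        self.design = design
        frame = design.frame
        cp = frame[frame["a"] == 1]
        self.final_rows = cp.groupby("trial_id")["t"].idxmax().to_numpy()
        n_trials = frame["trial_id"].nunique()
        self.n_excluded = int(n_trials - len(self.final_rows))

    @classmethod
    def from_trials(cls, trials, **design_kw):
        return cls(build_design(trials, **design_kw))

    def fit(
        self, n_inducing: int = 30, n_iter: int = 2000, seed: int = 0, **svgp_kw
    ) -> FinalMoveEVResults:
        frame = self.design.frame
        X = self.design.X
        gps, aucs = {}, {}
        for omega in sorted(frame["omega"].unique()):
            rows = self.final_rows[
                frame.loc[self.final_rows, "omega"].to_numpy() == omega
            ]
            y = frame.loc[rows, "w"].to_numpy()
            if len(np.unique(y)) < 2:
                raise ValueError(
                    f"opponent {omega:g}: single-class outcomes at final moves"
                )
            gp = _fit_classifier(
                X[rows], y, min(n_inducing, len(rows)), n_iter, seed, **svgp_kw
            )
            gp._n_train = len(rows)
            gps[float(omega)] = gp
            aucs[float(omega)] = gp.score_auc(X[rows], y)
        return FinalMoveEVResults(self, gps, aucs, self.n_excluded)
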