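"""ANOVA-style variance decomposition of per-timepoint indices.

Every index value carries a participant label and a (nested) trial label.
As in classical analysis of variance the value decomposes into a
participant-level mean, a trial-level offset and a point-level residual,
and with group-size weighting the corresponding sums of squares add up to
the total sum of squares *exactly* (law of total variance):

    sigma2_participants + sigma2_trials + sigma2_residual = sigma2_total.

Dividing by the total yields three proportions summing to one. The
permutation null jointly shuffles the (participant, trial) label pair
across data points and recomputes the decomposition; structured data
produce observed proportions far outside the permuted distribution, while
the permuted proportions themselves cluster near zero (up to the
degrees-of-freedom floor of an additive decomposition, roughly the number
of groups over the number of points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["VarianceComponents", "decompose", "permutation_test", "PermutationResult"]


@dataclass(frozen=True)
class VarianceComponents:
    """Raw variance components, their proportions, and group counts."""

    var_participants: float
    var_trials: float
    var_residual: float
    var_total: float
    prop_participants: float
    prop_trials: float
    prop_residual: float
    n_points: int
    n_participants: int
    n_trials: int

    def proportions(self) -> np.ndarray:
        return np.array(
            [self.prop_participants, self.prop_trials, self.prop_residual]
        )


def _codes(values, participants, trials):
    values = np.asarray(values, float).ravel()
    participants = np.asarray(participants)
    trials = np.asarray(trials)
    if not (len(values) == len(participants) == len(trials)):
        raise ValueError("values and labels must have equal length")
    _, p_idx = np.unique(participants, return_inverse=True)
    # nest trials within participants: a cell is a distinct (participant, trial)
    _, t_idx = np.unique(trials, return_inverse=True)
    n_t = t_idx.max() + 1
    _, c_idx = np.unique(p_idx.astype(np.int64) * n_t + t_idx, return_inverse=True)
    return values, p_idx, c_idx


def decompose(values, participant_labels, trial_labels) -> VarianceComponents:
    """Split total variance into participant / trial / residual parts.

    Weighted by group sizes so the three parts sum to the total sample
    variance exactly. Requires at least two participants; a participant
    with a single trial contributes no trial-level variance (warned).
    """
    values, p_idx, c_idx = _codes(values, participant_labels, trial_labels)
    n = len(values)
    n_p = p_idx.max() + 1
    n_c = c_idx.max() + 1
    if n_p < 2:
        raise ValueError("need at least 2 participants")
    cnt_c = np.bincount(c_idx)
    mean_c = np.bincount(c_idx, values) / cnt_c
    cnt_p = np.bincount(p_idx)
    mean_p = np.bincount(p_idx, values) / cnt_p
    # map each cell to its participant
    cell_to_p = np.full(n_c, -1, dtype=int)
    cell_to_p[c_idx] = p_idx
    trials_per_p = np.bincount(cell_to_p, minlength=n_p)
    if np.any(trials_per_p < 2):
        warnings.warn(
            "participant(s) with a single trial contribute no trial-level variance"
        )
    grand = values.mean()
    ss_p = float(np.sum(cnt_p * (mean_p - grand) ** 2))
    ss_t = float(np.sum(cnt_c * (mean_c - mean_p[cell_to_p]) ** 2))
    ss_r = float(np.sum((values - mean_c[c_idx]) ** 2))
    ss_tot = ss_p + ss_t + ss_r
    if ss_tot <= 0:
        raise ValueError("zero total variance: decomposition undefined")
    return VarianceComponents(
        var_participants=ss_p / n,
        var_trials=ss_t / n,
        var_residual=ss_r / n,
        var_total=ss_tot / n,
        prop_participants=ss_p / ss_tot,
        prop_trials=ss_t / ss_tot,
        prop_residual=ss_r / ss_tot,
        n_points=n,
        n_participants=int(n_p),
        n_trials=int(n_c),
    )


@dataclass(frozen=True)
class PermutationResult:
    observed: VarianceComponents
    null_prop_participants: np.ndarray
    null_prop_trials: np.ndarray
    p_participants: float
    p_trials: float


def permutation_test(
    values, participant_labels, trial_labels, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Joint (participant, trial)-label shuffle null for the decomposition.

    Each permutation reassigns the whole label pair across data points
    (equivalently, permutes the values against the fixed label structure),
    so the total variance is identical across permutations while any real
    participant- or trial-level structure is destroyed. One-sided p-values
    use the (1 + #{null >= observed}) / (n_perm + 1) convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values, p_idx, c_idx = _codes(values, participant_labels, trial_labels)
    observed = decompose(values, p_idx, c_idx)
    n = len(values)
    cnt_c = np.bincount(c_idx)
    cnt_p = np.bincount(p_idx)
    n_c = len(cnt_c)
    cell_to_p = np.full(n_c, -1, dtype=int)
    cell_to_p[c_idx] = p_idx
    grand = values.mean()
    rng = np.random.default_rng(seed)
    null_p = np.empty(n_perm)
    null_t = np.empty(n_perm)
    ss_tot = observed.var_total * n
    for k in range(n_perm):
        v = values[rng.permutation(n)]
        mean_c = np.bincount(c_idx, v) / cnt_c
        mean_p = np.bincount(p_idx, v) / cnt_p
        ss_p = np.sum(cnt_p * (mean_p - grand) ** 2)
        ss_t = np.sum(cnt_c * (mean_c - mean_p[cell_to_p]) ** 2)
        null_p[k] = ss_p / ss_tot
        null_t[k] = ss_t / ss_tot
    p_p = (1.0 + np.sum(null_p >= observed.prop_participants)) / (n_perm + 1.0)
    p_t = (1.0 + np.sum(null_t >= observed.prop_trials)) / (n_perm + 1.0)
    return PermutationResult(observed, null_p, null_t, float(p_p), float(p_t))
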