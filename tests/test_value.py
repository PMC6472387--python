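"""Action-value models, final-move EV, timing analysis, hypothesis contrast."""

import dataclasses
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from penaltyshot.agents import HazardShooter, SyntheticShooterParams
from penaltyshot.design import Design, STATE_COLUMNS, build_design
from penaltyshot.engine import GameConfig, run_trial
from penaltyshot.models import EmpiricalQ, FinalMoveEV
from penaltyshot.value import (
    fit_final_move_ev,
    hypothesis_comparison,
    timing_analysis,
    TimingResult,
)

CFG = GameConfig()


def frozen_goalie_trials(n=150, seed=0, params=None):
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n):
        tr = run_trial(
            HazardShooter(params or SyntheticShooterParams()),
            lambda s, r: 0.0,
            CFG,
            seed=rng,
            participant_id="p000",
            opponent_id=0,
            trial_index=i,
        )
        trials.append(tr)
    return trials


def synthetic_design(n=3000, seed=0, label_fn=None):
    """Design built directly from fabricated standardized states."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {f"z_{c}": rng.normal(size=n) for c in STATE_COLUMNS}
    )
    frame["omega"] = rng.integers(0, 2, n).astype(float)
    frame["participant_id"] = "p000"
    frame["trial_id"] = np.arange(n) // 30
    frame["trial_index"] = frame["trial_id"]
    frame["t"] = np.arange(n) % 30 + 1
    frame["trial_len"] = 30
    frame["a"] = rng.integers(0, 2, n)
    frame["w"] = label_fn(frame, rng) if label_fn else rng.integers(0, 2, n)
    for c in STATE_COLUMNS:
        frame[c] = frame[f"z_{c}"]
    scal = {"p000": (np.zeros(len(STATE_COLUMNS)), np.ones(len(STATE_COLUMNS)))}
    return Design(frame, scal)


class TestEmpiricalQ:
    def test_state_independent_outcomes_predict_base_rate(self):
        des = synthetic_design(2500, seed=1,
                               label_fn=lambda f, rng: rng.random(len(f)) < 0.6)
        res = EmpiricalQ(des).fit(n_inducing=20, n_iter=800, seed=0)
        p = res.predict_proba()
        assert abs(p.mean() - 0.6) < 0.06
        assert p.std() < 0.08

    def test_outcome_driven_by_late_puck_position_is_predictable(self):
        trials = frozen_goalie_trials(60, seed=2)
        des = build_design(trials)
        # outcome := sign of puck_y at trial end (fully state-determined)
        frame = des.frame
        final_sign = frame.groupby("trial_id")["puck_y"].transform("last") > 0
        frame["w"] = final_sign.astype(int)
        res = EmpiricalQ(des).fit(n_inducing=30, n_iter=2500, seed=0,
                                  learning_rate=0.03)
        test_rows = res.test_idx
        late = frame.iloc[test_rows]["t"].to_numpy() > 47
        X = res.model._inputs()[test_rows][late]
        y = frame.iloc[test_rows]["w"].to_numpy()[late]
        assert res.gp.score_auc(X, y) >= 0.9

    def test_action_contrast_where_switching_matters(self):
        # construct outcomes where switching is right exactly when the
        # puck sits high: Q(a=1|s) - Q(a=0|s) must change sign with puck_y
        def labels(f, rng):
            good = (f["a"] == 1) == (f["z_puck_y"] > 0)
            return (rng.random(len(f)) < np.where(good, 0.9, 0.1)).astype(int)

        des = synthetic_design(4000, seed=3, label_fn=labels)
        res = EmpiricalQ(des).fit(n_inducing=25, n_iter=1500, seed=0)
        state_hi = np.zeros((1, 8))
        state_hi[0, 1] = 1.5
        state_lo = np.zeros((1, 8))
        state_lo[0, 1] = -1.5
        q0_hi, q1_hi = res.q_values(state_hi)
        q0_lo, q1_lo = res.q_values(state_lo)
        assert q1_hi[0] - q0_hi[0] > 0.2
        assert q1_lo[0] - q0_lo[0] < -0.2


class TestFinalMoveEV:
    def test_agrees_with_kinematic_rollout_against_frozen_goalie(self):
        trials = frozen_goalie_trials(160, seed=4)
        des = build_design(trials, standardize="global")
        model = FinalMoveEV(des)
        res = model.fit(n_inducing=30, n_iter=2000, seed=0, learning_rate=0.03)
        frame = des.frame
        rows = model.final_rows
        # brute-force rollout: straight line at v_p from the final move to
        # the bar plane, frozen bar at center
        v_p = CFG.puck_speed
        width = CFG.bar_half_height + CFG.puck_radius
        crossing = 94
        agree = wins = 0
        for r in rows:
            row = frame.loc[r]
            steps = crossing - row["t"]
            new_dir = -np.sign(row["puck_vy"]) or 1.0
            y_cross = np.clip(
                row["puck_y"] + new_dir * v_p * steps,
                -(1 - CFG.puck_radius), 1 - CFG.puck_radius,
            )
            rollout_win = abs(y_cross) > width
            assert rollout_win == bool(row["w"])  # oracle sanity
            ev = res.ev(des.X[[r]], 0.0)[0]
            agree += (ev >= 0.5) == rollout_win
        assert agree / len(rows) >= 0.9

    def test_duplicating_trials_leaves_predictions_essentially_unchanged(self):
        trials = frozen_goalie_trials(80, seed=5)
        doubled = trials + [
            dataclasses.replace(t, trial_index=t.trial_index + 80)
            for t in trials
        ]
        d1 = build_design(trials, standardize="global")
        d2 = build_design(doubled, standardize="global")
        r1 = FinalMoveEV(d1).fit(n_inducing=25, n_iter=1500, seed=0)
        r2 = FinalMoveEV(d2).fit(n_inducing=25, n_iter=1500, seed=0)
        X = d1.X[FinalMoveEV(d1).final_rows]
        assert np.mean(np.abs(r1.ev(X, 0.0) - r2.ev(X, 0.0))) < 0.05

    def test_single_class_outcome_stratum_rejected(self):
        trials = frozen_goalie_trials(40, seed=6)
        des = build_design(trials)
        des.frame["w"] = 1
        with pytest.raises(ValueError):
            FinalMoveEV(des).fit(n_inducing=10, n_iter=100)

    def test_trials_without_changepoints_are_excluded_and_counted(self):
        trials = frozen_goalie_trials(30, seed=7)
        flat = dataclasses.replace(
            trials[0],
            puck_u=np.where(trials[0].puck_u == 0, 0.0, 1.0),
            trial_index=30,
        )
        model = FinalMoveEV(build_design(trials + [flat]))
        assert model.n_excluded == 1

    def test_unknown_opponent_rejected(self):
        trials = frozen_goalie_trials(30, seed=8)
        res = FinalMoveEV(build_design(trials)).fit(n_inducing=10, n_iter=200)
        with pytest.raises(KeyError):
            res.ev(np.zeros((1, 8)), omega=3.0)


class TestTiming:
    def _stub(self, design, curve_fn):
        model = SimpleNamespace(final_rows=FinalMoveEV(design).final_rows)
        return SimpleNamespace(model=model,
                               ev=lambda X, omega: curve_fn(len(X)))

    def test_monotone_ev_curve_puts_t_opt_at_last_step(self):
        trials = frozen_goalie_trials(5, seed=9)
        des = build_design(trials)
        res = self._stub(des, lambda n: np.linspace(0.1, 0.9, n))
        tim = timing_analysis(res, des)
        for _, row in tim.trials.iterrows():
            g = des.frame[des.frame["trial_id"] == row["trial_id"]]
            assert row["t_opt"] == g["t"].max()

    def test_flat_curve_breaks_ties_to_earliest_step(self):
        trials = frozen_goalie_trials(5, seed=10)
        des = build_design(trials)
        res = self._stub(des, lambda n: np.full(n, 0.5))
        tim = timing_analysis(res, des)
        for _, row in tim.trials.iterrows():
            g = des.frame[des.frame["trial_id"] == row["trial_id"]]
            assert row["t_opt"] == g["t"].min()

    def test_deviation_is_normalized_absolute_gap(self):
        trials = frozen_goalie_trials(20, seed=11)
        des = build_design(trials)
        res = self._stub(des, lambda n: np.linspace(0, 1, n))
        tim = timing_analysis(res, des)
        got = tim.trials.dropna(subset=["t_move"])
        manual = (got["t_move"] - got["t_opt"]).abs() / got["trial_len"]
        assert np.allclose(got["deviation"], manual)

    def test_win_rate_counts_trials_without_changepoints(self):
        trials = frozen_goalie_trials(20, seed=12)
        flat = dataclasses.replace(
            trials[0],
            puck_u=np.where(trials[0].puck_u == 0, 0.0, 1.0),
            trial_index=20, outcome=1,
        )
        des = build_design(trials + [flat])
        res = self._stub(des, lambda n: np.linspace(0, 1, n))
        tim = timing_analysis(res, des)
        assert int(tim.participants["n_trials"].iloc[0]) == 21


class TestHypothesisComparison:
    def test_fewer_than_two_participants_rejected(self):
        tim = TimingResult(
            pd.DataFrame(), pd.DataFrame({"participant_id": ["a"],
                                          "win_rate": [0.5],
                                          "mean_deviation": [0.1]}), {}
        )
        with pytest.raises(ValueError):
            hypothesis_comparison(tim)

    def test_identical_participants_show_no_strong_discrimination(self):
        from penaltyshot.agents import TimedShooter, generate_dataset

        params = [SyntheticShooterParams(skill=0.5) for _ in range(6)]
        factory = lambda p, o, e, g: TimedShooter(p, o, e, goalie=g, delay=1)
        trials, _ = generate_dataset(6, 30, seed=13,
                                     participant_params=params,
                                     shooter_factory=factory)
        des = build_design(trials, standardize="global")
        res = fit_final_move_ev(des, n_inducing=25, n_iter=1200, seed=0)
        rep = hypothesis_comparison(timing_analysis(res, des))
        assert abs(rep.ev_offset_late) < 0.1
        assert abs(rep.timing_gap) < 0.1
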