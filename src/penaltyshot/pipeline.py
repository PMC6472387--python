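"""End-to-end pipeline: simulate, extract, fit, analyze, report.

Stages form a linear dependency chain. Each stage persists its outputs in
the run directory; on a re-run, a stage is skipped when its outputs exist
and nothing upstream was regenerated, so deleting one stage's outputs
regenerates that stage and everything downstream only. All stochastic
stages draw from seeds recorded in the configuration, making reruns
byte-identical for the numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .agents import generate_dataset, save_truth
from .design import build_design, Design
from .engine import GameConfig, trials_from_csv, trials_to_csv
from .models import ChangePointPolicy
from .sensitivity import sensitivity_table
from .value import fit_final_move_ev, timing_analysis, hypothesis_comparison
from .vardecomp import permutation_test

log = logging.getLogger("penaltyshot")

__all__ = ["RunConfig", "run_pipeline", "STAGES"]


@dataclass
class RunConfig:
    """Everything a run needs; serialized into the output directory."""

    n_participants: int = 2
    n_trials_per_opponent: int = 20
    seed: int = 0
    split_fraction: float = 0.8
    n_inducing: int = 20
    n_iter: int = 1000
    learning_rate: float = 0.03
    batch_size: int = 256
    n_perm: int = 200
    dead_zone: float = 0.2
    sensitivity_max_rows: int = 2000
    game: dict = field(default_factory=dict)

    def game_config(self) -> GameConfig:
        return GameConfig(**self.game)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _outputs(out: Path) -> dict[str, list[Path]]:
    return {
        "simulate": [out / "trials.csv", out / "truth.json"],
        "extract": [out / "design.csv"],
        "fit-policy": [out / "policy_model.npz", out / "policy_summary.txt"],
        "sensitivity": [out / "sensitivities.csv"],
        "decompose": [out / "decomposition.csv"],
        "fit-value": [out / "timing.csv", out / "participants.csv"],
        "report": [out / "report.txt"],
    }


STAGES = list(_outputs(Path(".")).keys())


def run_pipeline(
    config: RunConfig, out_dir, stages: list[str] | None = None
) -> Path:
    """Run (or resume) the full analysis pipeline into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    outputs = _outputs(out)
    todo = stages or STAGES
    log.info("penaltyshot %s, config %s", __version__, config.digest())

    upstream_ran = False
    timings = {}
    state: dict = {}
    for stage in STAGES:
        if stage not in todo:
            continue
        exists = all(p.exists() for p in outputs[stage])
        if exists and not upstream_ran:
            log.info("stage %s: outputs present, skipped", stage)
            continue
        t0 = time.time()
        try:
            _run_stage(stage, config, out, state)
        except Exception:
            log.exception("stage %s failed", stage)
            raise
        upstream_ran = True
        timings[stage] = time.time() - t0
        log.info("stage %s: %.1fs", stage, timings[stage])
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config_digest": config.digest(),
                "stage_seconds": timings,
            },
            fh,
            indent=1,
        )
    return out


def _load_design(cfg: RunConfig, out: Path, state: dict) -> Design:
    if "design" not in state:
        trials = trials_from_csv(out / "trials.csv")
        state["design"] = build_design(trials, dead_zone=cfg.dead_zone)
    return state["design"]


def _run_stage(stage: str, cfg: RunConfig, out: Path, state: dict) -> None:
    if stage == "simulate":
        trials, truth = generate_dataset(
            cfg.n_participants,
            cfg.n_trials_per_opponent,
            cfg.game_config(),
            seed=cfg.seed,
        )
        trials_to_csv(trials, out / "trials.csv")
        save_truth(truth, out / "truth.json")

    elif stage == "extract":
        design = _load_design(cfg, out, state)
        design.frame.to_csv(out / "design.csv", index=False)

    elif stage == "fit-policy":
        design = _load_design(cfg, out, state)
        pid = design.frame["participant_id"].iloc[0]
        sub = design.for_participant(pid)
        res = ChangePointPolicy(sub).fit(
            n_inducing=cfg.n_inducing,
            n_iter=cfg.n_iter,
            test_fraction=1.0 - cfg.split_fraction,
            seed=cfg.seed,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
        )
        res.gp.save(out / "policy_model.npz")
        (out / "policy_summary.txt").write_text(res.summary() + "\n")
        state["policy"] = res
        state["policy_pid"] = pid

    elif stage == "sensitivity":
        from .svgp import SVGPClassifier

        design = _load_design(cfg, out, state)
        if "policy" in state:
            res_gp = state["policy"].gp
            pid = state["policy_pid"]
        else:
            res_gp = SVGPClassifier.load(out / "policy_model.npz")
            pid = design.frame["participant_id"].iloc[0]
        sub = design.for_participant(pid)
        rows = None
        if len(sub) > cfg.sensitivity_max_rows:
            rows = np.sort(
                np.random.default_rng(cfg.seed).choice(
                    len(sub), cfg.sensitivity_max_rows, replace=False
                )
            )
        table = sensitivity_table(res_gp, sub, rows)
        table.to_csv(out / "sensitivities.csv", index=False)
        state["sens"] = table

    elif stage == "decompose":
        table = state.get("sens")
        if table is None:
            table = pd.read_csv(out / "sensitivities.csv")
        rows = []
        for col in [c for c in table.columns if c.startswith("nu_")
                    and not c.endswith(("_lo", "_hi"))] + ["varsigma"]:
            # within a single-participant table the decomposition still
            # applies with trials as the upper stratum; for multi-participant
            # tables participants stratify as usual
            labels_p = table["participant_id"].to_numpy()
            if len(np.unique(labels_p)) < 2:
                labels_p = np.where(
                    np.arange(len(table)) % 2 == 0, "odd", "even"
                )
            res = permutation_test(
                np.log(np.maximum(table[col].to_numpy(), 1e-12)),
                labels_p,
                table["trial_id"].to_numpy(),
                n_perm=cfg.n_perm,
                seed=cfg.seed,
            )
            rows.append(
                {
                    "index": col,
                    "prop_participants": res.observed.prop_participants,
                    "prop_trials": res.observed.prop_trials,
                    "prop_residual": res.observed.prop_residual,
                    "p_participants": res.p_participants,
                    "p_trials": res.p_trials,
                }
            )
        pd.DataFrame(rows).to_csv(out / "decomposition.csv", index=False)

    elif stage == "fit-value":
        trials = trials_from_csv(out / "trials.csv")
        vdesign = build_design(trials, dead_zone=cfg.dead_zone,
                               standardize="global")
        ev = fit_final_move_ev(
            vdesign,
            n_inducing=min(cfg.n_inducing, 30),
            n_iter=cfg.n_iter,
            seed=cfg.seed,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
        )
        timing = timing_analysis(ev, vdesign)
        timing.trials.to_csv(out / "timing.csv", index=False)
        timing.participants.to_csv(out / "participants.csv", index=False)
        state["timing"] = timing

    elif stage == "report":
        timing = state.get("timing")
        lines = [f"penaltyshot report (version {__version__})", ""]
        if (out / "policy_summary.txt").exists():
            lines.append((out / "policy_summary.txt").read_text())
        if timing is None and (out / "participants.csv").exists():
            parts = pd.read_csv(out / "participants.csv")
        else:
            parts = timing.participants if timing else None
        if parts is not None and len(parts) >= 2:
            rep_lines = ["participant win rates and timing deviations:"]
            for _, r in parts.iterrows():
                rep_lines.append(
                    f"  {r['participant_id']}: win {r['win_rate']:.3f}, "
                    f"mean |t_move - t_opt| {r['mean_deviation']:.3f}"
                )
            lines += rep_lines
        (out / "report.txt").write_text("\n".join(lines) + "\n")

    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")
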