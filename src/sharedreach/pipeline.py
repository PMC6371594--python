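"""End-to-end orchestration: scenes -> detection -> localization -> trials -> sweep.

A single :class:`RunConfig` (YAML or JSON) drives the whole pipeline with
one root seed; per-stage seeds are derived deterministically from it, so a
given (config, seed) pair reproduces every artifact bit-for-bit (timings
aside).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, calibration as cal, evaluation, imaging, synthetic
from .kinematics import JointConfig
from .shared_control import SharedControlParams, TargetSet
from .synthetic import SceneSpec, TrajectorySpec

log = logging.getLogger("sharedreach")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "child_seed"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


def child_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    # hash() is salted per process for str, so use a stable digest
    digest = sum((i + 1) * b for i, b in enumerate(stage.encode())) % (2**31)
    ss = np.random.SeedSequence([root_seed, digest])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    out_dir: str = "sharedreach_run"
    scenes_per_count: int = 20
    target_counts: tuple[int, ...] = (2, 3, 4)
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    alphas: tuple[float, ...] = evaluation.DEFAULT_GRID
    betas: tuple[float, ...] = evaluation.DEFAULT_GRID
    step_scale: float = 1.5
    reach_tolerance: float = 0.02
    calibration_path: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        traj = TrajectorySpec(**raw.pop("trajectory", {}))
        cfg = cls(trajectory=traj, **raw)
        cfg.target_counts = tuple(cfg.target_counts)
        cfg.alphas = tuple(cfg.alphas)
        cfg.betas = tuple(cfg.betas)
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # tag the failing stage for the CLI
                raise PipelineError(f"[{name}] {exc}") from exc
            return out, time.perf_counter() - t0

        return wrapped

    return deco


@_stage("scenes")
def _stage_scenes(config: RunConfig, model: cal.CalibrationModel, out: Path):
    """Render the validation scene batch and run detection + localization."""
    transform = cal.FrameTransform()
    seed = child_seed(config.seed, "scenes")
    n_correct = 0
    n_total = 0
    loc_errors = []
    scene_rows = []
    localized_four: TargetSet | None = None
    scene_dir = out / "scenes"
    scene_dir.mkdir(parents=True, exist_ok=True)
    idx = 0
    for count in config.target_counts:
        for rep in range(config.scenes_per_count):
            rng = np.random.default_rng([seed, idx])
            spec = SceneSpec(
                target_positions=synthetic.sample_scene_positions(count, rng)
            )
            rgb, depth, truth = synthetic.render_scene(spec, model)
            clusters = imaging.detect_targets(rgb)
            correct = len(clusters) == count
            n_correct += correct
            n_total += 1
            err = np.nan
            if correct:
                targets = cal.localize_targets(clusters, depth, model, transform)
                truth_robot = np.array(
                    [
                        transform.R @ p + transform.translation
                        for p in truth[["x", "y", "z"]].to_numpy()
                    ]
                )
                est = targets.robot_positions
                d = np.linalg.norm(
                    est[:, None, :] - truth_robot[None, :, :], axis=2
                )
                err = float(d.min(axis=1).max())  # worst matched target
                loc_errors.append(err)
                if count == 4 and localized_four is None:
                    localized_four = targets
            scene_rows.append(
                {
                    "scene_id": idx,
                    "n_targets": count,
                    "n_detected": len(clusters),
                    "correct": bool(correct),
                    "max_localization_error_m": err,
                }
            )
            if idx < 3:  # keep a few example images as artifacts
                imaging.write_mask(
                    imaging.denoise(imaging.segment_green(rgb)),
                    scene_dir / f"scene{idx:02d}_mask.png",
                )
            idx += 1
    pd.DataFrame(scene_rows).to_csv(out / "scenes.csv", index=False)
    summary = {
        "n_scenes": n_total,
        "n_correct": n_correct,
        "accuracy_percent": 100.0 * n_correct / n_total,
        "max_localization_error_m": float(np.nanmax(loc_errors)) if loc_errors else None,
        "mean_localization_error_m": float(np.nanmean(loc_errors)) if loc_errors else None,
    }
    return summary, localized_four


@_stage("trials")
def _stage_trials(config: RunConfig, targets: TargetSet, start: JointConfig, out: Path):
    spec = TrajectorySpec(
        **{**asdict(config.trajectory), "seed": child_seed(config.seed, "trials")}
    )
    trials = synthetic.generate_trials(spec, targets, _start_position(targets, start))
    return spec, trials


def _start_position(targets: TargetSet, start: JointConfig):
    from .kinematics import forward

    return forward(start, targets.dh).position


@_stage("sweep")
def _stage_sweep(config: RunConfig, trials, targets: TargetSet, start: JointConfig, out: Path):
    result = evaluation.sweep(
        trials,
        targets,
        start,
        alphas=config.alphas,
        betas=config.betas,
        step_scale=config.step_scale,
        reach_tolerance=config.reach_tolerance,
    )
    result.table.to_csv(out / "sweep.csv", index=False)
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run report."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = (
        cal.CalibrationModel.from_json(config.calibration_path)
        if config.calibration_path
        else cal.CalibrationModel()
    )
    timings: dict[str, float] = {}

    (scene_summary, localized), timings["scenes"] = _stage_scenes(config, model, out)
    log.info("detection: %s", scene_summary)

    if localized is not None and len(localized) >= 4:
        targets = localized
        _, start = synthetic.default_target_layout()
    else:
        targets, start = synthetic.default_target_layout()
    (traj_spec, trials), timings["trials"] = _stage_trials(config, targets, start, out)

    sweep_result, timings["sweep"] = _stage_sweep(config, trials, targets, start, out)

    # Significance test at the largest (alpha, beta) cell of the grid
    amax, bmax = max(config.alphas), max(config.betas)
    params = SharedControlParams(
        alpha=amax,
        beta=bmax,
        step_scale=config.step_scale,
        reach_tolerance=config.reach_tolerance,
    )
    dec_i, dec_n, _, n_excl = evaluation.trial_decreases(trials, targets, params, start)
    t_stat, p_val = evaluation.intended_vs_nonintended_test(dec_i, dec_n)

    report = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: child_seed(config.seed, s) for s in ("scenes", "trials")},
        "detection": scene_summary,
        "trajectory_spec": asdict(traj_spec),
        "sweep": {
            "n_alphas": len(config.alphas),
            "n_betas": len(config.betas),
            "table_path": "sweep.csv",
            "n_excluded_trials": sweep_result.n_excluded,
            "max_cell": {
                "alpha": amax,
                "beta": bmax,
                "decrease_intended": float(sweep_result.cell(amax, bmax).decrease_intended),
                "decrease_nonintended": float(
                    sweep_result.cell(amax, bmax).decrease_nonintended
                ),
            },
        },
        "intended_vs_nonintended": {
            "alpha": amax,
            "beta": bmax,
            "t": t_stat,
            "p_one_tailed": p_val,
            "n_intended": int(len(dec_i)),
            "n_nonintended": int(len(dec_n)),
            "n_excluded": n_excl,
        },
        "chance_level_percent": {
            str(n): evaluation.chance_level(n) for n in config.target_counts
        },
        "timings_s": timings,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
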