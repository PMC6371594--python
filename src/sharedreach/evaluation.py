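"""Outcome metrics for shared-control reaching.

The primary outcome is the shortest distance between a trajectory and a
target — the minimum Euclidean distance from any waypoint to the target
centre — and its percent decrease under compensation relative to the raw
(uncompensated) integrated decoded trajectory:

    decrease (%) = 100 * (d_raw - d_compensated) / d_raw.

Negative values mean compensation moved the trajectory farther from the
target.  The module evaluates single trials, sweeps the blending-parameter
grid (alpha, beta) in {0.05, ..., 1.00}^2, tests intended versus
nonintended decreases with a one-tailed two-sample t-test, and computes the
chance level 100 / n_targets of reaching the instructed target at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import JointConfig, forward
from .shared_control import (
    DecodedTrajectory,
    SharedControlParams,
    TargetSet,
    run_trial,
)

__all__ = [
    "TrialResult",
    "SweepResult",
    "DegenerateSamplesError",
    "UndefinedBaselineError",
    "DEFAULT_GRID",
    "shortest_distance",
    "percent_decrease",
    "integrate_raw",
    "evaluate_trial",
    "sweep",
    "intended_vs_nonintended_test",
    "chance_level",
]

#: The (alpha, beta) sweep lattice: 0.05 to 1.00 in steps of 0.05.
DEFAULT_GRID = tuple(np.round(np.arange(1, 21) * 0.05, 2))


class UndefinedBaselineError(ValueError):
    """Raw shortest distance is zero; percent decrease is undefined."""


class DegenerateSamplesError(ValueError):
    """Both samples have zero variance; the t statistic is undefined."""


@dataclass
class TrialResult:
    """Per-trial shortest distances and percent decreases."""

    trial_id: int
    direction_label: int
    d_raw_intended: float
    d_comp_intended: float
    d_raw_nonintended: dict[int, float]
    d_comp_nonintended: dict[int, float]
    decrease_intended: float
    decrease_nonintended: dict[int, float]


@dataclass
class SweepResult:
    """Mean decreases per (alpha, beta) cell, overall and per direction.

    ``table`` has one row per cell with columns alpha, beta,
    decrease_intended, decrease_nonintended and decrease_intended_dir<d>.
    ``n_excluded`` counts trials dropped for an undefined baseline.
    """

    table: pd.DataFrame
    n_excluded: int = 0

    def cell(self, alpha: float, beta: float) -> pd.Series:
        match = self.table[
            (np.isclose(self.table.alpha, alpha)) & (np.isclose(self.table.beta, beta))
        ]
        if match.empty:
            raise KeyError(f"no sweep cell at alpha={alpha}, beta={beta}")
        return match.iloc[0]


def shortest_distance(waypoints: np.ndarray, target: np.ndarray) -> float:
    """Minimum Euclidean distance from any waypoint to the target centre."""
    waypoints = np.asarray(waypoints, dtype=float).reshape(-1, 3)
    if len(waypoints) == 0:
        raise ValueError("waypoints must be non-empty")
    return float(np.linalg.norm(waypoints - np.asarray(target, dtype=float), axis=1).min())


def percent_decrease(d_raw: float, d_comp: float) -> float:
    """100 * (d_raw - d_comp) / d_raw; negative when compensation worsened."""
    if d_raw == 0:
        raise UndefinedBaselineError("raw shortest distance is zero")
    return 100.0 * (d_raw - d_comp) / d_raw


def integrate_raw(
    trajectory: DecodedTrajectory, start_position: np.ndarray, scale: float = 1.0
) -> np.ndarray:
    """Integrate the decoded velocities from the start with no compensation.

    This is the raw baseline trajectory.  By default the velocities are
    integrated unscaled; ``scale`` applies the controller's step gain for
    the alternative baseline convention.
    """
    v = np.asarray(trajectory.velocities, dtype=float)
    return np.vstack(
        [start_position, start_position + scale * np.cumsum(v, axis=0)]
    )


def evaluate_trial(
    trajectory: DecodedTrajectory,
    targets: TargetSet,
    params: SharedControlParams,
    start: JointConfig,
    trial_id: int = 0,
    raw_scale: float = 1.0,
) -> TrialResult:
    """Run one trial and compute shortest-distance decreases for all targets."""
    start_position = forward(start, targets.dh).position
    raw = integrate_raw(trajectory, start_position, raw_scale)
    run = run_trial(trajectory, targets, params, start)

    intended_id = trajectory.true_target_id
    d_raw_i = shortest_distance(raw, targets[intended_id].position)
    d_comp_i = shortest_distance(run.waypoints, targets[intended_id].position)
    d_raw_n, d_comp_n, dec_n = {}, {}, {}
    for t in targets.targets:
        if t.id == intended_id:
            continue
        d_raw_n[t.id] = shortest_distance(raw, t.position)
        d_comp_n[t.id] = shortest_distance(run.waypoints, t.position)
        dec_n[t.id] = percent_decrease(d_raw_n[t.id], d_comp_n[t.id])
    return TrialResult(
        trial_id=trial_id,
        direction_label=trajectory.direction_label,
        d_raw_intended=d_raw_i,
        d_comp_intended=d_comp_i,
        d_raw_nonintended=d_raw_n,
        d_comp_nonintended=d_comp_n,
        decrease_intended=percent_decrease(d_raw_i, d_comp_i),
        decrease_nonintended=dec_n,
    )


def trial_decreases(
    trials: list[DecodedTrajectory],
    targets: TargetSet,
    params: SharedControlParams,
    start: JointConfig,
    raw_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, list[TrialResult], int]:
    """Evaluate an ensemble at one parameter setting.

    Returns (intended decreases, nonintended decreases pooled over targets,
    per-trial results, number of trials excluded for undefined baselines).
    """
    intended, nonintended, results = [], [], []
    n_excluded = 0
    for i, tr in enumerate(trials):
        try:
            res = evaluate_trial(tr, targets, params, start, trial_id=i, raw_scale=raw_scale)
        except UndefinedBaselineError:
            n_excluded += 1
            continue
        results.append(res)
        intended.append(res.decrease_intended)
        nonintended.extend(res.decrease_nonintended.values())
    return np.asarray(intended), np.asarray(nonintended), results, n_excluded


def sweep(
    trials: list[DecodedTrajectory],
    targets: TargetSet,
    start: JointConfig,
    alphas=DEFAULT_GRID,
    betas=DEFAULT_GRID,
    step_scale: float = 1.5,
    reach_tolerance: float = 0.02,
    raw_scale: float = 1.0,
) -> SweepResult:
    """Evaluate the trial ensemble over the (alpha, beta) lattice.

    Each cell runs every trial with identical start and parameters and
    records the mean intended and (pooled) nonintended percent decreases,
    overall and per reaching direction.
    """
    if not trials:
        raise ValueError("trials must be non-empty")
    directions = sorted({t.direction_label for t in trials})
    rows = []
    total_excluded = 0
    for alpha in alphas:
        for beta in betas:
            params = SharedControlParams(
                alpha=float(alpha),
                beta=float(beta),
                step_scale=step_scale,
                reach_tolerance=reach_tolerance,
            )
            dec_i, dec_n, results, n_excl = trial_decreases(
                trials, targets, params, start, raw_scale
            )
            total_excluded += n_excl
            row = {
                "alpha": float(alpha),
                "beta": float(beta),
                "decrease_intended": float(dec_i.mean()) if len(dec_i) else np.nan,
                "decrease_nonintended": float(dec_n.mean()) if len(dec_n) else np.nan,
            }
            for d in directions:
                vals = [r.decrease_intended for r in results if r.direction_label == d]
                row[f"decrease_intended_dir{d}"] = float(np.mean(vals)) if vals else np.nan
            rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), n_excluded=total_excluded)


def intended_vs_nonintended_test(
    decreases_intended: np.ndarray,
    decreases_nonintended: np.ndarray,
    welch: bool = False,
) -> tuple[float, float]:
    """One-tailed two-sample t-test of 'intended decrease > nonintended decrease'.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    a = np.asarray(decreases_intended, dtype=float)
    b = np.asarray(decreases_nonintended, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least two observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        raise DegenerateSamplesError("both samples have zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=not welch, alternative="greater")
    return float(t), float(p)


def chance_level(n_targets: int) -> float:
    """Chance success rate (%) of reaching the instructed target: 100 / n."""
    if n_targets < 1:
        raise ValueError("n_targets must be at least 1")
    return 100.0 / n_targets
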