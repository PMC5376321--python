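"""Identification of free plant/controller parameters from step-response targets.

The rig's firmware constants (PID gains, gating logic) and some physical
characteristics (sensor response time, effective mixing volume, small-valve
flow) are not directly observable, so they are fitted so that the simulated
21% -> hypoxic step jointly reproduces a target set of transient metrics.
The objective is the weighted sum of squared *relative* residuals of the four
metrics, making seconds and percentage points commensurable; the search is a
multi-start Nelder-Mead simplex (derivative-free: the gating latch makes the
objective piecewise smooth at best).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .config import RunConfig
from .errors import ValidationError
from .metrics import TransientMetrics, compute_metrics
from .simulate import step_response

#: Objective contribution of a missing (NaN) metric: large enough to dominate
#: any plausible relative residual, finite so the simplex can climb out.
MISSING_METRIC_PENALTY = 25.0

METRIC_NAMES = ("time_to_target_s", "settle_time_s",
                "undershoot_duration_s", "undershoot_nadir_pct")


@dataclass
class CalibrationResult:
    """Best parameter set found plus per-metric diagnostics."""

    parameters: dict[str, float]
    objective: float
    residuals: dict[str, float]
    metrics: TransientMetrics
    converged: bool
    n_evals: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "objective": self.objective,
            "residuals": self.residuals,
            "metrics": self.metrics.as_dict(),
            "converged": self.converged,
            "n_evals": self.n_evals,
            "warnings": self.warnings,
        }


def _targets_from_config(config: RunConfig) -> TransientMetrics:
    c = config.calibration
    return TransientMetrics(c.target_time_to_target_s, c.target_settle_time_s,
                            c.target_undershoot_duration_s, c.target_undershoot_nadir_pct)


def _weights_from_config(config: RunConfig) -> dict[str, float]:
    c = config.calibration
    return {
        "time_to_target_s": c.weight_time_to_target,
        "settle_time_s": c.weight_settle_time,
        "undershoot_duration_s": c.weight_undershoot_duration,
        "undershoot_nadir_pct": c.weight_undershoot_nadir,
    }


def residuals_for(metrics: TransientMetrics, targets: TransientMetrics) -> dict[str, float]:
    """Per-metric relative residuals (NaN metric -> NaN residual)."""
    out = {}
    m, g = metrics.as_dict(), targets.as_dict()
    for name in METRIC_NAMES:
        tgt = g[name]
        val = m[name]
        denom = tgt if tgt != 0.0 else 1.0  # absolute residual for a zero target
        out[name] = (val - tgt) / denom if not math.isnan(val) else float("nan")
    return out


def objective_for(
    metrics: TransientMetrics, targets: TransientMetrics, weights: dict[str, float]
) -> float:
    res = residuals_for(metrics, targets)
    total = 0.0
    for name in METRIC_NAMES:
        w = weights.get(name, 1.0)
        r = res[name]
        total += w * (MISSING_METRIC_PENALTY if math.isnan(r) else r * r)
    return total


def calibrate(
    config: RunConfig,
    targets: TransientMetrics | None = None,
    parameters: dict[str, tuple[float, float]] | None = None,
    weights: dict[str, float] | None = None,
    seed: int = 0,
    n_starts: int | None = None,
    max_evals_per_start: int | None = None,
) -> CalibrationResult:
    """Fit free parameters so the simulated step reproduces the target metrics.

    ``parameters`` maps flat config paths (``"section.key"``) to (lower,
    upper) bounds; defaults come from the config's calibration section, as do
    targets and weights.  Deterministic given ``seed``: start points and the
    sensor-noise stream are drawn from it.  The best point found is always
    returned, with ``converged=False`` if no start terminated successfully.
    """
    cal = config.calibration
    if targets is None:
        targets = _targets_from_config(config)
    if parameters is None:
        parameters = {k: tuple(v) for k, v in cal.parameters.items()}
    if not parameters:
        raise ValidationError("calibration.parameters", "no free parameters given")
    if weights is None:
        weights = _weights_from_config(config)
    n_starts = cal.n_starts if n_starts is None else n_starts
    max_evals = cal.max_evals_per_start if max_evals_per_start is None else max_evals_per_start

    names = list(parameters)
    lo = np.array([parameters[k][0] for k in names], dtype=float)
    hi = np.array([parameters[k][1] for k in names], dtype=float)
    if np.any(lo > hi):
        raise ValidationError("calibration.parameters", "lower bound exceeds upper bound")

    warns: list[str] = []
    if all(weights.get(n, 1.0) == 0.0 for n in METRIC_NAMES):
        warns.append("all metric weights are zero: objective is identically 0")
        metrics = _eval_metrics(config, dict(zip(names, config_values(config, names))), seed)
        return CalibrationResult(
            parameters=dict(zip(names, config_values(config, names))),
            objective=0.0, residuals=residuals_for(metrics, targets),
            metrics=metrics, converged=True, n_evals=1, warnings=warns)

    rng = np.random.default_rng(seed)
    sim_seed = seed  # sensor-noise stream fixed across evaluations
    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        x = np.minimum(np.maximum(x, lo), hi)
        metrics = _eval_metrics(config, dict(zip(names, x)), sim_seed)
        return objective_for(metrics, targets, weights)

    # start points: current config values first, then seeded uniform draws
    starts = [np.minimum(np.maximum(config_values(config, names), lo), hi)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    best_x, best_f, converged = None, math.inf, False
    for x0 in starts:
        x_cur = np.asarray(x0, dtype=float)
        # two chained simplex runs per start: the fresh simplex of the second
        # run escapes the plateaus the tick-quantized metrics produce
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # NM emits maxfev warnings
                res = minimize(objective, x_cur, method="Nelder-Mead",
                               bounds=list(zip(lo, hi)),
                               options={"maxfev": max_evals, "xatol": 1e-4,
                                        "fatol": 1e-6})
            x_cur = np.minimum(np.maximum(res.x, lo), hi)
            if res.fun < best_f:
                best_x, best_f = x_cur.copy(), float(res.fun)
                converged = converged or bool(res.success)

    params = dict(zip(names, (float(v) for v in best_x)))
    metrics = _eval_metrics(config, params, sim_seed)
    return CalibrationResult(
        parameters=params,
        objective=best_f,
        residuals=residuals_for(metrics, targets),
        metrics=metrics,
        converged=converged,
        n_evals=n_evals,
        warnings=warns,
    )


def parameter_recovery_experiment(
    config: RunConfig,
    seed: int,
    relative_perturbation: float = 0.05,
    max_evals: int = 200,
) -> tuple[TransientMetrics, TransientMetrics, dict[str, float]]:
    """Self-consistency check: can calibration recover a known twin?

    Draws a "true" parameter set uniformly within the configured bounds
    (redrawing if the resulting transient lacks one of the four features),
    measures its step-response metrics, then calibrates against those metrics
    starting from a multiplicatively perturbed point.  Returns (target
    metrics, recovered metrics, relative residuals).
    """
    cal = config.calibration
    bounds = {k: tuple(v) for k, v in cal.parameters.items()}
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    rng = np.random.default_rng(seed)
    sim_seed = int(rng.integers(0, 2**31 - 1))  # shared by target and objective runs

    truth = None
    for _ in range(20):
        x = lo + rng.random(len(names)) * (hi - lo)
        m = _eval_metrics(config, dict(zip(names, x)), sim_seed)
        if (not any(math.isnan(v) for v in m.as_dict().values())
                and m.undershoot_duration_s > 0.0):
            truth, targets = x, m
            break
    if truth is None:
        raise ValidationError("calibration.parameters",
                              "could not draw a feature-complete parameter set")

    start = np.minimum(np.maximum(
        truth * (1.0 + relative_perturbation * (2.0 * rng.random(len(names)) - 1.0)),
        lo), hi)
    start_config = config.replace(dict(zip(names, (float(v) for v in start))))
    result = calibrate(start_config, targets=targets, parameters=bounds,
                       seed=sim_seed, n_starts=1, max_evals_per_start=max_evals)
    return targets, result.metrics, result.residuals


def config_values(config: RunConfig, names: list[str]) -> np.ndarray:
    return np.array([config.get(n) for n in names], dtype=float)


def _eval_metrics(config: RunConfig, params: dict[str, float], seed: int) -> TransientMetrics:
    cfg = config.replace({k: float(v) for k, v in params.items()})
    cal = cfg.calibration
    sim = step_response(cfg, duration_s=cal.sim_duration_s, seed=seed)
    return compute_metrics(sim, cfg.protocol.level_1_pct, cal.metrics_band_pct)
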