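"""Steady-state calibration: bisection on the replication rate and the
feedback scaling law.

The TD-to-stem ratio at steady state is governed by the balance of
replication and death and rises monotonically with the baseline replication
rate ``lam_P_hat``; ``calibrate_replication`` exploits that with a bisection.
The absolute steady sizes then follow from the scaling law: multiplying all
Hill regulation constants ``k_i`` by a factor ``A`` maps the steady totals to
``(Pbar*/A, Wbar*/A)`` while leaving the ratio unchanged (the Hill arguments
``k_i' * (Xbar/A) = k_i * Xbar`` are invariant and the dynamics are linear in
the densities).  ``two_step_control`` chains the two: first pin the ratio
(default 7) via ``lam_P_hat``, then rescale the ``k_i`` so the steady TD
total hits its target (default 10), and re-verify with one final steady run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fv_solver import run_to_steady
from .model_core import FeedbackParams, Grid, ModelParams

__all__ = ["CalibrationResult", "rescale_feedback", "calibrate_replication", "two_step_control"]

DEFAULT_BRACKET = (0.6785, 1.1377)


@dataclass
class CalibrationResult:
    """Outcome of the two-step control strategy."""

    lam_P_hat: float
    scale: float
    params: ModelParams
    achieved_ratio: float
    achieved_W: float
    converged: bool
    iterations: int = 0
    history: list[tuple[float, float]] = field(default_factory=list)  # (lam_P, ratio)


def rescale_feedback(params: FeedbackParams, factor: float) -> FeedbackParams:
    """Multiply all regulation constants ``k_i`` by ``factor`` (scaling law)."""
    return params.scaled(factor)


def _steady_totals(
    params: ModelParams,
    grid: Grid,
    initial: tuple[np.ndarray, np.ndarray],
    steady_tol: float,
    t_max: float,
    dt: float | None,
) -> tuple[float, float, bool]:
    state, converged, _ = run_to_steady(params, grid, initial, tol=steady_tol, t_max=t_max, dt=dt)
    P_bar, W_bar = state.totals
    return P_bar, W_bar, converged


def calibrate_replication(
    params: ModelParams,
    grid: Grid,
    initial: tuple[np.ndarray, np.ndarray],
    target_ratio: float = 7.0,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    rel_tol: float = 1e-2,
    max_iter: int = 40,
    steady_tol: float = 1e-6,
    t_max: float = 400.0,
    dt: float | None = None,
) -> CalibrationResult:
    """Bisection on ``lam_P_hat`` until the simulated steady ratio hits the target.

    Each evaluation is a full steady-state run of the structured PDE.  The
    bracket endpoints must straddle the target ratio; the bisection stops
    when ``|ratio - target| / target < rel_tol``.
    """
    lo, hi = bracket
    if not hi > lo:
        raise ValueError(f"bracket ({lo}, {hi}) is empty")

    def ratio_at(lam: float) -> tuple[float, float, float]:
        p = replace(params, feedback=replace(params.feedback, lam_P_hat=lam))
        P_bar, W_bar, _ = _steady_totals(p, grid, initial, steady_tol, t_max, dt)
        if not P_bar > 0:
            raise RuntimeError(f"stem pool died out at lam_P_hat = {lam}; ratio undefined")
        return W_bar / P_bar, P_bar, W_bar

    history: list[tuple[float, float]] = []
    r_lo, *_ = ratio_at(lo)
    r_hi, *_ = ratio_at(hi)
    history += [(lo, r_lo), (hi, r_hi)]
    if not (min(r_lo, r_hi) <= target_ratio <= max(r_lo, r_hi)):
        raise ValueError(
            f"bracket does not straddle the target ratio {target_ratio}: "
            f"ratio({lo}) = {r_lo:.4f}, ratio({hi}) = {r_hi:.4f}"
        )
    increasing = r_hi > r_lo

    lam = 0.5 * (lo + hi)
    ratio = r_lo
    P_bar = W_bar = float("nan")
    it = 0
    for it in range(1, max_iter + 1):
        lam = 0.5 * (lo + hi)
        ratio, P_bar, W_bar = ratio_at(lam)
        history.append((lam, ratio))
        if abs(ratio - target_ratio) / target_ratio < rel_tol:
            break
        if (ratio < target_ratio) == increasing:
            lo = lam
        else:
            hi = lam
    calibrated = replace(params, feedback=replace(params.feedback, lam_P_hat=lam))
    return CalibrationResult(
        lam_P_hat=lam,
        scale=1.0,
        params=calibrated,
        achieved_ratio=ratio,
        achieved_W=W_bar,
        converged=abs(ratio - target_ratio) / target_ratio < rel_tol,
        iterations=it,
        history=history,
    )


def two_step_control(
    params: ModelParams,
    grid: Grid,
    initial: tuple[np.ndarray, np.ndarray],
    target_ratio: float = 7.0,
    target_W: float = 10.0,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    rel_tol: float = 1e-2,
    steady_tol: float = 1e-6,
    t_max: float = 400.0,
    dt: float | None = None,
) -> CalibrationResult:
    """Pin the steady ratio via ``lam_P_hat``, then the steady TD total via the
    ``k``-scaling law; re-verify with one final steady run."""
    step1 = calibrate_replication(
        params,
        grid,
        initial,
        target_ratio=target_ratio,
        bracket=bracket,
        rel_tol=rel_tol,
        steady_tol=steady_tol,
        t_max=t_max,
        dt=dt,
    )
    if not step1.achieved_W > 0:
        raise RuntimeError("steady TD total is zero after ratio calibration; size targeting infeasible")
    fb = step1.params.feedback
    if fb.k1 == fb.k2 == fb.k3 == fb.k4 == 0.0:
        raise RuntimeError("all feedback constants are zero: the steady size is not set by feedback, size targeting infeasible")
    scale = step1.achieved_W / target_W
    scaled = replace(step1.params, feedback=rescale_feedback(fb, scale))
    P_bar, W_bar, converged = _steady_totals(scaled, grid, initial, steady_tol, t_max, dt)
    return CalibrationResult(
        lam_P_hat=step1.lam_P_hat,
        scale=scale,
        params=scaled,
        achieved_ratio=W_bar / P_bar if P_bar > 0 else float("nan"),
        achieved_W=W_bar,
        converged=converged and step1.converged,
        iterations=step1.iterations,
        history=step1.history,
    )
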