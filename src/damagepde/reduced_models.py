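"""Reduced comparators: no-partition transport model, total-count ODEs,
stem-attrition and quiescence extensions, and their stability thresholds.

Integrating the structured PDE over damage collapses it to a planar linear
ODE system for the totals ``(Pbar, Wbar)`` with renewal fraction
``f = (1 + p1 - p2) / 2`` (equivalently ``(2 p1 + p3) / 2``).  The
no-partition transport model keeps the damage structure but replaces the
nonlocal division kernels with local reactions; it shares the totals
dynamics exactly while its damage distributions drift without bound.

The attrition extension adds a constant stem death rate ``delta_P``; the
quiescence extension adds a dormant stem pool (entry ``s_P``, reactivation
``r_Q``, dormant death ``delta_Q``) and is reduced to the planar system by a
quasi-steady approximation of the dormant pool.  Stability of the trivial
equilibrium follows Routh-Hurwitz (trace < 0, determinant > 0); the
determinant changes sign at the critical renewal fraction ``f_crit``, and
quiescence shifts it upward by a surcharge ``delta_f``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fv_solver import SimState, Trajectory, _upwind, choose_timestep
from .model_core import Grid, ModelParams, effective_rates

__all__ = [
    "TotalsParams",
    "StabilityReport",
    "totals_rhs",
    "simulate_totals",
    "simulate_no_partition",
    "linear_stability",
    "critical_renewal_attrition",
    "attrition_steady_ratio",
    "quiescence_delta_f",
]


@dataclass(frozen=True)
class TotalsParams:
    """Constant-rate parameters of the planar totals ODE system.

    ``f_convention`` records which identity produced the renewal fraction
    ("p1p2" for ``(1 + p1 - p2)/2``, "p1p3" for ``(2 p1 + p3)/2``); with
    ``p3 = 1 - p1 - p2`` the two coincide.
    """

    f: float
    lam_P: float
    lam_R: float = 0.0
    delta_W: float = 0.0
    delta_P: float = 0.0
    s_P: float = 0.0
    r_Q: float = 0.0
    delta_Q: float = 0.0
    f_convention: str = "p1p2"

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"renewal fraction must lie in [0, 1], got {self.f}")
        for name in ("lam_P", "lam_R", "delta_W", "delta_P", "s_P", "r_Q", "delta_Q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class StabilityReport:
    """Jacobian of the planar totals system and Routh-Hurwitz verdict."""

    a: float
    b: float
    c: float
    d: float
    f_crit: float | None = None
    delta_f: float | None = None

    @property
    def trace(self) -> float:
        return self.a + self.d

    @property
    def det(self) -> float:
        return self.a * self.d - self.b * self.c

    @property
    def stable(self) -> bool:
        return self.trace < 0 and self.det > 0


def totals_rhs(P_bar: float, W_bar: float, params: TotalsParams) -> tuple[float, float]:
    """Right-hand side of the totals ODEs with constant TD death rate.

    ``dPbar/dt = (2f - 1) lam_P Pbar + lam_R Wbar - delta_P Pbar`` and
    ``dWbar/dt = (2 - 2f) lam_P Pbar - (lam_R + delta_W) Wbar``.
    """
    if P_bar < 0 or W_bar < 0:
        raise ValueError("totals must be nonnegative")
    dP = (2.0 * params.f - 1.0) * params.lam_P * P_bar + params.lam_R * W_bar - params.delta_P * P_bar
    dW = (2.0 - 2.0 * params.f) * params.lam_P * P_bar - (params.lam_R + params.delta_W) * W_bar
    return dP, dW


def simulate_totals(
    params: TotalsParams,
    initial: tuple[float, float],
    t_end: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-Euler integration of the totals ODEs (same stepper as the PDE,
    so trajectory comparisons are apples-to-apples discrete statements)."""
    n = int(round(t_end / dt))
    times = dt * np.arange(n + 1)
    P = np.empty(n + 1)
    W = np.empty(n + 1)
    P[0], W[0] = initial
    for i in range(n):
        dP, dW = totals_rhs(P[i], W[i], params)
        P[i + 1] = P[i] + dt * dP
        W[i + 1] = W[i] + dt * dW
    return times, P, W


def simulate_no_partition(
    params: ModelParams,
    grid: Grid,
    initial: tuple[np.ndarray, np.ndarray],
    t_end: float,
    dt: float | None = None,
    snapshot_times: Sequence[float] = (),
) -> Trajectory:
    """Integrate the local advection-reaction comparator (no damage remapping).

    Reactions act pointwise: ``(2f - 1) lam_P P + lam_R W`` feeds the stem
    density and ``(2 - 2f) lam_P P - (lam_R + delta(x)) W`` the TD density,
    with the feedback-regulated ``f``, ``lam_P`` and ``lam_R`` evaluated at
    the current totals.  Totals obey the same planar ODEs as the partitioned
    model; the damage distributions, however, drift rightward without bound.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    dt = choose_timestep(params, grid, dt)
    state = SimState(t=0.0, P=np.array(initial[0], dtype=float), W=np.array(initial[1], dtype=float), grid=grid)
    delta_x = params.death.rate(grid.nodes)

    n_steps = int(round(t_end / dt)) if abs(round(t_end / dt) * dt - t_end) < 1e-9 * max(t_end, dt) else int(np.ceil(t_end / dt - 1e-12))
    times = [0.0]
    P_bar = [grid.mass(state.P)]
    W_bar = [grid.mass(state.W)]
    clamped = [0.0]
    pending = sorted(float(t) for t in snapshot_times)
    snapshots: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    for _ in range(n_steps):
        rates = effective_rates(state.totals, params.feedback)
        f = 0.5 * (1.0 + rates.p1 - rates.p2)
        dP = _upwind(state.P, params.v_P, params.inflow, grid)
        dP += (2.0 * f - 1.0) * rates.lam_P * state.P + rates.lam_R * state.W - params.delta_P * state.P
        dW = _upwind(state.W, params.v_W, params.inflow, grid)
        dW += (2.0 - 2.0 * f) * rates.lam_P * state.P - (rates.lam_R + delta_x) * state.W
        P_new = np.maximum(state.P + dt * dP, 0.0)
        W_new = np.maximum(state.W + dt * dW, 0.0)
        state = SimState(t=state.t + dt, P=P_new, W=W_new, grid=grid)
        times.append(state.t)
        P_bar.append(grid.mass(state.P))
        W_bar.append(grid.mass(state.W))
        clamped.append(0.0)
        while pending and state.t >= pending[0] - 1e-9:
            snapshots[pending.pop(0)] = (state.P.copy(), state.W.copy())

    traj = Trajectory(
        times=np.asarray(times),
        P_bar=np.asarray(P_bar),
        W_bar=np.asarray(W_bar),
        clamped=np.asarray(clamped),
        grid=grid,
        snapshots=snapshots,
    )
    traj.final_state = state  # type: ignore[attr-defined]
    return traj


def linear_stability(params: TotalsParams) -> StabilityReport:
    """Jacobian entries and Routh-Hurwitz stability of the trivial equilibrium.

    ``a = (2f - 1) lam_P - delta_P``, ``b = lam_R``, ``c = 2 (1 - f) lam_P``,
    ``d = -(lam_R + delta_W)``.  When the attrition threshold is defined
    (``delta_W > 0`` and ``lam_P > 0``) the report carries ``f_crit``; when
    quiescence rates are set it also carries the surcharge ``delta_f``.
    """
    a = (2.0 * params.f - 1.0) * params.lam_P - params.delta_P
    b = params.lam_R
    c = 2.0 * (1.0 - params.f) * params.lam_P
    d = -(params.lam_R + params.delta_W)
    f_crit = None
    if params.delta_W > 0 and params.lam_P > 0:
        f_crit = critical_renewal_attrition(params.delta_P, params.delta_W, params.lam_P, params.lam_R)
    delta_f = None
    if params.s_P > 0 or params.delta_Q > 0 or params.r_Q > 0:
        delta_f = quiescence_delta_f(params.s_P, params.r_Q, params.delta_Q, params.lam_P, params.delta_W, params.lam_R)
    return StabilityReport(a=a, b=b, c=c, d=d, f_crit=f_crit, delta_f=delta_f)


def critical_renewal_attrition(delta_P: float, delta_W: float, lam_P: float, lam_R: float) -> float:
    """Renewal fraction at which the totals Jacobian determinant vanishes.

    ``f_crit = (delta_P delta_W + delta_P lam_R + delta_W lam_P
    - lam_P lam_R) / (2 delta_W lam_P)``; at ``delta_P = 0`` this reduces to
    ``(delta_W - lam_R) / (2 delta_W)``.
    """
    if not delta_W > 0:
        raise ValueError("delta_W must be positive")
    if not lam_P > 0:
        raise ValueError("lam_P must be positive")
    return (delta_P * delta_W + delta_P * lam_R + delta_W * lam_P - lam_P * lam_R) / (2.0 * delta_W * lam_P)


def attrition_steady_ratio(delta_P: float, delta_W: float, lam_P: float) -> float:
    """Steady stem-to-TD ratio ``Pbar*/Wbar* = delta_W / (lam_P - delta_P)``."""
    if not lam_P > delta_P:
        raise ValueError("no positive steady ratio: requires lam_P > delta_P")
    return delta_W / (lam_P - delta_P)


def quiescence_delta_f(s_P: float, r_Q: float, delta_Q: float, lam_P: float, delta_W: float, lam_R: float) -> float:
    """Self-renewal surcharge from a leaky quiescent pool.

    ``delta_f = s_P delta_Q / (r_Q + delta_Q) * (lam_R + delta_W) /
    (2 lam_P delta_W)``: the extra renewal needed to offset stem cells that
    enter dormancy and die (rate ``delta_Q``) before reactivating (rate
    ``r_Q``).  Zero when dormant cells never die; decreasing in the
    reactivation rate.
    """
    if not (r_Q + delta_Q) > 0:
        raise ValueError("r_Q + delta_Q must be positive")
    if not lam_P > 0 or not delta_W > 0:
        raise ValueError("lam_P and delta_W must be positive")
    return s_P * delta_Q / (r_Q + delta_Q) * (lam_R + delta_W) / (2.0 * lam_P * delta_W)
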