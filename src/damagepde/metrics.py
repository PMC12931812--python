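"""Damage-distribution summary statistics and the overshoot fraction.

Per compartment: the mass-weighted mean damage, the damage at the density
peak (mode), and the rightmost support (largest damage with density above a
small relative floor).  Across a trajectory: the overshoot fraction ``R``,
the maximal relative excess of the transient TD-to-stem ratio above its
anchor steady value (7 in the calibrated scenarios), clamped at zero when
the ratio never exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import Grid

__all__ = [
    "DamageMetrics",
    "mean_damage",
    "mode_and_support",
    "overshoot_fraction",
    "linear_fit_mean",
    "damage_metrics",
]

DEFAULT_SUPPORT_FLOOR = 1e-8
STEADY_RATIO_ANCHOR = 7.0


@dataclass(frozen=True)
class DamageMetrics:
    mean_P: float
    mode_P: float
    support_P: float
    mean_W: float
    mode_W: float
    support_W: float
    overshoot: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "mean_P": self.mean_P,
            "mode_P": self.mode_P,
            "support_P": self.support_P,
            "mean_W": self.mean_W,
            "mode_W": self.mode_W,
            "support_W": self.support_W,
        }
        if self.overshoot is not None:
            d["R"] = self.overshoot
        return d


def mean_damage(u: np.ndarray, grid: Grid) -> float:
    """Mass-weighted mean damage ``sum(x_i u_i) / sum(u_i)``."""
    u = grid.conform(u)
    total = u.sum()
    if not total > 0:
        raise ValueError("mean damage undefined for zero total mass")
    return float((grid.nodes * u).sum() / total)


def mode_and_support(u: np.ndarray, grid: Grid, rel_floor: float = DEFAULT_SUPPORT_FLOOR) -> tuple[float, float]:
    """Damage at the density peak and the rightmost supported damage.

    The mode takes the smallest damage on ties.  Support uses a relative
    floor (``u_i > rel_floor * max(u)``) because strict positivity is
    meaningless in floating point.
    """
    u = grid.conform(u)
    peak = u.max()
    if not peak > 0:
        raise ValueError("mode/support undefined for a nonpositive density")
    mode = float(grid.nodes[int(np.argmax(u))])
    above = np.nonzero(u > rel_floor * peak)[0]
    support = float(grid.nodes[above[-1]])
    return mode, support


def overshoot_fraction(ratio_series: np.ndarray, steady_ratio: float = STEADY_RATIO_ANCHOR) -> float:
    """``R = max(0, max_t ratio - steady) / steady``; 0 if never exceeded."""
    ratio_series = np.asarray(ratio_series, dtype=float)
    if ratio_series.size == 0:
        raise ValueError("ratio series is empty")
    if not steady_ratio > 0:
        raise ValueError("steady ratio must be positive")
    peak = np.nanmax(ratio_series)
    return float(max(0.0, peak - steady_ratio) / steady_ratio)


def linear_fit_mean(times: np.ndarray, means: np.ndarray, window: tuple[float, float] | None = None) -> tuple[float, float, float]:
    """Ordinary least-squares line through ``means(t)``; returns (slope, intercept, R^2)."""
    times = np.asarray(times, dtype=float)
    means = np.asarray(means, dtype=float)
    if window is not None:
        keep = (times >= window[0]) & (times <= window[1])
        times, means = times[keep], means[keep]
    if times.size < 3:
        raise ValueError("need at least 3 points for a least-squares fit")
    if np.ptp(times) == 0:
        raise ValueError("degenerate fit: constant time values")
    slope, intercept = np.polyfit(times, means, 1)
    resid = means - (slope * times + intercept)
    ss_tot = float(((means - means.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return float(slope), float(intercept), r2


def damage_metrics(
    P: np.ndarray,
    W: np.ndarray,
    grid: Grid,
    ratio_series: np.ndarray | None = None,
    steady_ratio: float = STEADY_RATIO_ANCHOR,
    rel_floor: float = DEFAULT_SUPPORT_FLOOR,
) -> DamageMetrics:
    """Bundle the per-compartment metrics (and ``R`` when a ratio series is given)."""
    mode_P, support_P = mode_and_support(P, grid, rel_floor)
    mode_W, support_W = mode_and_support(W, grid, rel_floor)
    R = None if ratio_series is None else overshoot_fraction(ratio_series, steady_ratio)
    return DamageMetrics(
        mean_P=mean_damage(P, grid),
        mode_P=mode_P,
        support_P=support_P,
        mean_W=mean_damage(W, grid),
        mode_W=mode_W,
        support_W=support_W,
        overshoot=R,
    )
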