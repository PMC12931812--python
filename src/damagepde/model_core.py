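"""Domain types and elementary operations for the damage-structured lineage model.

The model tracks two cell populations structured by a continuous damage
variable ``x``: a stem-like pool ``P(t, x)`` and a terminally differentiated
(TD) pool ``W(t, x)``.  Damage advects rightward at constant speeds, stem
divisions redistribute damage between daughters through delta-function
partition kernels, and Hill-type feedback couples the division probabilities
and rates to the total population sizes.

This module holds the value types (grid, partition fractions, feedback
parameters, death model, dedifferentiation rule, full parameter set) and the
scalar operations built on them: grid construction, the CFL timestep bound,
Hill regulation, effective rates, and the damage-dependent death rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, NamedTuple

import numpy as np

__all__ = [
    "Grid",
    "PartitionFractions",
    "FeedbackParams",
    "DeathModel",
    "DediffRule",
    "ModelParams",
    "EffectiveRates",
    "make_grid",
    "cfl_timestep",
    "hill_regulation",
    "effective_rates",
    "death_rate",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class Grid:
    """Uniform node-collocated grid on the truncated damage domain ``[0, A]``.

    Densities live on the ``N + 1`` nodes ``x_i = i * dx``; the mass of a
    density vector ``u`` is the rectangle sum ``dx * sum(u)``.
    """

    domain_length: float
    num_cells: int

    def __post_init__(self) -> None:
        if not (self.domain_length > 0):
            raise ValueError(f"domain_length must be positive, got {self.domain_length}")
        if int(self.num_cells) != self.num_cells or self.num_cells < 2:
            raise ValueError(f"num_cells must be an integer >= 2, got {self.num_cells}")

    @property
    def dx(self) -> float:
        return self.domain_length / self.num_cells

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(0.0, self.domain_length, self.num_cells + 1)

    @property
    def size(self) -> int:
        """Length of a conforming density vector (number of nodes)."""
        return self.num_cells + 1

    def mass(self, u: np.ndarray) -> float:
        """Rectangle-rule total mass ``dx * sum(u)``."""
        u = self.conform(u)
        return float(self.dx * u.sum())

    def first_moment(self, u: np.ndarray) -> float:
        """Rectangle-rule damage first moment ``dx * sum(x_i * u_i)``."""
        u = self.conform(u)
        return float(self.dx * (self.nodes * u).sum())

    def conform(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if u.shape != (self.size,):
            raise ValueError(f"density vector of shape {u.shape} does not conform to grid with {self.size} nodes")
        return u

    def indicator(self, lo: float, hi: float, height: float = 1.0) -> np.ndarray:
        """Cell-averaged indicator ``height * chi_[lo, hi]``.

        Each node carries the average of the indicator over its dual cell
        ``[x_i - dx/2, x_i + dx/2]``, so the rectangle-rule mass equals the
        continuum mass ``height * (hi - lo)`` exactly whenever the interval
        lies inside the domain.
        """
        if not (0.0 <= lo < hi):
            raise ValueError(f"invalid interval [{lo}, {hi}]")
        x = self.nodes
        left = np.clip(x - 0.5 * self.dx, lo, hi)
        right = np.clip(x + 0.5 * self.dx, lo, hi)
        return height * (right - left) / self.dx

    def gaussian(self, amplitude: float, center: float, width: float) -> np.ndarray:
        """Gaussian profile ``amplitude * exp(-(x - center)^2 / (2 width^2))`` sampled at nodes."""
        x = self.nodes
        return amplitude * np.exp(-((x - center) ** 2) / (2.0 * width**2))


def make_grid(domain_length: float, num_cells: int) -> Grid:
    """Build a uniform grid with ``num_cells`` cells on ``[0, domain_length]``."""
    return Grid(domain_length=float(domain_length), num_cells=int(num_cells))


@dataclass(frozen=True)
class PartitionFractions:
    """Damage fractions inherited by daughters in the three division modes.

    ``alpha``: symmetric self-renewal (P -> P + P), ``beta``: symmetric
    differentiation (P -> W + W), ``gamma``: asymmetric division (P -> P + W,
    stem daughter receives ``gamma1``).  Each pair sums to one so that every
    division conserves total damage.
    """

    alpha1: float = 0.5
    alpha2: float = 0.5
    beta1: float = 0.5
    beta2: float = 0.5
    gamma1: float = 1.0 / 3.0
    gamma2: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        for name1, name2 in (("alpha1", "alpha2"), ("beta1", "beta2"), ("gamma1", "gamma2")):
            a, b = getattr(self, name1), getattr(self, name2)
            if not (0.0 < a < 1.0 and 0.0 < b < 1.0):
                raise ValueError(f"{name1}={a}, {name2}={b} must lie in (0, 1)")
            if abs(a + b - 1.0) > _SUM_TOL:
                raise ValueError(f"{name1} + {name2} must equal 1, got {a + b}")

    @classmethod
    def from_first(cls, alpha1: float = 0.5, beta1: float = 0.5, gamma1: float = 1.0 / 3.0) -> "PartitionFractions":
        return cls(alpha1, 1.0 - alpha1, beta1, 1.0 - beta1, gamma1, 1.0 - gamma1)


@dataclass(frozen=True)
class FeedbackParams:
    """Baselines and Hill-regulation constants for division and transition rates.

    The baselines ``p1_hat``, ``p2_hat`` (division probabilities),
    ``lam_P_hat`` (stem replication rate) and ``lam_R_hat`` (dedifferentiation
    rate) apply in the absence of feedback.  Each is divided by
    ``1 + (k_i * signal)^m_i`` at runtime, where the signal is the total TD
    mass for ``p1``, ``p2``, ``lam_P`` and the total stem mass for ``lam_R``.

    ``p1_hat + p2_hat <= 1`` is required at construction; since Hill
    regulation only decreases ``p1`` and ``p2``, the asymmetric-division
    probability ``p3 = 1 - p1 - p2`` then stays nonnegative at runtime.
    """

    p1_hat: float = 0.5
    p2_hat: float = 0.5
    lam_P_hat: float = 1.0
    lam_R_hat: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    m1: float = 2.0
    m2: float = 2.0
    m3: float = 2.0
    m4: float = 2.0
    # runtime p2 = 1 - p3_hat - p1: the asymmetric share keeps its baseline
    # value and differentiation takes the remainder, so p3 is constant in
    # time (identically zero when p1_hat + p2_hat = 1); p2's own Hill
    # regulation is then unused
    p2_complement: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1_hat <= 1.0 and 0.0 <= self.p2_hat <= 1.0):
            raise ValueError("baseline probabilities must lie in [0, 1]")
        if self.p1_hat + self.p2_hat > 1.0 + _SUM_TOL:
            raise ValueError(f"p1_hat + p2_hat = {self.p1_hat + self.p2_hat} exceeds 1; p3 would be negative")
        if self.lam_P_hat < 0 or self.lam_R_hat < 0:
            raise ValueError("baseline rates must be nonnegative")
        for i in (1, 2, 3, 4):
            if getattr(self, f"k{i}") < 0:
                raise ValueError(f"k{i} must be nonnegative")
            if not getattr(self, f"m{i}") > 0:
                raise ValueError(f"m{i} must be positive")

    @property
    def p3_hat(self) -> float:
        return 1.0 - self.p1_hat - self.p2_hat

    def scaled(self, factor: float) -> "FeedbackParams":
        """All regulation constants ``k_i`` multiplied by ``factor`` (scaling law)."""
        if not factor > 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        return replace(
            self,
            k1=factor * self.k1,
            k2=factor * self.k2,
            k3=factor * self.k3,
            k4=factor * self.k4,
        )


@dataclass(frozen=True)
class DeathModel:
    """TD death rate ``delta(x)``: constant or linear in damage (``c * x``)."""

    kind: Literal["constant", "linear"] = "linear"
    value: float = 0.6

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear"):
            raise ValueError(f"unknown death model kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("death rate coefficient must be nonnegative")

    def rate(self, x: np.ndarray | float) -> np.ndarray | float:
        x_arr = np.asarray(x, dtype=float)
        if np.any(x_arr < 0):
            raise ValueError("damage x must be nonnegative")
        if self.kind == "constant":
            out = np.full_like(x_arr, self.value)
        else:
            out = self.value * x_arr
        return out if np.ndim(x) else float(out)


def death_rate(model: DeathModel, x: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the TD death rate ``delta(x)`` of ``model`` at damage ``x``."""
    return model.rate(x)


@dataclass(frozen=True)
class DediffRule:
    """How TD cells re-enter the stem pool.

    variant:
      * ``constant`` -- every TD cell dedifferentiates at rate ``lam_R``,
        keeping its damage (full retention).
      * ``threshold`` -- only TD cells with damage ``x >= x_c`` dedifferentiate
        (threshold-dependent dedifferentiation, the "detoxification loop").
      * ``partial_repair`` -- dedifferentiating cells keep a fixed fraction
        ``rho`` of their damage.
      * ``state_dependent`` -- the retention fraction is
        ``rho(x') = rho_min + (rho_max - rho_min) * shape(x')`` with a
        monotone shape function.
    """

    variant: Literal["constant", "threshold", "partial_repair", "state_dependent"] = "constant"
    x_c: float = 0.6
    rho: float = 1.0
    rho_min: float = 0.0
    rho_max: float = 1.0
    shape: Callable[[np.ndarray], np.ndarray] | None = None
    loss_form: Literal["local", "kernel"] = "local"

    def __post_init__(self) -> None:
        if self.variant not in ("constant", "threshold", "partial_repair", "state_dependent"):
            raise ValueError(f"unknown dedifferentiation variant {self.variant!r}")
        if self.x_c < 0:
            raise ValueError("threshold x_c must be nonnegative")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("retention fraction rho must lie in [0, 1]")
        if not (0.0 <= self.rho_min <= self.rho_max <= 1.0):
            raise ValueError("need 0 <= rho_min <= rho_max <= 1")
        if self.variant == "state_dependent" and self.shape is None:
            raise ValueError("state_dependent rule requires a shape function")
        if self.loss_form not in ("local", "kernel"):
            raise ValueError(f"unknown loss form {self.loss_form!r}")

    def retention(self, x: np.ndarray) -> np.ndarray:
        """Per-damage retention fraction ``rho(x')``."""
        x = np.asarray(x, dtype=float)
        if self.variant == "partial_repair":
            return np.full_like(x, self.rho)
        if self.variant == "state_dependent":
            s = np.clip(np.asarray(self.shape(x), dtype=float), 0.0, 1.0)
            return self.rho_min + (self.rho_max - self.rho_min) * s
        return np.ones_like(x)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the structured PDE model."""

    v_P: float = 0.05
    v_W: float = 0.05
    fractions: PartitionFractions = field(default_factory=PartitionFractions)
    feedback: FeedbackParams = field(default_factory=FeedbackParams)
    death: DeathModel = field(default_factory=DeathModel)
    dediff: DediffRule = field(default_factory=DediffRule)
    inflow: float = 0.0  # boundary density g at x = 0
    courant: float = 0.25
    delta_P: float = 0.0  # stem attrition rate (reduced models / extensions)
    remap_method: Literal["scatter", "gather"] = "scatter"

    def __post_init__(self) -> None:
        if self.v_P < 0 or self.v_W < 0:
            raise ValueError("drift speeds must be nonnegative")
        if not (0.0 < self.courant < 1.0):
            raise ValueError(f"courant number must lie in (0, 1), got {self.courant}")
        if self.inflow < 0:
            raise ValueError("boundary inflow g must be nonnegative")
        if self.delta_P < 0:
            raise ValueError("stem attrition rate must be nonnegative")

    @property
    def v_max(self) -> float:
        return max(self.v_P, self.v_W)


class EffectiveRates(NamedTuple):
    """Feedback-regulated rates at given totals; ``p1 + p2 + p3 == 1``."""

    p1: float
    p2: float
    p3: float
    lam_P: float
    lam_R: float


def cfl_timestep(grid: Grid, v_P: float, v_W: float, courant: float) -> float:
    """Timestep ``dt = C * dx / max(v_P, v_W)`` from the CFL stability bound."""
    if not (0.0 < courant < 1.0):
        raise ValueError(f"courant number must lie in (0, 1), got {courant}")
    v = max(v_P, v_W)
    if v <= 0.0:
        raise ValueError("both drift speeds are zero: the CFL bound is vacuous, supply dt explicitly")
    return courant * grid.dx / v


def hill_regulation(baseline: float, k: float, m: float, signal: float) -> float:
    """Decreasing Hill regulation ``baseline / (1 + (k * signal)^m)``.

    Equals the baseline at zero signal (or ``k = 0``) and decreases
    monotonically in both the signal and the regulation constant ``k``.
    """
    if baseline < 0 or k < 0 or signal < 0:
        raise ValueError("baseline, k and signal must be nonnegative")
    if not m > 0:
        raise ValueError("Hill exponent must be positive")
    if not np.isfinite(baseline) or not np.isfinite(k) or not np.isfinite(signal):
        raise ValueError("arguments must be finite")
    return baseline / (1.0 + (k * signal) ** m)


def effective_rates(totals: tuple[float, float], feedback: FeedbackParams) -> EffectiveRates:
    """Regulated ``(p1, p2, p3, lam_P, lam_R)`` at totals ``(Pbar, Wbar)``.

    ``p1``, ``p2`` and ``lam_P`` are suppressed by the TD total, ``lam_R`` by
    the stem total; ``p3 = 1 - p1 - p2`` by normalization.
    """
    P_bar, W_bar = totals
    if P_bar < 0 or W_bar < 0:
        raise ValueError("totals must be nonnegative")
    p1 = hill_regulation(feedback.p1_hat, feedback.k1, feedback.m1, W_bar)
    if feedback.p2_complement:
        p2 = 1.0 - feedback.p3_hat - p1
    else:
        p2 = hill_regulation(feedback.p2_hat, feedback.k2, feedback.m2, W_bar)
    lam_P = hill_regulation(feedback.lam_P_hat, feedback.k3, feedback.m3, W_bar)
    lam_R = hill_regulation(feedback.lam_R_hat, feedback.k4, feedback.m4, P_bar)
    p3 = 1.0 - p1 - p2
    return EffectiveRates(p1=p1, p2=p2, p3=p3, lam_P=lam_P, lam_R=lam_R)
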