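"""Fujimura-Sugihara (FS) sprint motion model.

The FS model describes a player driven by a constant-magnitude force along a
direction ``n_hat`` against viscous (speed-proportional) resistance:

    m d2x/dt2 = F n_hat - k dx/dt

Only two parameter combinations are identifiable from position data: the
drag-to-mass ratio ``alpha = k/m`` (1/s) and the terminal sprint speed
``vmax = F/k`` (m/s).  With initial position at the origin and initial
velocity ``v0`` the closed-form solution is

    x(t) = A(alpha, t) * v0 + B(alpha, vmax, t) * n_hat
    A(alpha, t)       = (1 - exp(-alpha t)) / alpha
    B(alpha, vmax, t) = vmax * (t - A(alpha, t))

Sweeping ``n_hat`` over all directions places the arrival points on a circle
with center ``A * v0`` and radius ``B`` -- the *arrival circle*.  This module
provides the closed form, the circle geometry, the inverse maps used for
parameter estimation (slope -> alpha, radius -> vmax), and a fixed-step RK4
integrator that also covers the variable-coefficient extension
``m x'' = F(t) n_hat(t) - k(t) x'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "MotionState",
    "ArrivalCircle",
    "ExtendedModelSpec",
    "Trajectory",
    "coef_A",
    "coef_B",
    "arrival_point",
    "arrival_circle",
    "invert_alpha",
    "vmax_from_radius",
    "simulate_ode",
]

#: Kinetic parameters reported by Fujimura & Sugihara's original sprint
#: experiment (field-hockey players), quoted here as reference constants.
FUJIMURA_ALPHA = 1.3  # 1/s
FUJIMURA_VMAX = 7.8  # m/s


@dataclass(frozen=True)
class KineticParams:
    """The FS model's two identifiable constants.

    Parameters
    ----------
    alpha : float
        Drag-to-mass ratio k/m, 1/s.  Must be positive.
    vmax : float
        Terminal sprint speed F/k, m/s.  Must be positive.
    """

    alpha: float
    vmax: float

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and > 0, got {self.alpha}")
        if not (np.isfinite(self.vmax) and self.vmax > 0):
            raise ValueError(f"vmax must be finite and > 0, got {self.vmax}")


@dataclass(frozen=True)
class MotionState:
    """Kinematic state of a player: position (m), velocity (m/s), time (s)."""

    position: np.ndarray
    velocity: np.ndarray
    time: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        vel = np.asarray(self.velocity, dtype=float)
        if pos.shape != (2,) or vel.shape != (2,):
            raise ValueError("position and velocity must be 2-vectors")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(vel)) and np.isfinite(self.time)):
            raise ValueError("MotionState components must be finite")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "velocity", vel)


@dataclass(frozen=True)
class ArrivalCircle:
    """Locus of points reachable in exactly ``delta_t`` seconds by sprinting.

    For an initial velocity v0 the center is ``A(alpha, delta_t) * v0`` and
    the radius is ``B(alpha, vmax, delta_t)``.
    """

    center: np.ndarray
    radius: float
    delta_t: float

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float)
        if center.shape != (2,):
            raise ValueError("center must be a 2-vector")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        object.__setattr__(self, "center", center)

    def point_at(self, angle: float) -> np.ndarray:
        """Point on the circle at the given angle (radians)."""
        return self.center + self.radius * np.array([math.cos(angle), math.sin(angle)])


def coef_A(alpha: float, t: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """First closed-form coefficient ``A(alpha, t) = (1 - exp(-alpha t))/alpha``.

    Multiplies the initial velocity in the solution; it is the distance
    travelled per unit initial speed while the initial momentum decays.
    Uses ``expm1`` so that the ``alpha -> 0`` limit (A -> t) is reached
    without cancellation.

    Parameters
    ----------
    alpha : float
        Drag-to-mass ratio, 1/s; must be > 0.
    t : float or ndarray
        Elapsed time, s; must be >= 0.
    """
    if not (np.isfinite(alpha) and alpha > 0):
        raise ValueError(f"alpha must be finite and > 0, got {alpha}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or not np.all(np.isfinite(t_arr)):
        raise ValueError(f"t must be finite and >= 0, got {t}")
    out = -np.expm1(-alpha * t_arr) / alpha
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def coef_B(params: KineticParams, t: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Second coefficient ``B = vmax * (t - A(alpha, t))`` -- the sprint radius.

    Distance covered in ``t`` seconds by a standing start at full drive;
    non-negative and strictly increasing in ``t``.
    """
    a = coef_A(params.alpha, t)
    out = params.vmax * (np.asarray(t, dtype=float) - np.asarray(a))
    return float(out) if np.isscalar(t) else out


_UNIT_TOL = 1e-6


def _check_unit(n_hat: np.ndarray) -> np.ndarray:
    n = np.asarray(n_hat, dtype=float)
    if n.shape != (2,):
        raise ValueError("n_hat must be a 2-vector")
    norm = math.hypot(n[0], n[1])
    if abs(norm - 1.0) > _UNIT_TOL:
        raise ValueError(f"n_hat must be a unit vector, |n_hat| = {norm}")
    return n


def arrival_point(
    v0: Sequence[float],
    n_hat: Sequence[float],
    params: KineticParams,
    t: float,
) -> np.ndarray:
    """Arrival position after ``t`` s of full drive along ``n_hat``.

    Evaluates the closed form ``A * v0 + B * n_hat`` for a player starting at
    the origin with velocity ``v0``.  The returned point lies at distance
    ``B`` from the circle center ``A * v0``.
    """
    n = _check_unit(n_hat)
    v = np.asarray(v0, dtype=float)
    if v.shape != (2,):
        raise ValueError("v0 must be a 2-vector")
    a = coef_A(params.alpha, t)
    b = coef_B(params, t)
    return a * v + b * n


def arrival_circle(v0: Sequence[float], params: KineticParams, t: float) -> ArrivalCircle:
    """Arrival circle for initial velocity ``v0``: center ``A v0``, radius ``B``."""
    v = np.asarray(v0, dtype=float)
    if v.shape != (2,):
        raise ValueError("v0 must be a 2-vector")
    a = coef_A(params.alpha, t)
    b = coef_B(params, t)
    return ArrivalCircle(center=a * v, radius=float(b), delta_t=float(t))


_ALPHA_BRACKET = (1e-8, 1e3)


def invert_alpha(slope: float, t: float, xtol: float = 1e-12) -> float:
    """Solve ``A(alpha, t) = slope`` for ``alpha``.

    ``A`` is strictly decreasing in ``alpha`` with range ``(0, t)``, so the
    root is unique; it is found by bracketed root search on
    ``alpha in [1e-8, 1e3]``.

    Parameters
    ----------
    slope : float
        Proportionality coefficient of the circle center x-coordinate on
        initial speed (the regression slope), dimension s.  Must satisfy
        ``0 < slope < t``.
    t : float
        The time interval at which the slope was measured, s.
    """
    if not (np.isfinite(t) and t > 0):
        raise ValueError(f"t must be finite and > 0, got {t}")
    if not (np.isfinite(slope) and slope > 0):
        raise ValueError(f"slope must be > 0, got {slope}")
    if slope >= t:
        raise ValueError(
            f"slope ({slope}) must be < t ({t}): A(alpha, t) < t for every alpha > 0"
        )
    lo, hi = _ALPHA_BRACKET

    def f(a: float) -> float:
        return coef_A(a, t) - slope

    if f(lo) <= 0:
        raise ValueError(f"slope {slope} too close to t={t}; alpha below {lo}")
    if f(hi) >= 0:
        raise ValueError(f"slope {slope} too small for t={t}; alpha above {hi}")
    alpha = brentq(f, lo, hi, xtol=xtol, rtol=8.9e-16)
    return float(alpha)


def vmax_from_radius(r_c: float, alpha: float, t: float) -> float:
    """Terminal speed from an observed sprint radius: ``vmax = r_c / (t - A)``.

    Inverts ``B(alpha, vmax, t) = r_c`` at known ``alpha``.  For any
    ``alpha > 0`` and ``t > 0`` the denominator ``t - A`` is positive.
    """
    if r_c < 0:
        raise ValueError(f"r_c must be >= 0, got {r_c}")
    if not (np.isfinite(t) and t > 0):
        raise ValueError(f"t must be > 0, got {t}")
    denom = t - coef_A(alpha, t)
    return float(r_c / denom)


TimeFunction = Callable[[float], float]


def _as_time_function(value: Union[float, TimeFunction]) -> TimeFunction:
    if callable(value):
        return value
    val = float(value)
    return lambda t: val


def _as_direction_function(
    value: Union[Sequence[float], Callable[[float], Sequence[float]]],
) -> Callable[[float], np.ndarray]:
    if callable(value):
        return lambda t: np.asarray(value(t), dtype=float)
    vec = np.asarray(value, dtype=float)
    return lambda t: vec


@dataclass
class ExtendedModelSpec:
    """Specification of the variable-coefficient model ``m x'' = F(t) n - k(t) x'``.

    ``driving_force`` and ``drag_coefficient`` may be constants or callables
    of time; ``direction`` may be a fixed 2-vector or a callable returning
    one.  The direction is re-normalized defensively at every evaluation.
    The raw constants m, F, k live here because only alpha = k/m and
    vmax = F/k are identifiable from the closed form.
    """

    mass: float
    driving_force: Union[float, TimeFunction]
    drag_coefficient: Union[float, TimeFunction]
    direction: Union[Sequence[float], Callable[[float], Sequence[float]]] = (1.0, 0.0)

    def __post_init__(self):
        if not (np.isfinite(self.mass) and self.mass > 0):
            raise ValueError(f"mass must be > 0, got {self.mass}")
        self._force = _as_time_function(self.driving_force)
        self._drag = _as_time_function(self.drag_coefficient)
        self._direction = _as_direction_function(self.direction)

    @classmethod
    def from_kinetic(
        cls,
        params: KineticParams,
        direction: Union[Sequence[float], Callable[[float], Sequence[float]]] = (1.0, 0.0),
        mass: float = 70.0,
    ) -> "ExtendedModelSpec":
        """Constant-coefficient spec with k = alpha*m and F = vmax*k."""
        k = params.alpha * mass
        return cls(mass=mass, driving_force=params.vmax * k, drag_coefficient=k, direction=direction)

    def acceleration(self, t: float, velocity: np.ndarray) -> np.ndarray:
        f = self._force(t)
        k = self._drag(t)
        if not (np.isfinite(f) and np.isfinite(k)):
            raise ValueError(f"non-finite coefficients at t={t}: F={f}, k={k}")
        if f < 0:
            raise ValueError(f"driving force must be >= 0, got {f} at t={t}")
        if k <= 0:
            raise ValueError(f"drag coefficient must be > 0, got {k} at t={t}")
        n = self._direction(t)
        norm = math.hypot(n[0], n[1])
        if norm == 0 or not np.isfinite(norm):
            raise ValueError(f"direction must be non-zero at t={t}")
        n = n / norm
        return (f * n - k * velocity) / self.mass


@dataclass
class Trajectory:
    """Integrated trajectory: arrays of times, positions, velocities."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> MotionState:
        return MotionState(self.positions[i], self.velocities[i], float(self.times[i]))

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def final(self) -> MotionState:
        return self[-1]


def simulate_ode(
    spec: ExtendedModelSpec,
    initial: MotionState,
    t_end: float,
    dt: float = 1e-3,
) -> Trajectory:
    """Integrate ``m x'' = F(t) n_hat(t) - k(t) x'`` by classical fixed-step RK4.

    With constant coefficients and a constant direction the result matches
    the closed form (``arrival_point``) to integrator accuracy, which is the
    correctness oracle.  A fixed step keeps the output reproducible.

    Parameters
    ----------
    spec : ExtendedModelSpec
    initial : MotionState
        State at ``initial.time``.
    t_end : float
        Duration to integrate, s (relative to ``initial.time``).
    dt : float
        Fixed step, s; the final partial step is shortened to land on
        ``t_end`` exactly.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if t_end < 0:
        raise ValueError(f"t_end must be >= 0, got {t_end}")

    n_full = int(math.floor(t_end / dt + 1e-12))
    remainder = t_end - n_full * dt
    steps = [dt] * n_full
    if remainder > 1e-12 * max(1.0, t_end):
        steps.append(remainder)

    t0 = initial.time
    times = np.empty(len(steps) + 1)
    positions = np.empty((len(steps) + 1, 2))
    velocities = np.empty((len(steps) + 1, 2))
    times[0] = t0
    positions[0] = initial.position
    velocities[0] = initial.velocity

    x = initial.position.copy()
    v = initial.velocity.copy()
    t = t0
    acc = spec.acceleration
    for i, h in enumerate(steps, start=1):
        k1x = v
        k1v = acc(t, v)
        k2x = v + 0.5 * h * k1v
        k2v = acc(t + 0.5 * h, v + 0.5 * h * k1v)
        k3x = v + 0.5 * h * k2v
        k3v = acc(t + 0.5 * h, v + 0.5 * h * k2v)
        k4x = v + h * k3v
        k4v = acc(t + h, v + h * k3v)
        x = x + (h / 6.0) * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
        v = v + (h / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        t = t + h
        times[i] = t
        positions[i] = x
        velocities[i] = v

    return Trajectory(times=times, positions=positions, velocities=velocities)
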