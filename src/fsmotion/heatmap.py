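"""Velocity-frame heat maps of arrival points and circle estimation.

For every player and frame t with a defined velocity, the position at
t + delta_t is expressed in the *velocity frame*: coordinates translated so
the player sits at the origin and rotated so the current velocity points
along +x.  Accumulating these arrival points over players and frames, for a
fixed delta_t and an initial-speed bin [v0, v0 + 0.3) m/s, gives a 2-D count
grid (heat map) whose boundary is, for sprinting motion, the arrival circle
of the FS model.

Grid cells are squares of side ``0.2 * delta_t`` m anchored at the origin
(half-open cells ``[i*s, (i+1)*s)``).  Before estimating the boundary,
isolated cells -- occupied cells with fewer than ``c`` occupied Moore
neighbours -- are removed as outliers, with ``c`` = 8 / 6 / 4 depending on
delta_t.  The boundary circle is then estimated from the extents of the
surviving cell centers:

    (x_c, y_c) = ((x_max + x_min)/2, (y_max + y_min)/2)
    r_c        = (x_max - x_min + y_max - y_min) / 4
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import convolve

from .data import PlaySegment, TrackingDataset
from .synthetic import SprintEnsemble

__all__ = [
    "HeatMapGrid",
    "CircleEstimate",
    "ZeroVelocityError",
    "EmptyHeatMapError",
    "velocity_frame_point",
    "build_heatmap",
    "default_c",
    "filter_isolated_cells",
    "circle_from_extent",
    "arrival_observations",
]


class ZeroVelocityError(ValueError):
    """The velocity frame is undefined for a zero current velocity."""


class EmptyHeatMapError(ValueError):
    """No occupied cells to analyse."""


@dataclass
class HeatMapGrid:
    """Count grid of velocity-frame arrival points for one (delta_t, v0 bin).

    ``counts[i, j]`` counts points with ``floor(x / cell_size) == i + i0``
    and ``floor(y / cell_size) == j + j0``; the integer offsets anchor the
    grid to the velocity-frame origin, so cell (0, 0) of the *index plane*
    spans ``[0, cell_size) x [0, cell_size)``.
    """

    delta_t: float
    v0_bin: Tuple[float, float]  # [lo, hi) m/s
    cell_size: float
    i0: int
    j0: int
    counts: np.ndarray  # 2-D int array, may be empty

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_points(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.counts.size == 0 or not np.any(self.counts)

    def occupied_centers(self) -> np.ndarray:
        """(n, 2) coordinates of the centers of occupied cells, metres."""
        ii, jj = np.nonzero(self.counts)
        x = (ii + self.i0 + 0.5) * self.cell_size
        y = (jj + self.j0 + 0.5) * self.cell_size
        return np.column_stack([x, y])


@dataclass
class CircleEstimate:
    """Circle approximation of one heat map's boundary."""

    v0_bin: Tuple[float, float]
    x_c: float
    y_c: float
    r_c: float
    n_points: int
    # extents of the surviving occupied cells (centers), for diagnostics
    x_min: float = math.nan
    x_max: float = math.nan
    y_min: float = math.nan
    y_max: float = math.nan

    def __post_init__(self):
        if self.r_c < 0:
            raise ValueError("r_c must be >= 0")

    @property
    def v0_mid(self) -> float:
        return 0.5 * (self.v0_bin[0] + self.v0_bin[1])


def velocity_frame_point(
    pos_t: Sequence[float],
    vel_t: Sequence[float],
    pos_t_plus: Sequence[float],
) -> np.ndarray:
    """One arrival point in the velocity frame.

    Translates by ``-pos_t`` and rotates so ``vel_t`` maps to the +x axis;
    the rotation is norm-preserving, so the returned point keeps the true
    displacement distance.

    Raises
    ------
    ZeroVelocityError
        If ``|vel_t| == 0`` (the frame is undefined; callers must exclude
        such samples explicitly).
    """
    pos_t = np.asarray(pos_t, dtype=float)
    vel_t = np.asarray(vel_t, dtype=float)
    pos_t_plus = np.asarray(pos_t_plus, dtype=float)
    speed = math.hypot(vel_t[0], vel_t[1])
    if speed == 0.0:
        raise ZeroVelocityError("velocity frame undefined for zero velocity")
    c, s = vel_t[0] / speed, vel_t[1] / speed
    d = pos_t_plus - pos_t
    return np.array([c * d[0] + s * d[1], -s * d[0] + c * d[1]])


def _velocity_frame_points(
    disp: np.ndarray, vel: np.ndarray, speed: np.ndarray
) -> np.ndarray:
    """Vectorized velocity-frame transform; caller guarantees speed > 0."""
    c = vel[:, 0] / speed
    s = vel[:, 1] / speed
    return np.column_stack(
        [c * disp[:, 0] + s * disp[:, 1], -s * disp[:, 0] + c * disp[:, 1]]
    )


def arrival_observations(
    dataset: TrackingDataset,
    delta_t: float,
    lag: float = 1.0,
    exclude_goalkeeper: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """All qualifying (initial speed, velocity-frame arrival point) samples.

    For every player and frame t where the lagged velocity is defined and
    t + delta_t falls inside the same play segment, emits the initial speed
    and the arrival point in the velocity frame.  Overlapping windows at the
    native frame rate are all used.  Zero-velocity samples are skipped (the
    count is reported in a warning).

    Returns ``(speeds, points)`` with shapes (n,) and (n, 2).
    """
    dt = dataset.sample_interval
    k_dt = delta_t / dt
    if abs(k_dt - round(k_dt)) > 1e-6 or round(k_dt) < 1:
        raise ValueError(
            f"delta_t {delta_t} s must be a positive multiple of the sampling interval {dt} s"
        )
    k_dt = int(round(k_dt))
    k_lag = lag / dt
    if abs(k_lag - round(k_lag)) > 1e-6 or round(k_lag) < 1:
        raise ValueError(f"lag {lag} s must be a positive multiple of {dt} s")
    k_lag = int(round(k_lag))

    speeds_all, points_all = [], []
    n_zero = 0
    for seg in dataset.segments:
        for pid, sub in seg.data.groupby("player_id"):
            if exclude_goalkeeper and sub["role"].iloc[0] == "GK":
                continue
            xy = sub.sort_values("time_s")[["x_m", "y_m"]].to_numpy()
            n = len(xy)
            if n <= k_lag + k_dt:
                continue
            # frames t = k_lag .. n - 1 - k_dt (velocity defined, window inside)
            pos_t = xy[k_lag : n - k_dt]
            vel = (xy[k_lag : n - k_dt] - xy[: n - k_dt - k_lag]) / lag
            pos_plus = xy[k_lag + k_dt :]
            speed = np.hypot(vel[:, 0], vel[:, 1])
            ok = speed > 0
            n_zero += int((~ok).sum())
            disp = pos_plus[ok] - pos_t[ok]
            points_all.append(_velocity_frame_points(disp, vel[ok], speed[ok]))
            speeds_all.append(speed[ok])
    if n_zero:
        warnings.warn(f"excluded {n_zero} zero-velocity samples", stacklevel=2)
    if not speeds_all:
        return np.empty(0), np.empty((0, 2))
    return np.concatenate(speeds_all), np.vstack(points_all)


def _grid_from_points(
    points: np.ndarray,
    delta_t: float,
    v0_bin: Tuple[float, float],
    cell_size: float,
) -> HeatMapGrid:
    if len(points) == 0:
        return HeatMapGrid(
            delta_t=delta_t,
            v0_bin=v0_bin,
            cell_size=cell_size,
            i0=0,
            j0=0,
            counts=np.zeros((0, 0), dtype=np.int64),
        )
    ii = np.floor(points[:, 0] / cell_size).astype(np.int64)
    jj = np.floor(points[:, 1] / cell_size).astype(np.int64)
    i0, j0 = int(ii.min()), int(jj.min())
    counts = np.zeros((int(ii.max()) - i0 + 1, int(jj.max()) - j0 + 1), dtype=np.int64)
    np.add.at(counts, (ii - i0, jj - j0), 1)
    return HeatMapGrid(
        delta_t=delta_t, v0_bin=v0_bin, cell_size=cell_size, i0=i0, j0=j0, counts=counts
    )


def build_heatmap(
    source: Union[TrackingDataset, SprintEnsemble, Tuple[np.ndarray, np.ndarray]],
    delta_t: float,
    v0_bin: Tuple[float, float],
    cell_size: Optional[float] = None,
    lag: float = 1.0,
) -> HeatMapGrid:
    """Accumulate velocity-frame arrival points into a count grid.

    ``source`` may be a :class:`TrackingDataset` (goalkeepers excluded, all
    overlapping windows used), a :class:`SprintEnsemble`, or a precomputed
    ``(speeds, points)`` pair from :func:`arrival_observations` (cheapest
    when binning many v0 bins from the same data).  ``cell_size`` defaults
    to ``0.2 * delta_t`` m.  An empty selection yields a valid empty grid.
    """
    if cell_size is None:
        cell_size = 0.2 * delta_t
    lo, hi = v0_bin
    if not hi > lo:
        raise ValueError(f"invalid v0 bin {v0_bin}")

    if isinstance(source, TrackingDataset):
        speeds, points = arrival_observations(source, delta_t, lag=lag)
    elif isinstance(source, SprintEnsemble):
        if abs(source.delta_t - delta_t) > 1e-9:
            raise ValueError(
                f"ensemble delta_t {source.delta_t} does not match requested {delta_t}"
            )
        vel = source.vel0
        speeds = np.hypot(vel[:, 0], vel[:, 1])
        disp = source.pos1 - source.pos0
        ok = speeds > 0
        if not np.all(ok):
            warnings.warn(f"excluded {int((~ok).sum())} zero-velocity samples", stacklevel=2)
        points = _velocity_frame_points(disp[ok], vel[ok], speeds[ok])
        speeds = speeds[ok]
    else:
        speeds, points = source

    mask = (speeds >= lo) & (speeds < hi)
    return _grid_from_points(points[mask], delta_t, (lo, hi), cell_size)


def default_c(delta_t: float) -> int:
    """Isolated-cell threshold used at each delta_t: 8 / 6 / 4.

    Shorter intervals give denser maps, so a stricter threshold is needed to
    strip outliers: 8 for delta_t < 1 s, 6 for 1 <= delta_t <= 3 s, 4 for
    delta_t > 3 s.
    """
    if delta_t <= 0:
        raise ValueError(f"delta_t must be > 0, got {delta_t}")
    if delta_t < 1.0:
        return 8
    if delta_t <= 3.0:
        return 6
    return 4


_MOORE_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.int64)


def filter_isolated_cells(grid: HeatMapGrid, c: int, strict: bool = False) -> HeatMapGrid:
    """Remove occupied cells with too few occupied Moore neighbours.

    A single pass: neighbour counts are taken on the *input* grid, and an
    occupied cell survives iff at least ``c`` (or, with ``strict=True``,
    strictly more than ``c``) of its 8 neighbours are occupied.  Blank cells
    are unchanged.  With c = 8 the strict reading is unsatisfiable in a
    Moore neighbourhood, so the inclusive form is the default.
    """
    if not 0 <= c <= 8:
        raise ValueError(f"c must be in [0, 8], got {c}")
    if strict and c >= 8:
        raise ValueError("strict adjacency with c = 8 removes every cell")
    if grid.counts.size == 0:
        return grid
    occupied = (grid.counts > 0).astype(np.int64)
    neighbours = convolve(occupied, _MOORE_KERNEL, mode="constant", cval=0)
    keep = occupied.astype(bool) & (neighbours > c if strict else neighbours >= c)
    return HeatMapGrid(
        delta_t=grid.delta_t,
        v0_bin=grid.v0_bin,
        cell_size=grid.cell_size,
        i0=grid.i0,
        j0=grid.j0,
        counts=np.where(keep, grid.counts, 0),
    )


def circle_from_extent(grid: HeatMapGrid) -> CircleEstimate:
    """Boundary circle from the extents of the occupied cell centers.

    Center = midpoint of the x and y extents; radius = mean of the two
    half-extents.  Cell centers (not edges) are used, which avoids a
    half-cell bias in the radius.
    """
    if grid.is_empty:
        raise EmptyHeatMapError(
            f"no occupied cells for v0 bin {grid.v0_bin} at delta_t={grid.delta_t}"
        )
    centers = grid.occupied_centers()
    x_min, y_min = centers.min(axis=0)
    x_max, y_max = centers.max(axis=0)
    return CircleEstimate(
        v0_bin=grid.v0_bin,
        x_c=0.5 * (x_max + x_min),
        y_c=0.5 * (y_max + y_min),
        r_c=0.25 * ((x_max - x_min) + (y_max - y_min)),
        n_points=grid.n_points,
        x_min=float(x_min),
        x_max=float(x_max),
        y_min=float(y_min),
        y_max=float(y_max),
    )
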