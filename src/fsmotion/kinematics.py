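"""Velocity estimation, speed distributions and mean squared displacement.

Velocity is the backward difference over a 1 s lag,
``v(t) = (x(t) - x(t - lag)) / lag``, matching how tracking-data studies
define instantaneous player velocity; no smoothing is applied (downstream
heat-map binning absorbs the noise).

The mean squared displacement of a player over a play segment of length T,

    MSD(tau) = < |x(t + tau) - x(t)|^2 >_t ,   t in [0, T - tau],

averaged over all sampled start frames, scales as ``tau**beta``: beta = 2
for straight-line (ballistic) motion and beta = 1 for a random walk.  Match
trajectories cross over from beta = 2 to beta = 1 around the ~10 s
straight-run timescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import PlaySegment, TrackingDataset

__all__ = [
    "VelocityFrame",
    "MSDCurve",
    "compute_velocity",
    "speed_distribution",
    "compute_msd",
    "average_msd",
    "fit_msd_exponent",
    "dataset_msd",
]

_LAG_TOL = 1e-6

#: tidy velocity table columns
VELOCITY_COLUMNS = ["player_id", "role", "time_s", "x_m", "y_m", "vx", "vy", "speed"]

VelocityFrame = pd.DataFrame  # alias: tidy table with VELOCITY_COLUMNS


def _lag_frames(lag: float, dt: float) -> int:
    k = lag / dt
    if abs(k - round(k)) > _LAG_TOL:
        raise ValueError(f"lag {lag} s is not a multiple of the sampling interval {dt} s")
    k = int(round(k))
    if k < 1:
        raise ValueError(f"lag must be a positive multiple of the sampling interval, got {lag}")
    return k


def compute_velocity(segment: PlaySegment, lag: float = 1.0) -> pd.DataFrame:
    """Per-player backward-difference velocities over ``lag`` seconds.

    Returns a tidy frame with columns ``player_id, role, time_s, x_m, y_m,
    vx, vy, speed``; times earlier than ``lag`` after the segment start are
    omitted (the difference is undefined there).
    """
    k = _lag_frames(lag, segment.sample_interval)
    out: List[pd.DataFrame] = []
    for pid, sub in segment.data.groupby("player_id"):
        sub = sub.sort_values("time_s")
        xy = sub[["x_m", "y_m"]].to_numpy()
        if len(xy) <= k:
            continue
        v = (xy[k:] - xy[:-k]) / lag
        speed = np.hypot(v[:, 0], v[:, 1])
        out.append(
            pd.DataFrame(
                {
                    "player_id": pid,
                    "role": sub["role"].iloc[0],
                    "time_s": sub["time_s"].to_numpy()[k:],
                    "x_m": xy[k:, 0],
                    "y_m": xy[k:, 1],
                    "vx": v[:, 0],
                    "vy": v[:, 1],
                    "speed": speed,
                }
            )
        )
    if not out:
        warnings.warn(
            f"segment {segment.segment_id!r} shorter than the {lag} s lag; no velocities",
            stacklevel=2,
        )
        return pd.DataFrame(columns=VELOCITY_COLUMNS)
    return pd.concat(out, ignore_index=True)


def speed_distribution(
    records: pd.DataFrame,
    role_filter: Optional[str] = "OUT",
    bin_width: float = 0.25,
    v_max: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized speed histogram from a velocity table.

    Parameters
    ----------
    records : DataFrame
        Output of :func:`compute_velocity` (possibly concatenated).
    role_filter : str or None
        Keep only this role (``"OUT"`` by default -- goalkeepers rarely
        sprint and are excluded from the analyses); ``None`` keeps all.
    bin_width : float
        Histogram bin width, m/s.
    v_max : float, optional
        Upper edge; defaults to the maximum observed speed.

    Returns
    -------
    (edges, densities) : bin edges (n+1,) and probability densities (n,);
    densities integrate to 1 over the binned range.
    """
    if records.empty:
        raise ValueError("empty velocity records")
    speeds = (
        records.loc[records["role"] == role_filter, "speed"]
        if role_filter is not None
        else records["speed"]
    ).to_numpy()
    if speeds.size == 0:
        raise ValueError(f"no records with role {role_filter!r}")
    top = v_max if v_max is not None else float(speeds.max())
    n_bins = max(1, int(np.ceil(top / bin_width + 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    density, _ = np.histogram(speeds, bins=edges, density=True)
    return edges, density


@dataclass
class MSDCurve:
    """Mean squared displacement against lag time tau.

    ``n_obs`` counts the contributing curves (players/segments) per tau, so
    curves can be averaged with provenance intact.
    """

    tau: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # m^2
    n_obs: np.ndarray  # contributing curves per tau

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


def _default_taus(duration: float, dt: float, n: int = 60) -> np.ndarray:
    """Log-spaced multiples of the sampling interval up to T/2."""
    k_max = int(np.floor(duration / 2.0 / dt))
    if k_max < 1:
        raise ValueError("segment too short for any MSD lag")
    ks = np.unique(np.round(np.geomspace(1, k_max, num=min(n, k_max))).astype(int))
    return ks * dt


def compute_msd(
    segment: PlaySegment,
    player_id: str,
    taus: Optional[Sequence[float]] = None,
) -> MSDCurve:
    """Single-player MSD over one play segment.

    ``MSD(tau)`` is the average of ``|x(t + tau) - x(t)|^2`` over every
    sampled start frame ``t`` in ``[0, T - tau]``.  Lags ``tau >= T`` are
    excluded from the output.
    """
    sub = segment.player_positions(player_id)
    if sub.empty:
        raise ValueError(f"player {player_id!r} not in segment {segment.segment_id!r}")
    xy = sub[["x_m", "y_m"]].to_numpy()
    dt = segment.sample_interval
    duration = (len(xy) - 1) * dt
    if taus is None:
        taus = _default_taus(duration, dt)
    tau_list, msd_list = [], []
    for tau in taus:
        k = int(round(tau / dt))
        if abs(k * dt - tau) > _LAG_TOL:
            raise ValueError(f"tau {tau} is not a multiple of the sampling interval {dt}")
        if k < 1 or k >= len(xy):
            continue  # tau >= T: undefined for this segment
        d = xy[k:] - xy[:-k]
        tau_list.append(k * dt)
        msd_list.append(float(np.mean(np.einsum("ij,ij->i", d, d))))
    return MSDCurve(
        tau=np.array(tau_list), msd=np.array(msd_list), n_obs=np.ones(len(tau_list), dtype=int)
    )


def average_msd(curves: Iterable[MSDCurve]) -> MSDCurve:
    """Pointwise mean of MSD curves sharing a common tau grid."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    tau0 = curves[0].tau
    for c in curves[1:]:
        if len(c.tau) != len(tau0) or np.any(np.abs(c.tau - tau0) > _LAG_TOL):
            raise ValueError("curves have mismatched tau grids")
    msd = np.mean([c.msd for c in curves], axis=0)
    n_obs = np.sum([c.n_obs for c in curves], axis=0)
    return MSDCurve(tau=tau0.copy(), msd=msd, n_obs=n_obs)


def fit_msd_exponent(curve: MSDCurve, tau_window: Tuple[float, float]) -> float:
    """Scaling exponent beta: least-squares slope of log MSD vs log tau.

    Fitted over taus in ``[tau_lo, tau_hi]``; requires at least 3 points
    with strictly positive MSD in the window.
    """
    lo, hi = tau_window
    mask = (curve.tau >= lo) & (curve.tau <= hi)
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 MSD points in window [{lo}, {hi}] s")
    msd = curve.msd[mask]
    if np.any(msd <= 0):
        raise ValueError("MSD must be strictly positive inside the fit window")
    beta = np.polyfit(np.log(curve.tau[mask]), np.log(msd), 1)[0]
    return float(beta)


def dataset_msd(
    dataset: TrackingDataset,
    taus: Optional[Sequence[float]] = None,
    exclude_goalkeeper: bool = True,
) -> MSDCurve:
    """MSD averaged over all (player, segment) pairs of a dataset.

    Convenience wrapper: per-player curves on a common tau grid (derived
    from the shortest segment when ``taus`` is omitted), then a pointwise
    average, mirroring the per-match averaged MSD analysis.
    """
    if taus is None:
        shortest = min(seg.duration for seg in dataset.segments)
        taus = _default_taus(shortest, dataset.sample_interval)
    curves = []
    for seg in dataset.segments:
        for pid in seg.player_ids:
            if exclude_goalkeeper:
                role = seg.data.loc[seg.data["player_id"] == pid, "role"].iloc[0]
                if role == "GK":
                    continue
            curves.append(compute_msd(seg, pid, taus=taus))
    return average_msd(curves)
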