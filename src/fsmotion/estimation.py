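"""Kinetic-parameter estimation from per-v0-bin circle estimates.

The closed form predicts, for a fixed delta_t, that the arrival-circle
center x-coordinate is strictly proportional to the initial speed with
coefficient A(alpha, delta_t), while the radius B is independent of v0.
Estimation therefore proceeds per delta_t:

1. regress x_c on the bin-midpoint v0 through the origin over bins with
   v0 <= 6 m/s (sparse data bias corrupts higher bins) -> slope;
2. invert A(alpha, delta_t) = slope for alpha (bracketed root search);
3. average r_c over the same bins -> mean radius;
4. vmax = mean_r_c / (delta_t - A(alpha, delta_t)).

:class:`ArrivalCircleModel` packages the whole chain, tracking data in /
fitted parameters out, with a results object carrying the per-bin circle
table, rough standard errors and a text summary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data import TrackingDataset
from .heatmap import (
    CircleEstimate,
    EmptyHeatMapError,
    arrival_observations,
    build_heatmap,
    circle_from_extent,
    default_c,
    filter_isolated_cells,
)
from .motion import ArrivalCircle, KineticParams, arrival_circle, coef_A, invert_alpha, vmax_from_radius
from .synthetic import SprintEnsemble

__all__ = [
    "KineticFit",
    "center_regression",
    "mean_radius",
    "estimate_params",
    "sweep_delta_t",
    "ArrivalCircleModel",
    "ArrivalCircleResults",
]


@dataclass
class KineticFit:
    """Per-delta_t estimation output."""

    delta_t: float
    slope: float  # s; A(alpha, delta_t)
    alpha: float  # 1/s
    mean_r_c: float  # m
    vmax: float  # m/s
    v0_max_fit: float = 6.0
    n_bins_used: int = 0

    def __post_init__(self):
        if not 0 < self.slope < self.delta_t:
            raise ValueError(
                f"slope {self.slope} outside (0, {self.delta_t}) for delta_t={self.delta_t}"
            )
        if self.alpha <= 0 or self.vmax <= 0:
            raise ValueError("alpha and vmax must be > 0")

    @property
    def params(self) -> KineticParams:
        return KineticParams(alpha=self.alpha, vmax=self.vmax)


def _qualifying(
    estimates: Sequence[CircleEstimate], v0_max: float
) -> List[CircleEstimate]:
    # a bin qualifies when its lower edge does not exceed v0_max
    return [e for e in estimates if e.v0_bin[0] <= v0_max]


def center_regression(
    estimates: Sequence[CircleEstimate],
    v0_max: float = 6.0,
    through_origin: bool = True,
) -> float:
    """Slope of circle-center x_c against bin-midpoint initial speed.

    By default the line is constrained through the origin, as the closed
    form predicts strict proportionality (``x_c = A v0``); a free-intercept
    fit is available for diagnostics, in which case the returned slope is
    still the coefficient of v0.  Bins with lower edge above ``v0_max`` are
    excluded.
    """
    qual = _qualifying(estimates, v0_max)
    if len(qual) < 2:
        raise ValueError(
            f"need >= 2 circle estimates with v0 <= {v0_max}, have {len(qual)}"
        )
    v = np.array([e.v0_mid for e in qual])
    x = np.array([e.x_c for e in qual])
    if through_origin:
        return float(np.dot(v, x) / np.dot(v, v))
    return float(np.polyfit(v, x, 1)[0])


def mean_radius(estimates: Sequence[CircleEstimate], v0_max: float = 6.0) -> float:
    """Unweighted mean of r_c over bins with lower edge <= v0_max."""
    qual = _qualifying(estimates, v0_max)
    if not qual:
        raise ValueError(f"no circle estimates with v0 <= {v0_max}")
    return float(np.mean([e.r_c for e in qual]))


def estimate_params(
    estimates: Sequence[CircleEstimate],
    delta_t: float,
    v0_max: float = 6.0,
    through_origin: bool = True,
) -> KineticFit:
    """Full inversion chain: circles -> slope -> alpha -> mean radius -> vmax."""
    slope = center_regression(estimates, v0_max=v0_max, through_origin=through_origin)
    alpha = invert_alpha(slope, delta_t)
    r_bar = mean_radius(estimates, v0_max=v0_max)
    vmax = vmax_from_radius(r_bar, alpha, delta_t)
    return KineticFit(
        delta_t=delta_t,
        slope=slope,
        alpha=alpha,
        mean_r_c=r_bar,
        vmax=vmax,
        v0_max_fit=v0_max,
        n_bins_used=len(_qualifying(estimates, v0_max)),
    )


def _fit_to_row(fit: KineticFit) -> Dict[str, float]:
    return {
        "delta_t": fit.delta_t,
        "slope": fit.slope,
        "alpha": fit.alpha,
        "mean_r_c": fit.mean_r_c,
        "vmax": fit.vmax,
        "v0_max_fit": fit.v0_max_fit,
        "n_bins_used": fit.n_bins_used,
    }


def sweep_delta_t(
    dataset: TrackingDataset,
    delta_ts: Sequence[float],
    delta_v0: float = 0.3,
    v0_range: Tuple[float, float] = (0.0, 9.0),
    v0_max: float = 6.0,
    cell_factor: float = 0.2,
    c: Union[int, str] = "auto",
    lag: float = 1.0,
    strict_adjacency: bool = False,
) -> pd.DataFrame:
    """Run the full heat-map -> circle -> inversion chain for each delta_t.

    Returns a tidy table with one row per delta_t (columns of
    :class:`KineticFit` plus an ``error`` column); a failure at one delta_t
    is recorded and the sweep continues.
    """
    rows = []
    for dt_val in delta_ts:
        model = ArrivalCircleModel(
            dataset,
            delta_v0=delta_v0,
            v0_range=v0_range,
            cell_factor=cell_factor,
            c=c,
            lag=lag,
            strict_adjacency=strict_adjacency,
        )
        try:
            res = model.fit(dt_val, v0_max=v0_max)
            row = _fit_to_row(res.fit_)
            row["error"] = ""
        except (ValueError, EmptyHeatMapError) as exc:
            warnings.warn(f"delta_t={dt_val}: {exc}", stacklevel=2)
            row = {"delta_t": dt_val, "error": str(exc)}
        rows.append(row)
    columns = ["delta_t", "slope", "alpha", "mean_r_c", "vmax", "v0_max_fit", "n_bins_used", "error"]
    return pd.DataFrame(rows).reindex(columns=columns)


class ArrivalCircleModel:
    """Kinetic-parameter estimator for the FS model on tracking data.

    Parameters
    ----------
    data : TrackingDataset or SprintEnsemble or sequence of SprintEnsemble
        Tracking data (goalkeepers excluded automatically) or idealized
        sprint ensembles.
    delta_v0 : float
        Initial-speed bin width, m/s (0.3 m/s ~ 1 km/h).
    v0_range : (float, float)
        Speed range covered by the bins, m/s.
    cell_factor : float
        Heat-map cell side as a multiple of delta_t (0.2 -> cells of
        0.2*delta_t m).
    c : int or "auto"
        Isolated-cell threshold; "auto" applies the delta_t-dependent
        default (8/6/4).  Use 0 to disable filtering.
    lag : float
        Velocity-difference lag, s (tracking data only).
    strict_adjacency : bool
        Require strictly more than c occupied neighbours instead of at
        least c.

    Examples
    --------
    >>> model = ArrivalCircleModel(dataset)            # doctest: +SKIP
    >>> res = model.fit(delta_t=1.0)                   # doctest: +SKIP
    >>> res.alpha, res.vmax                            # doctest: +SKIP
    """

    def __init__(
        self,
        data: Union[TrackingDataset, SprintEnsemble, Sequence[SprintEnsemble]],
        delta_v0: float = 0.3,
        v0_range: Tuple[float, float] = (0.0, 9.0),
        cell_factor: float = 0.2,
        c: Union[int, str] = "auto",
        lag: float = 1.0,
        strict_adjacency: bool = False,
    ):
        if delta_v0 <= 0:
            raise ValueError("delta_v0 must be > 0")
        if cell_factor <= 0:
            raise ValueError("cell_factor must be > 0")
        self.data = data
        self.delta_v0 = float(delta_v0)
        self.v0_range = (float(v0_range[0]), float(v0_range[1]))
        self.cell_factor = float(cell_factor)
        self.c = c
        self.lag = float(lag)
        self.strict_adjacency = bool(strict_adjacency)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ArrivalCircleModel":
        """Build from a tidy tracking frame (see :mod:`fsmotion.data`)."""
        return cls(TrackingDataset.from_dataframe(df), **kwargs)

    def _bin_edges(self) -> np.ndarray:
        lo, hi = self.v0_range
        n = int(math.ceil((hi - lo) / self.delta_v0 - 1e-9))
        return lo + self.delta_v0 * np.arange(n + 1)

    def _resolve_c(self, delta_t: float) -> int:
        return default_c(delta_t) if self.c == "auto" else int(self.c)

    def estimate_circles(self, delta_t: float) -> List[CircleEstimate]:
        """Heat map + filter + circle estimate for every v0 bin.

        Bins whose filtered heat map is empty are skipped (with a warning).
        """
        cell = self.cell_factor * delta_t
        c_val = self._resolve_c(delta_t)
        edges = self._bin_edges()

        if isinstance(self.data, TrackingDataset):
            obs = arrival_observations(self.data, delta_t, lag=self.lag)
            sources: List[Tuple[Tuple[float, float], object]] = [
                ((edges[i], edges[i + 1]), obs) for i in range(len(edges) - 1)
            ]
        else:
            ensembles = (
                [self.data] if isinstance(self.data, SprintEnsemble) else list(self.data)
            )
            sources = []
            for ens in ensembles:
                lo = edges[np.searchsorted(edges, ens.v0, side="right") - 1]
                sources.append(((float(lo), float(lo + self.delta_v0)), ens))

        estimates: List[CircleEstimate] = []
        skipped = []
        for v0_bin, src in sources:
            grid = build_heatmap(src, delta_t, v0_bin, cell_size=cell)
            grid = filter_isolated_cells(grid, c_val, strict=self.strict_adjacency)
            if grid.is_empty:
                skipped.append(v0_bin)
                continue
            estimates.append(circle_from_extent(grid))
        if skipped:
            warnings.warn(
                f"delta_t={delta_t}: {len(skipped)} empty v0 bins skipped: {skipped}",
                stacklevel=2,
            )
        return estimates

    def fit(self, delta_t: float, v0_max: float = 6.0, through_origin: bool = True) -> "ArrivalCircleResults":
        """Estimate (alpha, vmax) at one delta_t."""
        circles = self.estimate_circles(delta_t)
        fit = estimate_params(
            circles, delta_t, v0_max=v0_max, through_origin=through_origin
        )
        return ArrivalCircleResults(model=self, fit_=fit, circles=circles)

    def fit_sweep(self, delta_ts: Sequence[float], v0_max: float = 6.0) -> pd.DataFrame:
        """Fit every delta_t; returns the tidy sweep table."""
        rows = []
        for dt_val in delta_ts:
            try:
                res = self.fit(dt_val, v0_max=v0_max)
                row = _fit_to_row(res.fit_)
                row["error"] = ""
            except (ValueError, EmptyHeatMapError) as exc:
                warnings.warn(f"delta_t={dt_val}: {exc}", stacklevel=2)
                row = {"delta_t": dt_val, "error": str(exc)}
            rows.append(row)
        columns = [
            "delta_t", "slope", "alpha", "mean_r_c", "vmax", "v0_max_fit",
            "n_bins_used", "error",
        ]
        return pd.DataFrame(rows).reindex(columns=columns)


@dataclass
class ArrivalCircleResults:
    """Fitted kinetic parameters at one delta_t, with diagnostics."""

    model: ArrivalCircleModel
    fit_: KineticFit
    circles: List[CircleEstimate] = field(default_factory=list)

    @property
    def delta_t(self) -> float:
        return self.fit_.delta_t

    @property
    def alpha(self) -> float:
        return self.fit_.alpha

    @property
    def vmax(self) -> float:
        return self.fit_.vmax

    @property
    def slope(self) -> float:
        return self.fit_.slope

    @property
    def mean_r_c(self) -> float:
        return self.fit_.mean_r_c

    @property
    def params(self) -> KineticParams:
        return self.fit_.params

    def circles_frame(self) -> pd.DataFrame:
        """Per-bin circle table (v0 bin, center, radius, counts, extents)."""
        return pd.DataFrame(
            {
                "v0_lo": [e.v0_bin[0] for e in self.circles],
                "v0_hi": [e.v0_bin[1] for e in self.circles],
                "v0_mid": [e.v0_mid for e in self.circles],
                "x_c": [e.x_c for e in self.circles],
                "y_c": [e.y_c for e in self.circles],
                "r_c": [e.r_c for e in self.circles],
                "n_points": [e.n_points for e in self.circles],
            }
        )

    def _qualifying(self) -> List[CircleEstimate]:
        return _qualifying(self.circles, self.fit_.v0_max_fit)

    @property
    def slope_se(self) -> float:
        """Standard error of the through-origin regression slope."""
        qual = self._qualifying()
        v = np.array([e.v0_mid for e in qual])
        x = np.array([e.x_c for e in qual])
        resid = x - self.slope * v
        dof = max(len(v) - 1, 1)
        return float(math.sqrt(resid @ resid / dof / (v @ v)))

    @property
    def alpha_se(self) -> float:
        """Delta-method propagation of the slope SE through the inversion."""
        a, t = self.alpha, self.delta_t
        dA_dalpha = (math.exp(-a * t) * (1 + a * t) - 1.0) / a**2  # < 0
        return float(abs(self.slope_se / dA_dalpha))

    @property
    def r_c_se(self) -> float:
        qual = self._qualifying()
        r = np.array([e.r_c for e in qual])
        if len(r) < 2:
            return math.nan
        return float(r.std(ddof=1) / math.sqrt(len(r)))

    @property
    def vmax_se(self) -> float:
        """First-order propagation from the radius SE (alpha held fixed)."""
        denom = self.delta_t - coef_A(self.alpha, self.delta_t)
        return float(self.r_c_se / denom)

    def predict_circle(self, v0: float) -> ArrivalCircle:
        """Model arrival circle for initial speed v0 along +x."""
        return arrival_circle(np.array([v0, 0.0]), self.params, self.delta_t)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        f = self.fit_
        lines = [
            "FS arrival-circle kinetic parameter fit",
            "=" * 55,
            f"delta_t:              {f.delta_t:10.3f}  s",
            f"v0 bins used:         {f.n_bins_used:10d}  (v0 <= {f.v0_max_fit:g} m/s)",
            f"slope A(alpha, dt):   {f.slope:10.4f}  +/- {self.slope_se:.4f}  s",
            f"alpha:                {f.alpha:10.4f}  +/- {self.alpha_se:.4f}  1/s",
            f"mean r_c:             {f.mean_r_c:10.4f}  +/- {self.r_c_se:.4f}  m",
            f"vmax:                 {f.vmax:10.4f}  +/- {self.vmax_se:.4f}  m/s",
            "=" * 55,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        f = self.fit_
        return (
            f"<ArrivalCircleResults delta_t={f.delta_t:g} alpha={f.alpha:.3f} "
            f"vmax={f.vmax:.3f}>"
        )
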