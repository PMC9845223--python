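"""Seeded synthetic tracking-data generator.

Real match tracking data are proprietary, so every downstream stage of the
pipeline is exercised on synthetic data that reproduces the statistical
structure observed in matches:

* 0.04 s sampling in contiguous play segments;
* a bimodal speed distribution with walking (~1 m/s) and jogging (~3 m/s)
  peaks and a near-exponential tail up to sprint speeds;
* persistence: each player holds an approximately straight course for runs
  of order 10 s before changing direction at random (giving the ballistic ->
  diffusive MSD crossover);
* isotropic positional noise of order +/- 1 m (optical-tracking accuracy).

Players are simulated as self-propelled particles obeying the FS equation of
motion with piecewise-constant parameters: a three-state behavioural Markov
chain (walk / jog / sprint) sets the kinetic parameters (alpha, vmax), and an
independent renewal process with exponential run times redraws the driving
direction uniformly.  Within each constant-(state, direction) run the exact
closed-form solution is used, so sprint intervals satisfy the FS solution
exactly before noise is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .data import COLUMNS, DEFAULT_SAMPLE_INTERVAL, PlaySegment, TrackingDataset
from .motion import KineticParams, coef_A

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "SprintEnsemble",
    "generate_dataset",
    "generate_sprint_ensemble",
    "add_noise",
]

STATES = ("walk", "jog", "sprint")


class ConfigError(ValueError):
    """Invalid generator configuration; ``fields`` lists the offending keys."""

    def __init__(self, errors: Dict[str, str]):
        self.fields = sorted(errors)
        super().__init__("; ".join(f"{k}: {v}" for k, v in sorted(errors.items())))


def _default_state_params() -> Dict[str, KineticParams]:
    # Terminal speeds set the walking / jogging peaks and the sprint top
    # speed; alpha = 1.3 1/s is the reference sprint responsiveness.
    return {
        "walk": KineticParams(alpha=1.3, vmax=1.0),
        "jog": KineticParams(alpha=1.3, vmax=3.0),
        "sprint": KineticParams(alpha=1.3, vmax=8.0),
    }


def _default_state_dwell() -> Dict[str, float]:
    # Mean dwell times (s): long walking spells, shorter jogs, brief sprints.
    # The implied time occupancy (~80% walk, ~20% jog, ~0.5% sprint) follows
    # time-motion studies of match play, where standing/walking dominates and
    # true sprinting is a small fraction of playing time; it also keeps the
    # long-lag MSD diffusive on a pitch-sized domain.
    return {"walk": 40.0, "jog": 10.0, "sprint": 2.0}


def _default_state_transitions() -> Dict[str, Dict[str, float]]:
    return {
        "walk": {"jog": 0.94, "sprint": 0.06},
        "jog": {"walk": 0.94, "sprint": 0.06},
        "sprint": {"jog": 0.5, "walk": 0.5},
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic match generator.

    Defaults describe one team's outfield players over a full match split
    into play segments, with TRACAB-like sampling and noise.
    """

    n_outfield: int = 20
    include_goalkeeper: bool = True
    n_segments: int = 6
    segment_duration: float = 600.0  # s
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL  # s
    state_params: Dict[str, KineticParams] = field(default_factory=_default_state_params)
    state_mean_dwell: Dict[str, float] = field(default_factory=_default_state_dwell)
    state_transitions: Dict[str, Dict[str, float]] = field(
        default_factory=_default_state_transitions
    )
    mean_run_duration: float = 10.0  # s, mean straight-line run before a turn
    redraw_direction_on_sprint: bool = True  # sprints start toward a new target
    # Turns are speed-limited: the new heading deviates by at most
    # pi * min(1, turn_speed_scale / speed), so slow players turn anywhere
    # while fast players cannot reverse without braking first.
    turn_speed_scale: float = 1.5  # m/s
    noise_sigma: float = 0.5  # m; 2*sigma = 1 m matches +/-1 m accuracy
    noise_model: str = "gaussian"  # or "uniform_disc"
    # Optical-tracking error is temporally smooth: the +/-1 m figure is an
    # absolute accuracy, not per-frame jitter (white +/-1 m noise at 25 Hz
    # would erase the observed walking-speed peak).  Positional errors are
    # therefore AR(1)-correlated with this timescale; 0 means white noise.
    noise_correlation_time: float = 15.0  # s
    pitch_bounds: Tuple[float, float] = (105.0, 68.0)  # m (x span, y span)
    boundary_margin: float = 2.0  # m; direction resampled toward interior
    seed: int = 0
    # Sprint-validation scenario: instead of the behavioural Markov chain,
    # players alternate long steady cruises at a uniform-random target speed
    # with full-drive sprints in a fresh uniform direction.  This populates
    # every initial-speed bin with quasi-steady motion and sprint departures
    # at all angles -- the regime the arrival-circle estimator is built for.
    cruise_speed_range: Optional[Tuple[float, float]] = None  # m/s; None = Markov chain
    cruise_mean_dwell: float = 8.0  # s

    @classmethod
    def sprint_validation(
        cls,
        n_outfield: int = 20,
        n_segments: int = 6,
        segment_duration: float = 600.0,
        sprint_params: Optional[KineticParams] = None,
        noise_sigma: float = 0.5,
        seed: int = 0,
        **kwargs,
    ) -> "GeneratorConfig":
        """Configuration for validating kinetic-parameter recovery.

        Cruise speeds are drawn uniformly over the fitted v0 range so every
        speed bin holds a steady population, and sprints (default alpha =
        1.3 1/s, vmax = 8 m/s) leave each cruise in a uniformly random
        direction, tracing the full arrival circle.
        """
        sprint = sprint_params or KineticParams(alpha=1.3, vmax=8.0)
        params = _default_state_params()
        params["sprint"] = sprint
        return cls(
            n_outfield=n_outfield,
            n_segments=n_segments,
            segment_duration=segment_duration,
            state_params=params,
            noise_sigma=noise_sigma,
            cruise_speed_range=(0.2, 6.5),
            cruise_mean_dwell=8.0,
            state_mean_dwell={"walk": 10.0, "jog": 4.0, "sprint": 2.5},
            seed=seed,
            **kwargs,
        )

    def validate(self) -> None:
        errors: Dict[str, str] = {}
        if self.n_outfield < 1:
            errors["n_outfield"] = "must be >= 1"
        if self.n_segments < 1:
            errors["n_segments"] = "must be >= 1"
        if self.segment_duration < 2.0:
            errors["segment_duration"] = "must be >= 2 s (1 s velocity lag + 1 arrival interval)"
        if self.sample_interval <= 0:
            errors["sample_interval"] = "must be > 0"
        if self.mean_run_duration <= 0:
            errors["mean_run_duration"] = "must be > 0"
        if self.noise_sigma < 0:
            errors["noise_sigma"] = "must be >= 0"
        if self.noise_model not in ("gaussian", "uniform_disc"):
            errors["noise_model"] = "must be 'gaussian' or 'uniform_disc'"
        if any(b <= 0 for b in self.pitch_bounds):
            errors["pitch_bounds"] = "spans must be > 0"
        if self.boundary_margin < 0:
            errors["boundary_margin"] = "must be >= 0"
        for s in STATES:
            if s not in self.state_params:
                errors[f"state_params[{s}]"] = "missing"
        for s in self.state_params:
            if self.state_mean_dwell.get(s, 0) <= 0:
                errors[f"state_mean_dwell[{s}]"] = "must be > 0"
            probs = self.state_transitions.get(s, {})
            unknown = set(probs) - set(self.state_params)
            if unknown:
                errors[f"state_transitions[{s}]"] = f"unknown states {sorted(unknown)}"
            total = sum(probs.values())
            if probs and (any(p < 0 for p in probs.values()) or abs(total - 1.0) > 1e-9):
                errors[f"state_transitions[{s}]"] = "probabilities must be >= 0 and sum to 1"
        if self.cruise_speed_range is not None:
            lo, hi = self.cruise_speed_range
            if not (0 <= lo < hi):
                errors["cruise_speed_range"] = "must satisfy 0 <= lo < hi"
            if self.cruise_mean_dwell <= 0:
                errors["cruise_mean_dwell"] = "must be > 0"
        if errors:
            raise ConfigError(errors)


def _closed_form_block(
    pos: np.ndarray,
    vel: np.ndarray,
    params: KineticParams,
    n_hat: np.ndarray,
    s: np.ndarray,
) -> np.ndarray:
    """Positions at elapsed times ``s`` from (pos, vel) under constant drive."""
    e = np.exp(-params.alpha * s)
    a = (1.0 - e) / params.alpha
    b = params.vmax * (s - a)
    return pos[None, :] + a[:, None] * vel[None, :] + b[:, None] * n_hat[None, :]


def _velocity_after(
    vel: np.ndarray, params: KineticParams, n_hat: np.ndarray, s: float
) -> np.ndarray:
    e = math.exp(-params.alpha * s)
    return vel * e + params.vmax * (1.0 - e) * n_hat


def _fold_into_box(xy: np.ndarray, bounds: Tuple[float, float]) -> np.ndarray:
    """Specular reflection of a free-space path into the pitch box.

    Each coordinate is folded with the triangle map of period ``2 * span``,
    which is exactly the path of a billiard reflecting off the walls.
    """
    out = np.empty_like(xy)
    for axis, span in enumerate(bounds):
        h = span / 2.0
        y = np.mod(xy[:, axis] + h, 2.0 * span)
        out[:, axis] = np.where(y < span, y - h, 3.0 * h - y)
    return out


def _uniform_direction(rng: np.random.Generator) -> np.ndarray:
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([math.cos(phi), math.sin(phi)])


def _turn_direction(
    rng: np.random.Generator,
    n_hat: np.ndarray,
    speed: float,
    turn_speed_scale: float,
) -> np.ndarray:
    """New heading after a turn, with a speed-limited maximum deflection."""
    if turn_speed_scale <= 0:
        return _uniform_direction(rng)
    max_turn = math.pi * min(1.0, turn_speed_scale / max(speed, 1e-9))
    dphi = rng.uniform(-max_turn, max_turn)
    c, s = math.cos(dphi), math.sin(dphi)
    return np.array([c * n_hat[0] - s * n_hat[1], s * n_hat[0] + c * n_hat[1]])


def _simulate_player(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    n_frames: int,
    bounds: Tuple[float, float],
    states: Optional[Tuple[str, ...]] = None,
) -> np.ndarray:
    """Noise-free trajectory of one player: (n_frames, 2) positions.

    Dynamics run in free space (exact closed form per constant-drive run);
    the finished path is folded into the pitch box by specular reflection,
    so straight runs stay straight up to wall bounces.
    """
    dt = cfg.sample_interval
    if states is None:
        states = tuple(cfg.state_params)
    hx, hy = bounds[0] / 2.0, bounds[1] / 2.0
    margin = min(cfg.boundary_margin, hx / 2.0, hy / 2.0)

    pos = np.array(
        [
            rng.uniform(-hx + margin, hx - margin),
            rng.uniform(-hy + margin, hy - margin),
        ]
    )
    state = states[rng.integers(len(states))]
    params = cfg.state_params[state]
    n_hat = _uniform_direction(rng)
    vel = params.vmax * n_hat

    t_dir = rng.exponential(cfg.mean_run_duration)
    t_state = rng.exponential(cfg.state_mean_dwell[state])

    out = np.empty((n_frames, 2))
    out[0] = pos
    next_frame = 1  # index of next frame to record
    t = 0.0
    t_total = (n_frames - 1) * dt
    while next_frame < n_frames:
        block = max(min(t_dir, t_state, t_total - t), 1e-9)
        # frames falling in (t, t + block]
        k_last = min(int(math.floor((t + block) / dt + 1e-9)), n_frames - 1)
        if k_last >= next_frame:
            s = (np.arange(next_frame, k_last + 1) * dt) - t
            out[next_frame : k_last + 1] = _closed_form_block(pos, vel, params, n_hat, s)
            next_frame = k_last + 1
        # advance the continuous state to the block end
        new_pos = _closed_form_block(pos, vel, params, n_hat, np.array([block]))[0]
        vel = _velocity_after(vel, params, n_hat, block)
        pos = new_pos
        t += block
        t_dir -= block
        t_state -= block

        speed = float(np.linalg.norm(vel))
        if t_dir <= 1e-12:
            n_hat = _turn_direction(rng, n_hat, speed, cfg.turn_speed_scale)
            t_dir = rng.exponential(cfg.mean_run_duration)
        if t_state <= 1e-12:
            probs = cfg.state_transitions[state]
            names = [s_ for s_ in probs if s_ in states]
            p = np.array([probs[s_] for s_ in names])
            p = p / p.sum()
            new_state = names[rng.choice(len(names), p=p)]
            if (
                cfg.redraw_direction_on_sprint
                and new_state == "sprint"
                and state != "sprint"
            ):
                # sprints are directed at a fresh target
                n_hat = _turn_direction(rng, n_hat, speed, cfg.turn_speed_scale)
                t_dir = rng.exponential(cfg.mean_run_duration)
            state = new_state
            params = cfg.state_params[state]
            t_state = rng.exponential(cfg.state_mean_dwell[state])
    return _fold_into_box(out, bounds)


def _simulate_player_validation(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    n_frames: int,
    bounds: Tuple[float, float],
) -> np.ndarray:
    """Sprint-validation trajectory: steady cruises + full-drive sprints.

    Spells alternate cruise (terminal speed uniform over
    ``cruise_speed_range``, exponential dwell ``cruise_mean_dwell``) and
    sprint (``state_params['sprint']``, exponential dwell
    ``state_mean_dwell['sprint']``); the drive direction is redrawn
    uniformly at every spell switch and held within spells.
    """
    dt = cfg.sample_interval
    hx, hy = bounds[0] / 2.0, bounds[1] / 2.0
    lo, hi = cfg.cruise_speed_range
    sprint = cfg.state_params["sprint"]
    sprint_dwell = cfg.state_mean_dwell["sprint"]

    pos = np.array([rng.uniform(-hx, hx), rng.uniform(-hy, hy)])
    n_hat = _uniform_direction(rng)
    params = KineticParams(sprint.alpha, max(rng.uniform(lo, hi), 1e-3))
    vel = params.vmax * n_hat
    sprinting = False
    t_state = rng.exponential(cfg.cruise_mean_dwell)

    out = np.empty((n_frames, 2))
    out[0] = pos
    next_frame = 1
    t = 0.0
    t_total = (n_frames - 1) * dt
    while next_frame < n_frames:
        block = max(min(t_state, t_total - t), 1e-9)
        k_last = min(int(math.floor((t + block) / dt + 1e-9)), n_frames - 1)
        if k_last >= next_frame:
            s = (np.arange(next_frame, k_last + 1) * dt) - t
            out[next_frame : k_last + 1] = _closed_form_block(pos, vel, params, n_hat, s)
            next_frame = k_last + 1
        pos = _closed_form_block(pos, vel, params, n_hat, np.array([block]))[0]
        vel = _velocity_after(vel, params, n_hat, block)
        t += block
        t_state -= block
        if t_state <= 1e-12:
            sprinting = not sprinting
            n_hat = _uniform_direction(rng)
            if sprinting:
                params = sprint
                t_state = rng.exponential(sprint_dwell)
            else:
                params = KineticParams(sprint.alpha, max(rng.uniform(lo, hi), 1e-3))
                t_state = rng.exponential(cfg.cruise_mean_dwell)
    return _fold_into_box(out, bounds)


def _gk_config(cfg: GeneratorConfig) -> GeneratorConfig:
    """Goalkeeper variant: no sprint state, confined near the goal."""
    return replace(cfg, state_transitions={
        "walk": {"jog": 1.0},
        "jog": {"walk": 1.0},
        "sprint": {"walk": 1.0},
    })


def generate_dataset(config: GeneratorConfig) -> TrackingDataset:
    """Generate a seeded synthetic tracking dataset.

    Deterministic given ``config.seed``.  Outfield players roam the full
    pitch; the optional goalkeeper (one per dataset, role ``"GK"``) walks and
    jogs inside a box near its goal line.  Positional noise per
    :func:`add_noise` is applied last.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.sample_interval
    n_frames = int(round(config.segment_duration / dt)) + 1

    segments = []
    for si in range(config.n_segments):
        rows = []
        for pi in range(config.n_outfield):
            if config.cruise_speed_range is not None:
                xy = _simulate_player_validation(rng, config, n_frames, config.pitch_bounds)
            else:
                xy = _simulate_player(rng, config, n_frames, config.pitch_bounds)
            rows.append(
                (f"P{pi + 1:02d}", "A" if pi % 2 == 0 else "B", "OUT", xy)
            )
        if config.include_goalkeeper:
            gk_bounds = (config.pitch_bounds[0] / 3.0, config.pitch_bounds[1] / 2.0)
            xy = _simulate_player(
                rng, _gk_config(config), n_frames, gk_bounds, states=("walk", "jog")
            )
            xy = xy + np.array([-config.pitch_bounds[0] / 3.0, 0.0])
            rows.append(("GK1", "A", "GK", xy))

        times = np.round(np.arange(n_frames) * dt, 9)
        frames = []
        for pid, team, role, xy in rows:
            frames.append(
                pd.DataFrame(
                    {
                        "segment_id": f"S{si + 1:02d}",
                        "time_s": times,
                        "player_id": pid,
                        "team": team,
                        "role": role,
                        "x_m": xy[:, 0],
                        "y_m": xy[:, 1],
                    }
                )
            )
        seg = PlaySegment(
            segment_id=f"S{si + 1:02d}",
            data=pd.concat(frames, ignore_index=True)[COLUMNS],
            sample_interval=dt,
        )
        if config.noise_sigma > 0:
            seg = add_noise(
                seg,
                config.noise_sigma,
                rng=rng,
                model=config.noise_model,
                correlation_time=config.noise_correlation_time,
            )
        segments.append(seg)
    return TrackingDataset(segments, dt)


def add_noise(
    segment: PlaySegment,
    noise_sigma: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    model: str = "gaussian",
    correlation_time: float = 0.0,
) -> PlaySegment:
    """Add isotropic zero-mean positional noise of stationary std ``noise_sigma``.

    By default the noise is independent per sample.  With the Gaussian model
    and the default sigma of 0.5 m, about 95% of per-axis errors fall within
    +/- 1 m, matching the stated accuracy of optical tracking.
    ``model="uniform_disc"`` draws uniformly from a disc of radius
    ``2 * noise_sigma`` instead.

    ``correlation_time > 0`` (Gaussian model only) makes the error of each
    player an AR(1) process with that timescale -- per-frame jitter is then
    much smaller than the stationary error, as in real optical tracking.
    """
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    if noise_sigma == 0:
        return segment
    if rng is None:
        rng = np.random.default_rng(seed)
    data = segment.data.copy()
    n = len(data)
    if model == "gaussian":
        if correlation_time > 0:
            offsets = np.empty((n, 2))
            rho = math.exp(-segment.sample_interval / correlation_time)
            innov = math.sqrt(1.0 - rho * rho)
            # per-player AR(1) series; data is sorted by (player, time)
            from scipy.signal import lfilter

            for _, idx in data.groupby("player_id").indices.items():
                m = len(idx)
                white = rng.normal(0.0, noise_sigma, size=(m, 2))
                driven = innov * white
                driven[0] = white[0]  # start in the stationary distribution
                offsets[idx] = lfilter([1.0], [1.0, -rho], driven, axis=0)
        else:
            offsets = rng.normal(0.0, noise_sigma, size=(n, 2))
    elif model == "uniform_disc":
        r = 2.0 * noise_sigma * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
        offsets = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    else:
        raise ValueError(f"unknown noise model {model!r}")
    data["x_m"] = data["x_m"].to_numpy() + offsets[:, 0]
    data["y_m"] = data["y_m"].to_numpy() + offsets[:, 1]
    return PlaySegment(segment.segment_id, data, segment.sample_interval)


@dataclass
class SprintEnsemble:
    """Idealized sprint observations for validating the heat-map stages.

    Each row is one (state at t, position at t + delta_t) pair drawn from the
    FS closed form: a player moving at speed ``v0`` sprints at full drive in
    a direction ``n_hat`` for ``delta_t`` seconds.  ``pos0``/``vel0`` give
    the state at t, ``pos1`` the (optionally noisy) position at t + delta_t.
    """

    pos0: np.ndarray  # (n, 2) m
    vel0: np.ndarray  # (n, 2) m/s
    pos1: np.ndarray  # (n, 2) m
    params: KineticParams
    v0: float
    delta_t: float

    def __len__(self) -> int:
        return len(self.pos0)


def generate_sprint_ensemble(
    params: KineticParams,
    v0: float,
    delta_t: float,
    n_directions: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    noise_sigma: float = 0.0,
    random_orientation: bool = True,
) -> SprintEnsemble:
    """Exact-solution sprint pairs over ``n_directions`` uniform directions.

    Drive directions are evenly spaced over the circle (relative to the
    initial velocity), so noise-free arrival points sample the arrival
    circle uniformly.  With ``random_orientation`` each observation gets an
    independent random absolute heading, exercising the velocity-frame
    rotation downstream; Gaussian noise of ``noise_sigma`` per axis is added
    to the arrival position only.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    if v0 < 0:
        raise ValueError("v0 must be >= 0")
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    theta = 2.0 * math.pi * np.arange(n_directions) / n_directions
    if random_orientation:
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n_directions)
    else:
        phi = np.zeros(n_directions)

    a = coef_A(params.alpha, delta_t)
    b = params.vmax * (delta_t - a)

    cos_p, sin_p = np.cos(phi), np.sin(phi)
    vel0 = v0 * np.column_stack([cos_p, sin_p])
    # displacement in the body frame (velocity along +x), rotated to absolute
    dx_body = a * v0 + b * np.cos(theta)
    dy_body = b * np.sin(theta)
    disp = np.column_stack(
        [cos_p * dx_body - sin_p * dy_body, sin_p * dx_body + cos_p * dy_body]
    )
    pos0 = np.zeros((n_directions, 2))
    pos1 = pos0 + disp
    if noise_sigma > 0:
        pos1 = pos1 + rng.normal(0.0, noise_sigma, size=pos1.shape)
    return SprintEnsemble(
        pos0=pos0, vel0=vel0, pos1=pos1, params=params, v0=v0, delta_t=delta_t
    )
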