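"""Containers for player tracking data.

Tracking data are per-frame absolute pitch coordinates (x, y) in metres for
each player, sampled at a uniform interval (0.04 s for optical systems such
as TRACAB) and organized in contiguous *play segments* -- the stretch of
play from a restart to a time-out.  The canonical in-memory form is a tidy
:class:`pandas.DataFrame` with columns::

    segment_id, time_s, player_id, team, role, x_m, y_m

where ``role`` is ``"GK"`` (goalkeeper) or ``"OUT"`` (outfield).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Sequence

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "ROLES", "PlaySegment", "TrackingDataset"]

COLUMNS = ["segment_id", "time_s", "player_id", "team", "role", "x_m", "y_m"]
ROLES = ("GK", "OUT")

#: Default sampling interval of optical tracking systems, s.
DEFAULT_SAMPLE_INTERVAL = 0.04

_TIME_TOL = 1e-6


@dataclass
class PlaySegment:
    """One contiguous play segment: frames for all players between two stops.

    ``data`` holds the tidy frame (sorted by player then time);
    ``sample_interval`` is the uniform frame spacing in seconds.
    """

    segment_id: str
    data: pd.DataFrame
    sample_interval: float

    @property
    def duration(self) -> float:
        """Segment length T in seconds (first to last frame)."""
        t = self.data["time_s"]
        return float(t.max() - t.min())

    @property
    def player_ids(self) -> List[str]:
        return sorted(self.data["player_id"].unique())

    def player_positions(self, player_id: str) -> pd.DataFrame:
        """Frames of one player, sorted by time."""
        sub = self.data[self.data["player_id"] == player_id]
        return sub.sort_values("time_s").reset_index(drop=True)

    def validate(self) -> None:
        """Check per-player uniform, strictly increasing time grids."""
        for pid, sub in self.data.groupby("player_id"):
            t = np.sort(sub["time_s"].to_numpy())
            if len(t) < 2:
                continue
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError(
                    f"segment {self.segment_id!r}: non-increasing times for player {pid!r}"
                )
            if np.any(np.abs(dt - self.sample_interval) > _TIME_TOL):
                raise ValueError(
                    f"segment {self.segment_id!r}: non-uniform sampling for player {pid!r}"
                )


class TrackingDataset:
    """A collection of play segments sharing one sampling interval."""

    def __init__(self, segments: Sequence[PlaySegment], sample_interval: float):
        if sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        self.segments: List[PlaySegment] = list(segments)
        self.sample_interval = float(sample_interval)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[PlaySegment]:
        return iter(self.segments)

    @property
    def total_duration(self) -> float:
        """Summed segment durations, s."""
        return float(sum(seg.duration for seg in self.segments))

    def to_dataframe(self) -> pd.DataFrame:
        """Concatenate all segments into one tidy frame (deterministic order)."""
        if not self.segments:
            return pd.DataFrame(columns=COLUMNS)
        frames = [seg.data[COLUMNS] for seg in self.segments]
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, sample_interval: float | None = None
    ) -> "TrackingDataset":
        """Build a dataset from a tidy frame, inferring the sampling interval
        from the smallest positive time step if not given."""
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        bad_roles = set(df["role"].unique()) - set(ROLES)
        if bad_roles:
            raise ValueError(f"invalid role values: {sorted(bad_roles)} (expected {ROLES})")
        if sample_interval is None:
            diffs = (
                df.sort_values(["segment_id", "player_id", "time_s"])
                .groupby(["segment_id", "player_id"])["time_s"]
                .diff()
                .dropna()
            )
            if diffs.empty:
                sample_interval = DEFAULT_SAMPLE_INTERVAL
            else:
                sample_interval = float(diffs[diffs > 0].min())
        segments = []
        for seg_id, sub in df.groupby("segment_id", sort=True):
            seg = PlaySegment(
                segment_id=str(seg_id),
                data=sub.sort_values(["player_id", "time_s"]).reset_index(drop=True),
                sample_interval=sample_interval,
            )
            seg.validate()
            segments.append(seg)
        return cls(segments, sample_interval)
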