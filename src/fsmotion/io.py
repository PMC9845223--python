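"""Reading and writing tracking CSV files and report tables.

Tracking CSV schema (header required)::

    segment_id,time_s,player_id,team,role,x_m,y_m

``role`` is ``GK`` or ``OUT``; ``time_s`` is in seconds on a uniform grid
(0.04 s by default); positions are metres in pitch-centered coordinates.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data import COLUMNS, ROLES, PlaySegment, TrackingDataset

__all__ = ["read_tracking", "write_tracking", "write_report", "SchemaError"]

PathLike = Union[str, os.PathLike]


class SchemaError(ValueError):
    """Tracking file violates the CSV schema; message names column and line."""


_NUMERIC = ("time_s", "x_m", "y_m")


def read_tracking(path: PathLike, sample_interval: Optional[float] = None) -> TrackingDataset:
    """Read and validate a tracking CSV.

    Raises :class:`SchemaError` naming the offending column and 1-based file
    line for malformed rows, and :class:`ValueError` naming the segment for
    non-uniform time grids.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(raw) == 0:
        raise SchemaError(f"{path}: no data rows")

    df = raw.copy()
    for col in _NUMERIC:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SchemaError(
                f"{path}: column {col!r}, line {line}: "
                f"invalid value {raw[col][bad.idxmax()]!r}"
            )
        df[col] = converted
    bad_role = ~raw["role"].isin(ROLES)
    if bad_role.any():
        line = int(bad_role.idxmax()) + 2
        raise SchemaError(
            f"{path}: column 'role', line {line}: "
            f"invalid value {raw['role'][bad_role.idxmax()]!r} (expected GK or OUT)"
        )
    return TrackingDataset.from_dataframe(df[COLUMNS], sample_interval=sample_interval)


def write_tracking(dataset: TrackingDataset, path: PathLike) -> None:
    """Write a dataset as tracking CSV with deterministic column/row order."""
    df = dataset.to_dataframe()
    df = df.sort_values(["segment_id", "player_id", "time_s"], kind="mergesort")
    df.to_csv(path, index=False, columns=COLUMNS)


def write_report(
    fits: pd.DataFrame,
    circles: pd.DataFrame,
    out_dir: PathLike,
) -> List[str]:
    """Write the per-delta_t kinetic-fit table and per-bin circle table.

    Returns the written file paths.  Re-running with identical inputs
    produces byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name, table in (("kinetic_fits.csv", fits), ("circle_estimates.csv", circles)):
        p = os.path.join(out_dir, name)
        table.to_csv(p, index=False)
        paths.append(p)
    return paths


def write_heatmap_grid(grid, path: PathLike) -> None:
    """Export one heat map as a dense CSV matrix with a small header block."""
    with open(path, "w") as fh:
        fh.write(f"# delta_t: {grid.delta_t}\n")
        fh.write(f"# v0_bin: {grid.v0_bin[0]},{grid.v0_bin[1]}\n")
        fh.write(f"# cell_size: {grid.cell_size}\n")
        fh.write(f"# origin_index: {grid.i0},{grid.j0}\n")
        np.savetxt(fh, grid.counts, fmt="%d", delimiter=",")
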