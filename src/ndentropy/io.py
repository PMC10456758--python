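"""Trajectory CSV dialect.

Coordinate tables carry one row per agent per frame with columns
``frame, id, x, y`` and optional ``vx, vy``.  Frames are analyzed
independently, so unlinked detections (ids reused arbitrarily across frames)
are acceptable input.  Unknown extra columns are preserved on round trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .neighbors import PointSet

REQUIRED_COLUMNS = ("frame", "id", "x", "y")
VELOCITY_COLUMNS = ("vx", "vy")


def validate_trajectory(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing}")
    if len(table) == 0:
        raise FormatError("trajectory table has no rows")
    dup = table.duplicated(subset=["frame", "id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        pair = (int(table.iloc[row]["frame"]), int(table.iloc[row]["id"]))
        raise FormatError(f"duplicate (frame, id) pair {pair} at row {row}")
    for col in ("x", "y"):
        if not np.all(np.isfinite(table[col].to_numpy(dtype=float))):
            raise FormatError(f"non-finite values in column {col!r}")
    if (table["frame"] < 0).any():
        raise FormatError("frame indices must be >= 0")
    return table


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read and validate a trajectory CSV (header row, comma-separated)."""
    table = pd.read_csv(path)
    return validate_trajectory(table)


def write_trajectory(table: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a trajectory CSV; round-trips with read_trajectory."""
    validate_trajectory(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def has_velocities(table: pd.DataFrame) -> bool:
    return all(c in table.columns for c in VELOCITY_COLUMNS)


def frame_point_set(
    table: pd.DataFrame,
    frame: int,
    boundary: str = "open",
    box: tuple[float, float] | None = None,
) -> PointSet:
    """Extract one frame as a PointSet."""
    sub = table[table["frame"] == frame]
    if len(sub) == 0:
        raise FormatError(f"frame {frame} not present in the table")
    return PointSet(coords=sub[["x", "y"]].to_numpy(dtype=float), boundary=boundary, box=box)


def iter_frames(table: pd.DataFrame):
    """Yield (frame_index, sub-table) in increasing frame order."""
    for frame, sub in table.groupby("frame", sort=True):
        yield int(frame), sub


def write_run_metadata(path: str | Path, metadata: dict) -> None:
    """Sidecar key-value text file describing a run (parameters, seed)."""
    lines = [f"{key} = {value}" for key, value in metadata.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Plain key = value config format; '#' starts a comment."""
    config: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        config[key.strip()] = value.strip()
    return config
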