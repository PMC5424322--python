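"""Track file I/O and deterministic report writing.

Tracks are CSV files with columns ``t,x,y``: ``t`` numeric (in a
declared unit) or ISO-8601 timestamps (converted to elapsed hours).
Coordinates must be planar/projected — geographic longitude/latitude
is rejected, since the models are Euclidean.  Reports (fits, model
selections, phase tables, EVAF curves) are written as deterministic
JSON (sorted keys, full-precision floats) and CSV mirrors, embedding
the configuration and seed that produced them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult
from .simulate import Track

__all__ = ["read_track_csv", "write_track_csv", "write_report", "track_to_frame"]

logger = logging.getLogger(__name__)


def track_to_frame(track: Track) -> pd.DataFrame:
    return pd.DataFrame({"t": track.t, "x": track.x, "y": track.y})


def write_track_csv(track: Track, path, *, change_times_sidecar: bool = True) -> None:
    """Write a track as CSV (t,x,y at full float precision).

    Multiphase tracks also get a ``<name>.changes.json`` sidecar with
    their true change times.
    """
    path = Path(path)
    track_to_frame(track).to_csv(path, index=False, float_format="%.17g")
    if change_times_sidecar and track.true_change_times is not None:
        sidecar = path.with_suffix(path.suffix + ".changes.json")
        sidecar.write_text(json.dumps({"true_change_times": list(map(float, track.true_change_times))},
                                      sort_keys=True))


def _looks_geographic(x: np.ndarray, y: np.ndarray) -> bool:
    """Heuristic lon/lat detector: degree-bounded, degree-scale spans,
    but offset well away from a local planar origin."""
    in_bounds = np.all(np.abs(x) <= 180.0) and np.all(np.abs(y) <= 90.0)
    small_span = np.ptp(x) < 2.0 and np.ptp(y) < 2.0
    offset = max(np.max(np.abs(x)), np.max(np.abs(y))) > 5.0
    return bool(in_bounds and small_span and offset)


def read_track_csv(
    path,
    time_format: str = "numeric",
    *,
    min_gap: float | None = None,
    allow_geographic: bool = False,
) -> Track:
    """Read a track CSV with columns t,x,y.

    ``time_format="iso8601"`` parses timestamps and converts them to
    elapsed hours from the first observation.  ``min_gap`` (same unit
    as t) drops points closer than the threshold to their predecessor
    — telemetry deployments often begin with a burst of spuriously
    dense fixes.  Rows are time-sorted; duplicate timestamps are an
    error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"t", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"track CSV must have columns t,x,y (missing {sorted(missing)})")
    if len(df) < 2:
        raise ValueError("a track needs at least 2 rows")
    if time_format == "iso8601":
        ts = pd.to_datetime(df["t"], utc=True, format="ISO8601")
        t = (ts - ts.min()).dt.total_seconds().to_numpy() / 3600.0
    elif time_format == "numeric":
        t = df["t"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown time_format {time_format!r}")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t, x, y = t[order], x[order], y[order]
    dups = np.flatnonzero(np.diff(t) == 0)
    if len(dups):
        raise ValueError(f"duplicate timestamps at sorted rows {list(dups[:10])}")
    if not allow_geographic and _looks_geographic(x, y):
        raise ValueError(
            "coordinates look like geographic lon/lat; project to planar "
            "units first (the models are Euclidean), or pass allow_geographic=True"
        )
    if min_gap is not None:
        keep = [0]
        for i in range(1, len(t)):
            if t[i] - t[keep[-1]] >= min_gap:
                keep.append(i)
        dropped = len(t) - len(keep)
        if dropped:
            logger.info("min_gap=%g dropped %d of %d rows", min_gap, dropped, len(t))
        t, x, y = t[keep], x[keep], y[keep]
    return Track(t=t, x=x, y=y)


def _jsonable(obj):
    if isinstance(obj, FitResult):
        return _jsonable(obj.to_record())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if hasattr(obj, "value"):  # enums
        return obj.value
    return obj


def write_report(results, path, *, config: dict | None = None, seed: int | None = None) -> None:
    """Write a deterministic JSON report (and a CSV mirror for tables).

    ``results`` may be a FitResult, a selection/phase DataFrame, an
    object with ``to_frame``, or any nesting of dicts/lists of those.
    The seed and configuration used are embedded so every output is
    self-describing; identical runs give byte-identical files.
    """
    path = Path(path)
    payload = {"config": _jsonable(config or {}), "seed": seed, "results": None}
    table = None
    if hasattr(results, "to_frame"):
        table = results.to_frame()
        payload["results"] = _jsonable(table)
    elif isinstance(results, pd.DataFrame):
        table = results
        payload["results"] = _jsonable(results.reset_index())
    else:
        payload["results"] = _jsonable(results)
    path.write_text(json.dumps(payload, sort_keys=True, indent=1, allow_nan=True,
                               default=str) + "\n")
    if table is not None:
        table.to_csv(path.with_suffix(".csv"), index=False, float_format="%.17g")
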