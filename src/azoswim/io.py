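"""Delimited-text I/O for trajectories, MSD curves, D* tables and runs.

The trajectory reader consumes the spot-table dialect exported by particle
tracking software: one row per detected spot with a track identifier, x/y
coordinates (um) and a frame and/or time column.  Column names are matched
case-insensitively against common synonyms and can be overridden with an
explicit column map; comma and tab delimiters are sniffed.

Every writer prefixes its CSV with provenance comment lines (package
version, a hash of the generating configuration, and the seed when one
applies), so identical configurations reproduce identical files.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .msd import DiffusionEstimate, MSDCurve, Trajectory

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "write_msd_curves",
    "write_estimates",
    "write_run",
    "provenance_header",
]

logger = logging.getLogger("azoswim")

#: case-insensitive synonyms for the required spot-table columns
_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "track_id": ("track_id", "track id", "track", "particle", "trajectory", "id"),
    "x": ("position_x", "x", "x_um", "x (um)", "pos_x"),
    "y": ("position_y", "y", "y_um", "y (um)", "pos_y"),
    "frame": ("frame", "t_frame", "frame_idx"),
    "time": ("position_t", "time", "time_s", "t", "time (s)"),
}


def _resolve_columns(columns: Sequence[str],
                     column_map: Mapping[str, str] | None) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in columns}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for field, synonyms in _COLUMN_SYNONYMS.items():
        if field in column_map:
            if column_map[field] not in columns:
                raise ValueError(
                    f"mapped column {column_map[field]!r} for {field!r} not in file"
                )
            resolved[field] = column_map[field]
            continue
        for syn in synonyms:
            if syn in lower:
                resolved[field] = lower[syn]
                break
    missing = [f for f in ("track_id", "x", "y") if f not in resolved]
    if "frame" not in resolved and "time" not in resolved:
        missing.append("frame or time")
    if missing:
        raise ValueError(
            f"could not resolve required columns: {missing}; "
            f"available columns: {list(columns)}"
        )
    return resolved


def read_trajectories(
    path,
    column_map: Mapping[str, str] | None = None,
    frame_interval: float = 0.2,
    dialect: str | None = None,
) -> list[Trajectory]:
    """Read a spot-table export into one Trajectory per track.

    Rows are grouped by track id and sorted by time (derived as
    frame * ``frame_interval`` when only a frame column is present).
    Tracks with fewer than two spots are dropped with a logged count.
    ``dialect`` forces the delimiter ("," or "\\t"); by default it is
    sniffed.
    """
    sep = dialect if dialect is not None else None
    df = pd.read_csv(path, sep=sep, engine="python", comment="#",
                     skip_blank_lines=True)
    cols = _resolve_columns(df.columns, column_map)
    if "time" in cols:
        times = df[cols["time"]].astype(float)
    else:
        times = df[cols["frame"]].astype(float) * frame_interval
    work = pd.DataFrame({
        "track_id": df[cols["track_id"]].astype(str),
        "time": times,
        "x": df[cols["x"]].astype(float),
        "y": df[cols["y"]].astype(float),
    })
    trajectories: list[Trajectory] = []
    dropped = 0
    for track_id, grp in work.groupby("track_id", sort=True):
        grp = grp.sort_values("time")
        if len(grp) < 2:
            dropped += 1
            continue
        trajectories.append(Trajectory(
            track_id=str(track_id),
            times=grp["time"].to_numpy(),
            positions=grp[["x", "y"]].to_numpy(),
            frame_interval=frame_interval,
        ))
    if dropped:
        logger.warning("dropped %d track(s) with fewer than 2 spots", dropped)
    if not trajectories:
        raise ValueError(f"no usable tracks (>= 2 spots) found in {path}")
    return trajectories


def provenance_header(config: Mapping, seed: int | None = None) -> str:
    """Comment block recording package version, config hash, and seed."""
    payload = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:12]
    lines = [
        f"# azoswim {__version__}",
        f"# config_hash {digest}",
        f"# seed {seed if seed is not None else 'none'}",
    ]
    return "\n".join(lines) + "\n"


def _write_with_header(df: pd.DataFrame, path, config: Mapping,
                       seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    path.write_text(provenance_header(config, seed) + buf.getvalue())


def write_trajectories(trajectories: Iterable[Trajectory], path,
                       seed: int | None = None) -> None:
    """Write tracks in the same spot-table dialect the reader consumes."""
    trajectories = list(trajectories)
    rows = []
    for traj in trajectories:
        frames = np.rint(traj.times / traj.frame_interval).astype(int)
        for f, t, (x, y) in zip(frames, traj.times, traj.positions):
            rows.append({"track_id": traj.track_id, "frame": f,
                         "time_s": t, "x_um": x, "y_um": y})
    meta = trajectories[0].meta if trajectories and trajectories[0].meta else {}
    _write_with_header(pd.DataFrame(rows), path, config=meta,
                       seed=meta.get("seed", seed))


def write_msd_curves(curves: Iterable[MSDCurve], path,
                     config: Mapping | None = None) -> None:
    """Long-format (track_id, tau, msd, n_pairs) table."""
    rows = []
    for c in curves:
        for tau, v, n in zip(c.lags, c.values, c.n_pairs):
            rows.append({"track_id": c.track_id, "tau_s": tau,
                         "msd_um2": v, "n_pairs": n})
    _write_with_header(pd.DataFrame(rows), path, config=config or {})


def write_estimates(estimates: Iterable[DiffusionEstimate], path,
                    config: Mapping | None = None) -> None:
    """Per-track D' / D* / direction table."""
    rows = [{
        "track_id": e.track_id,
        "D_prime_um2_s": e.D_prime,
        "D_star_um2_s": e.D_star,
        "direction": e.direction.value,
        "fit_tau_min_s": e.fit_window[0],
        "fit_tau_max_s": e.fit_window[1],
        "r_squared": e.r_squared,
    } for e in estimates]
    _write_with_header(pd.DataFrame(rows), path, config=config or {})


def write_run(series, path, config: Mapping | None = None,
              seed: int | None = None, stride: int = 1) -> None:
    """Simulation time series as CSV (one row per Euler step or stride)."""
    _write_with_header(series.to_dataframe(stride=stride), path,
                       config=config or {}, seed=seed)
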