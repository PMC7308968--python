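"""Plain-text file formats: marker tracks, force signals, cohort tables.

All CSVs are self-describing via ``#``-prefixed header comment lines (frame
rate, units, seeds); frame numbers are 0-based.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .kinematics import MARKER_NAMES, ForceSignal, MarkerFrame

__all__ = [
    "write_marker_csv",
    "read_marker_csv",
    "marker_frames_from_table",
    "write_force_csv",
    "read_force_csv",
    "write_cohort_csv",
    "read_cohort_csv",
]


def _read_comment_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def write_marker_csv(path, tracks: Mapping[str, np.ndarray], fps: float,
                     units: str = "m", comments: Mapping[str, str] | None = None) -> None:
    """Write marker trajectories: one row per frame.

    ``tracks`` maps marker name to an ``(n_frames, 2)`` or ``(n_frames, 3)``
    array. Columns are ``frame,time_s,<MARKER>_x,<MARKER>_y[,<MARKER>_z]``.
    """
    if units not in ("m", "px"):
        raise ValueError("units must be 'm' or 'px'")
    names = [m for m in MARKER_NAMES if m in tracks] + [m for m in tracks if m not in MARKER_NAMES]
    arrs = {m: np.atleast_2d(np.asarray(tracks[m], dtype=float)) for m in names}
    n_frames = next(iter(arrs.values())).shape[0]
    ndim = next(iter(arrs.values())).shape[1]
    if any(a.shape != (n_frames, ndim) for a in arrs.values()):
        raise ValueError("all marker tracks must share the same shape")
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(n_frames),
        "time_s": np.arange(n_frames) / fps,
    }
    axes = "xyz"[:ndim]
    for m in names:
        for i, ax in enumerate(axes):
            cols[f"{m}_{ax}"] = arrs[m][:, i]
    df = pd.DataFrame(cols)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fps={fps:g}\n# units={units}\n# frames=0-based\n")
        for key, val in (comments or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


def read_marker_csv(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a marker-trajectory CSV; returns the table and header metadata."""
    path = Path(path)
    meta = _read_comment_meta(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return df, meta


def marker_frames_from_table(df: pd.DataFrame) -> list[MarkerFrame]:
    """Build per-frame 2D :class:`MarkerFrame` objects from a marker table.

    For 3D tables the sagittal (x, y) components are used.
    """
    names = sorted({c.rsplit("_", 1)[0] for c in df.columns
                    if c.endswith(("_x", "_y")) and c not in ("time_s",)})
    frames = []
    for _, row in df.iterrows():
        pts = {m: np.array([row[f"{m}_x"], row[f"{m}_y"]]) for m in names}
        frames.append(MarkerFrame(points=pts, frame_index=int(row["frame"]),
                                  time_s=float(row["time_s"])))
    return frames


def write_force_csv(path, force: ForceSignal, comments: Mapping[str, str] | None = None) -> None:
    """Write a vertical-force signal as ``time_s,fz_n`` rows."""
    df = pd.DataFrame({"time_s": force.times_s, "fz_n": force.samples})
    with open(Path(path), "w") as fh:
        fh.write(f"# rate_hz={force.rate_hz:g}\n# threshold_n={force.threshold_n:g}\n")
        for key, val in (comments or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


def read_force_csv(path) -> ForceSignal:
    path = Path(path)
    meta = _read_comment_meta(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "rate_hz" in meta:
        rate = float(meta["rate_hz"])
    else:
        dt = np.diff(df["time_s"].to_numpy())
        rate = 1.0 / float(np.median(dt))
    thr = float(meta.get("threshold_n", 20.0))
    return ForceSignal(samples=df["fz_n"].to_numpy(dtype=float), rate_hz=rate, threshold_n=thr)


def write_cohort_csv(path, df: pd.DataFrame, comments: Mapping[str, str] | None = None) -> None:
    """Write the long-format angle table (one row per measurement per joint)."""
    with open(Path(path), "w") as fh:
        for key, val in (comments or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), comment="#", float_precision="round_trip")
    required = {"subject", "session", "observer", "system", "repetition", "joint", "angle_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df
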