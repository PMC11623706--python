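"""File formats: trajectory CSV, TIFF stacks with JSON sidecars, configs.

Trajectory tables are plain UTF-8 CSV with '.' decimals, one row per cell
per frame: ``cell_id, frame, time_s, x_um, y_um, theta_rad, state,
wetness`` with state spelled as CLOSED / PARTIAL / OPEN (or UNKNOWN for
unlabeled tracks).  Image stacks are multi-page TIFF (float32) with a
sidecar JSON carrying ``pixel_size_um``, ``frame_interval_s`` and
``exposure_s``; hue maps are single-channel float TIFF with the same
sidecar convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .render import HueMap, ImageStack
from .swarm import CellTrack

__all__ = [
    "write_tracks",
    "read_tracks",
    "write_stack",
    "read_stack",
    "write_hue_map",
    "read_hue_map",
    "load_config_file",
]

STATE_TOKENS = {"CLOSED": 0, "PARTIAL": 1, "OPEN": 2, "UNKNOWN": -1}
TOKEN_OF_STATE = {v: k for k, v in STATE_TOKENS.items()}
TRACK_COLUMNS = [
    "cell_id", "frame", "time_s", "x_um", "y_um", "theta_rad", "state", "wetness",
]


def write_tracks(tracks: list[CellTrack], path: str | Path) -> None:
    """Write trajectories as the canonical CSV schema."""
    rows = []
    for tr in tracks:
        wet = tr.wetness if tr.wetness is not None else np.full(tr.n_frames, np.nan)
        for f in range(tr.n_frames):
            rows.append(
                (
                    tr.cell_id,
                    f,
                    tr.times[f],
                    tr.x[f],
                    tr.y[f],
                    tr.theta[f],
                    TOKEN_OF_STATE.get(int(tr.states[f]), "UNKNOWN"),
                    wet[f],
                )
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_tracks(path: str | Path) -> list[CellTrack]:
    """Read the canonical trajectory CSV back into CellTrack objects.

    Unknown state tokens and non-uniform frame times are rejected with the
    offending row identified; an empty table (header only) returns an
    empty list.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(df) == 0:
        return []
    bad = ~df["state"].isin(STATE_TOKENS)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"unknown state token {df['state'].iloc[row]!r} at row {row}"
        )
    tracks = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        times = grp["time_s"].to_numpy(dtype=float)
        if len(times) >= 2:
            dt = np.diff(times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError(
                    f"non-uniform timebase for cell_id {cid} "
                    f"(first rows {grp.index[:3].tolist()})"
                )
        wet = grp["wetness"].to_numpy(dtype=float)
        tracks.append(
            CellTrack(
                cell_id=int(cid),
                times=times,
                x=grp["x_um"].to_numpy(dtype=float),
                y=grp["y_um"].to_numpy(dtype=float),
                theta=grp["theta_rad"].to_numpy(dtype=float),
                states=np.array([STATE_TOKENS[s] for s in grp["state"]], dtype=np.int8),
                wetness=None if np.all(np.isnan(wet)) else wet,
            )
        )
    return tracks


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Multi-page float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "exposure_s": stack.exposure,
        "n_frames": len(stack.frames),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar} for stack {path}"
        )
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if meta.get("n_frames") not in (None, len(frames)):
        raise ValueError(
            f"sidecar reports {meta['n_frames']} frames, file has {len(frames)}"
        )
    return ImageStack(
        frames=frames,
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta["frame_interval_s"]),
        exposure=float(meta["exposure_s"]),
    )


def write_hue_map(hue: HueMap, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, hue.values.astype(np.float32),
                     photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps({"pixel_size_um": hue.pixel_size})
    )


def read_hue_map(path: str | Path) -> HueMap:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return HueMap(values=tifffile.imread(path), pixel_size=float(meta["pixel_size_um"]))


def load_config_file(path: str | Path) -> dict:
    """Read a JSON or YAML configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data
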