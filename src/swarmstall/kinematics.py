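"""Cell tracking and speed statistics.

Centroid linking uses greedy mutual-nearest-neighbor matching between
consecutive frames within a displacement gate.  Instantaneous speeds use
central differences (forward/backward at track ends).  Summary statistics
mirror the standard swarm-motility readouts: the full speed histogram, the
mean over the fast subset (speed > 7 um/s, the split between cells
affected by local drying and freely moving cells), a Gaussian-tail check
of the speed distribution (a Rayleigh speed law is exactly quadratic in
log-density), and the mean speed conditioned on the number of neighbors
within a cutoff radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .swarm import CellTrack

__all__ = [
    "link_tracks",
    "instantaneous_speeds",
    "speed_summary",
    "tail_gaussian_check",
    "speed_vs_neighbors",
    "SpeedSummary",
    "TailFit",
]

FAST_THRESHOLD = 7.0  # um/s
MIN_TRACK_FRAMES = 5  # shorter tracks are excluded from statistics
DEFAULT_CUTOFFS = (3.0, 5.0, 7.0, 10.0)  # um


def link_tracks(
    per_frame_centroids: list[np.ndarray],
    max_displacement: float,
    frame_interval: float = 0.02,
) -> list[CellTrack]:
    """Greedy mutual-nearest-neighbor linking of per-frame centroids.

    ``per_frame_centroids[f]`` is an (n_f, 2) array of (x, y) positions in
    um.  A detection links to the previous frame's track only when each is
    the other's nearest neighbor within ``max_displacement``; unmatched
    detections start new tracks.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    active: dict[int, list[tuple[int, float, float]]] = {}
    finished: list[list[tuple[int, float, float]]] = []
    next_id = 0
    prev_pts = None
    prev_track_of_row: dict[int, int] = {}

    tracks_data: dict[int, list[tuple[int, float, float]]] = {}
    for f, pts in enumerate(per_frame_centroids):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        cur_track_of_row: dict[int, int] = {}
        if prev_pts is not None and len(prev_pts) and len(pts):
            tree_prev = cKDTree(prev_pts)
            tree_cur = cKDTree(pts)
            d_pc, nn_pc = tree_cur.query(prev_pts, k=1,
                                         distance_upper_bound=max_displacement)
            d_cp, nn_cp = tree_prev.query(pts, k=1,
                                          distance_upper_bound=max_displacement)
            for i_prev in range(len(prev_pts)):
                j = nn_pc[i_prev]
                if (
                    np.isfinite(d_pc[i_prev])
                    and j < len(pts)
                    and nn_cp[j] == i_prev
                    and np.isfinite(d_cp[j])
                ):
                    tid = prev_track_of_row[i_prev]
                    tracks_data[tid].append((f, pts[j, 0], pts[j, 1]))
                    cur_track_of_row[j] = tid
        for j in range(len(pts)):
            if j not in cur_track_of_row:
                tid = next_id
                next_id += 1
                tracks_data[tid] = [(f, pts[j, 0], pts[j, 1])]
                cur_track_of_row[j] = tid
        prev_pts = pts
        prev_track_of_row = cur_track_of_row

    out = []
    for tid, rows in sorted(tracks_data.items()):
        arr = np.array(rows, dtype=float)
        frames = arr[:, 0].astype(int)
        out.append(
            CellTrack(
                cell_id=tid,
                times=frames * frame_interval,
                x=arr[:, 1],
                y=arr[:, 2],
                theta=np.zeros(len(arr)),
                states=np.full(len(arr), -1, dtype=np.int8),
            )
        )
    return out


@dataclass
class SpeedSample:
    """One instantaneous speed observation with neighbor context."""

    cell_id: int
    time: float
    speed: float
    neighbors: dict[float, int] | None = None


def instantaneous_speeds(track: CellTrack, periodic: bool = True) -> np.ndarray:
    """Central-difference speed (um/s) per frame; forward/backward at ends.

    Positions on a periodic arena use minimum-image displacements when the
    track carries arena metadata.
    """
    if track.n_frames < 2:
        raise ValueError("need >= 2 samples for speeds")
    dt = track.frame_interval
    x, y = track.x, track.y
    dx = np.diff(x)
    dy = np.diff(y)
    if periodic and track.arena is not None:
        w, h = track.arena
        dx -= w * np.round(dx / w)
        dy -= h * np.round(dy / h)
    # cumulative unwrapped positions make central differences exact
    xu = np.concatenate([[0.0], np.cumsum(dx)])
    yu = np.concatenate([[0.0], np.cumsum(dy)])
    vx = np.gradient(xu, dt)
    vy = np.gradient(yu, dt)
    return np.hypot(vx, vy)


@dataclass
class SpeedSummary:
    """Histogram plus the fast-subset mean speed."""

    bin_edges: np.ndarray
    counts: np.ndarray
    fast_mean: float          # NaN when no sample exceeds the threshold
    fast_threshold: float
    n_samples: int
    n_fast: int


def speed_summary(
    speeds: np.ndarray,
    fast_threshold: float = FAST_THRESHOLD,
    bin_width: float = 1.0,
) -> SpeedSummary:
    """Histogram of speeds and the mean over the fast subset (> threshold)."""
    speeds = np.asarray(speeds, dtype=float).ravel()
    if len(speeds) == 0:
        raise ValueError("no speed samples")
    top = max(speeds.max(), fast_threshold) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(speeds, bins=edges)
    fast = speeds[speeds > fast_threshold]
    return SpeedSummary(
        bin_edges=edges,
        counts=counts,
        fast_mean=float(fast.mean()) if len(fast) else float("nan"),
        fast_threshold=fast_threshold,
        n_samples=len(speeds),
        n_fast=len(fast),
    )


@dataclass
class TailFit:
    """Quadratic fit of log-density above the mode."""

    curvature: float          # coefficient of speed^2; Rayleigh: -1/(2 sigma^2)
    r_squared: float
    n_bins: int


def tail_gaussian_check(
    bin_edges: np.ndarray, counts: np.ndarray
) -> TailFit:
    """Fit log-density above the histogram mode to a quadratic in speed.

    A Rayleigh speed distribution has log f(v) = log v - v^2/(2 sigma^2) +
    const, which is dominated by the quadratic term above the mode; high
    R^2 of the quadratic fit is the Gaussian-tail signature.
    """
    counts = np.asarray(counts, dtype=float)
    centers = 0.5 * (np.asarray(bin_edges)[:-1] + np.asarray(bin_edges)[1:])
    mode = np.argmax(counts)
    sel = np.arange(mode + 1, len(counts))
    sel = sel[counts[sel] > 0]
    if len(sel) < 5:
        raise ValueError("need >= 5 positive tail bins above the mode")
    xs, ys = centers[sel], np.log(counts[sel])
    coef = np.polyfit(xs, ys, 2)
    fit = np.polyval(coef, xs)
    ss_res = np.sum((ys - fit) ** 2)
    ss_tot = np.sum((ys - ys.mean()) ** 2)
    return TailFit(
        curvature=float(coef[0]),
        r_squared=float(1.0 - ss_res / ss_tot) if ss_tot > 0 else float("nan"),
        n_bins=len(sel),
    )


def speed_vs_neighbors(
    tracks: list[CellTrack],
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    min_track_frames: int = MIN_TRACK_FRAMES,
    use_ground_truth_speed: bool = False,
) -> dict[float, dict[int, float]]:
    """Mean speed binned by neighbor count, for each cutoff radius.

    Neighbor counts use center-to-center minimum-image distances at every
    frame; empty neighbor-count bins are simply absent from the returned
    mapping (never reported as zero).  All tracks must share the same
    frame times and arena.
    """
    tracks = [t for t in tracks if t.n_frames >= min_track_frames]
    if not tracks:
        raise ValueError("no tracks of sufficient length")
    arena = tracks[0].arena
    n_frames = tracks[0].n_frames
    if any(t.n_frames != n_frames for t in tracks):
        raise ValueError("tracks must share the same frame grid")
    xs = np.stack([t.x for t in tracks])
    ys = np.stack([t.y for t in tracks])
    if use_ground_truth_speed:
        speeds = np.stack([t.speed for t in tracks])
    else:
        speeds = np.stack([instantaneous_speeds(t) for t in tracks])

    sums: dict[float, dict[int, float]] = {r: {} for r in cutoffs}
    nums: dict[float, dict[int, int]] = {r: {} for r in cutoffs}
    boxsize = list(arena) if arena is not None else None
    for f in range(n_frames):
        pts = np.column_stack([xs[:, f], ys[:, f]])
        if boxsize is not None:
            pts = np.mod(pts, boxsize)
        tree = cKDTree(pts, boxsize=boxsize)
        for r in cutoffs:
            k = tree.query_ball_point(pts, r, return_length=True) - 1
            for ki, vi in zip(k, speeds[:, f]):
                sums[r][ki] = sums[r].get(ki, 0.0) + vi
                nums[r][ki] = nums[r].get(ki, 0) + 1
    return {
        r: {ki: sums[r][ki] / nums[r][ki] for ki in sorted(sums[r])}
        for r in cutoffs
    }
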