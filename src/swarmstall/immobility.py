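"""Detection of temporarily immobile cells and bin-occupancy statistics.

At 0.2 s exposure a stalled rod renders sharply (its pixels are covered
for the whole exposure) while a cell moving at v um/s loses a strip of
roughly ``v * exposure`` um of fully-covered body length.  Thresholding a
long-exposure frame near full intensity and keeping only connected
components whose area is close to the rod body area therefore isolates the
immobile cells: with the defaults (intensity threshold 0.95, minimum area
0.9 x body area) a rod translating along its axis drops out of the area
band at roughly 7 um/s, the empirical split between "slow/stationary" and
freely moving cells.

The occupancy statistics divide the field of view into a 10 x 10 grid and
ask, per long-exposure frame, whether at least one third of a cell body
area of immobile-cell mask falls in each bin.  For a surface with no fixed
traps, the per-bin occupation fraction over a window of duration T has a
mean independent of T, an approximately Gaussian distribution across bins,
and an across-bin standard deviation decaying as T^(-1/2) (central limit
scaling); its temporal autocorrelation decays within a few seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .model import FlagellarState
from .render import StackMeta, _cell_corners, _pose_at
from .swarm import CellTrack

__all__ = [
    "ImmobileMask",
    "OccupancySeries",
    "OccupancyStats",
    "detect_immobile",
    "immobile_fraction",
    "ground_truth_immobile",
    "ground_truth_immobile_all",
    "ground_truth_masks",
    "bin_occupancy",
    "occupancy_stats",
    "fit_std_exponent",
    "normality_check",
    "occupancy_autocorrelation",
]

DEFAULT_INTENSITY_THRESHOLD = 0.95
DEFAULT_MIN_AREA_FRACTION = 0.9   # of the nominal body area, px
DEFAULT_MIN_COVERAGE = 1.0 / 3.0  # of the nominal body area, px
GRID = (10, 10)
STALL_COVERAGE_RULE = 0.9  # ground truth: OPEN >= 90% of the exposure window


@dataclass
class ImmobileMask:
    """Binary immobile-cell mask with labeled connected components."""

    mask: np.ndarray            # bool, (rows, cols)
    labels: np.ndarray          # int, same shape; 0 = background
    areas: np.ndarray           # px per component, 1-indexed by label
    centroids: np.ndarray       # (n, 2) as (row, col)

    @property
    def n_components(self) -> int:
        return len(self.areas)


def _label_mask(mask: np.ndarray) -> ImmobileMask:
    labels = cc_label(mask, connectivity=2)
    props = regionprops(labels)
    areas = np.array([p.area for p in props], dtype=float)
    cents = np.array([p.centroid for p in props], dtype=float).reshape(-1, 2)
    return ImmobileMask(mask=mask, labels=labels, areas=areas, centroids=cents)


def detect_immobile(
    long_frame: np.ndarray,
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
    min_area_px: float | None = None,
    cell_area_px: float | None = None,
) -> ImmobileMask:
    """Threshold a long-exposure frame and keep near-body-size components.

    ``min_area_px`` defaults to 0.9 x ``cell_area_px`` (which itself
    defaults to a 7 um^2 rod; pass the value for the stack's pixel size).
    """
    frame = np.asarray(long_frame, dtype=float)
    if frame.min() < 0 or frame.max() > 1:
        raise ValueError("frame intensities must lie in [0, 1]")
    if not 0.0 < intensity_threshold < 1.0:
        raise ValueError("intensity_threshold must lie in (0, 1)")
    if min_area_px is None:
        if cell_area_px is None:
            raise ValueError("provide min_area_px or cell_area_px")
        min_area_px = DEFAULT_MIN_AREA_FRACTION * cell_area_px
    raw = frame >= intensity_threshold
    labeled = cc_label(raw, connectivity=2)
    keep = np.zeros_like(raw)
    for p in regionprops(labeled):
        if p.area >= min_area_px:
            keep[labeled == p.label] = True
    return _label_mask(keep)


def immobile_fraction(mask: ImmobileMask, n_cells_total: int) -> float:
    """Detected immobile components as a fraction of all cells."""
    if n_cells_total < 1:
        raise ValueError("n_cells_total must be >= 1")
    return float(np.clip(mask.n_components / n_cells_total, 0.0, 1.0))


def ground_truth_immobile(
    tracks: Sequence[CellTrack], t0: float, exposure: float,
    rule: float = STALL_COVERAGE_RULE,
) -> np.ndarray:
    """Ground-truth labels: cell stalled (OPEN) >= ``rule`` of [t0, t0+exp]."""
    flags = np.zeros(len(tracks), dtype=bool)
    for i, tr in enumerate(tracks):
        if tr.state_track is None:
            raise ValueError("tracks must carry their StateTrack")
        frac = tr.state_track.occupancy_in_window(
            t0, t0 + exposure, FlagellarState.OPEN
        )
        flags[i] = frac >= rule
    return flags


def _open_time_interpolant(track: CellTrack):
    """Cumulative time-in-OPEN as a piecewise-linear function of time."""
    st = track.state_track
    knots = np.concatenate([[st.t_start[0]], st.t_end])
    increments = np.where(st.states == FlagellarState.OPEN, st.durations, 0.0)
    cum = np.concatenate([[0.0], np.cumsum(increments)])
    return knots, cum


def ground_truth_immobile_all(
    tracks: Sequence[CellTrack],
    frame_starts: np.ndarray,
    exposure: float,
    rule: float = STALL_COVERAGE_RULE,
) -> np.ndarray:
    """Vectorized ground-truth stall labels, (n_frames, n_cells) bool."""
    frame_starts = np.asarray(frame_starts, dtype=float)
    out = np.empty((len(frame_starts), len(tracks)), dtype=bool)
    for i, tr in enumerate(tracks):
        if tr.state_track is None:
            raise ValueError("tracks must carry their StateTrack")
        knots, cum = _open_time_interpolant(tr)
        open_time = np.interp(frame_starts + exposure, knots, cum) - np.interp(
            frame_starts, knots, cum
        )
        out[:, i] = open_time / exposure >= rule
    return out


def ground_truth_masks(
    tracks: Sequence[CellTrack],
    meta: StackMeta,
    n_frames: int,
    rule: float = STALL_COVERAGE_RULE,
    labeled: bool = False,
) -> Iterator[ImmobileMask | np.ndarray]:
    """Rasterized ground-truth immobile masks per long-exposure frame.

    Yields one mask per frame (frame f covers
    ``[f * frame_interval, f * frame_interval + exposure]``); useful for
    scoring detection and for occupancy statistics that do not depend on
    the intensity-detection path.  Plain boolean arrays by default;
    ``labeled=True`` adds connected-component labeling.
    """
    starts = np.arange(n_frames) * meta.frame_interval
    flags_all = ground_truth_immobile_all(tracks, starts, meta.exposure, rule)
    for f in range(n_frames):
        t0 = starts[f]
        flags = flags_all[f]
        img = np.zeros(meta.shape, dtype=bool)
        mid = t0 + meta.exposure / 2.0
        for i in np.nonzero(flags)[0]:
            tr = tracks[i]
            x, y, th = _pose_at(tr, mid)
            corners = _cell_corners(x, y, th, tr.cell_length, tr.cell_width)
            cpx = corners / meta.pixel_size
            rows, cols = meta.shape
            xs = [0.0] + ([cols] if cpx[:, 0].min() < 0 else []) + (
                [-cols] if cpx[:, 0].max() >= cols else [])
            ys = [0.0] + ([rows] if cpx[:, 1].min() < 0 else []) + (
                [-rows] if cpx[:, 1].max() >= rows else [])
            for sx in xs:
                for sy in ys:
                    rr, cc = draw_polygon(cpx[:, 1] + sy, cpx[:, 0] + sx,
                                          shape=meta.shape)
                    img[rr, cc] = True
        yield _label_mask(img) if labeled else img


@dataclass
class OccupancySeries:
    """Per-bin binary occupancy per long-exposure frame on a 10 x 10 grid."""

    occupancy: np.ndarray       # bool, (n_frames, 10, 10)
    frame_interval: float       # s

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3 or self.occupancy.shape[1:] != GRID:
            raise ValueError("occupancy must have shape (n_frames, 10, 10)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.occupancy)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


def bin_occupancy(
    masks: Iterable[ImmobileMask | np.ndarray],
    frame_interval: float,
    min_coverage_px: float,
    grid: tuple[int, int] = GRID,
) -> OccupancySeries:
    """Binary bin occupancy: masked area in a bin >= ``min_coverage_px``.

    ``min_coverage_px`` should be one third of the cell body area in
    pixels (the "at least 1/3 of a cell in a bin" counting rule).  Image
    dimensions must divide evenly by the grid.
    """
    rows_per = cols_per = None
    frames = []
    for m in masks:
        mask = m.mask if isinstance(m, ImmobileMask) else np.asarray(m, dtype=bool)
        r, c = mask.shape
        if r % grid[0] or c % grid[1]:
            raise ValueError("image dimensions must divide evenly by the grid")
        rows_per, cols_per = r // grid[0], c // grid[1]
        binned = mask.reshape(grid[0], rows_per, grid[1], cols_per).sum(axis=(1, 3))
        frames.append(binned >= min_coverage_px)
    if not frames:
        raise ValueError("no masks provided")
    return OccupancySeries(
        occupancy=np.stack(frames), frame_interval=frame_interval
    )


@dataclass
class OccupancyStats:
    """Window statistics of bin occupancy per window duration."""

    durations: np.ndarray       # s, strictly increasing
    mean_fraction: np.ndarray   # mean over (bin, window) samples
    std: np.ndarray             # std over (bin, window) samples
    per_bin_fraction: list[np.ndarray]  # per duration: (n_windows, 10, 10)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.durations) <= 0):
            raise ValueError("durations must be strictly increasing")
        if np.any((self.mean_fraction < 0) | (self.mean_fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")


def default_durations(step: float = 5.0, stop: float = 360.0) -> np.ndarray:
    """Window durations 5-360 s in steps of 5 s."""
    return np.arange(step, stop + step / 2, step)


def occupancy_stats(
    series: OccupancySeries, durations: Sequence[float] | None = None
) -> OccupancyStats:
    """Disjoint-window occupation fractions for each window duration.

    For each duration T the series is split into ``floor(duration / T)``
    disjoint windows; each (bin, window) pair yields one occupation
    fraction (occupied frames / frames in window).
    """
    if durations is None:
        durations = default_durations()
    durations = np.asarray(sorted(durations), dtype=float)
    if series.n_frames == 0:
        raise ValueError("empty occupancy series")
    if durations[-1] > series.duration + 1e-9:
        raise ValueError(
            f"longest duration {durations[-1]} s exceeds series length "
            f"{series.duration} s"
        )
    occ = series.occupancy.astype(float)
    means, stds, per_bin = [], [], []
    for T in durations:
        frames_per = max(1, int(round(T / series.frame_interval)))
        n_win = series.n_frames // frames_per
        trimmed = occ[: n_win * frames_per].reshape(n_win, frames_per, *GRID)
        frac = trimmed.mean(axis=1)  # (n_win, 10, 10)
        means.append(frac.mean())
        stds.append(frac.std(ddof=1))
        per_bin.append(frac)
    return OccupancyStats(
        durations=durations,
        mean_fraction=np.array(means),
        std=np.array(stds),
        per_bin_fraction=per_bin,
    )


def fit_std_exponent(stats_: OccupancyStats) -> float:
    """OLS slope of log(std) against log(duration).

    Zero-std durations are excluded (with a warning); at least 5 positive
    entries are required.  The central-limit expectation is -1/2.
    """
    pos = stats_.std > 0
    if np.any(~pos):
        import warnings

        warnings.warn("durations with zero std excluded from exponent fit")
    if pos.sum() < 5:
        raise ValueError("need >= 5 durations with positive std")
    slope, _ = np.polyfit(np.log(stats_.durations[pos]), np.log(stats_.std[pos]), 1)
    return float(slope)


def normality_check(per_bin_counts: np.ndarray) -> tuple[float, float, bool]:
    """Shapiro-Wilk test of per-bin occupation counts.

    Returns ``(statistic, p_value, degenerate)``; constant input is
    reported as degenerate with NaN statistics rather than an error.
    """
    counts = np.asarray(per_bin_counts, dtype=float).ravel()
    if len(counts) < 20:
        raise ValueError("need >= 20 bins for the normality check")
    if np.ptp(counts) == 0:
        return float("nan"), float("nan"), True
    res = stats.shapiro(counts)
    return float(res.statistic), float(res.pvalue), False


def occupancy_autocorrelation(
    series: OccupancySeries, max_lag: int | None = None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Bin-averaged temporal autocorrelation of occupancy fluctuations.

    Per bin the mean is subtracted; autocovariances are averaged across
    bins and normalized to 1 at lag 0.  Returns ``(lags_s, corr,
    decay_time_1e, first_zero_crossing)`` where the 1/e time is the primary
    decay definition (zero crossings are noisier) -- both in seconds, NaN
    if not reached.
    """
    occ = series.occupancy.astype(float).reshape(series.n_frames, -1)
    fluct = occ - occ.mean(axis=0)
    var = (fluct**2).mean(axis=0)
    if np.all(var == 0):
        raise ValueError("zero-variance occupancy series")
    if max_lag is None:
        max_lag = series.n_frames // 4
    n = series.n_frames
    acov = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        acov[lag] = np.mean(
            np.sum(fluct[: n - lag] * fluct[lag:], axis=0) / (n - lag)
        )
    corr = acov / acov[0]
    lags_s = np.arange(max_lag + 1) * series.frame_interval

    below = np.nonzero(corr <= 1.0 / np.e)[0]
    decay_1e = float(lags_s[below[0]]) if len(below) else float("nan")
    crossing = np.nonzero(corr <= 0.0)[0]
    first_zero = float(lags_s[crossing[0]]) if len(crossing) else float("nan")
    return lags_s, corr, decay_1e, first_zero
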