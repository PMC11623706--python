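"""Rasterization of swarm configurations into microscopy-like images.

Two render paths:

* intensity frames with exposure-time motion blur -- each frame is the mean
  of several instantaneous rasterizations spread uniformly over the
  exposure window, so a stalled cell stays sharp while a cell moving at
  ~20 um/s smears into a faint streak at 0.2 s exposure;
* DIC-like hue maps -- an abstract hue axis on which wet cells and the agar
  background sit in the 43-45 band while drying cells descend through
  green (25-27), blue (21-24) and black (<=20) with a transverse profile
  across the rod, mimicking the slope-dependent color of differential
  interference contrast.

Geometry: 0-based pixel indices, x rightward / y downward, physical
coordinate ``x_um = col * pixel_size`` (the arena wraps periodically onto
the image).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import polygon as draw_polygon

from .swarm import CellTrack

__all__ = [
    "StackMeta",
    "ImageStack",
    "HueMap",
    "rasterize_cells",
    "render_frame",
    "render_stack",
    "synthesize_long_exposure",
    "render_dic_hue",
]

BACKGROUND_HUE = (43.0, 45.0)  # wet cells and bare agar
DRY_HUE_TOP = 27.0             # greenest hue a drying cell shows
DRY_HUE_SPAN = 13.0            # fully dry cells span [14, 27]
WET_THRESHOLD = 0.5            # wetness above this renders as background


@dataclass(frozen=True)
class StackMeta:
    """Image geometry and timing: um/px, frame spacing and exposure (s)."""

    shape: tuple[int, int]        # (rows, cols)
    pixel_size: float             # um / px
    frame_interval: float         # s
    exposure: float               # s

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0 or self.exposure <= 0:
            raise ValueError("pixel_size, frame_interval, exposure must be > 0")
        if self.exposure > self.frame_interval + 1e-12:
            raise ValueError("exposure must not exceed frame_interval")

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)


@dataclass
class ImageStack:
    """Ordered intensity frames in [0, 1] plus geometry metadata."""

    frames: np.ndarray            # (n, rows, cols) float32
    pixel_size: float
    frame_interval: float
    exposure: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or len(self.frames) == 0:
            raise ValueError("frames must be a non-empty (n, rows, cols) array")
        if self.exposure > self.frame_interval + 1e-12:
            raise ValueError("exposure must not exceed frame_interval")
        if float(self.frames.min()) < 0 or float(self.frames.max()) > 1:
            raise ValueError("intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def meta(self) -> StackMeta:
        return StackMeta(
            shape=self.frames.shape[1:],
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            exposure=self.exposure,
        )

    @property
    def duration(self) -> float:
        return len(self.frames) * self.frame_interval


@dataclass
class HueMap:
    """Per-pixel hue values on the DIC threshold scale (>= 0)."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("hue values must be finite and >= 0")


def _cell_corners(x: float, y: float, theta: float, length: float, width: float) -> np.ndarray:
    """Corner coordinates (um) of the rotated rod rectangle, (4, 2) as (x, y)."""
    c, s = np.cos(theta), np.sin(theta)
    hl, hw = length / 2.0, width / 2.0
    local = np.array([[-hl, -hw], [hl, -hw], [hl, hw], [-hl, hw]])
    rot = np.array([[c, -s], [s, c]])
    return local @ rot.T + np.array([x, y])


def _pose_at(track: CellTrack, t: float) -> tuple[float, float, float]:
    """Linear interpolation of the track pose at time ``t`` (min-image)."""
    times = track.times
    if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
        raise ValueError(f"time {t} outside track support [{times[0]}, {times[-1]}]")
    j = int(np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2))
    frac = (t - times[j]) / (times[j + 1] - times[j])
    frac = float(np.clip(frac, 0.0, 1.0))
    if track.arena is not None:
        w, h = track.arena
        dx = track.x[j + 1] - track.x[j]
        dy = track.y[j + 1] - track.y[j]
        dx -= w * np.round(dx / w)
        dy -= h * np.round(dy / h)
        x = np.mod(track.x[j] + frac * dx, w)
        y = np.mod(track.y[j] + frac * dy, h)
    else:
        x = track.x[j] + frac * (track.x[j + 1] - track.x[j])
        y = track.y[j] + frac * (track.y[j + 1] - track.y[j])
    dth = np.angle(np.exp(1j * (track.theta[j + 1] - track.theta[j])))
    th = track.theta[j] + frac * dth
    return float(x), float(y), float(th)


def _draw_rect(img: np.ndarray, corners_um: np.ndarray, pixel_size: float,
               value: float = 1.0, periodic: bool = True) -> None:
    """Fill a rectangle (um coordinates) into ``img``, wrapping if needed."""
    rows, cols = img.shape
    cpx = corners_um / pixel_size  # (x, y) in pixel units
    shifts = [(0.0, 0.0)]
    if periodic:
        xmin, xmax = cpx[:, 0].min(), cpx[:, 0].max()
        ymin, ymax = cpx[:, 1].min(), cpx[:, 1].max()
        sx = [0.0] + ([cols] if xmin < 0 else []) + ([-cols] if xmax >= cols else [])
        sy = [0.0] + ([rows] if ymin < 0 else []) + ([-rows] if ymax >= rows else [])
        shifts = [(dx, dy) for dx in sx for dy in sy]
    for dx, dy in shifts:
        rr, cc = draw_polygon(cpx[:, 1] + dy, cpx[:, 0] + dx, shape=img.shape)
        img[rr, cc] = value


def rasterize_cells(tracks: list[CellTrack], t: float, meta: StackMeta) -> np.ndarray:
    """Instantaneous binary rasterization: rods at 1 on background 0."""
    img = np.zeros(meta.shape, dtype=np.float64)
    for track in tracks:
        x, y, th = _pose_at(track, t)
        corners = _cell_corners(x, y, th, track.cell_length, track.cell_width)
        _draw_rect(img, corners, meta.pixel_size)
    return img


def render_frame(
    tracks: list[CellTrack],
    t: float,
    meta: StackMeta,
    n_subsamples: int = 11,
    noise_sigma: float = 0.0,
    smooth_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One motion-blurred frame: mean of instants over [t, t + exposure].

    ``n_subsamples`` instants uniformly span the exposure window (endpoints
    included); optional Gaussian smoothing (px) and additive Gaussian noise
    are applied to each instant before averaging.  The result is clipped to
    [0, 1] only when noise is present.
    """
    if n_subsamples < 1:
        raise ValueError("n_subsamples must be >= 1")
    if noise_sigma and rng is None:
        rng = np.random.default_rng(0)
    sub_times = (
        np.linspace(t, t + meta.exposure, n_subsamples)
        if n_subsamples > 1
        else np.array([t])
    )
    acc = np.zeros(meta.shape, dtype=np.float64)
    for ts in sub_times:
        inst = rasterize_cells(tracks, ts, meta)
        if smooth_sigma > 0:
            from scipy.ndimage import gaussian_filter

            inst = gaussian_filter(inst, smooth_sigma)
        if noise_sigma > 0:
            inst = inst + rng.normal(0.0, noise_sigma, size=inst.shape)
        acc += inst
    out = acc / len(sub_times)
    if noise_sigma > 0:
        out = np.clip(out, 0.0, 1.0)
    return out


def render_stack(
    tracks: list[CellTrack],
    meta: StackMeta,
    n_frames: int | None = None,
    n_subsamples: int = 11,
    noise_sigma: float = 0.0,
    smooth_sigma: float = 0.0,
    seed: int | np.random.SeedSequence | None = 0,
) -> ImageStack:
    """Render a full stack at the metadata frame rate starting at t = 0."""
    if not tracks:
        raise ValueError("no tracks to render")
    t_max = tracks[0].times[-1]
    if n_frames is None:
        n_frames = int(np.floor((t_max - meta.exposure) / meta.frame_interval)) + 1
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    frame_seeds = ss.spawn(n_frames)
    frames = np.empty((n_frames, *meta.shape), dtype=np.float32)
    for f in range(n_frames):
        t = f * meta.frame_interval
        frames[f] = render_frame(
            tracks,
            t,
            meta,
            n_subsamples=n_subsamples,
            noise_sigma=noise_sigma,
            smooth_sigma=smooth_sigma,
            rng=np.random.default_rng(frame_seeds[f]),
        )
    return ImageStack(
        frames=np.clip(frames, 0.0, 1.0),
        pixel_size=meta.pixel_size,
        frame_interval=meta.frame_interval,
        exposure=meta.exposure,
    )


def synthesize_long_exposure(stack: ImageStack, ratio: int) -> ImageStack:
    """Average runs of ``ratio`` consecutive frames into long-exposure frames.

    Mirrors acquiring at a ``ratio``-fold slower frame rate with a
    ``ratio``-fold longer exposure (e.g. 50 frames/s, 0.02 s -> 5 frames/s,
    0.2 s); a trailing remainder of frames is dropped.
    """
    if ratio < 1 or int(ratio) != ratio:
        raise ValueError("ratio must be a positive integer")
    ratio = int(ratio)
    n_out = len(stack.frames) // ratio
    if n_out == 0:
        raise ValueError("stack shorter than one output frame")
    grouped = stack.frames[: n_out * ratio].reshape(n_out, ratio, *stack.frames.shape[1:])
    return ImageStack(
        frames=grouped.mean(axis=1, dtype=np.float64).astype(np.float32),
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval * ratio,
        exposure=stack.exposure * ratio,
    )


def _transverse_fraction(
    rr: np.ndarray, cc: np.ndarray, x: float, y: float, theta: float,
    half_width_px: float,
) -> np.ndarray:
    """|perpendicular offset| / half-width for pixels of a rod, in [0, 1]."""
    dx = cc - x
    dy = rr - y
    perp = np.abs(-np.sin(theta) * dx + np.cos(theta) * dy)
    return np.clip(perp / max(half_width_px, 1e-9), 0.0, 1.0)


def render_dic_hue(
    tracks: list[CellTrack],
    t: float,
    meta: StackMeta,
    seed: int | np.random.Generator | None = 0,
    wet_threshold: float = WET_THRESHOLD,
    noise_rate: float = 0.001,
) -> HueMap:
    """Hue map at time ``t`` from track poses and wetness ground truth.

    Background and wet cells (wetness >= ``wet_threshold``) draw hues
    Uniform(43, 45).  A drying cell's pixels descend from green toward
    black with dryness ``d = (wet_threshold - w)/wet_threshold``:
    ``hue = 27 - 13 d sqrt(1 - |u|)`` where ``u`` is the transverse offset
    across the rod, so a fully dry rod shows black flanked by blue with
    green edges.  A small fraction ``noise_rate`` of pixels is replaced by
    Uniform(28, 42) noise, the otherwise-empty band.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hue = rng.uniform(*BACKGROUND_HUE, size=meta.shape).astype(np.float64)
    ps = meta.pixel_size
    for track in tracks:
        if track.wetness is None:
            raise ValueError("tracks must carry wetness ground truth")
        j = int(np.clip(np.searchsorted(track.times, t, side="right") - 1,
                        0, len(track.times) - 1))
        w = float(track.wetness[j])
        if not 0.0 <= w <= 1.0:
            raise ValueError("wetness must lie in [0, 1]")
        if w >= wet_threshold:
            continue  # wet cells are indistinguishable from background
        x, y, th = _pose_at(track, t)
        dryness = (wet_threshold - w) / wet_threshold
        corners = _cell_corners(x, y, th, track.cell_length, track.cell_width) / ps
        rows, cols = meta.shape
        xs = [0.0] + ([cols] if corners[:, 0].min() < 0 else []) + (
            [-cols] if corners[:, 0].max() >= cols else [])
        ys = [0.0] + ([rows] if corners[:, 1].min() < 0 else []) + (
            [-rows] if corners[:, 1].max() >= rows else [])
        for sx in xs:
            for sy in ys:
                rr, cc = draw_polygon(corners[:, 1] + sy, corners[:, 0] + sx,
                                      shape=meta.shape)
                if len(rr) == 0:
                    continue
                u = _transverse_fraction(
                    rr, cc, x / ps + sx, y / ps + sy, th,
                    track.cell_width / (2 * ps),
                )
                hue[rr, cc] = DRY_HUE_TOP - DRY_HUE_SPAN * dryness * np.sqrt(1.0 - u)
    if noise_rate > 0:
        mask = rng.random(meta.shape) < noise_rate
        hue[mask] = rng.uniform(28.0, 42.0, size=int(mask.sum()))
    return HueMap(values=hue, pixel_size=ps)
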