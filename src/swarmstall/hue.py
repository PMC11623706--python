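"""DIC hue classification and wet/dry event extraction.

Pixels are classified on the hue axis with the fixed integer band edges:
hue <= 20 black, 21-24 blue, 25-27 green (all rod topography exposed by
local drying), 28-42 unclassified (rare), and >= 43 background (bare agar
and cells under a liquid film).  Fractional hues are floored before
thresholding; the bands are exhaustive and mutually exclusive.

A cell's wet/dry state over time is summarized by the fraction of
non-background pixels inside its padded, cell-oriented bounding rectangle.
Stopping (drying) and wetting events are extracted from that fraction with
a hysteresis pair of thresholds, which guarantees alternation of the two
event types.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon

from .render import HueMap, StackMeta, _cell_corners, _pose_at
from .swarm import CellTrack

__all__ = [
    "HueClass",
    "classify_hue",
    "dry_fraction_timeseries",
    "dry_fraction_frame",
    "WetnessEvent",
    "detect_wetness_events",
    "stall_durations",
]

DEFAULT_PAD_UM = 0.25
HYSTERESIS_ON = 0.5
HYSTERESIS_OFF = 0.2


class HueClass(enum.IntEnum):
    BLACK = 0
    BLUE = 1
    GREEN = 2
    UNCLASSIFIED = 3
    BACKGROUND = 4


def classify_hue(hue_map: HueMap | np.ndarray) -> np.ndarray:
    """Map hues to classes; total and exhaustive over finite hues >= 0."""
    values = hue_map.values if isinstance(hue_map, HueMap) else np.asarray(hue_map)
    if np.any(~np.isfinite(values)):
        raise ValueError("hue values must be finite")
    if np.any(values < 0):
        raise ValueError("hue values must be >= 0")
    floored = np.floor(values)
    out = np.full(values.shape, HueClass.UNCLASSIFIED, dtype=np.uint8)
    out[floored <= 20] = HueClass.BLACK
    out[(floored >= 21) & (floored <= 24)] = HueClass.BLUE
    out[(floored >= 25) & (floored <= 27)] = HueClass.GREEN
    out[floored >= 43] = HueClass.BACKGROUND
    return out


def _cell_region(track: CellTrack, t: float, meta: StackMeta, pad: float):
    """Pixel indices of the padded cell-oriented rectangle (wrapping)."""
    x, y, th = _pose_at(track, t)
    corners = _cell_corners(
        x, y, th, track.cell_length + 2 * pad, track.cell_width + 2 * pad
    ) / meta.pixel_size
    rows, cols = meta.shape
    xs = [0.0] + ([cols] if corners[:, 0].min() < 0 else []) + (
        [-cols] if corners[:, 0].max() >= cols else [])
    ys = [0.0] + ([rows] if corners[:, 1].min() < 0 else []) + (
        [-rows] if corners[:, 1].max() >= rows else [])
    rr_all, cc_all = [], []
    for sx in xs:
        for sy in ys:
            rr, cc = draw_polygon(corners[:, 1] + sy, corners[:, 0] + sx,
                                  shape=meta.shape)
            rr_all.append(rr)
            cc_all.append(cc)
    return np.concatenate(rr_all), np.concatenate(cc_all)


def dry_fraction_frame(
    class_map: np.ndarray, track: CellTrack, t: float, meta: StackMeta,
    pad: float = DEFAULT_PAD_UM,
) -> float:
    """Non-background fraction of the cell's padded oriented box at ``t``."""
    rr, cc = _cell_region(track, t, meta, pad)
    if len(rr) == 0:
        raise ValueError("empty cell region")
    return float(np.mean(class_map[rr, cc] != HueClass.BACKGROUND))


def dry_fraction_timeseries(
    class_maps: Iterable[np.ndarray],
    track: CellTrack,
    meta: StackMeta,
    pad: float = DEFAULT_PAD_UM,
    frame_times: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-frame non-background fraction around one cell.

    ``class_maps`` iterates over classified hue maps; ``frame_times``
    defaults to the track's own frame times.  A fully wet cell yields 0
    (its pixels carry background hue); a fully dry stationary rod yields
    roughly (body area) / (padded box area).
    """
    fractions = []
    for f, cmap in enumerate(class_maps):
        t = track.times[f] if frame_times is None else frame_times[f]
        fractions.append(dry_fraction_frame(cmap, track, t, meta, pad))
    return np.asarray(fractions)


@dataclass
class WetnessEvent:
    """One drying (STOPPING) or re-wetting (WETTING) transition.

    STOPPING: the dry fraction rises through the upper hysteresis
    threshold; ``t_start`` is the last wet sample before the rise and
    ``t_end`` the first sample at/above the threshold.  WETTING mirrors it
    downward through the lower threshold.  ``classes`` lists the dominant
    non-background classes over the transition, condensed.
    """

    cell_id: int
    kind: str                 # "STOPPING" | "WETTING"
    t_start: float
    t_end: float
    classes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("event must have t_end > t_start")
        if self.kind not in ("STOPPING", "WETTING"):
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def detect_wetness_events(
    dry_fraction: np.ndarray,
    times: np.ndarray,
    cell_id: int = 0,
    on: float = HYSTERESIS_ON,
    off: float = HYSTERESIS_OFF,
) -> list[WetnessEvent]:
    """Hysteresis detection of drying/re-wetting transitions.

    The cell is declared dry when the fraction rises through ``on`` and
    wet again when it falls through ``off`` (0 < off < on < 1), so events
    strictly alternate STOPPING, WETTING, STOPPING, ...  Transitions still
    open at the end of the series are dropped.
    """
    if not 0.0 < off < on < 1.0:
        raise ValueError("need 0 < off < on < 1")
    frac = np.asarray(dry_fraction, dtype=float)
    times = np.asarray(times, dtype=float)
    if frac.shape != times.shape:
        raise ValueError("dry_fraction and times must align")
    events: list[WetnessEvent] = []
    dry = frac[0] >= on
    last_wet_idx = 0
    last_dry_idx = 0 if dry else None
    for i in range(1, len(frac)):
        if not dry and frac[i] >= on:
            events.append(
                WetnessEvent(
                    cell_id=cell_id,
                    kind="STOPPING",
                    t_start=float(times[last_wet_idx]),
                    t_end=float(times[i]),
                )
            )
            dry = True
            last_dry_idx = i
        elif dry and frac[i] <= off:
            events.append(
                WetnessEvent(
                    cell_id=cell_id,
                    kind="WETTING",
                    t_start=float(times[last_dry_idx]),
                    t_end=float(times[i]),
                )
            )
            dry = False
            last_wet_idx = i
        elif dry:
            last_dry_idx = i
        else:
            if frac[i] <= off:
                last_wet_idx = i
    return events


def stall_durations(events: Sequence[WetnessEvent]) -> np.ndarray:
    """Dry-episode durations from paired STOPPING -> WETTING events.

    The duration runs from the moment the cell is declared dry (the end of
    a STOPPING transition) to the moment it is declared wet again (the end
    of the following WETTING transition); distributionally this mirrors
    the stalled (open-flagella) dwell times.
    """
    out = []
    for ev, nxt in zip(events, events[1:]):
        if ev.kind == "STOPPING" and nxt.kind == "WETTING":
            out.append(nxt.t_end - ev.t_end)
    return np.asarray(out)
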