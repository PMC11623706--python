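"""End-to-end pipeline: simulate -> render -> detect -> statistics.

The pipeline glues the generator, renderer and analysis stages together at
a configurable scale and writes every intermediate artifact plus a single
JSON summary of the headline statistics.  Defaults embody the canonical
acquisition constants (50 frames/s, 0.02 s exposure, long-exposure ratio
10, a 10 x 10 occupancy grid with window durations in 5 s steps, the
7 um/s fast-speed split and the DIC hue bands), at a reduced arena size so
a full run completes in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sp_stats

from . import ctmc, hue, immobility, kinematics, render
from .model import FlagellarState
from .model import default_flagellar_model
from .swarm import (
    SwarmConfig,
    simulate_swarm,
    swarm_motility_model,
    with_stall_bias,
)
from . import io as sio

__all__ = ["PipelineConfig", "ConfigError", "PipelineError", "run_pipeline"]

log = logging.getLogger("swarmstall")

SCHEMA_VERSION = 1
STAGES = ("simulate", "render", "detect", "occupancy", "kinematics", "hue", "ctmc")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Nested pipeline configuration with canonical defaults."""

    # generator
    arena_width: float = 40.0
    arena_height: float = 40.0
    n_cells: int | None = 20
    surface_fraction: float = 0.3          # used when n_cells is None
    duration: float = 60.0
    frame_interval: float = 0.02           # 50 frames/s
    stall_bias: float = 1.0                # > 1 emulates a drier surface
    motility_model: str = "fitted"         # "fitted" | "swarm"
    run_speed_mean: float = 19.5
    # renderer
    pixel_size: float = 0.4
    exposure: float = 0.02
    noise_sigma: float = 0.02
    n_subsamples: int = 11
    long_exposure_ratio: int = 10
    # detection / occupancy
    intensity_threshold: float = 0.95
    min_area_fraction: float = 0.9
    min_coverage_fraction: float = 1.0 / 3.0
    occupancy_durations_step: float = 5.0
    occupancy_durations_stop: float = 360.0
    # kinematics
    fast_threshold: float = 7.0
    neighbor_cutoffs: tuple[float, ...] = (3.0, 5.0, 7.0, 10.0)
    # hue
    hue_pad: float = 0.25
    hue_on: float = 0.5
    hue_off: float = 0.2
    hue_noise_rate: float = 0.001
    # ctmc fitting
    mixture_restarts: int = 10
    # seeding
    seed: int = 0
    stage_seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells is not None and self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1 (or null to derive from density)")
        if self.long_exposure_ratio < 1:
            raise ConfigError("long_exposure_ratio must be >= 1")
        if not 0 < self.hue_off < self.hue_on < 1:
            raise ConfigError("need 0 < hue_off < hue_on < 1")
        if self.motility_model not in ("fitted", "swarm"):
            raise ConfigError(f"unknown motility_model {self.motility_model!r}")
        w_px = self.arena_width / self.pixel_size
        h_px = self.arena_height / self.pixel_size
        if abs(w_px - round(w_px)) > 1e-9 or abs(h_px - round(h_px)) > 1e-9:
            raise ConfigError("arena must map to a whole number of pixels")
        if round(w_px) % 10 or round(h_px) % 10:
            raise ConfigError("image dimensions must divide by the 10 x 10 grid")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "neighbor_cutoffs" in data:
            data = {**data, "neighbor_cutoffs": tuple(data["neighbor_cutoffs"])}
        return cls(**data)

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        """Deterministic per-stage seed fan-out from the master seed.

        Overriding one stage's seed (``stage_seeds``) leaves every other
        stage's randomness unchanged.
        """
        if stage in self.stage_seeds:
            return np.random.SeedSequence(int(self.stage_seeds[stage]))
        return np.random.SeedSequence(
            entropy=int(self.seed), spawn_key=(STAGES.index(stage),)
        )

    def swarm_config(self) -> SwarmConfig:
        return SwarmConfig(
            arena_width=self.arena_width,
            arena_height=self.arena_height,
            n_cells=self.n_cells,
            surface_fraction=self.surface_fraction,
            run_speed_mean=self.run_speed_mean,
            duration=self.duration,
            frame_interval=self.frame_interval,
            seed=self.seed,
        )

    def stack_meta(self) -> render.StackMeta:
        shape = (
            int(round(self.arena_height / self.pixel_size)),
            int(round(self.arena_width / self.pixel_size)),
        )
        return render.StackMeta(
            shape=shape,
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            exposure=self.exposure,
        )

    def cell_area_px(self) -> float:
        return 7.0 * 1.0 / self.pixel_size**2


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _run_simulate(cfg: PipelineConfig, outdir: Path):
    if cfg.motility_model == "fitted":
        model = with_stall_bias(default_flagellar_model(), cfg.stall_bias)
    elif cfg.motility_model == "swarm":
        model = swarm_motility_model(stall_bias=cfg.stall_bias)
    else:
        raise ConfigError(f"unknown motility_model {cfg.motility_model!r}")
    tracks = simulate_swarm(cfg.swarm_config(), model, seed=cfg.stage_seed("simulate"))
    sio.write_tracks(tracks, outdir / "tracks.csv")
    log.info("simulated %d cells for %.1f s", len(tracks), cfg.duration)
    return model, tracks


@_stage("render")
def _run_render(cfg: PipelineConfig, tracks, outdir: Path):
    meta = cfg.stack_meta()
    stack = render.render_stack(
        tracks,
        meta,
        n_subsamples=cfg.n_subsamples,
        noise_sigma=cfg.noise_sigma,
        seed=cfg.stage_seed("render"),
    )
    long_stack = render.synthesize_long_exposure(stack, cfg.long_exposure_ratio)
    sio.write_stack(stack, outdir / "stack.tif")
    sio.write_stack(long_stack, outdir / "stack_long.tif")
    log.info(
        "rendered %d frames (%.0f frames/s), %d long-exposure frames",
        len(stack), 1 / stack.frame_interval, len(long_stack),
    )
    return stack, long_stack


@_stage("detect")
def _run_detect(cfg: PipelineConfig, long_stack, outdir: Path):
    masks = [
        immobility.detect_immobile(
            frame,
            intensity_threshold=cfg.intensity_threshold,
            min_area_px=cfg.min_area_fraction * cfg.cell_area_px(),
        )
        for frame in long_stack.frames
    ]
    fractions = [
        immobility.immobile_fraction(m, cfg.n_cells or 1) for m in masks
    ]
    log.info("mean immobile fraction %.3f", float(np.mean(fractions)))
    return masks, float(np.mean(fractions))


@_stage("occupancy")
def _run_occupancy(cfg: PipelineConfig, masks, long_stack, outdir: Path):
    series = immobility.bin_occupancy(
        masks,
        frame_interval=long_stack.frame_interval,
        min_coverage_px=cfg.min_coverage_fraction * cfg.cell_area_px(),
    )
    step = cfg.occupancy_durations_step
    stop = min(cfg.occupancy_durations_stop, series.duration / 2.0)
    durations = np.arange(step, stop + step / 2, step)
    if len(durations) < 5:
        durations = np.linspace(
            series.frame_interval * 2, series.duration / 2.0, 6
        )
    stats_ = immobility.occupancy_stats(series, durations)
    exponent = immobility.fit_std_exponent(stats_)
    counts = stats_.per_bin_fraction[0].mean(axis=0).ravel()
    sw_stat, sw_p, degenerate = immobility.normality_check(counts)
    _, _, decay_1e, first_zero = immobility.occupancy_autocorrelation(series)
    result = {
        "duration_s": stats_.durations.tolist(),
        "mean_fraction": stats_.mean_fraction.tolist(),
        "std": stats_.std.tolist(),
        "exponent": exponent,
        "shapiro_stat": sw_stat,
        "shapiro_p": sw_p,
        "shapiro_degenerate": degenerate,
        "decay_time_s": decay_1e,
        "first_zero_s": first_zero,
    }
    (outdir / "occupancy.json").write_text(json.dumps(result, indent=1, default=float))
    log.info(
        "mean occupancy %.3f, std exponent %.2f, 1/e decay %.2f s",
        float(np.mean(stats_.mean_fraction)), exponent, decay_1e,
    )
    return result


@_stage("kinematics")
def _run_kinematics(cfg: PipelineConfig, tracks, outdir: Path):
    centroids = [
        np.column_stack([[t.x[f] for t in tracks], [t.y[f] for t in tracks]])
        for f in range(tracks[0].n_frames)
    ]
    step = cfg.run_speed_mean * cfg.frame_interval
    linked = kinematics.link_tracks(
        centroids, max_displacement=max(3 * step, 1.0),
        frame_interval=cfg.frame_interval,
    )
    speeds = np.concatenate([
        kinematics.instantaneous_speeds(t)
        for t in tracks
    ])
    summary = kinematics.speed_summary(speeds, fast_threshold=cfg.fast_threshold)
    try:
        tail = kinematics.tail_gaussian_check(summary.bin_edges, summary.counts)
        tail_out = {"curvature": tail.curvature, "r_squared": tail.r_squared}
    except ValueError:
        tail_out = None
    curves = kinematics.speed_vs_neighbors(
        tracks, cutoffs=cfg.neighbor_cutoffs, use_ground_truth_speed=True
    )
    result = {
        "n_linked_tracks": len(linked),
        "fast_mean": summary.fast_mean,
        "n_fast": summary.n_fast,
        "n_samples": summary.n_samples,
        "tail_fit": tail_out,
        "speed_vs_neighbors": {
            str(r): {str(k): v for k, v in curve.items()}
            for r, curve in curves.items()
        },
    }
    (outdir / "kinematics.json").write_text(json.dumps(result, indent=1, default=float))
    log.info("fast-subset mean speed %.2f um/s (n=%d)", summary.fast_mean, summary.n_fast)
    return result


@_stage("hue")
def _run_hue(cfg: PipelineConfig, tracks, outdir: Path):
    meta = cfg.stack_meta()
    n_frames = tracks[0].n_frames
    rng_seed = cfg.stage_seed("hue")
    frame_seeds = rng_seed.spawn(n_frames)
    fractions = np.empty((len(tracks), n_frames))
    for f in range(n_frames):
        t = tracks[0].times[f]
        hmap = render.render_dic_hue(
            tracks, t, meta, seed=np.random.default_rng(frame_seeds[f]),
            noise_rate=cfg.hue_noise_rate,
        )
        cmap = hue.classify_hue(hmap)
        for i, tr in enumerate(tracks):
            fractions[i, f] = hue.dry_fraction_frame(cmap, tr, t, meta, cfg.hue_pad)
    all_events = []
    durations = []
    for i, tr in enumerate(tracks):
        evs = hue.detect_wetness_events(
            fractions[i], tr.times, cell_id=tr.cell_id,
            on=cfg.hue_on, off=cfg.hue_off,
        )
        all_events.extend(evs)
        durations.extend(hue.stall_durations(evs).tolist())
    open_dwells = np.concatenate([
        tr.state_track.durations[
            (tr.state_track.states == FlagellarState.OPEN)
            & ~tr.state_track.censored_flags()
        ]
        for tr in tracks
    ]) if tracks[0].state_track is not None else np.array([])
    ks_p = float("nan")
    if len(durations) >= 10 and len(open_dwells) >= 10:
        ks_p = float(sp_stats.ks_2samp(durations, open_dwells).pvalue)
    result = {
        "n_events": len(all_events),
        "n_stall_durations": len(durations),
        "mean_stall_duration_s": float(np.mean(durations)) if durations else None,
        "ks_p_vs_open_dwells": ks_p,
    }
    (outdir / "hue_events.json").write_text(json.dumps(result, indent=1, default=float))
    log.info("%d DIC events, KS p vs open dwells %.3f", len(all_events), ks_p)
    return result


@_stage("ctmc")
def _run_ctmc(cfg: PipelineConfig, tracks, outdir: Path):
    state_tracks = [t.state_track for t in tracks]
    dwells, counts = ctmc.extract_dwells(state_tracks)
    fits = {}
    for s in range(3):
        d = dwells.uncensored(s)
        fits[s] = ctmc.mle_exponential(d) if len(d) >= 2 else None
    p_hat, rates = ctmc.embedded_matrix(counts, dwells)
    open_d = dwells.uncensored(FlagellarState.OPEN)
    delta_aic = None
    if len(open_d) >= 10:
        single = ctmc.mle_exponential(open_d)
        mix = ctmc.fit_exponential_mixture(
            open_d, seed=np.random.default_rng(cfg.stage_seed("ctmc")),
            n_restarts=cfg.mixture_restarts,
        )
        delta_aic = ctmc.aic_compare(single, mix)
    mem_err = None
    if counts.n_transitions >= 100 and not np.any(np.isnan(p_hat)):
        mem_err = ctmc.memorylessness_error(p_hat, counts.two_step)
    by_state = ctmc.speed_by_state(tracks)
    result = {
        "exit_rates_per_s": [None if np.isnan(r) else float(r) for r in rates],
        "mean_dwells_s": [
            None if f is None else float(f.means[0]) for f in fits.values()
        ],
        "embedded": [[None if np.isnan(v) else float(v) for v in row] for row in p_hat],
        "delta_aic_single_minus_mixture": delta_aic,
        "memorylessness_max_rel_error": mem_err,
        "n_transitions": counts.n_transitions,
        "speed_by_state_mean": {
            by_state[s]["name"]: by_state[s]["mean"] for s in range(3)
        },
    }
    (outdir / "ctmc.json").write_text(json.dumps(result, indent=1, default=float))
    log.info("fitted exit rates %s 1/s", result["exit_rates_per_s"])
    return result


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and return (and write) the summary dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, tracks = _run_simulate(config, outdir)
    stack, long_stack = _run_render(config, tracks, outdir)
    masks, immobile_frac = _run_detect(config, long_stack, outdir)
    occupancy = _run_occupancy(config, masks, long_stack, outdir)
    kin = _run_kinematics(config, tracks, outdir)
    hue_res = _run_hue(config, tracks, outdir)
    ctmc_res = _run_ctmc(config, tracks, outdir)
    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "n_cells": config.n_cells,
        "surface_fraction": config.swarm_config().surface_fraction,
        "immobile_fraction_mean": immobile_frac,
        "occupancy": occupancy,
        "kinematics": kin,
        "hue": hue_res,
        "ctmc": ctmc_res,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True, default=float))
    return summary
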