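"""Synthetic swarm generator: state-coupled motility on a periodic arena.

Each cell carries an independent flagellar-state history (a CTMC sampled by
:func:`swarmstall.model.simulate_ctmc`) that drives its motion:

* CLOSED (run): straight motion with a per-dwell Rayleigh speed draw and a
  persistent heading;
* PARTIAL (tumble): slower motion (a configurable fraction of a run-speed
  draw) with the heading redrawn at the start of the dwell;
* OPEN (stall): exactly zero displacement.

Speeds are additionally modulated by the local density through a saturating
ramp ``g(k)`` of the number of neighbors within a cutoff radius: isolated
cells (k = 0) do not move, and the modulation saturates to 1 at ``k_sat``
neighbors -- the qualitative speed-vs-neighbors shape seen in swarms.

Each cell also carries a "wetness" scalar in [0, 1], a proxy for the local
liquid film.  Wetness relaxes toward 0 (first-order, time constant
``tau_dry``) while the cell is immobile -- stalled, or isolated under the
density coupling -- and back toward 1 (time constant ``tau_wet``) while it
moves.  Wetness is exported as ground truth for the DIC hue renderer.

The arena is periodic (minimum-image neighbor distances); cell bodies are
not sterically excluded, so overlaps can occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, special
from scipy.spatial import cKDTree

from .model import (
    FlagellarState,
    StateTrack,
    TransitionModel,
    simulate_ctmc,
)

__all__ = [
    "SwarmConfig",
    "CellTrack",
    "swarm_motility_model",
    "with_stall_bias",
    "simulate_swarm",
    "calibrate_saturation_speed",
    "calibrate_fast_subset_speed",
]

RAYLEIGH_MEAN_FACTOR = float(np.sqrt(np.pi / 2.0))  # mean = sigma * sqrt(pi/2)

CELL_LENGTH_UM = 7.0
CELL_WIDTH_UM = 1.0


@dataclass
class SwarmConfig:
    """Arena geometry, motility scales and coupling parameters.

    Lengths in micrometers, times in seconds, speeds in um/s.
    """

    arena_width: float = 60.0
    arena_height: float = 60.0
    n_cells: int | None = None
    surface_fraction: float = 0.3     # used when n_cells is None
    run_speed_mean: float = 19.5      # mean of the per-dwell Rayleigh run speed
    tumble_speed_fraction: float = 0.4
    tumble_spread: float = np.pi / 2  # reorientation drawn Uniform(+-spread)
    neighbor_cutoff: float = 7.0      # r_c for the density coupling
    k_sat: int = 5                    # g(k) = min(k, k_sat) / k_sat
    coupling_enabled: bool = True
    tau_dry: float = 2.0              # wetness decay while immobile
    tau_wet: float = 0.15             # wetness recovery while moving
    duration: float = 60.0
    frame_interval: float = 0.02      # 50 frames/s
    cell_length: float = CELL_LENGTH_UM
    cell_width: float = CELL_WIDTH_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arena_width <= 0 or self.arena_height <= 0:
            raise ValueError("arena dimensions must be positive")
        for name in (
            "run_speed_mean",
            "tumble_speed_fraction",
            "neighbor_cutoff",
            "duration",
            "frame_interval",
            "tau_dry",
            "tau_wet",
            "cell_length",
            "cell_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cells is None:
            area = self.arena_width * self.arena_height
            self.n_cells = max(
                1, round(self.surface_fraction * area / self.cell_area)
            )
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        # keep the reported surface fraction consistent with n_cells
        self.surface_fraction = (
            self.n_cells * self.cell_area / (self.arena_width * self.arena_height)
        )
        if self.surface_fraction > 1.0:
            raise ValueError("arena too small for n_cells at this density")

    @property
    def cell_area(self) -> float:
        return self.cell_length * self.cell_width

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    def to_dict(self) -> dict:
        return asdict(self)


def with_stall_bias(model: TransitionModel, bias: float) -> TransitionModel:
    """Scale the tumble -> stall branch probability by ``bias``.

    ``bias > 1`` emulates a drier surface (stalls entered more often);
    the CLOSED and OPEN rows and all exit rates are unchanged.
    """
    p = float(model.embedded[1, 2]) * bias
    if not 0 < p < 1:
        raise ValueError("stall bias drives the tumble branch out of (0, 1)")
    emb = model.embedded.copy()
    emb[1] = [1.0 - p, 0.0, p]
    return TransitionModel(exit_rates=model.exit_rates.copy(), embedded=emb)


def swarm_motility_model(stall_bias: float = 1.0) -> TransitionModel:
    """Population-level motility chain for the swarm generator.

    Runs last ~2 s between reorientations and stalls are entered from the
    tumble state with probability ``0.2 * stall_bias`` (wet-surface
    default), so that only a small fraction of the population is stalled at
    any time -- the regime in which a swarm shows scattered temporarily
    immobile cells among moving clusters.  ``stall_bias > 1`` emulates a
    drier surface (more frequent stalls); tumble and stall dwell scales
    keep the measured single-cell values (0.21 s and 0.95 s).
    """
    p_stall = 0.2 * stall_bias
    if not 0 < p_stall < 1:
        raise ValueError("stall_bias out of range")
    return TransitionModel(
        exit_rates=np.array([0.5, 4.76, 1.05]),
        embedded=np.array(
            [
                [0.0, 1.0, 0.0],
                [1.0 - p_stall, 0.0, p_stall],
                [0.0, 1.0, 0.0],
            ]
        ),
    )


@dataclass
class CellTrack:
    """Sampled trajectory of one cell in physical units.

    ``times`` are uniformly spaced frame times (s); positions in um with
    periodic wrap on the arena; ``theta`` is the heading/orientation (rad);
    ``states`` the flagellar state per frame; ``wetness`` the liquid proxy
    in [0, 1].  ``speed`` stores the generator's ground-truth frame speed
    (um/s) and ``neighbors`` the neighbor count used for the coupling.
    """

    cell_id: int
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    states: np.ndarray
    wetness: np.ndarray | None = None
    speed: np.ndarray | None = None
    neighbors: np.ndarray | None = None
    state_track: StateTrack | None = None
    cell_length: float = CELL_LENGTH_UM
    cell_width: float = CELL_WIDTH_UM
    arena: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int8)
        n = len(self.times)
        if not (len(self.x) == len(self.y) == len(self.theta) == len(self.states) == n):
            raise ValueError("all per-frame arrays must share one length")
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else np.nan

    @property
    def n_frames(self) -> int:
        return len(self.times)


def _min_image(delta: np.ndarray, box: float) -> np.ndarray:
    return delta - box * np.round(delta / box)


def simulate_swarm(
    config: SwarmConfig,
    model: TransitionModel | None = None,
    seed: int | np.random.SeedSequence | None = None,
    initial_state: FlagellarState | int | None = None,
) -> list[CellTrack]:
    """Simulate the swarm and return one :class:`CellTrack` per cell.

    ``seed`` overrides ``config.seed``; initial flagellar states are drawn
    from the jump chain's stationary distribution unless ``initial_state``
    pins them.  Output is bit-reproducible for a fixed seed.
    """
    if model is None:
        model = swarm_motility_model()
    if seed is None:
        seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    state_seed, motion_seed = ss.spawn(2)
    rng = np.random.default_rng(motion_seed)

    n = config.n_cells
    w, h = config.arena_width, config.arena_height
    dt = config.frame_interval
    n_frames = config.n_frames
    times = np.arange(n_frames) * dt

    # independent state history per cell
    state_rngs = [np.random.default_rng(s) for s in state_seed.spawn(n)]
    if initial_state is None:
        init_states = np.random.default_rng(state_seed).choice(
            3, size=n, p=model.embedded_stationary()
        )
    else:
        init_states = np.full(n, int(initial_state))
    tracks_states = [
        simulate_ctmc(model, t_total=config.duration + dt, initial=init_states[i],
                      seed=state_rngs[i])
        for i in range(n)
    ]

    # per-dwell base speeds: Rayleigh for runs, scaled Rayleigh for tumbles,
    # zero for stalls; heading kick at the start of each PARTIAL dwell
    sigma_run = config.run_speed_mean / RAYLEIGH_MEAN_FACTOR
    dwell_speeds: list[np.ndarray] = []
    dwell_kicks: list[np.ndarray] = []
    for i, st in enumerate(tracks_states):
        nd = len(st.states)
        draws = state_rngs[i].rayleigh(sigma_run, size=nd)
        speeds = np.where(
            st.states == FlagellarState.CLOSED,
            draws,
            np.where(
                st.states == FlagellarState.PARTIAL,
                config.tumble_speed_fraction * draws,
                0.0,
            ),
        )
        kicks = state_rngs[i].uniform(-config.tumble_spread, config.tumble_spread, size=nd)
        dwell_speeds.append(speeds)
        dwell_kicks.append(kicks)

    # frame-sampled state, base speed and tumble kick per cell
    dwell_idx = np.empty((n, n_frames), dtype=np.int64)
    states = np.empty((n, n_frames), dtype=np.int8)
    base_all = np.empty((n, n_frames))
    kick_all = np.empty((n, n_frames))
    for i, st in enumerate(tracks_states):
        idx = np.clip(
            np.searchsorted(st.t_start, times, side="right") - 1,
            0,
            len(st.states) - 1,
        )
        dwell_idx[i] = idx
        states[i] = st.states[idx]
        base_all[i] = dwell_speeds[i][idx]
        kick_all[i] = dwell_kicks[i][idx]

    x = rng.uniform(0, w, size=n)
    y = rng.uniform(0, h, size=n)
    theta = rng.uniform(-np.pi, np.pi, size=n)
    wet = np.ones(n)

    xs = np.empty((n, n_frames))
    ys = np.empty((n, n_frames))
    ths = np.empty((n, n_frames))
    wets = np.empty((n, n_frames))
    speeds_out = np.zeros((n, n_frames))
    ks_out = np.zeros((n, n_frames), dtype=np.int32)

    decay = np.exp(-dt / config.tau_dry)
    recover = np.exp(-dt / config.tau_wet)
    prev_dwell = dwell_idx[:, 0].copy()

    for f in range(n_frames):
        cur_dwell = dwell_idx[:, f]
        cur_state = states[:, f]

        # apply the tumble reorientation once per PARTIAL dwell entry
        if f > 0:
            tumbling = (cur_dwell != prev_dwell) & (cur_state == FlagellarState.PARTIAL)
            if np.any(tumbling):
                theta[tumbling] = np.mod(
                    theta[tumbling] + kick_all[tumbling, f] + np.pi, 2 * np.pi
                ) - np.pi
            prev_dwell = cur_dwell

        # neighbor counts with minimum-image distances
        pts = np.column_stack([np.mod(x, w), np.mod(y, h)])
        tree = cKDTree(pts, boxsize=[w, h])
        k = tree.query_ball_point(
            pts, config.neighbor_cutoff, return_length=True
        ) - 1  # exclude self
        ks_out[:, f] = k

        g = (
            np.minimum(k, config.k_sat) / config.k_sat
            if config.coupling_enabled
            else np.ones(n)
        )
        v = base_all[:, f] * g
        v[cur_state == FlagellarState.OPEN] = 0.0

        xs[:, f] = x
        ys[:, f] = y
        ths[:, f] = theta
        wets[:, f] = wet
        speeds_out[:, f] = v

        # advance to next frame
        x = np.mod(x + v * np.cos(theta) * dt, w)
        y = np.mod(y + v * np.sin(theta) * dt, h)
        # wetness decays whenever the cell is actually immobile (stalled,
        # or isolated under the density coupling) and recovers while moving
        immobile = v == 0.0
        wet = np.where(immobile, wet * decay, 1.0 - (1.0 - wet) * recover)

    tracks = []
    for i in range(n):
        tracks.append(
            CellTrack(
                cell_id=i,
                times=times,
                x=xs[i],
                y=ys[i],
                theta=ths[i],
                states=states[i],
                wetness=wets[i],
                speed=speeds_out[i],
                neighbors=ks_out[i],
                state_track=tracks_states[i],
                cell_length=config.cell_length,
                cell_width=config.cell_width,
                arena=(w, h),
            )
        )
    return tracks


def _rayleigh_tail_moments(mean: float, a: float) -> tuple[float, float]:
    """(P(S > a), E[S ; S > a]) for a Rayleigh with the given mean."""
    sigma = mean / RAYLEIGH_MEAN_FACTOR
    p = np.exp(-(a**2) / (2 * sigma**2))
    es = a * p + sigma * np.sqrt(np.pi / 2) * special.erfc(a / (sigma * np.sqrt(2)))
    return float(p), float(es)


def calibrate_saturation_speed(
    config: SwarmConfig,
    model: TransitionModel,
    saturation_speed: float = 20.0,
) -> SwarmConfig:
    """Set the run-speed scale so the density-saturated mean speed is fixed.

    At full coupling (g = 1) the long-run mean speed over all states is
    ``(f_C + tumble_fraction * f_P) * run_speed_mean`` where ``f`` are the
    time fractions of the states; solve for ``run_speed_mean`` so that this
    equals ``saturation_speed`` (the plateau of the speed-vs-neighbors
    curve, ~20 um/s in dense swarm regions).
    """
    f = model.time_fractions()
    denom = f[FlagellarState.CLOSED] + config.tumble_speed_fraction * f[FlagellarState.PARTIAL]
    out = SwarmConfig(**{**config.to_dict(), "run_speed_mean": saturation_speed / denom,
                         "n_cells": config.n_cells})
    return out


def calibrate_fast_subset_speed(
    config: SwarmConfig,
    model: TransitionModel,
    target_mean: float = 19.5,
    threshold: float = 7.0,
) -> SwarmConfig:
    """Set the run-speed scale so E[speed | speed > threshold] hits a target.

    Mirrors the experimental summary statistic: the mean speed of cells
    moving faster than 7 um/s (19.5 um/s on a wet surface).  Computed
    analytically for the run/tumble Rayleigh mixture weighted by state time
    fractions, with the density coupling at saturation (g = 1).
    """
    f = model.time_fractions()
    fc = f[FlagellarState.CLOSED]
    fp = f[FlagellarState.PARTIAL]
    frac = config.tumble_speed_fraction

    def fast_mean(run_mean: float) -> float:
        p_run, e_run = _rayleigh_tail_moments(run_mean, threshold)
        p_tum, e_tum = _rayleigh_tail_moments(frac * run_mean, threshold)
        num = fc * e_run + fp * e_tum
        den = fc * p_run + fp * p_tum
        return num / den

    sol = optimize.brentq(
        lambda m: fast_mean(m) - target_mean, threshold * 0.5, target_mean * 3.0
    )
    return SwarmConfig(**{**config.to_dict(), "run_speed_mean": float(sol),
                          "n_cells": config.n_cells})
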