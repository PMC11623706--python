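"""Three-state flagellar continuous-time Markov chain (CTMC).

Swarmer cells alternate between three flagellar arrangements -- a closed
bundle (run), a partially open bundle (tumble) and a fully open, spread-out
arrangement (stall).  Transitions are modelled as a CTMC: the dwell time in
state *i* is exponential with the state's exit rate, and the jump target is
drawn from the embedded (jump-chain) transition matrix, which has zero
diagonal and, for the fitted wild-type model, no direct CLOSED<->OPEN
transitions (every stall is entered and left through the partially open
state).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FlagellarState",
    "TransitionModel",
    "StateTrack",
    "default_flagellar_model",
    "simulate_ctmc",
    "sample_jump_chain",
]


class FlagellarState(enum.IntEnum):
    """Flagellar arrangement; integer values index transition matrices."""

    CLOSED = 0   # bundled flagella, straight runs
    PARTIAL = 1  # partially unbundled, reorientation (tumble)
    OPEN = 2     # fully spread flagella, cell stalls

N_STATES = 3
STATE_NAMES = tuple(s.name for s in FlagellarState)


@dataclass(frozen=True)
class TransitionModel:
    """Exit rates (1/s) plus embedded jump-chain probabilities.

    ``embedded`` must be row-stochastic with an exactly zero diagonal:
    a jump always lands in a different state, so dwell intervals are
    maximal by construction.
    """

    exit_rates: np.ndarray
    embedded: np.ndarray

    def __post_init__(self) -> None:
        rates = np.asarray(self.exit_rates, dtype=float)
        emb = np.asarray(self.embedded, dtype=float)
        object.__setattr__(self, "exit_rates", rates)
        object.__setattr__(self, "embedded", emb)
        if rates.shape != (N_STATES,) or np.any(rates <= 0):
            raise ValueError("exit_rates must be 3 positive rates (1/s)")
        if emb.shape != (N_STATES, N_STATES) or np.any(emb < 0):
            raise ValueError("embedded must be a non-negative 3x3 matrix")
        if np.any(np.diag(emb) != 0):
            raise ValueError("embedded diagonal must be exactly zero")
        if np.max(np.abs(emb.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("embedded rows must sum to 1 (tol 1e-12)")

    @property
    def mean_dwells(self) -> np.ndarray:
        """Mean dwell time per state, s."""
        return 1.0 / self.exit_rates

    def embedded_stationary(self) -> np.ndarray:
        """Stationary distribution pi of the jump chain (pi = pi P)."""
        p = self.embedded
        a = np.vstack([p.T - np.eye(N_STATES), np.ones(N_STATES)])
        b = np.concatenate([np.zeros(N_STATES), [1.0]])
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)  # numerical negatives for unreachable states
        return pi / pi.sum()

    def time_fractions(self) -> np.ndarray:
        """Long-run fraction of *time* spent in each state.

        Weights the jump-chain stationary vector by the mean dwell times.
        """
        w = self.embedded_stationary() * self.mean_dwells
        return w / w.sum()


def default_flagellar_model() -> TransitionModel:
    """Fitted wild-type model: exit rates 4, 4.76 and 1.05 1/s.

    The embedded chain routes every transition through the partially open
    state: CLOSED -> PARTIAL and OPEN -> PARTIAL with probability 1, and
    PARTIAL -> CLOSED / PARTIAL -> OPEN with probability 0.5 each.
    """
    return TransitionModel(
        exit_rates=np.array([4.0, 4.76, 1.05]),
        embedded=np.array(
            [
                [0.0, 1.0, 0.0],
                [0.5, 0.0, 0.5],
                [0.0, 1.0, 0.0],
            ]
        ),
    )


@dataclass
class StateTrack:
    """Piecewise-constant state history: contiguous dwell intervals.

    ``states[i]`` holds between ``t_start[i]`` and ``t_end[i]``; intervals
    tile ``[0, t_total]`` without gaps and consecutive states differ.  The
    first and last dwells are censored (their true length is unobserved).
    """

    states: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        n = len(self.states)
        if not (len(self.t_start) == len(self.t_end) == n) or n == 0:
            raise ValueError("states/t_start/t_end must be equal nonzero length")
        if np.any(self.t_end <= self.t_start):
            raise ValueError("dwell intervals must have t_end > t_start")
        if n > 1:
            if not np.allclose(self.t_end[:-1], self.t_start[1:]):
                raise ValueError("dwell intervals must be contiguous")
            if np.any(self.states[:-1] == self.states[1:]):
                raise ValueError("consecutive dwells must change state")

    @property
    def durations(self) -> np.ndarray:
        return self.t_end - self.t_start

    @property
    def t_total(self) -> float:
        return float(self.t_end[-1])

    def censored_flags(self) -> np.ndarray:
        """Boolean flag per dwell: first and last intervals are censored."""
        flags = np.zeros(len(self.states), dtype=bool)
        flags[0] = True
        flags[-1] = True
        return flags

    def state_at(self, t) -> np.ndarray:
        """State at time(s) ``t`` (right-open intervals; t_total allowed)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_start[0]) or np.any(t > self.t_end[-1] + 1e-12):
            raise ValueError("time outside track support")
        idx = np.clip(
            np.searchsorted(self.t_start, t, side="right") - 1,
            0,
            len(self.states) - 1,
        )
        return self.states[idx]

    def slice(self, t0: float, t1: float) -> "StateTrack":
        """Restrict the history to an observation window [t0, t1].

        Dwells straddling the window edges are truncated, so the first and
        last intervals of the result are genuinely censored.
        """
        if not (self.t_start[0] <= t0 < t1 <= self.t_end[-1]):
            raise ValueError("window outside track support")
        keep = (self.t_end > t0) & (self.t_start < t1)
        return StateTrack(
            states=self.states[keep],
            t_start=np.clip(self.t_start[keep], t0, t1),
            t_end=np.clip(self.t_end[keep], t0, t1),
        )

    def occupancy_in_window(self, t0: float, t1: float, state: int) -> float:
        """Fraction of [t0, t1] spent in ``state``."""
        if t1 <= t0:
            raise ValueError("window must have t1 > t0")
        lo = np.maximum(self.t_start, t0)
        hi = np.minimum(self.t_end, t1)
        overlap = np.clip(hi - lo, 0.0, None)
        return float(overlap[self.states == state].sum() / (t1 - t0))


def sample_jump_chain(
    embedded: np.ndarray,
    n_transitions: int,
    initial: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``n_transitions + 1`` states of the embedded jump chain."""
    emb = np.asarray(embedded, dtype=float)
    if np.max(np.abs(emb.sum(axis=1) - 1.0)) > 1e-12:
        raise ValueError("embedded rows must sum to 1")
    cum = np.cumsum(emb, axis=1)
    # scalar threshold comparison per step; cheap enough for 10^6 jumps
    t0 = cum[:, 0].tolist()
    t1 = cum[:, 1].tolist()
    u = rng.random(n_transitions)
    states = np.empty(n_transitions + 1, dtype=np.int8)
    s = int(initial)
    states[0] = s
    for i in range(n_transitions):
        ui = u[i]
        s = int(ui > t0[s]) + int(ui > t1[s])
        states[i + 1] = s
    return states


def simulate_ctmc(
    model: TransitionModel,
    t_total: float | None = None,
    initial: FlagellarState | int = FlagellarState.CLOSED,
    seed: int | np.random.Generator | None = None,
    n_transitions: int | None = None,
) -> StateTrack:
    """Gillespie simulation of the flagellar CTMC.

    Exactly one of ``t_total`` (simulate until this time, truncating the
    final dwell) or ``n_transitions`` (simulate a fixed number of jumps)
    must be given.

    Parameters
    ----------
    model : TransitionModel
    t_total : float, optional
        Total simulated time, s.  The last dwell is censored at ``t_total``.
    initial : FlagellarState
        State at time 0.
    seed : int, Generator or None
        Randomness source.
    n_transitions : int, optional
        Alternative stopping rule: number of jumps to simulate.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if (t_total is None) == (n_transitions is None):
        raise ValueError("specify exactly one of t_total or n_transitions")

    if n_transitions is not None:
        if n_transitions < 0:
            raise ValueError("n_transitions must be >= 0")
        states = sample_jump_chain(model.embedded, n_transitions, int(initial), rng)
        durations = rng.exponential(model.mean_dwells[states])
        t_end = np.cumsum(durations)
        t_start = np.concatenate([[0.0], t_end[:-1]])
        return StateTrack(states, t_start, t_end)

    if t_total <= 0:
        raise ValueError("t_total must be > 0")
    # sample jumps in blocks until the cumulative time passes t_total
    mean_block = float(model.time_fractions() @ model.mean_dwells)  # ~ mean dwell
    states_parts: list[np.ndarray] = []
    dur_parts: list[np.ndarray] = []
    elapsed = 0.0
    s = int(initial)
    while elapsed < t_total:
        remaining = t_total - elapsed
        block = max(16, int(1.5 * remaining / mean_block) + 4)
        chain = sample_jump_chain(model.embedded, block, s, rng)
        st = chain[:-1]
        du = rng.exponential(model.mean_dwells[st])
        states_parts.append(st)
        dur_parts.append(du)
        elapsed += float(du.sum())
        s = int(chain[-1])
    states = np.concatenate(states_parts)
    durations = np.concatenate(dur_parts)
    t_end = np.cumsum(durations)
    keep = np.searchsorted(t_end, t_total, side="left") + 1
    states, t_end = states[:keep], t_end[:keep]
    t_start = np.concatenate([[0.0], t_end[:-1]])
    t_end[-1] = t_total  # censor final dwell
    return StateTrack(states, t_start, t_end)
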