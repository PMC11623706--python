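"""Inference of the three-state flagellar Markov model from labeled tracks.

Given state-labeled trajectories, maximal constant-state runs become dwell
times (first and last dwells are censored and excluded from fits by
default).  Dwell times are fit by exponential maximum likelihood (the MLE
is the sample mean) and, for comparison, by a two-component exponential
mixture via EM; the Akaike information criterion arbitrates.  The embedded
jump chain is estimated from one-step transition counts, and memorylessness
is checked by comparing the empirical two-step transition matrix against
the square of the empirical one-step matrix (the Chapman-Kolmogorov
identity, exact for a Markov chain up to sampling error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import N_STATES, STATE_NAMES, FlagellarState, StateTrack
from .swarm import CellTrack

__all__ = [
    "DwellTimeSet",
    "TransitionCounts",
    "FitResult",
    "extract_dwells",
    "mle_exponential",
    "fit_exponential_mixture",
    "aic_compare",
    "embedded_matrix",
    "memorylessness_error",
    "speed_by_state",
]


@dataclass
class DwellTimeSet:
    """Per-state dwell durations (s) with censoring flags."""

    durations: dict[int, np.ndarray]
    censored: dict[int, np.ndarray]

    def uncensored(self, state: int) -> np.ndarray:
        return self.durations[state][~self.censored[state]]

    def mean_dwells(self) -> np.ndarray:
        """Uncensored sample mean per state (NaN where empty)."""
        out = np.full(N_STATES, np.nan)
        for s in range(N_STATES):
            d = self.uncensored(s)
            if len(d):
                out[s] = d.mean()
        return out


@dataclass
class TransitionCounts:
    """One-step and (overlapping) two-step jump counts, 3 x 3 each."""

    one_step: np.ndarray
    two_step: np.ndarray

    def __post_init__(self) -> None:
        self.one_step = np.asarray(self.one_step, dtype=float)
        self.two_step = np.asarray(self.two_step, dtype=float)
        for m in (self.one_step, self.two_step):
            if m.shape != (N_STATES, N_STATES) or np.any(m < 0):
                raise ValueError("counts must be non-negative 3 x 3")
        if np.any(np.diag(self.one_step) != 0):
            raise ValueError("one-step diagonal must be zero (maximal dwells)")

    @property
    def n_transitions(self) -> int:
        return int(self.one_step.sum())


def _dwells_from_state_sequence(
    states: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """(state, duration) per maximal run of a frame-sampled sequence."""
    states = np.asarray(states)
    change = np.nonzero(np.diff(states) != 0)[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(states)]])
    run_states = states[starts]
    run_durations = (ends - starts) * dt
    return run_states, run_durations


def extract_dwells(
    tracks: list[CellTrack] | list[StateTrack],
) -> tuple[DwellTimeSet, TransitionCounts]:
    """Dwell times and jump counts from state-labeled tracks.

    Accepts frame-sampled :class:`CellTrack` labels (dwell = run length x
    frame interval) or exact :class:`StateTrack` interval lists.  First
    and last dwells of every track are flagged censored.  Two-step counts
    pair the state at jump *n* with the state at jump *n + 2*, over all
    *n* (overlapping pairs).
    """
    durations: dict[int, list] = {s: [] for s in range(N_STATES)}
    censored: dict[int, list] = {s: [] for s in range(N_STATES)}
    one = np.zeros((N_STATES, N_STATES))
    two = np.zeros((N_STATES, N_STATES))
    for tr in tracks:
        if isinstance(tr, StateTrack):
            run_states = np.asarray(tr.states)
            run_durations = tr.durations
        else:
            sts = np.asarray(tr.states)
            if np.any((sts < 0) | (sts >= N_STATES)):
                bad = sts[(sts < 0) | (sts >= N_STATES)][0]
                raise ValueError(f"unknown state symbol {bad!r}")
            run_states, run_durations = _dwells_from_state_sequence(
                sts, tr.frame_interval
            )
        n = len(run_states)
        for i, (s, d) in enumerate(zip(run_states, run_durations)):
            durations[int(s)].append(float(d))
            censored[int(s)].append(i == 0 or i == n - 1)
        for a, b in zip(run_states[:-1], run_states[1:]):
            one[int(a), int(b)] += 1
        for a, b in zip(run_states[:-2], run_states[2:]):
            two[int(a), int(b)] += 1
    dwells = DwellTimeSet(
        durations={s: np.asarray(durations[s]) for s in range(N_STATES)},
        censored={s: np.asarray(censored[s], dtype=bool) for s in range(N_STATES)},
    )
    return dwells, TransitionCounts(one_step=one, two_step=two)


@dataclass
class FitResult:
    """Dwell-time model fit: single exponential or 2-component mixture."""

    family: str               # "exponential" | "mixture2"
    means: np.ndarray         # component means, s
    weights: np.ndarray       # sums to 1
    loglik: float
    n: int
    converged: bool = True

    @property
    def n_parameters(self) -> int:
        # mixture of k exponentials: k means + (k - 1) weights
        return 2 * len(self.means) - 1

    @property
    def aic(self) -> float:
        return 2 * self.n_parameters - 2 * self.loglik


def mle_exponential(dwells: np.ndarray) -> FitResult:
    """Exponential MLE: the fitted mean is the sample mean (closed form)."""
    d = np.asarray(dwells, dtype=float)
    if len(d) < 2:
        raise ValueError("need >= 2 dwells")
    if np.any(d <= 0):
        raise ValueError("dwells must be > 0")
    m = float(d.mean())
    loglik = len(d) * (-np.log(m) - 1.0)
    return FitResult(
        family="exponential",
        means=np.array([m]),
        weights=np.array([1.0]),
        loglik=float(loglik),
        n=len(d),
    )


def _mixture_loglik(d: np.ndarray, means: np.ndarray, weights: np.ndarray) -> float:
    dens = (weights / means) * np.exp(-d[:, None] / means)
    return float(np.sum(np.log(dens.sum(axis=1))))


def fit_exponential_mixture(
    dwells: np.ndarray,
    k: int = 2,
    seed: int | np.random.Generator | None = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FitResult:
    """EM fit of a k-component exponential mixture (default k = 2).

    Restarts from quantile-perturbed initializations; the best fit is
    floored at the single-exponential solution so the mixture log
    likelihood can never fall below the nested model's.
    """
    d = np.asarray(dwells, dtype=float)
    if len(d) < 10:
        raise ValueError("need >= 10 dwells for a mixture fit")
    if np.any(d <= 0):
        raise ValueError("dwells must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    single = mle_exponential(d)
    best_ll = -np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    any_converged = False
    qs = np.quantile(d, np.linspace(0.2, 0.8, k))
    for r in range(n_restarts):
        means = qs * np.exp(rng.normal(0.0, 0.5, size=k)) if r else qs.copy()
        means = np.maximum(means, 1e-12)
        weights = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            dens = (weights / means) * np.exp(-d[:, None] / means)
            total = dens.sum(axis=1, keepdims=True)
            resp = dens / total
            nk = resp.sum(axis=0)
            weights = nk / len(d)
            means = (resp * d[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
            means = np.maximum(means, 1e-12)
            ll = float(np.sum(np.log(total)))
            if ll - ll_prev < tol and np.isfinite(ll_prev):
                converged = True
                break
            ll_prev = ll
        ll = _mixture_loglik(d, means, weights)
        any_converged |= converged
        if ll > best_ll:
            best_ll = ll
            best = (means.copy(), weights.copy())

    if best is None or best_ll < single.loglik:
        # degenerate data: collapse to the nested single-exponential point
        means = np.array([single.means[0]] * k)
        weights = np.full(k, 1.0 / k)
        best_ll = single.loglik
        best = (means, weights)
    order = np.argsort(best[0])
    return FitResult(
        family=f"mixture{k}",
        means=best[0][order],
        weights=best[1][order],
        loglik=best_ll,
        n=len(d),
        converged=any_converged,
    )


def aic_compare(fit_single: FitResult, fit_mixture: FitResult) -> float:
    """Signed AIC difference: AIC(single) - AIC(mixture).

    Negative values favor the single exponential.
    """
    if fit_single.n != fit_mixture.n:
        raise ValueError("fits must be on identical data (n mismatch)")
    return float(fit_single.aic - fit_mixture.aic)


def embedded_matrix(
    counts: TransitionCounts, dwells: DwellTimeSet | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Row-normalized one-step matrix plus exit rates (1 / mean dwell).

    Rows with no outgoing transitions are returned as NaN and flagged by
    the caller's inspection; exit rates are None when no dwell set is
    given.
    """
    row_sums = counts.one_step.sum(axis=1)
    p = np.full((N_STATES, N_STATES), np.nan)
    nonzero = row_sums > 0
    p[nonzero] = counts.one_step[nonzero] / row_sums[nonzero, None]
    rates = None
    if dwells is not None:
        rates = 1.0 / dwells.mean_dwells()
    return p, rates


def memorylessness_error(
    one_step: np.ndarray,
    two_step_counts: np.ndarray,
    eps: float = 0.01,
) -> float:
    """Max relative deviation of the empirical two-step matrix from P^2.

    ``two_step_counts`` are raw counts (rows are normalized here);
    entries of P^2 at or below ``eps`` -- the structural zeros of the
    chain -- are excluded from the maximum.  For a memoryless chain the
    error tends to 0 as the number of transitions grows.
    """
    p = np.asarray(one_step, dtype=float)
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("one_step must be row-stochastic")
    q_counts = np.asarray(two_step_counts, dtype=float)
    row = q_counts.sum(axis=1)
    if np.any(row[(p @ p).sum(axis=1) > 0] <= 0):
        raise ValueError("two-step counts missing for a reachable row")
    q = np.zeros_like(q_counts)
    q[row > 0] = q_counts[row > 0] / row[row > 0, None]
    p2 = p @ p
    sel = p2 > eps
    return float(np.max(np.abs(q[sel] - p2[sel]) / p2[sel]))


def speed_by_state(
    tracks: list[CellTrack],
    bin_width: float = 1.0,
    use_ground_truth_speed: bool = True,
) -> dict[int, dict]:
    """Per-state speed histograms and means from co-sampled labels.

    Samples with missing labels (state < 0) are dropped; the dropped count
    is reported under the ``"dropped"`` key.  Empty states yield empty
    histograms.
    """
    from .kinematics import instantaneous_speeds

    speeds_all, states_all = [], []
    for tr in tracks:
        v = (
            tr.speed
            if use_ground_truth_speed and tr.speed is not None
            else instantaneous_speeds(tr)
        )
        speeds_all.append(np.asarray(v, dtype=float))
        states_all.append(np.asarray(tr.states))
    v = np.concatenate(speeds_all)
    s = np.concatenate(states_all)
    dropped = int(np.sum(s < 0))
    out: dict[int, dict] = {"dropped": dropped}
    top = float(v.max()) + bin_width if len(v) else bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    for st in range(N_STATES):
        vs = v[s == st]
        counts, _ = np.histogram(vs, bins=edges)
        out[st] = {
            "name": STATE_NAMES[st],
            "mean": float(vs.mean()) if len(vs) else float("nan"),
            "n": len(vs),
            "bin_edges": edges,
            "counts": counts,
        }
    return out
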