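"""Tests of dwell-time extraction, exponential fits and Markov checks."""

import numpy as np
import pytest
from scipy import optimize

from swarmstall.ctmc import (
    FitResult,
    TransitionCounts,
    aic_compare,
    embedded_matrix,
    extract_dwells,
    fit_exponential_mixture,
    memorylessness_error,
    mle_exponential,
    speed_by_state,
)
from swarmstall.model import (
    FlagellarState,
    StateTrack,
    default_flagellar_model,
    simulate_ctmc,
)
from swarmstall.swarm import CellTrack


def frame_track(states, dt=0.1):
    states = np.asarray(states)
    times = np.arange(len(states)) * dt
    z = np.zeros(len(states))
    return CellTrack(0, times, z, z, z, states)


class TestExtractDwells:
    def test_constructed_sequence(self):
        """C,C,P,P,P,O at 0.1 s: dwells 0.2/0.3/0.1 with end censoring."""
        dwells, counts = extract_dwells([frame_track([0, 0, 1, 1, 1, 2])])
        assert dwells.durations[0] == pytest.approx([0.2])
        assert dwells.durations[1] == pytest.approx([0.3])
        assert dwells.durations[2] == pytest.approx([0.1])
        assert dwells.censored[0][0] and dwells.censored[2][0]
        assert not dwells.censored[1][0]
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 2] = 1
        assert np.array_equal(counts.one_step, expected)
        assert counts.two_step[0, 2] == 1

    def test_unknown_state_symbol_rejected(self):
        with pytest.raises(ValueError):
            extract_dwells([frame_track([0, 0, 7])])

    def test_jump_frequencies_match_generator(self, fitted_model):
        """Oracle: the embedded matrix fed to the simulator (3 sigma)."""
        track = simulate_ctmc(fitted_model, n_transitions=20_000, seed=3)
        _, counts = extract_dwells([track])
        p_hat, _ = embedded_matrix(counts)
        for i in range(3):
            n = counts.one_step[i].sum()
            p = fitted_model.embedded[i]
            sigma = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
            assert np.all(np.abs(p_hat[i] - p) <= np.maximum(3 * sigma, 1e-9))

    def test_no_closed_open_adjacency_in_fitted_model(self, fitted_model):
        track = simulate_ctmc(fitted_model, n_transitions=10_000, seed=6)
        _, counts = extract_dwells([track])
        assert counts.one_step[0, 2] == 0
        assert counts.one_step[2, 0] == 0

    def test_censoring_exclusion_removes_downward_bias(self, fitted_model):
        """Dwells truncated by the observation window bias the mean low.

        A long history chopped into short observation windows truncates
        the boundary dwells; an estimate that keeps those truncated pieces
        undershoots the true OPEN mean (0.95 s), and the censoring flags
        mark exactly the boundary dwells so callers can treat them apart.
        """
        long_track = simulate_ctmc(fitted_model, t_total=4000.0, seed=7)
        windows = [
            long_track.slice(t0, t0 + 4.0)
            for t0 in np.arange(0.0, 3996.0, 4.0)
        ]
        dwells, _ = extract_dwells(windows)
        full = dwells.durations[FlagellarState.OPEN]
        true_mean = 0.95
        se = true_mean / np.sqrt(len(full))
        assert full.mean() < true_mean - 3 * se
        for w in windows[:20]:
            flags = w.censored_flags()
            assert flags[0] and flags[-1]


class TestMleExponential:
    def test_sample_mean_closed_form(self):
        fit = mle_exponential(np.array([1.0, 3.0]))
        assert fit.means[0] == pytest.approx(2.0)
        assert 1 / fit.means[0] == pytest.approx(0.5)

    def test_printed_dwell_means_give_printed_rates(self):
        for mean, rate in [(0.25, 4.0), (0.21, 4.76), (0.95, 1.05)]:
            fit = mle_exponential(np.full(100, mean))
            sig3 = float(f"{1 / fit.means[0]:.3g}")
            assert sig3 == rate

    def test_large_sample_recovery(self):
        rng = np.random.default_rng(9)
        fit = mle_exponential(rng.exponential(0.95, 100_000))
        assert fit.means[0] == pytest.approx(0.95, rel=0.01)

    def test_closed_form_agrees_with_numeric_optimizer(self):
        """The score equation root matches the sample mean to 1e-10."""
        rng = np.random.default_rng(10)
        d = rng.exponential(0.5, 500)
        n, s = len(d), d.sum()
        rate = optimize.brentq(lambda lam: n / lam - s, 1e-6, 1e6,
                               xtol=1e-14, rtol=1e-15)
        assert abs(1 / rate - mle_exponential(d).means[0]) < 1e-10

    def test_insufficient_or_invalid_data_rejected(self):
        with pytest.raises(ValueError):
            mle_exponential(np.array([1.0]))
        with pytest.raises(ValueError):
            mle_exponential(np.array([1.0, -1.0]))


class TestMixtureFit:
    def test_two_component_recovery(self):
        """0.5/0.5 mixture of means 0.2 and 2.0 recovered within 15%."""
        rng = np.random.default_rng(11)
        d = np.concatenate([
            rng.exponential(0.2, 1000), rng.exponential(2.0, 1000)
        ])
        fit = fit_exponential_mixture(d, seed=12)
        assert fit.means[0] == pytest.approx(0.2, rel=0.15)
        assert fit.means[1] == pytest.approx(2.0, rel=0.15)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_single_exponential_truth_gains_little(self):
        rng = np.random.default_rng(13)
        d = rng.exponential(0.95, 500)
        single = mle_exponential(d)
        mix = fit_exponential_mixture(d, seed=14)
        assert mix.loglik >= single.loglik  # nesting, never below
        assert mix.loglik - single.loglik < 3.0

    def test_mixture_never_below_single_loglik(self):
        rng = np.random.default_rng(15)
        for s in range(5):
            d = rng.exponential(1.0, 50)
            single = mle_exponential(d)
            mix = fit_exponential_mixture(d, seed=s)
            assert mix.loglik >= single.loglik - 1e-9


class TestAicCompare:
    def test_equal_logliks_differ_by_parameter_count(self):
        a = FitResult("exponential", np.array([1.0]), np.array([1.0]),
                      loglik=-100.0, n=50)
        b = FitResult("mixture2", np.array([0.5, 2.0]), np.array([0.5, 0.5]),
                      loglik=-100.0, n=50)
        assert aic_compare(a, b) == pytest.approx(-4.0)
        assert a.aic == pytest.approx(2 * 1 + 200.0)
        assert b.aic == pytest.approx(2 * 3 + 200.0)

    def test_single_truth_mostly_favors_single(self):
        rng = np.random.default_rng(16)
        favored = 0
        for s in range(11):
            d = rng.exponential(1.0, 500)
            delta = aic_compare(
                mle_exponential(d), fit_exponential_mixture(d, seed=s)
            )
            favored += delta <= 0
        assert favored > 5

    def test_bimodal_truth_favors_mixture(self):
        rng = np.random.default_rng(17)
        d = np.concatenate([
            rng.exponential(0.1, 1000), rng.exponential(3.0, 1000)
        ])
        delta = aic_compare(
            mle_exponential(d), fit_exponential_mixture(d, seed=18)
        )
        assert delta > 0

    def test_mismatched_data_rejected(self):
        a = FitResult("exponential", np.array([1.0]), np.array([1.0]), -1.0, 50)
        b = FitResult("mixture2", np.array([1.0, 2.0]),
                      np.array([0.5, 0.5]), -1.0, 60)
        with pytest.raises(ValueError):
            aic_compare(a, b)


class TestEmbeddedMatrix:
    def test_row_normalization_example(self):
        counts = TransitionCounts(
            one_step=np.array([[0, 10, 0], [5, 0, 5], [0, 10, 0]], dtype=float),
            two_step=np.zeros((3, 3)),
        )
        p, _ = embedded_matrix(counts)
        assert np.allclose(
            p, [[0, 1, 0], [0.5, 0, 0.5], [0, 1, 0]]
        )

    def test_empty_row_flagged_nan(self):
        counts = TransitionCounts(
            one_step=np.array([[0, 10, 0], [5, 0, 5], [0, 0, 0]], dtype=float),
            two_step=np.zeros((3, 3)),
        )
        p, _ = embedded_matrix(counts)
        assert np.all(np.isnan(p[2]))
        assert not np.any(np.isnan(p[:2]))

    def test_generator_rates_recovered(self, fitted_model):
        """5 x 10^4 transitions: rates within 2%, probabilities within 0.01."""
        track = simulate_ctmc(fitted_model, n_transitions=50_000, seed=19)
        dwells, counts = extract_dwells([track])
        p_hat, rates = embedded_matrix(counts, dwells)
        assert np.allclose(rates, fitted_model.exit_rates, rtol=0.02)
        assert np.all(np.abs(p_hat - fitted_model.embedded) < 0.01)


class TestMemorylessness:
    def test_exact_square_gives_zero_error(self):
        p = np.array([[0, 1, 0], [0.5, 0, 0.5], [0, 1, 0]])
        q_counts = (p @ p) * 1000
        assert memorylessness_error(p, q_counts) == pytest.approx(0.0)

    def test_error_shrinks_with_sample_size(self, fitted_model):
        """Median error over seeds decreases as transitions grow."""
        medians = []
        for n in (1_000, 10_000, 100_000):
            errs = []
            for s in range(9):
                track = simulate_ctmc(fitted_model, n_transitions=n,
                                      seed=100 + s)
                dwells, counts = extract_dwells([track])
                p_hat, _ = embedded_matrix(counts, dwells)
                errs.append(memorylessness_error(p_hat, counts.two_step))
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]

    def test_semi_markov_cycle_flagged(self):
        """A deterministic C-P-O-P cycle is far from memoryless.

        The one-step frequencies match the fitted chain, but two steps
        after CLOSED the cycle is always in OPEN, whereas a Markov chain
        would return to CLOSED half the time: the analytic two-step
        frequencies give a relative error of 1 at (C, C).
        """
        cycle = np.tile([0, 1, 2, 1], 500)
        track = StateTrack(
            states=cycle,
            t_start=np.arange(len(cycle), dtype=float),
            t_end=np.arange(1, len(cycle) + 1, dtype=float),
        )
        dwells, counts = extract_dwells([track])
        p_hat, _ = embedded_matrix(counts, dwells)
        err = memorylessness_error(p_hat, counts.two_step)
        assert err > 0.5

    def test_non_stochastic_one_step_rejected(self):
        with pytest.raises(ValueError):
            memorylessness_error(np.eye(3) * 0.5, np.ones((3, 3)))


class TestSpeedByState:
    def test_generator_state_speed_ordering(self, uncoupled_tracks):
        _, tracks = uncoupled_tracks
        out = speed_by_state(tracks)
        assert out[int(FlagellarState.OPEN)]["mean"] == 0.0
        assert (
            out[int(FlagellarState.CLOSED)]["mean"]
            > out[int(FlagellarState.PARTIAL)]["mean"]
        )
        assert out["dropped"] == 0

    def test_missing_labels_dropped_and_counted(self):
        times = np.arange(0, 1, 0.02)
        z = np.zeros(len(times))
        tr = CellTrack(0, times, z, z, z, np.full(len(times), -1),
                       speed=np.abs(z) + 1.0)
        out = speed_by_state([tr])
        assert out["dropped"] == len(times)
        assert out[0]["n"] == 0
        assert np.isnan(out[0]["mean"])
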