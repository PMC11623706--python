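"""Tests of immobile-cell detection and bin-occupancy statistics."""

import numpy as np
import pytest

from swarmstall.immobility import (
    OccupancySeries,
    OccupancyStats,
    bin_occupancy,
    detect_immobile,
    fit_std_exponent,
    immobile_fraction,
    normality_check,
    occupancy_autocorrelation,
    occupancy_stats,
)
from swarmstall.render import StackMeta, render_stack, synthesize_long_exposure
from swarmstall.swarm import CellTrack

PIXEL = 0.2
CELL_AREA_PX = 7.0 / PIXEL**2  # 175 px


def scene_tracks(stalled, moving, duration=0.42):
    """Straight-line tracks: ``stalled`` poses and ``moving`` (pose, v)."""
    times = np.arange(0.0, duration, 0.02)
    tracks = []
    cid = 0
    for x, y, th in stalled:
        tracks.append(
            CellTrack(cid, times, np.full_like(times, float(x)),
                      np.full_like(times, float(y)), np.full_like(times, th),
                      2 * np.ones(len(times)))
        )
        cid += 1
    for (x, y, th), v in moving:
        tracks.append(
            CellTrack(cid, times,
                      np.mod(x + v * np.cos(th) * times, 60.0),
                      np.mod(y + v * np.sin(th) * times, 60.0),
                      np.full_like(times, th), np.zeros(len(times))))
        cid += 1
    return tracks


def long_frame(tracks):
    meta = StackMeta(shape=(300, 300), pixel_size=PIXEL, frame_interval=0.02,
                     exposure=0.02)
    stack = render_stack(tracks, meta, n_frames=10, n_subsamples=11)
    return synthesize_long_exposure(stack, 10).frames[0]


STALLED = [(10, 10, 0.3), (30, 40, 1.2), (50, 20, 2.0)]
MOVING = [((10, 30, 0.0), 7.0), ((20, 50, 0.5), 7.5), ((40, 10, 1.0), 10.0),
          ((50, 50, 2.2), 15.0), ((30, 25, 2.8), 20.0), ((15, 45, 0.2), 25.0),
          ((45, 35, 1.8), 8.0)]


class TestDetectImmobile:
    def test_stalled_cells_detected_with_pixel_accuracy(self):
        """3 stalled + 7 moving cells: exactly the stalled ones survive.

        Oracle: the generator's stall labels; centroids must match the
        stalled poses within 1 px.
        """
        frame = long_frame(scene_tracks(STALLED, MOVING))
        mask = detect_immobile(frame, cell_area_px=CELL_AREA_PX)
        assert mask.n_components == 3
        expected = sorted((y / PIXEL, x / PIXEL) for x, y, _ in STALLED)
        got = sorted(map(tuple, mask.centroids))
        for (er, ec), (gr, gc) in zip(expected, got):
            assert abs(er - gr) <= 1.0 and abs(ec - gc) <= 1.0

    def test_only_moving_cells_yields_empty_mask(self):
        """Cells moving at >= 7 um/s all smear below the detection band."""
        frame = long_frame(scene_tracks([], MOVING))
        mask = detect_immobile(frame, cell_area_px=CELL_AREA_PX)
        assert mask.n_components == 0

    def test_all_stalled_yields_one_component_per_cell(self):
        frame = long_frame(scene_tracks(STALLED, []))
        mask = detect_immobile(frame, cell_area_px=CELL_AREA_PX)
        assert mask.n_components == len(STALLED)

    def test_invalid_inputs_rejected(self):
        frame = np.zeros((20, 20))
        with pytest.raises(ValueError):
            detect_immobile(frame, intensity_threshold=1.5, min_area_px=10)
        with pytest.raises(ValueError):
            detect_immobile(frame + 2.0, min_area_px=10)
        with pytest.raises(ValueError):
            detect_immobile(frame)  # neither min_area nor cell area given


class TestImmobileFraction:
    def test_fraction_arithmetic(self):
        frame = long_frame(scene_tracks(STALLED, MOVING))
        mask = detect_immobile(frame, cell_area_px=CELL_AREA_PX)
        assert immobile_fraction(mask, 10) == pytest.approx(0.3)

    def test_empty_mask_gives_zero(self):
        mask = detect_immobile(np.zeros((20, 20)), min_area_px=10)
        assert immobile_fraction(mask, 5) == 0.0
        with pytest.raises(ValueError):
            immobile_fraction(mask, 0)


class TestBinOccupancy:
    def test_single_cell_inside_one_bin(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[42:47, 31:39] = True  # 40 px blob inside bin (4, 3)
        series = bin_occupancy([mask], 0.2, min_coverage_px=30)
        assert series.occupancy.sum() == 1
        assert series.occupancy[0, 4, 3]

    def test_straddling_cell_counts_by_area_split(self):
        """A 60/40 split across a bin boundary.

        Oracle: exact pixel-area split of the constructed rectangle (a
        35 x 5 px rod with 21 columns in one bin, 14 in the next).
        """
        mask = np.zeros((400, 400), dtype=bool)  # 40 px bins
        mask[100:105, 179:214] = True  # 5 x 35 px rod, 175 px total
        left = mask[:, 160:200].sum()
        right = mask[:, 200:240].sum()
        assert (left, right) == (105, 70)  # exact 60/40 split
        series = bin_occupancy([mask], 0.2, min_coverage_px=175 / 3)
        assert series.occupancy[0, 2, 4] and series.occupancy[0, 2, 5]
        series_half = bin_occupancy([mask], 0.2, min_coverage_px=175 / 2)
        assert series_half.occupancy[0, 2, 4]
        assert not series_half.occupancy[0, 2, 5]

    def test_grid_must_divide_image(self):
        with pytest.raises(ValueError):
            bin_occupancy([np.zeros((99, 100), dtype=bool)], 0.2, 10)


class TestOccupancyStats:
    def test_always_occupied_bin_has_fraction_one(self):
        occ = np.zeros((100, 10, 10), dtype=bool)
        occ[:, 2, 2] = True
        series = OccupancySeries(occ, 1.0)
        st = occupancy_stats(series, [5, 10, 20, 25, 50])
        for frac in st.per_bin_fraction:
            assert np.all(frac[:, 2, 2] == 1.0)

    def test_bernoulli_occupancy_matches_binomial_closed_form(self):
        """i.i.d. Bernoulli(0.06) occupancy: mean 0.06 and binomial std.

        Oracle: std of a window fraction is sqrt(p(1-p)/n_frames).
        """
        rng = np.random.default_rng(0)
        p = 0.06
        occ = rng.random((3600, 10, 10)) < p
        series = OccupancySeries(occ, 1.0)
        st = occupancy_stats(series, [5, 10, 30, 60, 120, 360])
        assert np.all(np.abs(st.mean_fraction - p) < 0.005)
        expected = np.sqrt(p * (1 - p) / st.durations)
        assert np.allclose(st.std, expected, rtol=0.1)

    def test_duration_exceeding_series_rejected(self):
        series = OccupancySeries(np.zeros((10, 10, 10), dtype=bool), 1.0)
        with pytest.raises(ValueError):
            occupancy_stats(series, [5, 100])


class TestStdExponent:
    def test_memoryless_occupancy_scales_as_inverse_sqrt(self):
        rng = np.random.default_rng(1)
        occ = rng.random((3600, 10, 10)) < 0.06
        st = occupancy_stats(OccupancySeries(occ, 1.0),
                             [5, 10, 20, 40, 90, 180, 360])
        assert fit_std_exponent(st) == pytest.approx(-0.5, abs=0.1)

    def test_constant_and_inverse_constructed_inputs(self):
        durations = np.array([5.0, 10, 20, 40, 80])
        flat = OccupancyStats(durations, np.full(5, 0.1), np.full(5, 0.02),
                              [np.zeros((1, 10, 10))] * 5)
        assert fit_std_exponent(flat) == pytest.approx(0.0, abs=1e-12)
        inv = OccupancyStats(durations, np.full(5, 0.1), 0.5 / durations,
                             [np.zeros((1, 10, 10))] * 5)
        assert fit_std_exponent(inv) == pytest.approx(-1.0, abs=1e-12)


class TestNormalityCheck:
    def test_gaussian_counts_accepted_in_most_seeds(self):
        """Shapiro-Wilk on Gaussian counts: p > 0.05 in >= 90% of seeds.

        Oracle: repeated simulation of the test's null behavior.
        """
        passes = sum(
            normality_check(np.random.default_rng(s).normal(10, 2, 100))[1] > 0.05
            for s in range(20)
        )
        assert passes >= 18

    def test_bimodal_counts_rejected(self):
        rng = np.random.default_rng(2)
        counts = np.concatenate([rng.normal(0, 0.3, 50), rng.normal(10, 0.3, 50)])
        _, p, degenerate = normality_check(counts)
        assert not degenerate and p < 0.05

    def test_constant_counts_flagged_degenerate(self):
        _, _, degenerate = normality_check(np.full(100, 3.0))
        assert degenerate


class TestAutocorrelation:
    def test_white_noise_has_no_memory(self):
        rng = np.random.default_rng(3)
        occ = rng.random((5000, 10, 10)) < 0.2
        series = OccupancySeries(occ, 1.0)
        _, corr, _, _ = occupancy_autocorrelation(series, max_lag=20)
        assert corr[0] == pytest.approx(1.0)
        assert np.all(np.abs(corr[1:]) < 3 / np.sqrt(5000))

    def test_renewal_decay_time_tracks_on_dwell(self):
        """Two-state on/off occupancy: 1/e time ~ 1/(r_on + r_off).

        Oracle: the analytic autocorrelation of a two-state Markov chain is
        exp(-(r_on + r_off) t); with off-rate << on-rate the decay time is
        close to the mean occupied dwell.  Also checks monotone growth of
        the measured decay with the on-dwell mean.
        """
        rng = np.random.default_rng(4)
        decays = []
        for tau_on in (1.0, 2.0, 4.0):
            tau_off = 20.0 * tau_on
            dt = 0.1
            n = 30_000
            p_on = dt / tau_off
            p_off = dt / tau_on
            states = np.empty((n, 100), dtype=bool)
            s = np.zeros(100, dtype=bool)
            flips = rng.random((n, 100))
            for i in range(n):
                s = np.where(s, flips[i] > p_off, flips[i] < p_on)
                states[i] = s
            series = OccupancySeries(states.reshape(n, 10, 10), dt)
            _, _, d1e, _ = occupancy_autocorrelation(series, max_lag=400)
            expected = 1.0 / (1 / tau_on + 1 / tau_off)
            assert d1e == pytest.approx(expected, rel=0.2)
            decays.append(d1e)
        assert decays[0] < decays[1] < decays[2]

    def test_zero_variance_rejected(self):
        series = OccupancySeries(np.zeros((100, 10, 10), dtype=bool), 1.0)
        with pytest.raises(ValueError):
            occupancy_autocorrelation(series)
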