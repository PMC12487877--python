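import numpy as np
import pytest

from qdpi import fluor_quant as fq
from qdpi.io_core import SessionKey


def block_median_oracle(stack, window):
    """Independent per-block background subtraction (explicit loops)."""
    out = np.empty(stack.shape, dtype=float)
    for start in range(0, stack.shape[0], window):
        block = stack[start : start + window].astype(float)
        bg = np.median(block, axis=0)
        out[start : start + window] = np.maximum(block - bg, 0.0)
    return out


class TestBackgroundSubtraction:
    def test_constant_stack_maps_to_zero(self):
        stack = np.full((10, 4, 4), 7.0)
        assert np.all(fq.subtract_rolling_background(stack, window=4) == 0)

    def test_single_frame_spike_preserved_under_median(self):
        stack = np.full((9, 3, 3), 10.0)
        stack[4, 1, 1] += 100.0
        out = fq.subtract_rolling_background(stack, window=9)
        assert out[4, 1, 1] == pytest.approx(100.0)
        assert np.all(out[[0, 1, 2, 3, 5, 6, 7, 8]] == 0)

    def test_window_larger_than_stack_is_single_block(self, rng):
        stack = rng.uniform(0, 100, (100, 5, 5))
        np.testing.assert_allclose(
            fq.subtract_rolling_background(stack, window=1500),
            fq.subtract_rolling_background(stack, window=100),
        )

    @pytest.mark.parametrize("window", [3, 7, 50])
    def test_matches_brute_force_block_oracle(self, rng, window):
        stack = rng.uniform(0, 255, (41, 4, 6))
        np.testing.assert_allclose(
            fq.subtract_rolling_background(stack, window=window),
            block_median_oracle(stack, window),
        )

    def test_median_subtraction_idempotent_within_block(self, rng):
        stack = rng.uniform(0, 50, (11, 3, 3))  # odd block: exact idempotence
        once = fq.subtract_rolling_background(stack, window=11)
        twice = fq.subtract_rolling_background(once, window=11)
        np.testing.assert_allclose(twice, once)

    def test_selectable_statistics(self):
        stack = np.stack([np.full((2, 2), v) for v in [1.0, 2.0, 9.0]])
        out_min = fq.subtract_rolling_background(stack, window=3, stat="min")
        assert out_min[2, 0, 0] == pytest.approx(8.0)
        with pytest.raises(ValueError):
            fq.subtract_rolling_background(stack, window=3, stat="mode")


class TestFrameMaxTrace:
    def test_single_bright_pixel(self):
        frame = np.zeros((1, 5, 5))
        frame[0, 2, 3] = 42
        assert fq.frame_max_trace(frame).per_frame_values[0] == 42

    def test_all_zero_frame(self):
        assert fq.frame_max_trace(np.zeros((1, 4, 4))).per_frame_values[0] == 0

    def test_mask_restricts_pixels(self):
        frame = np.zeros((1, 4, 4))
        frame[0, 0, 0] = 50  # outside mask
        frame[0, 2, 2] = 30
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 2] = True
        assert fq.frame_max_trace(frame, mask=mask).per_frame_values[0] == 30

    def test_empty_mask_yields_missing_value(self):
        trace = fq.frame_max_trace(np.ones((2, 3, 3)), mask=np.zeros((3, 3), dtype=bool))
        assert np.all(np.isnan(trace.per_frame_values))

    def test_masked_agrees_with_unmasked_when_spot_inside_mask(self, gaussian_frame):
        frame = gaussian_frame(cx=20, cy=20)[None]
        mask = np.zeros((41, 41), dtype=bool)
        mask[10:31, 10:31] = True
        full = fq.frame_max_trace(frame).per_frame_values
        masked = fq.frame_max_trace(frame, mask=mask).per_frame_values
        np.testing.assert_allclose(masked, full)


class TestSummaries:
    def test_linear_percentile_on_ramp(self):
        trace = fq.IntensityTrace(SessionKey(), np.arange(101.0))
        s = fq.summarize_session(trace)
        assert s.p95_value == pytest.approx(95.0)
        assert s.mean_value == pytest.approx(50.0)

    def test_constant_trace(self):
        s = fq.summarize_session(fq.IntensityTrace(SessionKey(), np.full(10, 3.5)))
        assert (s.mean_value, s.p95_value) == (3.5, 3.5)

    def test_matches_sort_based_percentile_oracle(self, rng):
        values = rng.uniform(0, 1, 333)
        s = fq.summarize_session(fq.IntensityTrace(SessionKey(), values))
        v = np.sort(values)
        pos = 0.95 * (len(v) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expected = v[lo] + (pos - lo) * (v[hi] - v[lo])
        assert s.p95_value == pytest.approx(expected)

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            fq.summarize_session(fq.IntensityTrace(SessionKey(), np.array([])))


def summaries(values):
    return [
        fq.SessionSummary(SessionKey(), mean_value=v, p95_value=v) for v in np.atleast_1d(values)
    ]


class TestSNR:
    def test_identical_distributions_give_unity(self):
        assert fq.snr_mean_ratio(summaries([5, 5]), summaries([5, 5])) == pytest.approx(1.0)

    def test_mean_ratio_arithmetic(self):
        assert fq.snr_mean_ratio(summaries(25.1), summaries(10.0)) == pytest.approx(2.51)

    def test_recovers_generator_ratio(self, rng):
        qd = summaries(rng.normal(25.0, 1.0, 50))
        control = summaries(rng.normal(10.0, 1.0, 50))
        assert fq.snr_mean_ratio(qd, control) == pytest.approx(2.5, rel=0.05)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            fq.snr_mean_ratio(summaries(5.0), summaries(0.0))

    def test_spatial_sd_constant_frames(self):
        assert fq.snr_spatial_sd(np.full((3, 4, 4), 9.0)) == 0.0

    def test_spatial_sd_checkerboard_closed_form(self):
        frame = np.indices((4, 4)).sum(axis=0) % 2 * 2.0  # half 0, half 2
        assert fq.snr_spatial_sd(frame[None]) == pytest.approx(1.0)

    def test_spatial_sd_matches_per_frame_oracle(self, rng):
        stack = rng.uniform(0, 50, (7, 6, 6))
        expected = np.mean([stack[i].std() for i in range(7)])
        assert fq.snr_spatial_sd(stack) == pytest.approx(expected)


class TestLongevity:
    def test_first_crossing_day(self):
        res = fq.longevity([0, 1, 2], [5, 4, 3], threshold=3.5)
        assert res.crossing_day == 2 and not res.censored

    def test_censored_when_never_crossing(self):
        res = fq.longevity([0, 7, 119], [50, 40, 30], threshold=3.5)
        assert res.censored and res.crossing_day is None and res.last_day == 119

    def test_exponential_decay_recovers_analytic_crossing(self):
        days = np.arange(0, 30)
        half_life = 4.0
        values = 100.0 * 2.0 ** (-days / half_life)
        threshold = 10.0
        analytic = days[np.argmax(values < threshold)]
        res = fq.longevity(days, values, threshold=threshold)
        assert res.crossing_day == analytic

    def test_threshold_from_pooled_controls(self):
        controls = [fq.IntensityTrace(SessionKey(), np.arange(101.0))]
        assert fq.control_threshold(controls) == pytest.approx(99.0)

    @pytest.mark.parametrize("t_lo,t_hi", [(2.0, 5.0), (1.0, 10.0)])
    def test_monotone_in_threshold(self, t_lo, t_hi):
        """Raising the control threshold never increases the crossing day."""
        days = np.arange(10)
        values = 20.0 * 0.7**days
        lo = fq.longevity(days, values, threshold=t_lo)
        hi = fq.longevity(days, values, threshold=t_hi)
        lo_day = lo.crossing_day if not lo.censored else np.inf
        hi_day = hi.crossing_day if not hi.censored else np.inf
        assert hi_day <= lo_day


class TestAutocorrelation:
    def test_delta_frame_gives_delta_map(self):
        frame = np.zeros((9, 9))
        frame[4, 4] = 3.0
        acmap = fq.spatial_autocorrelation(frame[None], frame_stride=1)
        assert acmap.values[acmap.center] == pytest.approx(1.0)
        rest = acmap.values.copy()
        rest[acmap.center] = 0
        assert np.all(np.abs(rest) < 1e-12)

    def test_gaussian_spot_autocorr_widens_by_sqrt2(self, gaussian_frame):
        sigma = 2.0
        frame = gaussian_frame(sigma=sigma)
        acmap = fq.estimate_spread(fq.spatial_autocorrelation(frame[None], 1))
        assert acmap.spread_x == pytest.approx(sigma * np.sqrt(2), rel=0.02)
        assert acmap.spread_y == pytest.approx(sigma * np.sqrt(2), rel=0.02)

    def test_map_equals_point_reflection(self, rng):
        frame = rng.uniform(0, 1, (8, 10))
        acmap = fq.spatial_autocorrelation(frame[None], 1)
        np.testing.assert_allclose(acmap.values, acmap.values[::-1, ::-1], atol=1e-9)

    def test_all_zero_frames_skipped_with_warning(self, gaussian_frame):
        stack = np.stack([np.zeros((41, 41)), gaussian_frame()])
        with pytest.warns(UserWarning, match="all-zero"):
            acmap = fq.spatial_autocorrelation(stack, frame_stride=1)
        assert acmap.n_frames_used == 1

    def test_stride_samples_every_nth_frame(self, gaussian_frame):
        stack = np.stack([gaussian_frame()] * 5)
        assert fq.spatial_autocorrelation(stack, frame_stride=2).n_frames_used == 3


class TestSpreadEstimation:
    def test_exact_gaussian_map_recovered(self):
        yy, xx = np.mgrid[0:41, 0:41].astype(float)
        surface = np.exp(-((xx - 20) ** 2 / (2 * 9.0) + (yy - 20) ** 2 / (2 * 25.0)))
        acmap = fq.AutocorrMap(values=surface, n_frames_used=1)
        out = fq.estimate_spread(acmap)
        assert out.spread_x == pytest.approx(3.0, abs=1e-3)
        assert out.spread_y == pytest.approx(5.0, abs=1e-3)

    def test_flat_map_flagged_degenerate(self):
        acmap = fq.AutocorrMap(values=np.ones((21, 21)), n_frames_used=1)
        out = fq.estimate_spread(acmap)
        assert out.spread_x is None and out.spread_y is None

    @pytest.mark.parametrize("sigma", [1.0, 2.0, 4.0])
    def test_spread_scales_linearly_with_spot_sigma(self, gaussian_frame, sigma):
        frame = gaussian_frame(sigma=sigma, shape=(61, 61), cx=30, cy=30)
        out = fq.estimate_spread(fq.spatial_autocorrelation(frame[None], 1))
        assert out.spread_x == pytest.approx(sigma * np.sqrt(2), rel=0.05)
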