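import numpy as np
import pytest

from cardiostage.errors import DegenerateFeatureError
from cardiostage.features import (
    FeatureSeries,
    abd_range_windows,
    detect_rpeaks,
    extract_feature_matrix,
    ibi_window_features,
    interpolate_gaps,
    rolling_hr_sd,
    standardize,
)
from cardiostage.signal_io import ChannelSignal, RawRecording


def spike_train(spacing_s, duration_s, fs):
    """An impulse train with unit spikes at exact sample positions."""
    n = int(duration_s * fs)
    x = np.zeros(n)
    planted = []
    t = 0.5
    while t < duration_s:
        p = int(round(t * fs))
        if p < n:
            x[p] = 1.0
            planted.append(p / fs)
        t += spacing_s
    return x, np.array(planted)


class TestDetectRpeaks:
    @pytest.mark.parametrize("spacing", [1.0, 0.5])
    def test_recovers_planted_spacing(self, spacing):
        fs = 250.0
        x, planted = spike_train(spacing, 60.0, fs)
        peaks = detect_rpeaks(x, fs)
        assert abs(len(peaks) - len(planted)) <= 1
        d = np.abs(peaks[:, None] - planted[None, :]).min(axis=1)
        assert np.max(d) <= 0.010
        assert abs(np.median(np.diff(peaks)) - spacing) <= 0.010

    def test_flat_signal_gives_empty(self):
        assert len(detect_rpeaks(np.zeros(5000), 125)) == 0

    def test_too_short_signal_gives_empty(self):
        assert len(detect_rpeaks(np.random.default_rng(0).normal(size=500), 125)) == 0

    def test_peaks_strictly_increasing_with_refractory(self):
        fs = 125.0
        x, _ = spike_train(0.8, 120.0, fs)
        peaks = detect_rpeaks(x, fs)
        assert (np.diff(peaks) >= 0.25).all()


class TestIbiWindowFeatures:
    def test_constant_ibi(self):
        peaks = np.arange(0.5, 15.0, 1.0)
        hr, sd = ibi_window_features(peaks, 15.0)
        assert not hr.missing[0]
        assert hr.values[0] == pytest.approx(60.0)
        assert sd.values[0] == pytest.approx(0.0)

    def test_alternating_ibis_match_closed_form(self):
        # 8 IBIs alternating 0.8/1.2 s: mean 1.0 -> 60 BPM,
        # sample SD = sqrt(8 * 0.2^2 / 7) = 0.2138 s
        times = [0.5]
        for k in range(8):
            times.append(times[-1] + (0.8 if k % 2 == 0 else 1.2))
        hr, sd = ibi_window_features(np.array(times), 15.0)
        assert hr.values[0] == pytest.approx(60.0)
        assert sd.values[0] == pytest.approx(np.sqrt(8 * 0.04 / 7), abs=1e-9)

    def test_single_peak_window_is_missing(self):
        hr, sd = ibi_window_features(np.array([0.5]), 15.0)
        assert hr.missing[0] and sd.missing[0]

    def test_implausible_ibis_discarded(self):
        # a 2.5-s missed-beat gap is outside [0.3, 2.0] s and must not
        # drag the mean heart rate down
        peaks = np.concatenate([np.arange(0.5, 5.0, 1.0),
                                np.arange(7.0, 15.0, 1.0)])
        hr, sd = ibi_window_features(peaks, 15.0)
        assert hr.values[0] == pytest.approx(60.0)
        assert sd.values[0] == pytest.approx(0.0)

    def test_ibi_assigned_to_window_of_ending_peak(self):
        # one IBI straddling the boundary ends at 15.4 -> window 1
        peaks = np.array([0.5, 1.5, 2.5, 14.6, 15.4, 16.4, 17.4, 18.4, 19.4])
        hr, _ = ibi_window_features(peaks, 30.0)
        assert not hr.missing[1]


class TestRollingHrSd:
    def make(self, values):
        return FeatureSeries(np.asarray(values, float),
                             np.zeros(len(values), dtype=bool))

    def test_constant_series_gives_zero(self):
        out = rolling_hr_sd(self.make([60.0] * 40))
        assert not out.missing.any()
        np.testing.assert_allclose(out.values, 0.0)

    def test_alternating_series_matches_sample_sd(self):
        # full window holds eight 55s and eight 65s: SD = sqrt(16*25/15)
        vals = [55.0, 65.0] * 20
        out = rolling_hr_sd(self.make(vals))
        expected = np.sqrt(16 * 25 / 15)
        interior = out.values[8:-8]
        np.testing.assert_allclose(interior, expected, atol=0.01)

    def test_long_missing_run_blanks_enclosed_centers(self):
        s = self.make([60.0] * 40)
        s.missing[10:22] = True  # 12 consecutive missing
        out = rolling_hr_sd(s)
        assert out.missing[14:18].all()

    def test_edges_use_truncated_window(self):
        out = rolling_hr_sd(self.make([60.0] * 20))
        assert not out.missing[0]  # 8 members available in [0, 8)


class TestAbdRange:
    def test_constant_signal(self):
        out = abd_range_windows(np.ones(25 * 45), 25)
        np.testing.assert_allclose(out.values, 0.0)
        assert len(out.values) == 3

    def test_known_span(self):
        x = np.zeros(25 * 15)
        x[10], x[300] = 2.0, -1.0
        out = abd_range_windows(x, 25)
        assert out.values[0] == pytest.approx(3.0)

    def test_sine_range_is_twice_amplitude(self):
        t = np.arange(25 * 15) / 25
        out = abd_range_windows(3.0 * np.sin(2 * np.pi * t / 5.0), 25)
        assert out.values[0] == pytest.approx(6.0, rel=0.01)

    def test_partial_final_window_dropped(self):
        out = abd_range_windows(np.ones(25 * 20), 25)
        assert len(out.values) == 1


class TestInterpolateGaps:
    def make(self, values, missing_idx):
        missing = np.zeros(len(values), dtype=bool)
        missing[list(missing_idx)] = True
        return FeatureSeries(np.asarray(values, float), missing)

    def test_midpoint_fill(self):
        out = interpolate_gaps(self.make([1.0, 0.0, 3.0], [1]))
        assert out.values[1] == pytest.approx(2.0)
        assert not out.missing.any()

    def test_run_of_five_left_missing(self):
        out = interpolate_gaps(self.make([1.0] + [0.0] * 5 + [2.0], range(1, 6)))
        assert out.missing[1:6].all()

    def test_run_of_four_filled_linearly(self):
        out = interpolate_gaps(self.make([0.0] + [9.0] * 4 + [5.0], range(1, 5)))
        np.testing.assert_allclose(out.values, [0, 1, 2, 3, 4, 5])

    def test_leading_and_trailing_never_filled(self):
        out = interpolate_gaps(self.make([0.0, 2.0, 3.0, 0.0], [0, 3]))
        assert out.missing[0] and out.missing[3]

    def test_non_missing_values_untouched(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=50)
        missing = rng.random(50) < 0.3
        s = FeatureSeries(vals.copy(), missing)
        out = interpolate_gaps(s)
        np.testing.assert_array_equal(out.values[~missing], vals[~missing])


class TestStandardize:
    def test_simple_triplet(self):
        out = standardize(FeatureSeries([1.0, 2.0, 3.0], [False] * 3))
        np.testing.assert_allclose(out.values, [-1.0, 0.0, 1.0])
        assert out.mean == pytest.approx(2.0)
        assert out.sd == pytest.approx(1.0)

    def test_idempotent_up_to_tolerance(self):
        rng = np.random.default_rng(3)
        s = standardize(FeatureSeries(rng.normal(5, 2, 100), [False] * 100))
        again = standardize(s)
        np.testing.assert_allclose(again.values, s.values, atol=1e-12)

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            standardize(FeatureSeries([4.0] * 10, [False] * 10))

    def test_missing_entries_stay_missing(self):
        s = FeatureSeries([1.0, 0.0, 2.0, 3.0], [False, True, False, False])
        out = standardize(s)
        assert out.missing[1]


class TestExtractFeatureMatrix:
    def test_interval_count_and_z_score_contract(self, one_night):
        cfg, rec, truth = one_night
        m = extract_feature_matrix(rec)
        assert m.n_intervals == int(rec.duration_s // 15)
        for j in range(4):
            vals = m.values[:, j][~m.missing[:, j]]
            assert abs(np.mean(vals)) < 1e-6 * (1 + len(vals))
            assert abs(np.std(vals, ddof=1) - 1.0) < 1e-6

    def test_remaining_missing_set_to_zero(self, one_night):
        cfg, rec, truth = one_night
        m = extract_feature_matrix(rec)
        assert (m.values[m.missing] == 0.0).all()

    def test_stage_hr_recovery(self, acceptance_dataset, acceptance_preset):
        """Per-stage mean of raw HR matches the configured stage means."""
        _, matrices, truths = acceptance_dataset
        target = acceptance_preset.synthetic.stage_hr_bpm
        sums = np.zeros(4)
        counts = np.zeros(4)
        for m, truth in zip(matrices[:30], truths[:30]):
            raw = m.destandardized()
            stages = np.repeat(truth["stages"], 2)[: m.n_intervals]
            for s in range(4):
                sel = (stages == s) & ~m.missing[:, 0]
                sums[s] += np.nansum(raw[sel, 0])
                counts[s] += sel.sum()
        recovered = sums / counts
        np.testing.assert_allclose(recovered, target, atol=1.0)

    def test_zero_ecg_is_degenerate(self):
        rec = RawRecording(
            "z",
            ecg=ChannelSignal(np.zeros(125 * 300), 125),
            abd=ChannelSignal(np.random.default_rng(0).normal(size=25 * 300), 25),
        )
        with pytest.raises(DegenerateFeatureError):
            extract_feature_matrix(rec)
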