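import dataclasses

import numpy as np
import pytest

from cardiostage.errors import ConfigError
from cardiostage.features import abd_range_windows, detect_rpeaks
from cardiostage.labels import StageClass, expand_to_intervals
from cardiostage.synthetic import (
    SyntheticConfig,
    apply_dialect,
    make_qc_cohort,
    sample_stage_sequence,
    simulate_recording,
    synthesize_abd,
    synthesize_ecg,
    violation_config,
    write_fixture,
)

IDENTITY = tuple(tuple(1.0 if i == j else 0.0 for j in range(4)) for i in range(4))


class TestStageSequence:
    def test_identity_matrix_stays_in_wake(self):
        cfg = SyntheticConfig(duration_h=1.0, transition_matrix=IDENTITY)
        stages = sample_stage_sequence(cfg, 0)
        assert all(s is StageClass.WAKE for s in stages)
        assert len(stages) == 120

    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(duration_h=2.0)
        assert sample_stage_sequence(cfg, 3) == sample_stage_sequence(cfg, 3)
        assert sample_stage_sequence(cfg, 3) != sample_stage_sequence(cfg, 4)

    def test_non_stochastic_matrix_rejected(self):
        bad = tuple(tuple(0.3 for _ in range(4)) for _ in range(4))
        with pytest.raises(ConfigError):
            SyntheticConfig(transition_matrix=bad)

    def test_empirical_transition_frequencies_converge(self):
        cfg = SyntheticConfig(duration_h=8.0)
        counts = np.zeros((4, 4))
        for seed in range(200):
            stages = sample_stage_sequence(cfg, seed)
            codes = np.array([int(s) for s in stages])
            np.add.at(counts, (codes[:-1], codes[1:]), 1)
        empirical = counts / counts.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(
            empirical, np.asarray(cfg.transition_matrix), atol=0.02)


class TestEcg:
    def test_zero_variability_gives_periodic_peaks(self):
        cfg = SyntheticConfig(duration_h=0.5, transition_matrix=IDENTITY,
                              stage_ibi_sd_s=(0.0, 0.0, 0.0, 0.0),
                              hr_drift_amplitude_bpm=0.0)
        _, peaks = synthesize_ecg([StageClass.DEEP] * 60, cfg, 0)
        spacing = np.diff(peaks)
        assert np.std(spacing) <= 1.0 / cfg.ecg_sampling_rate_hz

    def test_detector_recovers_planted_peaks(self):
        cfg = SyntheticConfig(duration_h=8.0)
        stages = sample_stage_sequence(cfg, 5)
        ecg, planted = synthesize_ecg(stages, cfg, 5)
        detected = detect_rpeaks(ecg, cfg.ecg_sampling_rate_hz)
        # nearest detected peak for each planted peak, via sorted search
        idx = np.clip(np.searchsorted(detected, planted), 1, len(detected) - 1)
        d = np.minimum(np.abs(detected[idx] - planted),
                       np.abs(detected[idx - 1] - planted))
        assert (d <= 0.010).mean() >= 0.99

    def test_wake_heart_rate_matches_configuration(self):
        cfg = SyntheticConfig(duration_h=2.0)
        rates = []
        for seed in range(30):
            stages = sample_stage_sequence(cfg, seed)
            _, peaks = synthesize_ecg(stages, cfg, seed)
            ibis = np.diff(peaks)
            epoch_of_end = (peaks[1:] // 30).astype(int)
            wake = np.array([int(stages[min(e, len(stages) - 1)]) == 0
                             for e in epoch_of_end])
            if wake.sum() > 10:
                rates.append(60.0 / np.mean(ibis[wake]))
        assert np.mean(rates) == pytest.approx(cfg.stage_hr_bpm[0], abs=1.0)


class TestAbd:
    def test_no_bursts_means_breathing_range(self):
        cfg = SyntheticConfig(duration_h=0.5, movement_burst_rate_per_wake_epoch=0.0)
        abd = synthesize_abd([StageClass.WAKE] * 60, cfg, 1)
        ranges = abd_range_windows(abd, cfg.abd_sampling_rate_hz).values
        np.testing.assert_allclose(ranges, 2 * cfg.breathing_amplitude, rtol=0.25)

    def test_burst_windows_reach_saturation_span(self):
        cfg = SyntheticConfig(duration_h=0.5,
                              movement_burst_rate_per_wake_epoch=5.0)
        abd = synthesize_abd([StageClass.WAKE] * 60, cfg, 2)
        ranges = abd_range_windows(abd, cfg.abd_sampling_rate_hz).values
        assert ranges.max() >= 1.8 * cfg.abd_saturation

    def test_wake_movement_exceeds_deep(self):
        cfg = SyntheticConfig(duration_h=1.0)
        wake_means, deep_means = [], []
        for seed in range(30):
            wake = synthesize_abd([StageClass.WAKE] * 120, cfg, seed)
            deep = synthesize_abd([StageClass.DEEP] * 120, cfg, seed + 1000)
            wake_means.append(abd_range_windows(wake, cfg.abd_sampling_rate_hz).values.mean())
            deep_means.append(abd_range_windows(deep, cfg.abd_sampling_rate_hz).values.mean())
        assert np.mean(wake_means) > np.mean(deep_means)


class TestDialect:
    def test_dialect_a_is_identity(self):
        cfg = SyntheticConfig(label_dialect="A")
        stages = [StageClass.LIGHT, StageClass.DEEP, StageClass.DEEP, StageClass.DEEP]
        assert apply_dialect(stages, cfg, np.random.default_rng(0)) == stages

    def test_dialect_b_relabels_deep_run_boundaries(self):
        cfg = SyntheticConfig(label_dialect="B", dialect_b_relabel_prob=1.0)
        stages = [StageClass.LIGHT] + [StageClass.DEEP] * 5 + [StageClass.LIGHT]
        out = apply_dialect(stages, cfg, np.random.default_rng(0))
        assert out[1] is StageClass.LIGHT and out[5] is StageClass.LIGHT
        assert out[2:5] == [StageClass.DEEP] * 3

    def test_dialect_strings(self):
        cfg_a = SyntheticConfig(label_dialect="A", unknown_label_rate=0.0)
        cfg_b = SyntheticConfig(label_dialect="B", unknown_label_rate=0.0,
                                duration_h=1.0)
        cfg_a = dataclasses.replace(cfg_a, duration_h=1.0)
        rec_a, _ = simulate_recording(cfg_a, 2)
        rec_b, _ = simulate_recording(cfg_b, 2)
        assert set(rec_a.epoch_labels) <= {"W", "REM", "S2", "S4"}
        assert set(rec_b.epoch_labels) <= {"W", "REM", "N2", "N3"}


class TestSimulateRecording:
    def test_epoch_and_interval_arithmetic(self):
        cfg = SyntheticConfig(duration_h=10.0)
        rec, truth = simulate_recording(cfg, 1)
        assert len(rec.epoch_labels) == 1200
        hyp = expand_to_intervals([StageClass(int(s)) for s in truth["stages"]])
        assert hyp.n_intervals == 2400

    def test_byte_identical_fixtures_under_same_seed(self, tmp_path):
        cfg = SyntheticConfig(duration_h=0.5)
        p1 = write_fixture(tmp_path / "a", cfg, 9)
        p2 = write_fixture(tmp_path / "b", cfg, 9)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_unknown_labels_injected(self):
        cfg = SyntheticConfig(duration_h=4.0, unknown_label_rate=0.2)
        rec, _ = simulate_recording(cfg, 3)
        assert "?" in rec.epoch_labels


class TestQcCohort:
    def test_cohort_composition(self):
        cohort = make_qc_cohort(n_clean=3, violations={"over_duration": 1}, seed=1)
        kinds = [k for _, k, _ in cohort]
        assert kinds == ["clean"] * 3 + ["over_duration"]
        assert cohort[3][0].duration_h == 11.0

    def test_unknown_violation_kind_rejected(self):
        with pytest.raises(ConfigError):
            violation_config("bogus")
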