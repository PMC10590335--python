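"""Synthetic polysomnography: known hypnograms driving ECG + ABD signals.

The generator emulates exactly the signal properties the feature
pipeline relies on, nothing more:

* a Markov chain over {wake, REM, light, deep} at 30-s epochs with a
  realistic transition structure (long stage runs, wake at both ends);
* stage-dependent autonomic tone — each stage has a mean inter-beat
  interval (wake 70 BPM down to deep 56 BPM by default) and a
  stage-dependent short-term IBI variability;
* a slow sinusoidal heart-rate drift across the night (long-term HRV);
* ECG rendered as a stereotyped QRS-like template at each planted peak,
  adequate for QRS detectors though not morphologically realistic;
* an abdominal channel with low-amplitude breathing oscillation and,
  during wake epochs, Poisson-placed movement bursts clipped at the
  saturation amplitude.

Planted R-peak times and the clean stage sequence are returned as ground
truth, so detector recall and staging performance can be measured
exactly. Everything is deterministic under (config, seed).

Label dialects: dialect "A" emits R&K-style strings (S2/S4); dialect "B"
emits AASM-style strings (N2/N3) and additionally relabels boundary
epochs of deep-sleep runs as light sleep with a configured probability,
a controllable stand-in for the systematic scoring drift between the
two standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .labels import StageClass
from .signal_io import ChannelSignal, RawRecording

EPOCH_S = 30.0

#: default 30-s transition matrix, rows/cols ordered (wake, rem, light, deep)
DEFAULT_TRANSITIONS = (
    (0.920, 0.005, 0.070, 0.005),
    (0.020, 0.930, 0.050, 0.000),
    (0.030, 0.030, 0.900, 0.040),
    (0.005, 0.000, 0.075, 0.920),
)


@dataclass
class SyntheticConfig:
    duration_h: float = 8.0
    transition_matrix: tuple = DEFAULT_TRANSITIONS
    #: per-stage mean IBI (s): 70 / 65 / 60 / 56 BPM
    stage_mean_ibi_s: tuple = (60 / 70.0, 60 / 65.0, 60 / 60.0, 60 / 56.0)
    #: per-stage short-term IBI SD (s); wake most variable, deep least
    stage_ibi_sd_s: tuple = (0.050, 0.040, 0.025, 0.015)
    hr_drift_amplitude_bpm: float = 3.0
    hr_drift_period_s: float = 5400.0
    movement_burst_rate_per_wake_epoch: float = 0.3
    breathing_amplitude: float = 1.0
    breathing_freq_hz: float = 0.25
    abd_saturation: float = 5.0
    ecg_sampling_rate_hz: int = 125
    abd_sampling_rate_hz: int = 25
    label_dialect: str = "A"
    dialect_b_relabel_prob: float = 0.8
    unknown_label_rate: float = 0.02

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (4, 4) or (tm < 0).any() or not np.allclose(tm.sum(axis=1), 1.0):
            raise ConfigError("transition matrix must be 4x4 row-stochastic")
        ibi = np.asarray(self.stage_mean_ibi_s)
        if (ibi < 0.3).any() or (ibi > 2.0).any():
            raise ConfigError("stage mean IBIs must lie in [0.3, 2.0] s")
        if self.label_dialect not in ("A", "B"):
            raise ConfigError("label dialect must be 'A' or 'B'")

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_h * 3600.0 / EPOCH_S))

    @property
    def stage_hr_bpm(self) -> np.ndarray:
        return 60.0 / np.asarray(self.stage_mean_ibi_s)


# ---------------------------------------------------------------------------
# Stage sequence
# ---------------------------------------------------------------------------

def sample_stage_sequence(config: SyntheticConfig, seed: int) -> list[StageClass]:
    """Markov chain at 30-s steps, started in wake."""
    tm = np.asarray(config.transition_matrix, dtype=float)
    rng = np.random.default_rng([seed, 0])
    stages = [StageClass.WAKE]
    state = 0
    for _ in range(config.n_epochs - 1):
        state = int(rng.choice(4, p=tm[state]))
        stages.append(StageClass(state))
    return stages


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def _qrs_template(fs: float) -> tuple[np.ndarray, int]:
    """A Q-R-S gaussian-mixture spike; returns (template, center index)."""
    tt = (np.arange(int(round(0.08 * fs)) * 2 + 1) - int(round(0.08 * fs))) / fs
    shape = (
        -0.25 * np.exp(-(((tt + 0.025) / 0.010) ** 2))
        + 1.00 * np.exp(-((tt / 0.007) ** 2))
        - 0.30 * np.exp(-(((tt - 0.025) / 0.012) ** 2))
    )
    return shape, int(round(0.08 * fs))


def synthesize_ecg(stages: list[StageClass], config: SyntheticConfig,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render ECG samples; returns (samples, planted peak times in s).

    IBIs are drawn per current stage (gaussian around the stage mean,
    clipped to [0.3, 2] s) on top of a slow sinusoidal heart-rate drift.
    Planted peak times are aligned to the sampling grid so detector
    error can be measured in samples.
    """
    rng = np.random.default_rng([seed, 1])
    fs = float(config.ecg_sampling_rate_hz)
    duration = len(stages) * EPOCH_S
    n_samples = int(round(duration * fs))
    stage_hr = config.stage_hr_bpm
    drift_phase = rng.uniform(0, 2 * np.pi)

    peak_times = []
    t = rng.uniform(0.2, 1.0)
    while t < duration:
        stage = int(stages[min(int(t / EPOCH_S), len(stages) - 1)])
        hr = stage_hr[stage] + config.hr_drift_amplitude_bpm * np.sin(
            2 * np.pi * t / config.hr_drift_period_s + drift_phase)
        hr = max(hr, 30.0)
        ibi = 60.0 / hr + rng.normal(0.0, config.stage_ibi_sd_s[stage])
        ibi = float(np.clip(ibi, 0.3, 2.0))
        peak_times.append(t)
        t += ibi

    template, center = _qrs_template(fs)
    ecg = rng.normal(0.0, 0.02, n_samples)
    # mild baseline wander, well below the QRS band
    ts = np.arange(n_samples) / fs
    ecg += 0.05 * np.sin(2 * np.pi * ts / 3.3 + rng.uniform(0, 2 * np.pi))

    grid_times = []
    for pt in peak_times:
        p = int(round(pt * fs))
        if p >= n_samples:
            break
        lo = p - center
        hi = lo + len(template)
        s0, s1 = max(lo, 0), min(hi, n_samples)
        ecg[s0:s1] += template[s0 - lo:s1 - lo]
        grid_times.append(p / fs)
    return ecg, np.asarray(grid_times)


# ---------------------------------------------------------------------------
# Abdominal excursion
# ---------------------------------------------------------------------------

def synthesize_abd(stages: list[StageClass], config: SyntheticConfig,
                   seed: int) -> np.ndarray:
    """Breathing-like oscillation plus saturating wake-epoch bursts."""
    rng = np.random.default_rng([seed, 2])
    fs = float(config.abd_sampling_rate_hz)
    duration = len(stages) * EPOCH_S
    n_samples = int(round(duration * fs))
    ts = np.arange(n_samples) / fs
    abd = config.breathing_amplitude * np.sin(
        2 * np.pi * config.breathing_freq_hz * ts + rng.uniform(0, 2 * np.pi))
    abd += rng.normal(0.0, 0.05 * config.breathing_amplitude, n_samples)

    sat = config.abd_saturation
    for e, stage in enumerate(stages):
        if stage != StageClass.WAKE:
            continue
        n_bursts = rng.poisson(config.movement_burst_rate_per_wake_epoch)
        for _ in range(n_bursts):
            start = e * EPOCH_S + rng.uniform(0, EPOCH_S - 5.0)
            length = rng.uniform(2.0, 5.0)
            s0 = int(round(start * fs))
            s1 = min(int(round((start + length) * fs)), n_samples)
            burst = rng.normal(0.0, 2.0 * sat, s1 - s0)
            abd[s0:s1] = np.clip(burst, -sat, sat)
    return np.clip(abd, -sat, sat)


# ---------------------------------------------------------------------------
# Labels and full recordings
# ---------------------------------------------------------------------------

_DIALECT_STRINGS = {
    "A": {StageClass.WAKE: "W", StageClass.REM: "REM",
          StageClass.LIGHT: "S2", StageClass.DEEP: "S4"},
    "B": {StageClass.WAKE: "W", StageClass.REM: "REM",
          StageClass.LIGHT: "N2", StageClass.DEEP: "N3"},
}


def apply_dialect(stages: list[StageClass], config: SyntheticConfig,
                  rng: np.random.Generator) -> list[StageClass]:
    """Dialect B: relabel boundary epochs of deep runs as light."""
    if config.label_dialect != "B":
        return list(stages)
    out = list(stages)
    n = len(out)
    for i, s in enumerate(stages):
        if s != StageClass.DEEP:
            continue
        at_start = i == 0 or stages[i - 1] != StageClass.DEEP
        at_end = i == n - 1 or stages[i + 1] != StageClass.DEEP
        if (at_start or at_end) and rng.random() < config.dialect_b_relabel_prob:
            out[i] = StageClass.LIGHT
    return out


def simulate_recording(config: SyntheticConfig, seed: int,
                       recording_id: str | None = None
                       ) -> tuple[RawRecording, dict]:
    """Compose the generators into one night with ground truth.

    Returns the recording (with raw label strings, unknowns injected)
    and a ground-truth dict holding the planted peak times, the clean
    physiological stage codes, and the dialect-adjusted label codes.
    """
    stages = sample_stage_sequence(config, seed)
    ecg, peaks = synthesize_ecg(stages, config, seed)
    abd = synthesize_abd(stages, config, seed)

    rng = np.random.default_rng([seed, 3])
    label_stages = apply_dialect(stages, config, rng)
    strings = [_DIALECT_STRINGS[config.label_dialect][s] for s in label_stages]
    strings = [
        "?" if rng.random() < config.unknown_label_rate else s for s in strings
    ]

    rec = RawRecording(
        recording_id=recording_id or f"sim{seed:06d}",
        ecg=ChannelSignal(ecg, config.ecg_sampling_rate_hz),
        abd=ChannelSignal(abd, config.abd_sampling_rate_hz),
        epoch_labels=strings,
        duration_s=len(stages) * EPOCH_S,
    )
    truth = {
        "peak_times": peaks,
        "stages": np.array([int(s) for s in stages], dtype=np.int64),
        "label_stages": np.array([int(s) for s in label_stages], dtype=np.int64),
        "stage_hr_bpm": config.stage_hr_bpm.tolist(),
    }
    return rec, truth


def write_fixture(directory: str | Path, config: SyntheticConfig, seed: int,
                  recording_id: str | None = None) -> dict[str, Path]:
    """Write EDF + hypnogram CSV + ground-truth JSON for one night."""
    import json

    from .signal_io import write_edf, write_hypnogram_csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rec, truth = simulate_recording(config, seed, recording_id)
    paths = {
        "edf": directory / f"{rec.recording_id}.edf",
        "hypnogram": directory / f"{rec.recording_id}.hypnogram.csv",
        "truth": directory / f"{rec.recording_id}.truth.json",
    }
    write_edf(paths["edf"], rec)
    write_hypnogram_csv(paths["hypnogram"], rec.epoch_labels)
    paths["truth"].write_text(json.dumps({
        "peak_times": truth["peak_times"].tolist(),
        "stages": truth["stages"].tolist(),
        "label_stages": truth["label_stages"].tolist(),
        "stage_hr_bpm": truth["stage_hr_bpm"],
    }))
    return paths


# ---------------------------------------------------------------------------
# Cohorts with planted QC violations
# ---------------------------------------------------------------------------

def violation_config(kind: str, base: SyntheticConfig | None = None) -> SyntheticConfig:
    """A config engineered to trip one QC rule.

    * ``over_duration`` — an 11-h night (over the 10-h limit);
    * ``low_hr_sd`` — no drift, minimal IBI noise, a chain that never
      leaves wake: middle HR SD collapses below 1.5 BPM;
    * ``high_hr_sd`` — a 25-BPM drift with a short period: middle HR SD
      exceeds 13.5 BPM.
    """
    base = base or SyntheticConfig()
    if kind == "over_duration":
        return replace(base, duration_h=11.0)
    if kind == "low_hr_sd":
        frozen = tuple(tuple(1.0 if i == j else 0.0 for j in range(4)) for i in range(4))
        return replace(base, transition_matrix=frozen,
                       hr_drift_amplitude_bpm=0.0,
                       stage_ibi_sd_s=(0.005, 0.005, 0.005, 0.005))
    if kind == "high_hr_sd":
        return replace(base, hr_drift_amplitude_bpm=25.0, hr_drift_period_s=1800.0)
    raise ConfigError(f"unknown violation kind {kind!r}")


def make_qc_cohort(n_clean: int = 14,
                   violations: dict[str, int] | None = None,
                   base: SyntheticConfig | None = None,
                   seed: int = 0) -> list[tuple[SyntheticConfig, str, int]]:
    """(config, kind, per-night seed) triples; kind 'clean' passes QC."""
    base = base or SyntheticConfig()
    violations = violations if violations is not None else {
        "over_duration": 2, "low_hr_sd": 2, "high_hr_sd": 2,
    }
    cohort: list[tuple[SyntheticConfig, str, int]] = []
    i = 0
    for _ in range(n_clean):
        cohort.append((base, "clean", seed * 1000 + i))
        i += 1
    for kind, count in violations.items():
        for _ in range(count):
            cohort.append((violation_config(kind, base), kind, seed * 1000 + i))
            i += 1
    return cohort
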