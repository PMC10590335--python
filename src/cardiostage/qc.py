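"""Recording-level exclusion rules.

Mirrors the data-exclusion chain applied to every source database:
recordings longer than 10 h, recordings missing the ECG or abdominal
channel, and recordings whose mean-heart-rate SD over the middle 50% of
the night falls below 1.5 BPM (flat, likely detection failure) or above
13.5 BPM (dominated by detection errors) are excluded. Every rule is
evaluated on every recording so the report is an audit trail, not a
short-circuit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix, FeatureSeries, prestandardized_hr_series
from .signal_io import RawRecording

logger = logging.getLogger(__name__)

RULE_CHANNELS = "missing_channel"
RULE_DURATION = "over_duration"
RULE_HR_SD_LOW = "middle_hr_sd_low"
RULE_HR_SD_HIGH = "middle_hr_sd_high"
RULE_FEATURES = "feature_extraction_failed"


@dataclass
class QCConfig:
    max_duration_h: float = 10.0
    hr_sd_low_bpm: float = 1.5
    hr_sd_high_bpm: float = 13.5
    middle_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.middle_fraction <= 1):
            raise ValueError("middle_fraction must be in (0, 1]")
        if self.hr_sd_low_bpm >= self.hr_sd_high_bpm:
            raise ValueError("hr_sd_low_bpm must be below hr_sd_high_bpm")


@dataclass
class ExclusionReport:
    recording_id: str
    passed: bool
    failed_rules: list[str] = field(default_factory=list)
    middle_hr_sd_bpm: float | None = None


def middle_hr_sd(hr_mean: FeatureSeries, middle_fraction: float = 0.5) -> float | None:
    """Sample SD of mean HR over the central fraction of the night.

    The middle region is taken by interval index as the half-open slice
    [floor((1-f)/2 * n), floor((1+f)/2 * n)). Returns None when fewer
    than 2 non-missing values fall inside (undefined; the recording then
    fails QC).
    """
    n = len(hr_mean.values)
    if n == 0:
        return None
    lo = int(np.floor((1 - middle_fraction) / 2 * n))
    hi = int(np.floor((1 + middle_fraction) / 2 * n))
    vals = hr_mean.values[lo:hi][~hr_mean.missing[lo:hi]]
    if len(vals) < 2:
        return None
    return float(np.std(vals, ddof=1))


def apply_exclusions(recording: RawRecording,
                     features: FeatureMatrix | None,
                     config: QCConfig | None = None) -> ExclusionReport:
    """Evaluate every exclusion rule; failures are data, not exceptions."""
    config = config or QCConfig()
    failed: list[str] = []
    mid_sd: float | None = None

    has_ecg = len(recording.ecg.samples) > 0 and recording.ecg.sampling_rate_hz > 0
    has_abd = len(recording.abd.samples) > 0 and recording.abd.sampling_rate_hz > 0
    if not (has_ecg and has_abd):
        failed.append(RULE_CHANNELS)

    if recording.duration_s > config.max_duration_h * 3600.0:
        failed.append(RULE_DURATION)

    if features is None:
        failed.append(RULE_FEATURES)
    else:
        hr = prestandardized_hr_series(features)
        mid_sd = middle_hr_sd(hr, config.middle_fraction)
        if mid_sd is None:
            failed.append(RULE_HR_SD_LOW)
        else:
            if mid_sd < config.hr_sd_low_bpm:
                failed.append(RULE_HR_SD_LOW)
            if mid_sd > config.hr_sd_high_bpm:
                failed.append(RULE_HR_SD_HIGH)

    return ExclusionReport(
        recording_id=recording.recording_id,
        passed=not failed,
        failed_rules=failed,
        middle_hr_sd_bpm=mid_sd,
    )


def write_exclusion_reports(path: str | Path, reports: list[ExclusionReport]) -> None:
    df = pd.DataFrame(
        {
            "recording_id": [r.recording_id for r in reports],
            "passed": [r.passed for r in reports],
            "failed_rules": [";".join(r.failed_rules) for r in reports],
            "middle_hr_sd_bpm": [r.middle_hr_sd_bpm for r in reports],
        }
    )
    df.to_csv(path, index=False)
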