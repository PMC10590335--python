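"""Heart-rate and movement features on 15-s intervals.

Four streams are extracted per recording, in this fixed order:

1. ``hr_mean`` — mean heart rate (BPM) from the inter-beat intervals
   (IBIs) whose ending R-peak falls in the 15-s window;
2. ``ibi_sd`` — sample SD of those IBIs (s), short-term HR variability;
3. ``hr_sd_4min`` — sample SD of the ``hr_mean`` stream over a centered
   4-min (16-interval) window, long-term HR variability;
4. ``abd_range`` — max minus min of the abdominal-excursion signal in the
   window, a movement proxy that saturates during large body movements.

Each stream is gap-interpolated (linear, interior gaps of at most 4
intervals) and then z-scored per recording:

    X_standardized = (X - mu_X) / sigma_X

with mu_X and sigma_X the mean and sample SD of the non-missing entries.
Autonomic tone varies with sleep stage, so these streams carry stage
information despite containing no EEG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import scipy.signal

from .errors import DegenerateFeatureError
from .signal_io import FEATURE_COLUMNS

if TYPE_CHECKING:  # pragma: no cover
    from .signal_io import RawRecording

logger = logging.getLogger(__name__)

WINDOW_S = 15.0
#: physiologically plausible IBI band (s); beats outside are detector noise
IBI_MIN_S = 0.3
IBI_MAX_S = 2.0
#: 4 min of 15-s intervals
HR_SD_WINDOW_INTERVALS = 16
#: minimum non-missing members for a valid 4-min SD
HR_SD_MIN_MEMBERS = 8
MAX_INTERPOLATION_GAP = 4


@dataclass
class FeatureSeries:
    """One per-interval feature stream with an explicit missing mask."""

    values: np.ndarray
    missing: np.ndarray
    mean: float | None = None  # recording-level standardization constants
    sd: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask must have the same shape")


@dataclass
class FeatureMatrix:
    """n_intervals x 4 feature values in the fixed column order."""

    values: np.ndarray
    missing: np.ndarray
    columns: tuple[str, ...] = FEATURE_COLUMNS
    #: per-column (mean, sd) used for standardization, if standardized
    column_stats: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("feature matrix must be n_intervals x 4")

    @property
    def n_intervals(self) -> int:
        return self.values.shape[0]

    def destandardized(self) -> np.ndarray:
        """Reconstruct pre-standardization values (missing left at NaN)."""
        if self.column_stats is None:
            raise ValueError("matrix carries no standardization constants")
        out = np.array(self.values, copy=True)
        for j, (mu, sd) in enumerate(self.column_stats):
            out[:, j] = out[:, j] * sd + mu
        out[self.missing] = np.nan
        return out


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_rpeaks(ecg: np.ndarray, sampling_rate_hz: float) -> np.ndarray:
    """Detect ECG R-peak times (s) with a Pan–Tompkins-style QRS detector.

    Band-pass (5–30 Hz), square, integrate over 150 ms, threshold at a
    fraction of a high percentile of the envelope, then snap each
    candidate to the local maximum of the squared filtered signal. A
    refractory period of 0.25 s is enforced. Too-short or flat signals
    yield an empty array rather than an error.
    """
    ecg = np.asarray(ecg, dtype=float)
    fs = float(sampling_rate_hz)
    if fs < 100 or len(ecg) < 10 * fs:
        return np.array([])
    if np.ptp(ecg) == 0:
        return np.array([])

    nyq = fs / 2.0
    b, a = scipy.signal.butter(2, [5.0 / nyq, min(30.0, 0.9 * nyq) / nyq], btype="band")
    filt = scipy.signal.filtfilt(b, a, ecg)
    sq = filt ** 2
    win = max(1, int(round(0.150 * fs)))
    env = scipy.signal.convolve(sq, np.ones(win) / win, mode="same")

    thresh = 0.2 * np.percentile(env, 99)
    if thresh <= 0:
        return np.array([])
    refractory = int(round(0.25 * fs))
    locs, _ = scipy.signal.find_peaks(env, height=thresh, distance=refractory)
    if len(locs) == 0:
        return np.array([])

    # snap envelope peaks to the sharp QRS maximum
    half = int(round(0.10 * fs))
    snapped = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(len(sq), loc + half + 1)
        snapped.append(lo + int(np.argmax(sq[lo:hi])))
    peaks = np.unique(snapped)

    # enforce refractory after snapping: keep the larger of close pairs
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refractory:
            if sq[p] > sq[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return np.asarray(kept, dtype=float) / fs


# ---------------------------------------------------------------------------
# Windowed features
# ---------------------------------------------------------------------------

def ibi_window_features(peak_times: np.ndarray, duration_s: float,
                        window_s: float = WINDOW_S) -> tuple[FeatureSeries, FeatureSeries]:
    """Mean heart rate (BPM) and IBI SD (s) per 15-s window.

    An IBI belongs to the window containing its ending peak. Windows with
    fewer than two plausible IBIs (inside [0.3, 2.0] s) are missing.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    n_windows = int(np.floor(duration_s / window_s))
    hr = np.zeros(n_windows)
    sd = np.zeros(n_windows)
    missing = np.ones(n_windows, dtype=bool)

    if len(peak_times) >= 2:
        ibis = np.diff(peak_times)
        ends = peak_times[1:]
        ok = (ibis >= IBI_MIN_S) & (ibis <= IBI_MAX_S)
        ibis, ends = ibis[ok], ends[ok]
        idx = np.floor(ends / window_s).astype(int)
        inside = (idx >= 0) & (idx < n_windows)
        ibis, idx = ibis[inside], idx[inside]
        for w in range(n_windows):
            vals = ibis[idx == w]
            if len(vals) >= 2:
                hr[w] = 60.0 / np.mean(vals)
                sd[w] = np.std(vals, ddof=1)
                missing[w] = False

    return (FeatureSeries(hr, missing.copy()), FeatureSeries(sd, missing.copy()))


def rolling_hr_sd(hr_mean: FeatureSeries,
                  window_intervals: int = HR_SD_WINDOW_INTERVALS) -> FeatureSeries:
    """Sample SD of the mean-HR stream over a centered 4-min window.

    The window spans intervals [i - w/2, i + w/2); at the edges the
    truncated window is used. Output is missing where fewer than 8
    non-missing members are available.
    """
    n = len(hr_mean.values)
    out = np.zeros(n)
    missing = np.ones(n, dtype=bool)
    half = window_intervals // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half)
        vals = hr_mean.values[lo:hi][~hr_mean.missing[lo:hi]]
        if len(vals) >= HR_SD_MIN_MEMBERS:
            out[i] = np.std(vals, ddof=1)
            missing[i] = False
    return FeatureSeries(out, missing)


def abd_range_windows(abd: np.ndarray, sampling_rate_hz: float,
                      window_s: float = WINDOW_S) -> FeatureSeries:
    """Max minus min of the abdominal signal per half-open 15-s window."""
    abd = np.asarray(abd, dtype=float)
    spw = int(round(sampling_rate_hz * window_s))
    n_windows = len(abd) // spw
    if n_windows == 0:
        return FeatureSeries(np.zeros(0), np.ones(0, dtype=bool))
    trimmed = abd[: n_windows * spw].reshape(n_windows, spw)
    rng = trimmed.max(axis=1) - trimmed.min(axis=1)
    return FeatureSeries(rng, np.zeros(n_windows, dtype=bool))


# ---------------------------------------------------------------------------
# Gap interpolation and standardization
# ---------------------------------------------------------------------------

def interpolate_gaps(series: FeatureSeries,
                     max_gap: int = MAX_INTERPOLATION_GAP) -> FeatureSeries:
    """Fill interior missing runs of length <= max_gap linearly.

    Longer runs are left entirely missing (no partial fill) and leading /
    trailing runs are never filled. Non-missing values are untouched.
    """
    values = np.array(series.values, copy=True)
    missing = np.array(series.missing, copy=True)
    n = len(values)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        run = j - i
        interior = i > 0 and j < n
        if interior and run <= max_gap:
            left, right = values[i - 1], values[j]
            for k in range(run):
                values[i + k] = left + (right - left) * (k + 1) / (run + 1)
            missing[i:j] = False
        i = j
    return FeatureSeries(values, missing)


def standardize(series: FeatureSeries) -> FeatureSeries:
    """Per-recording z-score of the non-missing entries.

    Raises DegenerateFeatureError when the stream has no variance (the
    recording should then be excluded by QC).
    """
    valid = ~series.missing
    vals = series.values[valid]
    if len(vals) < 2:
        raise DegenerateFeatureError("fewer than 2 non-missing values")
    mu = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if sd <= 0:
        raise DegenerateFeatureError("zero variance feature stream")
    out = np.array(series.values, copy=True)
    out[valid] = (vals - mu) / sd
    return FeatureSeries(out, series.missing.copy(), mean=mu, sd=sd)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def extract_feature_matrix(recording: "RawRecording") -> FeatureMatrix:
    """Run the full feature pipeline on one recording.

    Order: R-peak detection -> windowed IBI features -> rolling 4-min HR
    SD -> ABD range -> gap interpolation per stream -> per-recording
    standardization. Entries still missing afterwards are set to 0, which
    is the recording mean under the z-score.
    """
    n_intervals = int(np.floor(recording.duration_s / WINDOW_S))
    duration = n_intervals * WINDOW_S

    peaks = detect_rpeaks(recording.ecg.samples, recording.ecg.sampling_rate_hz)
    hr, ibi_sd = ibi_window_features(peaks, duration)
    hr_sd = rolling_hr_sd(hr)
    abd = abd_range_windows(recording.abd.samples, recording.abd.sampling_rate_hz)

    streams = [hr, ibi_sd, hr_sd, abd]
    streams = [_fit_length(s, n_intervals) for s in streams]
    streams = [interpolate_gaps(s) for s in streams]
    streams = [standardize(s) for s in streams]

    values = np.stack([s.values for s in streams], axis=1)
    missing = np.stack([s.missing for s in streams], axis=1)
    values[missing] = 0.0
    stats = [(s.mean, s.sd) for s in streams]
    return FeatureMatrix(values=values, missing=missing, column_stats=stats)


def _fit_length(series: FeatureSeries, n: int) -> FeatureSeries:
    """Pad (as missing) or truncate a stream to exactly n intervals."""
    cur = len(series.values)
    if cur == n:
        return series
    if cur > n:
        return FeatureSeries(series.values[:n], series.missing[:n])
    values = np.concatenate([series.values, np.zeros(n - cur)])
    missing = np.concatenate([series.missing, np.ones(n - cur, dtype=bool)])
    return FeatureSeries(values, missing)


def prestandardized_hr_series(matrix: FeatureMatrix) -> FeatureSeries:
    """Recover the pre-standardization mean-HR stream (BPM) for QC."""
    raw = matrix.destandardized()
    col = list(matrix.columns).index("hr_mean")
    vals = raw[:, col]
    missing = np.isnan(vals)
    return FeatureSeries(np.where(missing, 0.0, vals), missing)
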