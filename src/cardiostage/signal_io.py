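"""Reading and writing the formats the pipeline touches.

Raw signals come in as EDF (the distribution format of every PSG database
this pipeline targets), expert hypnograms as plain-text CSV with one stage
string per 30-s epoch, and extracted feature matrices are persisted as
Parquet — a columnar container with an explicit schema, which gives
bit-stable round-trips and fast reload for training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelNotFoundError, FormatError, SchemaError

logger = logging.getLogger(__name__)

#: Fixed column order of every persisted feature matrix.
FEATURE_COLUMNS = ("hr_mean", "ibi_sd", "hr_sd_4min", "abd_range")


@dataclass
class ChannelSignal:
    """One raw signal channel: samples plus its true sampling rate."""

    samples: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz


@dataclass
class RawRecording:
    """A single night: ECG + abdominal excursion + 30-s epoch labels."""

    recording_id: str
    ecg: ChannelSignal
    abd: ChannelSignal
    epoch_labels: list[str] = field(default_factory=list)
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s == 0.0:
            self.duration_s = max(self.ecg.duration_s, self.abd.duration_s)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, ecg_channel_name: str, abd_channel_name: str) -> RawRecording:
    """Read ECG and ABD channels from an EDF file at their native rates.

    Each channel is loaded independently so that no cross-channel
    resampling occurs (EDF stores per-channel sampling rates; loading
    mixed-rate channels together would force a common rate).
    Channel names are config-supplied; no heuristic guessing is done.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        probe = mne.io.read_raw_edf(path, preload=False, verbose="error")
    except Exception as exc:  # unreadable / truncated file
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    available = list(probe.ch_names)

    channels = {}
    for name in (ecg_channel_name, abd_channel_name):
        if name not in available:
            raise ChannelNotFoundError(name, available)
        raw = mne.io.read_raw_edf(path, include=[name], preload=True, verbose="error")
        channels[name] = ChannelSignal(raw.get_data()[0], float(raw.info["sfreq"]))

    return RawRecording(
        recording_id=path.stem,
        ecg=channels[ecg_channel_name],
        abd=channels[abd_channel_name],
    )


def write_edf(path: str | Path, recording: RawRecording,
              ecg_channel_name: str = "ECG", abd_channel_name: str = "ABD") -> None:
    """Write a two-channel EDF file with 1-s data records.

    Samples are quantized to the 16-bit digital range of EDF, scaled to
    each channel's physical min/max; read-back therefore matches the
    written values to within one quantization step (lossless at the
    stored 16-bit precision). Sampling rates must be integer.
    """
    path = Path(path)
    chans = [recording.ecg, recording.abd]
    names = [ecg_channel_name, abd_channel_name]
    rates = []
    for ch in chans:
        r = ch.sampling_rate_hz
        if abs(r - round(r)) > 1e-9:
            raise ValueError("EDF writer requires integer sampling rates")
        rates.append(int(round(r)))

    n = len(chans)
    n_records = int(np.ceil(max(len(c.samples) / r for c, r in zip(chans, rates))))
    dig_min, dig_max = -32768, 32767

    def pad(s: str, w: int) -> bytes:
        return s.encode("ascii")[:w].ljust(w)

    phys_min, phys_max, digital = [], [], []
    for ch in chans:
        x = ch.samples
        lo = float(np.min(x)) if len(x) else 0.0
        hi = float(np.max(x)) if len(x) else 1.0
        if hi <= lo:
            hi = lo + 1.0
        # header stores limited precision; round-trip uses the printed values
        lo, hi = float(f"{lo:.6g}"), float(f"{hi:.6g}")
        lo = min(lo, float(np.min(x))) if len(x) else lo
        hi = max(hi, float(np.max(x))) if len(x) else hi
        phys_min.append(float(f"{lo:.6g}"))
        phys_max.append(float(f"{hi:.6g}"))

    # re-derive printable bounds that still enclose the data
    for i, ch in enumerate(chans):
        x = ch.samples
        while len(x) and (phys_min[i] > np.min(x) or phys_max[i] < np.max(x)):
            span = phys_max[i] - phys_min[i]
            phys_min[i] = float(f"{phys_min[i] - 0.01 * span:.6g}")
            phys_max[i] = float(f"{phys_max[i] + 0.01 * span:.6g}")

    for ch, lo, hi in zip(chans, phys_min, phys_max):
        d = np.round((ch.samples - lo) / (hi - lo) * (dig_max - dig_min) + dig_min)
        digital.append(np.clip(d, dig_min, dig_max).astype("<i2"))

    hdr = pad("0", 8)
    hdr += pad("X X X X", 80) + pad(f"Startdate 01-JAN-2020 X X X {recording.recording_id}"[:80], 80)
    hdr += pad("01.01.20", 8) + pad("00.00.00", 8)
    hdr += pad(str(256 * (n + 1)), 8) + pad("", 44)
    hdr += pad(str(n_records), 8) + pad("1", 8) + pad(str(n), 4)
    hdr += b"".join(pad(nm, 16) for nm in names)
    hdr += b"".join(pad("", 80) for _ in range(n))          # transducer
    hdr += b"".join(pad("", 8) for _ in range(n))           # physical dimension
    hdr += b"".join(pad(f"{p:.6g}", 8) for p in phys_min)
    hdr += b"".join(pad(f"{p:.6g}", 8) for p in phys_max)
    hdr += b"".join(pad(str(dig_min), 8) for _ in range(n))
    hdr += b"".join(pad(str(dig_max), 8) for _ in range(n))
    hdr += b"".join(pad("", 80) for _ in range(n))          # prefiltering
    hdr += b"".join(pad(str(r), 8) for r in rates)
    hdr += b"".join(pad("", 32) for _ in range(n))

    with open(path, "wb") as fh:
        fh.write(hdr)
        for rec in range(n_records):
            for d, r in zip(digital, rates):
                chunk = d[rec * r:(rec + 1) * r]
                if len(chunk) < r:
                    chunk = np.concatenate([chunk, np.zeros(r - len(chunk), "<i2")])
                fh.write(chunk.tobytes())


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def read_hypnogram_csv(path: str | Path) -> list[str]:
    """Read one raw stage string per line, in 30-s epoch order.

    Strings are preserved verbatim (including unknown/'?' entries); all
    cleaning happens downstream in the labels module.
    """
    lines = Path(path).read_text().splitlines()
    labels = [ln.strip() for ln in lines if ln.strip() != ""]
    if not labels:
        raise FormatError(f"hypnogram file {path} contains no labels")
    return labels


def write_hypnogram_csv(path: str | Path, labels: list[str]) -> None:
    Path(path).write_text("\n".join(str(x) for x in labels) + "\n")


# ---------------------------------------------------------------------------
# Feature matrix store
# ---------------------------------------------------------------------------

def write_feature_matrix(path: str | Path, matrix) -> None:
    """Persist a FeatureMatrix as Parquet with NaN marking missing entries."""
    values = np.array(matrix.values, dtype=float, copy=True)
    values[matrix.missing] = np.nan
    df = pd.DataFrame(values, columns=list(matrix.columns))
    meta = {}
    if matrix.column_stats is not None:
        for col, (mu, sd) in zip(matrix.columns, matrix.column_stats):
            meta[f"{col}.mean"] = mu
            meta[f"{col}.sd"] = sd
    df.attrs = meta
    table_meta = {str(k).encode(): str(v).encode() for k, v in meta.items()}
    import pyarrow as pa
    import pyarrow.parquet as pq

    table = pa.Table.from_pandas(df, preserve_index=False)
    table = table.replace_schema_metadata({**(table.schema.metadata or {}), **table_meta})
    pq.write_table(table, path)


def read_feature_matrix(path: str | Path):
    """Load a FeatureMatrix written by :func:`write_feature_matrix`.

    Missing entries come back masked with value 0 (the post-standardization
    convention: a missing entry equals the recording mean).
    """
    import pyarrow.parquet as pq

    from .features import FeatureMatrix

    table = pq.read_table(path)
    df = table.to_pandas()
    if tuple(df.columns) != FEATURE_COLUMNS:
        raise SchemaError(
            f"feature store {path} has columns {tuple(df.columns)}, "
            f"expected {FEATURE_COLUMNS}"
        )
    values = df.to_numpy(dtype=float)
    missing = np.isnan(values)
    values = np.where(missing, 0.0, values)
    meta = {k.decode(): v.decode() for k, v in (table.schema.metadata or {}).items()}
    stats = None
    if f"{FEATURE_COLUMNS[0]}.mean" in meta:
        stats = [
            (float(meta[f"{c}.mean"]), float(meta[f"{c}.sd"])) for c in FEATURE_COLUMNS
        ]
    return FeatureMatrix(values=values, missing=missing, column_stats=stats)
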