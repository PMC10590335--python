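"""Hypnogram cleaning: relabeling, unknown interpolation, 15-s expansion.

Expert hypnograms arrive as 30-s epoch strings under either the R&K
(W/S1-S4/REM) or AASM (W/N1-N3/REM) vocabulary. Both collapse onto four
classes: S1/S2/N1/N2 become light sleep, S3/S4/N3 become deep sleep, wake
and REM are kept. The encoded targets are wake=0, REM=1, light=2, deep=3
at 15-s resolution (each 30-s epoch label copied twice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class StageClass(IntEnum):
    WAKE = 0
    REM = 1
    LIGHT = 2
    DEEP = 3
    #: pre-cleaning sentinel; never survives fill_unknown_labels
    UNKNOWN = -1


N_CLASSES = 4

#: Default raw-label synonym table. Databases differ in spelling; the
#: numeric entries follow the common 0=wake / 1,2=N1,N2 / 3,4=N3,S4 /
#: 5=REM annotation convention.
DEFAULT_SYNONYMS: dict[str, StageClass] = {
    "W": StageClass.WAKE, "WAKE": StageClass.WAKE, "WK": StageClass.WAKE,
    "0": StageClass.WAKE,
    "R": StageClass.REM, "REM": StageClass.REM, "5": StageClass.REM,
    "S1": StageClass.LIGHT, "S2": StageClass.LIGHT,
    "N1": StageClass.LIGHT, "N2": StageClass.LIGHT,
    "1": StageClass.LIGHT, "2": StageClass.LIGHT,
    "LIGHT": StageClass.LIGHT, "LS": StageClass.LIGHT,
    "S3": StageClass.DEEP, "S4": StageClass.DEEP, "N3": StageClass.DEEP,
    "3": StageClass.DEEP, "4": StageClass.DEEP,
    "DEEP": StageClass.DEEP, "DS": StageClass.DEEP,
}


@dataclass
class IntervalHypnogram:
    """4-class stage codes at 15-s resolution."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_intervals(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalHypnogram):
            return NotImplemented
        return np.array_equal(self.labels, other.labels)


def relabel_stage(raw: str, synonyms: Mapping[str, StageClass] | None = None) -> StageClass:
    """Map one raw stage string to a StageClass; unrecognized -> UNKNOWN."""
    table = DEFAULT_SYNONYMS if synonyms is None else synonyms
    return table.get(str(raw).strip().upper(), StageClass.UNKNOWN)


def relabel_stages(raw_labels: Iterable[str],
                   synonyms: Mapping[str, StageClass] | None = None) -> list[StageClass]:
    return [relabel_stage(x, synonyms) for x in raw_labels]


def fill_unknown_labels(epoch_labels: Sequence[StageClass]) -> list[StageClass]:
    """Replace unknown epochs using adjacent labels.

    Interior unknown runs take the preceding known label (forward fill);
    unknown runs at the beginning or end of the recording become wake.
    An all-unknown sequence degenerates to all wake (logged).
    """
    labels = list(epoch_labels)
    if not labels:
        raise ValueError("empty label sequence")
    known = [i for i, s in enumerate(labels) if s != StageClass.UNKNOWN]
    if not known:
        logger.warning("all %d epoch labels unknown; relabeling everything as wake", len(labels))
        return [StageClass.WAKE] * len(labels)
    first, last = known[0], known[-1]
    out: list[StageClass] = []
    prev = StageClass.WAKE
    for i, s in enumerate(labels):
        if s == StageClass.UNKNOWN:
            out.append(StageClass.WAKE if (i < first or i > last) else prev)
        else:
            out.append(s)
            prev = s
    return out


def expand_to_intervals(epoch_labels: Sequence[StageClass]) -> IntervalHypnogram:
    """Copy each cleaned 30-s epoch label into its two 15-s intervals."""
    codes = encode(epoch_labels)
    return IntervalHypnogram(np.repeat(codes, 2))


def align_labels_to_signal(interval_labels: IntervalHypnogram,
                           n_feature_intervals: int) -> IntervalHypnogram:
    """Truncate labels/features to their common length.

    Label and signal durations occasionally disagree by an epoch; a
    mismatch larger than 2 intervals is logged as a warning.
    """
    n_labels = interval_labels.n_intervals
    n = min(n_labels, n_feature_intervals)
    if abs(n_labels - n_feature_intervals) > 2:
        logger.warning(
            "label/feature length mismatch: %d labels vs %d feature intervals",
            n_labels, n_feature_intervals,
        )
    return IntervalHypnogram(interval_labels.labels[:n])


def encode(stages: Sequence[StageClass]) -> np.ndarray:
    """Encode cleaned stages as integer codes {0,1,2,3}."""
    codes = np.array([int(s) for s in stages], dtype=np.int64)
    if codes.size and (codes.min() < 0 or codes.max() > 3):
        raise ValueError("encode() requires cleaned labels (no UNKNOWN)")
    return codes


def decode(codes: np.ndarray) -> list[StageClass]:
    return [StageClass(int(c)) for c in np.asarray(codes)]
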