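"""Hypnogram agreement metrics and reports.

Predictions are compared to the expert reference per 15-s interval with
a 4x4 confusion matrix (rows = reference, columns = predicted), overall
accuracy, and Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e)

where p_o is the observed agreement (the confusion-matrix trace over its
total) and p_e the chance agreement from the row/column marginals.
Pooled metrics are computed from the summed confusion matrix across
recordings; per-recording values are reported alongside. Padded
intervals are excluded from every metric — the synthetic wake padding
would otherwise inflate wake accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .labels import IntervalHypnogram, N_CLASSES

STAGE_NAMES = ("wake", "rem", "light", "deep")


def confusion_matrix(reference: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """4x4 counts; entry (i, j) = intervals with reference i, prediction j."""
    ref = np.asarray(reference, dtype=np.int64).ravel()
    pred = np.asarray(predicted, dtype=np.int64).ravel()
    if ref.shape != pred.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {pred.shape}")
    if ref.size and not ((0 <= ref).all() and (ref < N_CLASSES).all()
                         and (0 <= pred).all() and (pred < N_CLASSES).all()):
        raise ValueError("labels must be encoded in {0,1,2,3}")
    return np.bincount(ref * N_CLASSES + pred,
                       minlength=N_CLASSES * N_CLASSES).reshape(N_CLASSES, N_CLASSES)


def accuracy_from_cm(cm: np.ndarray) -> float:
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm) / total)


def kappa_from_cm(cm: np.ndarray) -> float:
    """Cohen's kappa from a confusion matrix.

    When chance agreement p_e equals 1 exactly (all mass in one cell of
    the diagonal), kappa is defined as 1 if the observed agreement is
    also perfect.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("kappa undefined for an empty confusion matrix")
    p_o = np.trace(cm) / total
    rows = cm.sum(axis=1) / total
    cols = cm.sum(axis=0) / total
    p_e = float(rows @ cols)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class EvalReport:
    confusion: np.ndarray
    accuracy: float
    kappa: float
    n_intervals: int
    per_recording: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "n_intervals": self.n_intervals,
            "per_recording": self.per_recording,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def confusion_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.confusion,
                          index=[f"ref_{s}" for s in STAGE_NAMES],
                          columns=[f"pred_{s}" for s in STAGE_NAMES])
        df.to_csv(path)


def evaluate_recordings(pairs: list[tuple[np.ndarray, np.ndarray]],
                        recording_ids: list[str] | None = None) -> EvalReport:
    """Pooled + per-recording metrics over (reference, predicted) pairs."""
    pooled = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    per_rec = []
    for idx, (ref, pred) in enumerate(pairs):
        cm = confusion_matrix(ref, pred)
        pooled += cm
        rid = recording_ids[idx] if recording_ids else str(idx)
        per_rec.append({
            "recording_id": rid,
            "accuracy": accuracy_from_cm(cm) if cm.sum() else None,
            "kappa": kappa_from_cm(cm) if cm.sum() else None,
            "n_intervals": int(cm.sum()),
        })
    return EvalReport(
        confusion=pooled,
        accuracy=accuracy_from_cm(pooled),
        kappa=kappa_from_cm(pooled),
        n_intervals=int(pooled.sum()),
        per_recording=per_rec,
    )


def sleep_characteristics(hypnogram: IntervalHypnogram) -> dict:
    """Night-level summary: duration, efficiency, stage percentages.

    Duration is counted in 30-s epochs; efficiency is the fraction of
    non-wake intervals.
    """
    labels = hypnogram.labels
    n = len(labels)
    if n == 0:
        raise ValueError("empty hypnogram")
    counts = np.bincount(labels, minlength=N_CLASSES)
    return {
        "duration_epochs": n / 2.0,
        "efficiency": float((n - counts[0]) / n),
        **{f"{name}_pct": float(100.0 * counts[i] / n)
           for i, name in enumerate(STAGE_NAMES)},
    }


def plot_hypnogram_comparison(reference: IntervalHypnogram,
                              predicted: IntervalHypnogram,
                              path: str | Path,
                              interval_s: float = 15.0) -> None:
    """Step plot of both hypnograms in conventional (inverted) orientation.

    Stage order top-to-bottom is W, REM, LS, DS; reference is dotted,
    prediction solid.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if reference.n_intervals != predicted.n_intervals:
        raise ValueError("reference and predicted lengths differ")
    t = np.arange(reference.n_intervals) * interval_s / 3600.0
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.step(t, reference.labels, where="post", linestyle=":", color="gray",
            label="reference")
    ax.step(t, predicted.labels, where="post", color="C0", label="predicted")
    ax.set_yticks(range(N_CLASSES))
    ax.set_yticklabels(["W", "REM", "LS", "DS"])
    ax.invert_yaxis()  # wake on top, conventional hypnogram orientation
    ax.set_xlabel("time (h)")
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
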