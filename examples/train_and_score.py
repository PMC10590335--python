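"""Train the staging network on a few synthetic nights and score one.

A miniature end-to-end run: simulate nights, extract features, pad to
the fixed 10-h input, train briefly, and evaluate the predicted
hypnogram against the reference. With only 4 nights and 5 epochs the
kappa is modest; the acceptance-scale experiment (60 nights, 50 epochs)
reaches kappa around 0.9.
"""

from cardiostage import labels as L
from cardiostage.config import load_preset
from cardiostage.evaluation import evaluate_recordings, sleep_characteristics
from cardiostage.features import extract_feature_matrix
from cardiostage.network import pad_to_input_length, predict_hypnogram
from cardiostage.synthetic import simulate_recording
from cardiostage.training import split_dataset, train_from_scratch

preset = load_preset("demo")

examples = []
for i in range(preset.n_nights):
    rec, _ = simulate_recording(preset.synthetic, seed=100 + i, recording_id=f"night{i}")
    matrix = extract_feature_matrix(rec)
    cleaned = L.fill_unknown_labels(L.relabel_stages(rec.epoch_labels))
    hyp = L.align_labels_to_signal(L.expand_to_intervals(cleaned), matrix.n_intervals)
    examples.append(pad_to_input_length(matrix, hyp, recording_id=f"night{i}"))

split = split_dataset(range(len(examples)), seed=0)
train_ex = [examples[i] for i in split.train_ids]
val_ex = [examples[i] for i in split.val_ids]
print(f"{len(train_ex)} training nights, {len(val_ex)} validation night(s)")

model, history = train_from_scratch(train_ex, val_ex, preset.training)
print(history[["epoch", "train_loss", "val_loss", "val_kappa"]].to_string(index=False))

pairs = []
for ex in val_ex:
    pred, _ = predict_hypnogram(model, ex)
    pairs.append((ex.labels[ex.pad_length:], pred.labels))
report = evaluate_recordings(pairs, [ex.recording_id for ex in val_ex])
print(f"\nvalidation: accuracy {report.accuracy:.3f}, kappa {report.kappa:.3f} "
      f"over {report.n_intervals} intervals")
print("confusion matrix (rows = reference, cols = predicted; order W/REM/LS/DS):")
print(report.confusion)

chars = sleep_characteristics(L.IntervalHypnogram(val_ex[0].labels[val_ex[0].pad_length:]))
print(f"\nreference night summary: efficiency {chars['efficiency']:.2f}, "
      f"wake {chars['wake_pct']:.0f}%, REM {chars['rem_pct']:.0f}%, "
      f"light {chars['light_pct']:.0f}%, deep {chars['deep_pct']:.0f}%")
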