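"""Compare two hypnograms: metrics, characteristics, and a figure.

Uses a simulated night as the reference and a noisy copy as the
"prediction" to show the evaluation surface without any training.
"""

import numpy as np

from cardiostage.evaluation import (
    accuracy_from_cm,
    confusion_matrix,
    kappa_from_cm,
    plot_hypnogram_comparison,
    sleep_characteristics,
)
from cardiostage.labels import IntervalHypnogram
from cardiostage.synthetic import SyntheticConfig, sample_stage_sequence

rng = np.random.default_rng(0)
stages = sample_stage_sequence(SyntheticConfig(duration_h=8.0), seed=12)
ref = IntervalHypnogram(np.repeat([int(s) for s in stages], 2))

# corrupt 12% of intervals to play the role of an imperfect scorer
noisy = ref.labels.copy()
flip = rng.random(len(noisy)) < 0.12
noisy[flip] = rng.integers(0, 4, flip.sum())
pred = IntervalHypnogram(noisy)

cm = confusion_matrix(ref.labels, pred.labels)
print("confusion matrix (rows = reference W/REM/LS/DS):")
print(cm)
print(f"accuracy {accuracy_from_cm(cm):.3f}, Cohen's kappa {kappa_from_cm(cm):.3f}")

chars = sleep_characteristics(ref)
print(f"reference night: {chars['duration_epochs']:.0f} epochs, "
      f"efficiency {chars['efficiency']:.2f}, deep sleep {chars['deep_pct']:.1f}%")

plot_hypnogram_comparison(ref, pred, "hypnogram_comparison.png")
print("wrote hypnogram_comparison.png (stages top-to-bottom: W, REM, LS, DS)")
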