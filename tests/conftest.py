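import dataclasses

import numpy as np
import pytest

from cardiostage import labels as L
from cardiostage.config import load_preset
from cardiostage.features import extract_feature_matrix
from cardiostage.network import pad_to_input_length
from cardiostage.synthetic import SyntheticConfig, simulate_recording
from cardiostage.training import split_dataset, train_from_scratch


def build_examples(synth_config, seeds, prefix="n"):
    """Simulate nights, extract features, clean labels, pad to 2400."""
    examples = []
    matrices = []
    truths = []
    for i, seed in enumerate(seeds):
        rec, truth = simulate_recording(synth_config, seed, f"{prefix}{i:03d}")
        matrix = extract_feature_matrix(rec)
        cleaned = L.fill_unknown_labels(L.relabel_stages(rec.epoch_labels))
        hyp = L.align_labels_to_signal(L.expand_to_intervals(cleaned),
                                       matrix.n_intervals)
        examples.append(pad_to_input_length(matrix, hyp,
                                            recording_id=f"{prefix}{i:03d}"))
        matrices.append(matrix)
        truths.append(truth)
    return examples, matrices, truths


@pytest.fixture(scope="session")
def one_night():
    """A single 4-h synthetic night with its ground truth."""
    cfg = SyntheticConfig(duration_h=4.0)
    rec, truth = simulate_recording(cfg, 11)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def acceptance_preset():
    return load_preset("acceptance_small")


@pytest.fixture(scope="session")
def acceptance_dataset(acceptance_preset):
    """The 60-night desk-scale corpus (dialect A) with feature matrices."""
    return build_examples(
        acceptance_preset.synthetic, range(1000, 1000 + acceptance_preset.n_nights))


@pytest.fixture(scope="session")
def trained_model_a(acceptance_preset, acceptance_dataset):
    """Model trained from scratch on the 60-night dialect-A corpus."""
    examples, _, _ = acceptance_dataset
    split = split_dataset(range(len(examples)), seed=7)
    train_ex = [examples[i] for i in split.train_ids]
    val_ex = [examples[i] for i in split.val_ids]
    cfg = dataclasses.replace(acceptance_preset.training, seed=7)
    model, history = train_from_scratch(train_ex, val_ex, cfg)
    return model, history, val_ex


@pytest.fixture(scope="session")
def dialect_b_data(acceptance_preset):
    """Dialect-B nights: fine-tune set, early-stop set, held-out eval set."""
    cfg_b = dataclasses.replace(acceptance_preset.synthetic, label_dialect="B")
    train_ex, _, _ = build_examples(cfg_b, range(2000, 2000 + acceptance_preset.finetune_nights), "bt")
    stop_ex, _, _ = build_examples(cfg_b, range(3500, 3505), "bs")
    eval_ex, _, _ = build_examples(cfg_b, range(3000, 3010), "be")
    return train_ex, stop_ex, eval_ex
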