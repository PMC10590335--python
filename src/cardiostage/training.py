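"""Dataset partitioning and the three training regimes.

The staging model is optimized in two phases: initial training on a
large R&K-labeled corpus (Adam, lr 1e-4), then fine-tuning on a smaller
AASM-labeled corpus with every encoder weight frozen (Adam, lr 1e-5) so
that only the middle and decoding blocks adapt to the newer scoring
standard. A from-scratch baseline trained only on the AASM-style data
provides the comparison that motivates the transfer step. The loss is
per-interval cross-entropy over the whole padded night (the padded
region carries wake labels); an optional mask can exclude the padding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .network import ModelConfig, PaddedExample, StagingModel, build_network, softmax

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 100
    learning_rate: float = 1e-4
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    freeze_encoder: bool = False
    #: exclude the padded region from the loss (off by default: the
    #: padding scheme labels padded intervals as wake on purpose)
    mask_padding: bool = False
    #: optional inverse-frequency class weighting (off by default; the
    #: model is allowed to inherit the natural stage imbalance)
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


@dataclass
class SplitSpec:
    train_ids: list
    val_ids: list
    seed: int


def split_dataset(ids, seed: int) -> SplitSpec:
    """Deterministic 4:1 train/validation partition.

    Recording ids are shuffled under the seed; validation receives
    floor(N/5), training the remaining ids. Recordings are treated as
    independent samples even when longitudinal.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 recordings to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = n // 5
    val = [ids[i] for i in order[:n_val]]
    train = [ids[i] for i in order[n_val:]]
    return SplitSpec(train_ids=train, val_ids=val, seed=seed)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray,
                       mask: np.ndarray | None = None,
                       class_weights: np.ndarray | None = None) -> float:
    """Mean per-interval cross-entropy; uniform output on 4 classes = ln 4."""
    n_classes = probs.shape[-1]
    onehot = np.eye(n_classes)[labels]
    ll = -np.sum(onehot * np.log(probs + 1e-12), axis=-1)
    w = np.ones_like(ll)
    if class_weights is not None:
        w = w * class_weights[labels]
    if mask is not None:
        w = w * mask
    total = w.sum()
    if total == 0:
        return 0.0
    return float((ll * w).sum() / total)


def _loss_and_logit_grad(probs: np.ndarray, labels: np.ndarray,
                         mask: np.ndarray | None,
                         class_weights: np.ndarray | None) -> tuple[float, np.ndarray]:
    n_classes = probs.shape[-1]
    onehot = np.eye(n_classes)[labels]
    w = np.ones(labels.shape)
    if class_weights is not None:
        w = w * class_weights[labels]
    if mask is not None:
        w = w * mask
    total = w.sum()
    loss = cross_entropy_loss(probs, labels, mask, class_weights)
    if total == 0:
        return loss, np.zeros_like(probs)
    dlogits = (probs - onehot) * w[..., None] / total
    return loss, dlogits


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def _stack(examples: list[PaddedExample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.stack([e.features for e in examples])
    y = np.stack([e.labels for e in examples])
    pads = np.array([e.pad_length for e in examples])
    return x, y, pads


def _valid_mask(y: np.ndarray, pads: np.ndarray) -> np.ndarray:
    idx = np.arange(y.shape[1])[None, :]
    return (idx >= pads[:, None]).astype(float)


def _class_weights(y: np.ndarray) -> np.ndarray:
    counts = np.bincount(y.ravel(), minlength=4).astype(float)
    counts[counts == 0] = 1.0
    w = counts.sum() / (4.0 * counts)
    return w


def _evaluate_split(model: StagingModel, x: np.ndarray, y: np.ndarray,
                    pads: np.ndarray, config: TrainConfig,
                    class_weights: np.ndarray | None,
                    batch: int = 16) -> dict:
    from .evaluation import confusion_matrix, accuracy_from_cm, kappa_from_cm

    losses = []
    cm = np.zeros((4, 4), dtype=np.int64)
    for i in range(0, len(x), batch):
        xb, yb, pb = x[i:i + batch], y[i:i + batch], pads[i:i + batch]
        probs = model.forward(xb, train=False)
        mask = _valid_mask(yb, pb) if config.mask_padding else None
        losses.append(cross_entropy_loss(probs, yb, mask, class_weights) * len(xb))
        pred = np.argmax(probs, axis=-1)
        valid = _valid_mask(yb, pb).astype(bool)  # metrics always trim padding
        cm += confusion_matrix(yb[valid], pred[valid])
    return {
        "loss": float(np.sum(losses) / len(x)),
        "accuracy": accuracy_from_cm(cm),
        "kappa": kappa_from_cm(cm),
    }


def _fit(model: StagingModel, train_examples: list[PaddedExample],
         val_examples: list[PaddedExample],
         config: TrainConfig) -> tuple[StagingModel, pd.DataFrame]:
    from .nn import Adam

    x_tr, y_tr, p_tr = _stack(train_examples)
    x_va, y_va, p_va = _stack(val_examples)
    weights = _class_weights(y_tr) if config.class_weighting else None

    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    stale = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        train_losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            xb, yb, pb = x_tr[sel], y_tr[sel], p_tr[sel]
            probs = model.forward(xb, train=True)
            mask = _valid_mask(yb, pb) if config.mask_padding else None
            loss, dlogits = _loss_and_logit_grad(probs, yb, mask, weights)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={config.learning_rate}, batch={len(sel)}"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            train_losses.append(loss * len(sel))
        val = _evaluate_split(model, x_va, y_va, p_va, config, weights)
        row = {
            "epoch": epoch,
            "train_loss": float(np.sum(train_losses) / len(x_tr)),
            "val_loss": val["loss"],
            "val_accuracy": val["accuracy"],
            "val_kappa": val["kappa"],
        }
        history.append(row)
        logger.info("epoch %d: train %.4f val %.4f acc %.3f kappa %.3f",
                    epoch, row["train_loss"], row["val_loss"],
                    row["val_accuracy"], row["val_kappa"])
        if val["loss"] < best_val - 1e-9:
            best_val = val["loss"]
            best_state = [p.data.copy() for p in model.params()]
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                logger.info("early stop at epoch %d", epoch)
                break

    if best_state is not None:
        for p, data in zip(model.params(), best_state):
            p.data = data
    return model, pd.DataFrame(history)


def train_initial(model: StagingModel, train_examples: list[PaddedExample],
                  val_examples: list[PaddedExample],
                  config: TrainConfig | None = None) -> tuple[StagingModel, pd.DataFrame]:
    """Initial optimization with all parameters trainable."""
    config = config or TrainConfig(learning_rate=1e-4, freeze_encoder=False)
    model.unfreeze_encoder()
    return _fit(model, train_examples, val_examples, config)


def fine_tune(model: StagingModel, train_examples: list[PaddedExample],
              val_examples: list[PaddedExample],
              config: TrainConfig | None = None) -> tuple[StagingModel, pd.DataFrame]:
    """Continue training with the encoding blocks frozen.

    Encoder weights (including batch-norm statistics) are bit-identical
    before and after; only middle and decoding blocks are updated.
    """
    config = config or TrainConfig(learning_rate=1e-5, freeze_encoder=True)
    if not config.freeze_encoder:
        raise ConfigError("fine_tune requires freeze_encoder=True; "
                          "use train_initial for unfrozen training")
    model.freeze_encoder()
    return _fit(model, train_examples, val_examples, config)


def train_from_scratch(train_examples: list[PaddedExample],
                       val_examples: list[PaddedExample],
                       config: TrainConfig | None = None,
                       model_config: ModelConfig | None = None) -> tuple[StagingModel, pd.DataFrame]:
    """Baseline: randomly initialized model trained on one corpus only."""
    import dataclasses

    config = config or TrainConfig(learning_rate=1e-4)
    model_config = model_config or ModelConfig()
    model_config = dataclasses.replace(model_config, seed=config.seed)
    model = build_network(model_config)
    return train_initial(model, train_examples, val_examples, config)
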