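"""The staging network: a temporal U-Net with a recurrent middle block.

The model maps a whole night of features (2400 intervals x 4 features,
i.e. 10 h at 15 s) to per-interval probabilities over the four stages.
Four encoding blocks of dilated convolutions (each followed by batch
norm, ReLU and 2x max-pooling) compress the night to 150 steps; a
convolution plus bidirectional LSTM middle block models long-range stage
sequencing; four decoding blocks upsample back to 2400, each
concatenating the residual output of its mirror encoder block; a 1x1
convolution with softmax produces the 4-class hypnogram.

With the default configuration the network has exactly 76,552 trainable
parameters and 496 non-trainable parameters (the running mean/variance
of 248 batch-normalized channels). The per-block widths were calibrated
so that the canonical doubling encoder (8-16-32-64) and the printed
parameter totals are both satisfied; ``architecture_summary`` documents
the resulting per-layer shapes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError, InputError
from .features import FeatureMatrix
from .labels import IntervalHypnogram
from .nn import Adam, BatchNorm1d, BiLSTM, Conv1d, MaxPool1d, Parameter, ReLU, Upsample1d

INPUT_LENGTH = 2400


@dataclass
class ModelConfig:
    input_length: int = INPUT_LENGTH
    n_features: int = 4
    n_classes: int = 4
    kernel: int = 3
    encoder_filters: tuple[int, ...] = (8, 16, 32, 64)
    encoder_dilations: tuple[int, ...] = (1, 2, 4, 8)
    middle_filters: int = 32
    middle_kernel: int = 3
    lstm_units: int = 50
    decoder_filters: tuple[int, ...] = (38, 30, 18, 10)
    decoder_dilations: tuple[int, ...] = (8, 4, 2, 1)
    pool_factor: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.encoder_filters) != 4 or len(self.decoder_filters) != 4:
            raise ConfigError("the architecture requires 4 encoding and 4 decoding blocks")
        if len(self.encoder_dilations) != 4 or len(self.decoder_dilations) != 4:
            raise ConfigError("one dilation rate per block is required")
        if self.input_length % self.pool_factor ** 4:
            raise ConfigError("input_length must be divisible by pool_factor^4")


class StagingModel:
    """Explicit forward/backward graph over the nn layer kernel."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel

        self.enc_convs: list[Conv1d] = []
        self.enc_bns: list[BatchNorm1d] = []
        self.enc_relus: list[ReLU] = []
        self.enc_pools: list[MaxPool1d] = []
        c_in = config.n_features
        for i, (f, d) in enumerate(zip(config.encoder_filters, config.encoder_dilations)):
            self.enc_convs.append(Conv1d(f"enc{i + 1}.conv", c_in, f, k, d, rng))
            self.enc_bns.append(BatchNorm1d(f"enc{i + 1}.bn", f))
            self.enc_relus.append(ReLU(f"enc{i + 1}.relu"))
            self.enc_pools.append(MaxPool1d(f"enc{i + 1}.pool", config.pool_factor))
            c_in = f

        self.mid_conv = Conv1d("mid.conv", c_in, config.middle_filters,
                               config.middle_kernel, 1, rng)
        self.mid_bn = BatchNorm1d("mid.bn", config.middle_filters)
        self.mid_relu = ReLU("mid.relu")
        self.lstm = BiLSTM("mid.lstm", config.middle_filters, config.lstm_units, rng)

        self.dec_ups: list[Upsample1d] = []
        self.dec_convs: list[Conv1d] = []
        self.dec_bns: list[BatchNorm1d] = []
        self.dec_relus: list[ReLU] = []
        c_in = 2 * config.lstm_units
        for i, (f, d) in enumerate(zip(config.decoder_filters, config.decoder_dilations)):
            res_ch = config.encoder_filters[3 - i]
            self.dec_ups.append(Upsample1d(f"dec{i + 1}.up", config.pool_factor))
            self.dec_convs.append(Conv1d(f"dec{i + 1}.conv", c_in + res_ch, f, k, d, rng))
            self.dec_bns.append(BatchNorm1d(f"dec{i + 1}.bn", f))
            self.dec_relus.append(ReLU(f"dec{i + 1}.relu"))
            c_in = f

        self.head = Conv1d("head.conv", c_in, config.n_classes, 1, 1, rng)
        self._res_grads: list[np.ndarray] | None = None

    # -- parameter plumbing -------------------------------------------------

    def encoder_layers(self):
        return [*self.enc_convs, *self.enc_bns]

    def all_layers(self):
        return [
            *self.enc_convs, *self.enc_bns, *self.enc_relus, *self.enc_pools,
            self.mid_conv, self.mid_bn, self.mid_relu, self.lstm,
            *self.dec_ups, *self.dec_convs, *self.dec_bns, *self.dec_relus,
            self.head,
        ]

    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for layer in self.all_layers():
            out.extend(layer.params())
        return out

    def freeze_encoder(self) -> None:
        for layer in self.encoder_layers():
            layer.set_trainable(False)

    def unfreeze_encoder(self) -> None:
        for layer in self.encoder_layers():
            layer.set_trainable(True)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, 2400, 4) -> per-interval class probabilities (B, 2400, 4)."""
        if x.ndim != 3 or x.shape[1] != self.config.input_length:
            raise InputError(f"expected (batch, {self.config.input_length}, "
                             f"{self.config.n_features}) input, got {x.shape}")
        if not np.isfinite(x).all():
            raise InputError("input contains non-finite values")
        residuals = []
        h = x
        for conv, bn, relu, pool in zip(self.enc_convs, self.enc_bns,
                                        self.enc_relus, self.enc_pools):
            r = relu.forward(bn.forward(conv.forward(h, train), train), train)
            residuals.append(r)
            h = pool.forward(r, train)
        h = self.mid_relu.forward(self.mid_bn.forward(self.mid_conv.forward(h, train), train), train)
        h = self.lstm.forward(h, train)
        for i, (up, conv, bn, relu) in enumerate(zip(self.dec_ups, self.dec_convs,
                                                     self.dec_bns, self.dec_relus)):
            h = up.forward(h, train)
            h = np.concatenate([h, residuals[3 - i]], axis=2)
            h = relu.forward(bn.forward(conv.forward(h, train), train), train)
        self._logits = self.head.forward(h, train)
        return softmax(self._logits)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate gradients given the loss gradient w.r.t. the logits."""
        g = self.head.backward(dlogits)
        res_grads: list[np.ndarray | None] = [None] * 4
        cfg = self.config
        up_ch = [2 * cfg.lstm_units, *cfg.decoder_filters[:3]]
        for i in reversed(range(4)):
            g = self.dec_convs[i].backward(self.dec_bns[i].backward(self.dec_relus[i].backward(g)))
            res_grads[3 - i] = g[:, :, up_ch[i]:]
            g = self.dec_ups[i].backward(g[:, :, :up_ch[i]])
        g = self.lstm.backward(g)
        g = self.mid_conv.backward(self.mid_bn.backward(self.mid_relu.backward(g)))
        for i in reversed(range(4)):
            g = self.enc_pools[i].backward(g)
            g = g + res_grads[i]
            g = self.enc_convs[i].backward(self.enc_bns[i].backward(self.enc_relus[i].backward(g)))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_network(config: ModelConfig | None = None) -> StagingModel:
    return StagingModel(config or ModelConfig())


def count_parameters(model: StagingModel) -> tuple[int, int]:
    """(trainable, non_trainable) exact integer parameter counts.

    Non-trainable covers batch-norm running statistics plus any frozen
    weights; freezing therefore moves parameters between the two counts
    without changing their total.
    """
    trainable = sum(p.size for p in model.params() if p.trainable)
    non_trainable = sum(p.size for p in model.params() if not p.trainable)
    return trainable, non_trainable


# ---------------------------------------------------------------------------
# Padding and prediction
# ---------------------------------------------------------------------------

@dataclass
class PaddedExample:
    """A night padded at the beginning to the fixed 10-h input length.

    The first ``pad_length`` feature rows are all-zero and the first
    ``pad_length`` labels are wake (0).
    """

    features: np.ndarray
    labels: np.ndarray
    pad_length: int
    recording_id: str = ""


def pad_to_input_length(matrix: FeatureMatrix, hypnogram: IntervalHypnogram,
                        input_length: int = INPUT_LENGTH,
                        recording_id: str = "") -> PaddedExample:
    """Left-pad features with zeros and labels with wake to 2400 intervals."""
    n = min(matrix.n_intervals, hypnogram.n_intervals)
    if max(matrix.n_intervals, hypnogram.n_intervals) > input_length:
        raise InputError(
            f"recording has {max(matrix.n_intervals, hypnogram.n_intervals)} intervals, "
            f"over the {input_length} input limit; it should have been excluded by QC"
        )
    pad = input_length - n
    features = np.zeros((input_length, matrix.values.shape[1]))
    features[pad:] = matrix.values[:n]
    labels = np.zeros(input_length, dtype=np.int64)
    labels[pad:] = hypnogram.labels[:n]
    return PaddedExample(features=features, labels=labels, pad_length=pad,
                         recording_id=recording_id)


def predict_hypnogram(model: StagingModel,
                      example: PaddedExample) -> tuple[IntervalHypnogram, np.ndarray]:
    """Score one night; returns the trimmed hypnogram and probabilities.

    Argmax ties break toward the lowest class code (numpy argmax takes
    the first maximum). The padded region is trimmed using pad_length.
    """
    x = example.features[None, :, :]
    if not np.isfinite(x).all():
        raise InputError("feature matrix contains non-finite values")
    probs = model.forward(x, train=False)[0]
    codes = np.argmax(probs, axis=-1)
    p = example.pad_length
    return IntervalHypnogram(codes[p:]), probs[p:]


# ---------------------------------------------------------------------------
# Checkpoints and summaries
# ---------------------------------------------------------------------------

def save_checkpoint(model: StagingModel, path: str | Path) -> None:
    arrays = {p.name: p.data for p in model.params()}
    cfg = asdict(model.config)
    np.savez(path, __config__=json.dumps(cfg), **arrays)


def load_checkpoint(path: str | Path) -> StagingModel:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["__config__"]))
        for key in ("encoder_filters", "encoder_dilations", "decoder_filters",
                    "decoder_dilations"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = StagingModel(ModelConfig(**cfg_dict))
        for p in model.params():
            p.data = np.array(data[p.name])
    return model


def architecture_summary(model: StagingModel) -> str:
    """Per-layer output shapes and parameter counts, as text."""
    cfg = model.config
    lines = []
    lines.append(f"{'layer':<14}{'output shape':<22}{'params':>10}{'  notes'}")
    lines.append("-" * 62)
    length = cfg.input_length
    lines.append(f"{'input':<14}{f'({length}, {cfg.n_features})':<22}{0:>10}")
    for i, (conv, bn) in enumerate(zip(model.enc_convs, model.enc_bns)):
        n = sum(p.size for p in conv.params()) + 2 * bn.channels
        lines.append(f"{f'enc{i+1}':<14}{f'({length}, {conv.c_out})':<22}{n:>10}"
                     f"  k={conv.kernel} d={conv.dilation}, bn+relu, pool/{cfg.pool_factor}")
        length //= cfg.pool_factor
    n = sum(p.size for p in model.mid_conv.params()) + 2 * model.mid_bn.channels
    lines.append(f"{'mid.conv':<14}{f'({length}, {cfg.middle_filters})':<22}{n:>10}"
                 f"  k={cfg.middle_kernel} d=1, bn+relu")
    n = sum(p.size for p in model.lstm.params())
    lines.append(f"{'mid.bilstm':<14}{f'({length}, {2 * cfg.lstm_units})':<22}{n:>10}"
                 f"  units={cfg.lstm_units} per direction")
    for i, (conv, bn) in enumerate(zip(model.dec_convs, model.dec_bns)):
        length *= cfg.pool_factor
        res = cfg.encoder_filters[3 - i]
        n = sum(p.size for p in conv.params()) + 2 * bn.channels
        lines.append(f"{f'dec{i+1}':<14}{f'({length}, {conv.c_out})':<22}{n:>10}"
                     f"  up x{cfg.pool_factor}, concat enc{4 - i} (+{res}), "
                     f"k={conv.kernel} d={conv.dilation}, bn+relu")
    n = sum(p.size for p in model.head.params())
    lines.append(f"{'head':<14}{f'({length}, {cfg.n_classes})':<22}{n:>10}  1x1 conv, softmax")
    lines.append("-" * 62)
    t, nt = count_parameters(model)
    lines.append(f"trainable parameters:     {t}")
    lines.append(f"non-trainable parameters: {nt}  (batch-norm running stats, "
                 f"{sum(cfg.encoder_filters) + cfg.middle_filters + sum(cfg.decoder_filters)} channels)")
    return "\n".join(lines)
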