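import numpy as np
import pytest

from cardiostage.errors import ConfigError, InputError
from cardiostage.features import FeatureMatrix
from cardiostage.labels import IntervalHypnogram
from cardiostage.network import (
    ModelConfig,
    StagingModel,
    architecture_summary,
    build_network,
    count_parameters,
    load_checkpoint,
    pad_to_input_length,
    predict_hypnogram,
    save_checkpoint,
)
from cardiostage.nn import Conv1d


def tiny_config(**overrides):
    base = dict(input_length=32, n_features=3, encoder_filters=(3, 4, 5, 6),
                decoder_filters=(6, 5, 4, 3), middle_filters=5, lstm_units=4,
                seed=3)
    base.update(overrides)
    return ModelConfig(**base)


def make_matrix(n, n_cols=4, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureMatrix(values=rng.normal(size=(n, n_cols)),
                         missing=np.zeros((n, n_cols), bool),
                         columns=tuple(f"f{i}" for i in range(n_cols)))


class TestArchitecture:
    def test_default_parameter_counts(self):
        model = build_network()
        trainable, non_trainable = count_parameters(model)
        assert trainable == 76552
        assert non_trainable == 496

    def test_conv_layer_closed_form_count(self):
        conv = Conv1d("c", c_in=3, c_out=7, kernel=5)
        assert sum(p.size for p in conv.params()) == 7 * (5 * 3 + 1)

    def test_non_trainable_is_batchnorm_running_stats(self):
        model = build_network()
        buffers = [p for p in model.params() if p.buffer]
        assert sum(p.size for p in buffers) == 496
        assert all("running" in p.name for p in buffers)

    def test_freezing_conserves_total(self):
        model = build_network()
        t0, n0 = count_parameters(model)
        model.freeze_encoder()
        t1, n1 = count_parameters(model)
        assert t0 + n0 == t1 + n1
        assert t1 < t0
        model.unfreeze_encoder()
        assert count_parameters(model) == (t0, n0)

    def test_counts_invariant_to_input_content(self):
        model = StagingModel(tiny_config())
        before = count_parameters(model)
        rng = np.random.default_rng(0)
        model.forward(rng.normal(size=(2, 32, 3)), train=True)
        assert count_parameters(model) == before

    @pytest.mark.parametrize("overrides", [
        dict(encoder_filters=(3, 4, 5)),
        dict(decoder_dilations=(1, 2)),
        dict(input_length=30),
    ])
    def test_invalid_structure_rejected(self, overrides):
        with pytest.raises(ConfigError):
            tiny_config(**overrides)

    def test_summary_lists_counts(self):
        model = build_network()
        text = architecture_summary(model)
        assert "76552" in text and "496" in text


class TestForward:
    def test_probability_rows_sum_to_one(self):
        model = StagingModel(tiny_config())
        x = np.random.default_rng(1).normal(size=(3, 32, 3))
        probs = model.forward(x, train=False)
        assert probs.shape == (3, 32, 4)
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-5)

    def test_non_finite_input_rejected(self):
        model = StagingModel(tiny_config())
        x = np.zeros((1, 32, 3))
        x[0, 5, 1] = np.nan
        with pytest.raises(InputError):
            model.forward(x)

    def test_conv_temporal_equivariance(self):
        """Shifting the input shifts the conv feature maps (away from borders)."""
        rng = np.random.default_rng(5)
        conv = Conv1d("c", 2, 4, kernel=3, dilation=4, rng=rng)
        x = rng.normal(size=(1, 100, 2))
        shift = 7
        xs = np.roll(x, shift, axis=1)
        y = conv.forward(x)
        ys = conv.forward(xs)
        margin = 20
        np.testing.assert_allclose(
            ys[:, margin + shift:100 - margin, :],
            y[:, margin:100 - margin - shift, :], atol=1e-12)

    def test_gradients_match_finite_differences(self):
        model = StagingModel(tiny_config())
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 32, 3))
        y = rng.integers(0, 4, size=(2, 32))
        onehot = np.eye(4)[y]

        def loss():
            probs = model.forward(x, train=True)
            return -np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=-1))

        probs = model.forward(x, train=True)
        dlogits = (probs - onehot) / y.size
        for p in model.params():
            p.zero_grad()
        model.backward(dlogits)
        eps = 1e-6
        checked = 0
        for p in model.params():
            if p.buffer:
                continue
            flat = p.data.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = p.grad.ravel()[i]
                if abs(num) > 1e-6 or abs(ana) > 1e-6:
                    assert ana == pytest.approx(num, rel=1e-4, abs=1e-8), p.name
                    checked += 1
        assert checked > 20


class TestPadding:
    def test_pad_arithmetic_and_content(self):
        m = make_matrix(2000)
        hyp = IntervalHypnogram(np.random.default_rng(0).integers(0, 4, 2000))
        ex = pad_to_input_length(m, hyp)
        assert ex.pad_length == 400
        assert (ex.features[:400] == 0).all()
        assert (ex.labels[:400] == 0).all()
        np.testing.assert_array_equal(ex.features[400:], m.values)
        np.testing.assert_array_equal(ex.labels[400:], hyp.labels)

    def test_exact_length_is_identity(self):
        m = make_matrix(2400)
        hyp = IntervalHypnogram(np.ones(2400, dtype=int))
        ex = pad_to_input_length(m, hyp)
        assert ex.pad_length == 0
        np.testing.assert_array_equal(ex.features, m.values)

    def test_over_length_rejected(self):
        m = make_matrix(2500)
        hyp = IntervalHypnogram(np.zeros(2500, dtype=int))
        with pytest.raises(InputError):
            pad_to_input_length(m, hyp)


class TestPredict:
    def test_uniform_probabilities_break_ties_to_wake(self):
        model = StagingModel(tiny_config())
        model.head.w.data[...] = 0.0
        model.head.b.data[...] = 0.0
        m = make_matrix(20, n_cols=3)
        hyp = IntervalHypnogram(np.ones(20, dtype=int))
        ex = pad_to_input_length(m, hyp, input_length=32)
        pred, probs = predict_hypnogram(model, ex)
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)
        assert (pred.labels == 0).all()

    def test_padded_region_trimmed(self):
        model = StagingModel(tiny_config())
        m = make_matrix(20, n_cols=3)
        hyp = IntervalHypnogram(np.zeros(20, dtype=int))
        ex = pad_to_input_length(m, hyp, input_length=32)
        pred, probs = predict_hypnogram(model, ex)
        assert pred.n_intervals == 20
        assert probs.shape == (20, 4)


class TestCheckpoint:
    def test_round_trip_preserves_weights_and_outputs(self, tmp_path):
        model = StagingModel(tiny_config())
        x = np.random.default_rng(2).normal(size=(1, 32, 3))
        before = model.forward(x)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        for a, b in zip(model.params(), loaded.params()):
            assert a.name == b.name
            np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_allclose(loaded.forward(x), before, atol=1e-14)
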