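import numpy as np
import pytest

from eegadvdenoise import autodiff as ad
from eegadvdenoise.autodiff import Tensor
from eegadvdenoise.exceptions import ShapeError
from eegadvdenoise.models import (
    BatchNorm1d,
    Discriminator,
    DiscriminatorConfig,
    LSTMGenerator,
    LSTMGeneratorConfig,
    ResNetGenerator,
    ResNetGeneratorConfig,
    load_model,
    save_model,
)


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestLSTMGenerator:
    def test_zero_weights_sigmoid_head_outputs_half(self, rng):
        gen = LSTMGenerator(LSTMGeneratorConfig(input_size=2, hidden_size=4))
        y = gen.forward(Tensor(rng.standard_normal((3, 7, 2))))
        np.testing.assert_allclose(y.data, 0.5)

    @pytest.mark.parametrize("L", [1, 7, 33])
    def test_output_length_equals_input_length(self, rng, L):
        gen = LSTMGenerator(
            LSTMGeneratorConfig(input_size=1, hidden_size=3), rng=np.random.default_rng(0)
        )
        y = gen.forward(Tensor(rng.standard_normal((2, L, 1))))
        assert y.shape == (2, L, 1)

    def test_matches_hand_rolled_recurrence(self, rng):
        """Two timesteps, hidden size 2, against a direct NumPy transcription
        of the gate equations."""
        cfg = LSTMGeneratorConfig(input_size=1, hidden_size=2, output_activation="none")
        gen = LSTMGenerator(cfg, rng=np.random.default_rng(7))
        p = {k: t.data for k, t in gen.params.items()}
        x = rng.standard_normal((1, 2, 1))

        h = np.zeros(2)
        c = np.zeros(2)
        expected = []
        for t in range(2):
            xt = x[0, t]
            f = _sig(p["W_f"] @ xt + p["U_f"] @ h + p["b_f"])
            i = _sig(p["W_i"] @ xt + p["U_i"] @ h + p["b_i"])
            c_tilde = np.tanh(p["W_c"] @ xt + p["U_c"] @ h + p["b_c"])
            c = f * c + i * c_tilde
            o = _sig(p["W_o"] @ xt + p["U_o"] @ h + p["b_o"])
            h = o * np.tanh(c)
            expected.append(p["W_fc"] @ h + p["b_fc"])
        y = gen.forward(Tensor(x))
        np.testing.assert_allclose(y.data[0], np.array(expected), atol=1e-12)

    def test_tanh_head_bounds(self, rng):
        cfg = LSTMGeneratorConfig(input_size=1, hidden_size=4, output_activation="tanh")
        gen = LSTMGenerator(cfg, rng=np.random.default_rng(1))
        y = gen.forward(Tensor(rng.standard_normal((2, 10, 1)) * 5))
        assert np.all(np.abs(y.data) < 1.0)

    def test_epoch_layout_round_trip(self, rng):
        gen = LSTMGenerator(LSTMGeneratorConfig(input_size=3, hidden_size=4),
                            rng=np.random.default_rng(2))
        x = rng.standard_normal((2, 3, 16))
        assert gen.forward_epochs(Tensor(x)).shape == (2, 3, 16)

    def test_parameter_count_formula(self):
        H, F, O = 8, 3, 3
        gen = LSTMGenerator(LSTMGeneratorConfig(input_size=F, hidden_size=H))
        expected = 4 * (H * F + H * H + H) + O * H + O
        assert gen.n_parameters() == expected


class TestResNetGenerator:
    def test_zero_weights_output_half(self, rng):
        gen = ResNetGenerator(ResNetGeneratorConfig(n_channels=1, base_filters=4, n_blocks=2))
        y = gen.forward_epochs(Tensor(rng.standard_normal((2, 1, 16))))
        np.testing.assert_allclose(y.data, 0.5)

    def test_output_in_open_unit_interval_and_shape_preserved(self, rng):
        gen = ResNetGenerator(
            ResNetGeneratorConfig(n_channels=2, base_filters=4, n_blocks=2),
            rng=np.random.default_rng(0),
        )
        x = rng.standard_normal((3, 2, 32))
        y = gen.forward_epochs(Tensor(x))
        assert y.shape == x.shape
        assert np.all(y.data > 0) and np.all(y.data < 1)

    def test_odd_length_rejected(self, rng):
        gen = ResNetGenerator(ResNetGeneratorConfig(n_channels=1, base_filters=4, n_blocks=1))
        with pytest.raises(ShapeError, match="divisible by 2"):
            gen.forward_epochs(Tensor(rng.standard_normal((1, 1, 15))))

    def test_zero_blocks_act_as_identity_on_nonnegative_activations(self, rng):
        """With block weights zeroed the residual path contributes 0, so
        y_{k+1} = ReLU(y_k) equals y_k on the (nonnegative) post-ReLU
        stem activations."""
        gen = ResNetGenerator(
            ResNetGeneratorConfig(n_channels=1, base_filters=4, n_blocks=3),
            rng=np.random.default_rng(3),
        )
        for name, t in gen.params.items():
            if name.startswith("block"):
                t.data[...] = 0.0
        x = Tensor(rng.standard_normal((2, 1, 16)))
        pad = gen.config.kernel_size // 2
        stem = ad.relu(
            gen.bns["bn0"](
                ad.conv1d(x, gen.params["conv0.w"], gen.params["conv0.b"], stride=2, padding=pad),
                False,
            )
        )
        after = stem
        for k in range(gen.config.n_blocks):
            after = ad.relu(after)  # blocks reduce to ReLU of identity
        np.testing.assert_allclose(after.data, stem.data)

    def test_block_count_matches_config(self):
        gen = ResNetGenerator(ResNetGeneratorConfig(n_channels=1, base_filters=2, n_blocks=16))
        block_convs = [k for k in gen.params if k.startswith("block") and k.endswith(".w")]
        assert len(block_convs) == 32  # two convs per block


class TestDiscriminator:
    def test_zero_weights_heads(self, rng):
        x = Tensor(rng.standard_normal((2, 1, 512)))
        d_sig = Discriminator(DiscriminatorConfig(in_channels=1)).build(512)
        np.testing.assert_allclose(d_sig.forward(x).data, 0.5)
        d_lin = Discriminator(DiscriminatorConfig(in_channels=1, head="linear")).build(512)
        np.testing.assert_allclose(d_lin.forward(x).data, 0.0)

    def test_filter_doubling_and_stride_pattern(self):
        cfg = DiscriminatorConfig()
        assert cfg.filters == [64, 64, 128, 128, 256, 256, 512, 512]
        assert cfg.strides == [1, 2, 1, 2, 1, 2, 1, 2]
        assert cfg.downsample == 16

    @pytest.mark.parametrize("L", [64, 512])
    def test_flattened_width_formula(self, L):
        d = Discriminator(DiscriminatorConfig(in_channels=1))
        assert d.flattened_width(L) == 1024 * L // 16

    def test_indivisible_length_rejected(self, rng):
        d = Discriminator(DiscriminatorConfig(in_channels=1)).build(512)
        with pytest.raises(ShapeError, match="divisible"):
            d.forward(Tensor(rng.standard_normal((1, 1, 500))))

    def test_scores_are_scalar_per_item(self, rng):
        d = Discriminator(
            DiscriminatorConfig(in_channels=2, base_filters=4, n_layers=4, proj_filters=8),
            rng=np.random.default_rng(1),
        ).build(32, rng=np.random.default_rng(2))
        out = d.forward(Tensor(rng.standard_normal((5, 2, 32))))
        assert out.shape == (5,)
        assert np.all((out.data > 0) & (out.data < 1))

    def test_layer_and_no_norm_variants_run(self, rng):
        for norm in ("layer", "none"):
            d = Discriminator(
                DiscriminatorConfig(in_channels=1, base_filters=4, n_layers=4,
                                    proj_filters=8, norm=norm, head="linear"),
                rng=np.random.default_rng(0),
            ).build(32, rng=np.random.default_rng(1))
            out = d.forward(Tensor(rng.standard_normal((3, 1, 32))))
            assert np.all(np.isfinite(out.data))


class TestBatchNorm:
    def test_training_mode_standardizes_batch(self, rng):
        bn = BatchNorm1d(2)
        x = Tensor(rng.standard_normal((8, 2, 16)) * 3 + 1)
        y = bn(x, training=True)
        np.testing.assert_allclose(y.data.mean(axis=(0, 2)), 0.0, atol=1e-10)
        np.testing.assert_allclose(y.data.std(axis=(0, 2)), 1.0, atol=1e-2)

    def test_inference_uses_running_stats(self, rng):
        bn = BatchNorm1d(1)
        x = Tensor(rng.standard_normal((4, 1, 8)))
        bn(x, training=True)
        y1 = bn(x, training=False).data
        y2 = bn(x, training=False).data  # no state drift in eval mode
        np.testing.assert_array_equal(y1, y2)


class TestPersistence:
    def test_generator_round_trip(self, rng, tmp_path):
        gen = LSTMGenerator(LSTMGeneratorConfig(input_size=1, hidden_size=6),
                            rng=np.random.default_rng(5))
        x = Tensor(rng.standard_normal((2, 12, 1)))
        save_model(gen, tmp_path / "g")
        back = load_model(tmp_path / "g")
        np.testing.assert_array_equal(back.forward(x).data, gen.forward(x).data)

    def test_discriminator_round_trip_includes_dense_head(self, rng, tmp_path):
        d = Discriminator(
            DiscriminatorConfig(in_channels=1, base_filters=4, n_layers=4, proj_filters=8),
            rng=np.random.default_rng(6),
        ).build(32, rng=np.random.default_rng(7))
        x = Tensor(rng.standard_normal((3, 1, 32)))
        save_model(d, tmp_path / "d")
        back = load_model(tmp_path / "d")
        np.testing.assert_array_equal(back.forward(x).data, d.forward(x).data)

    def test_manifest_rebuilds_architecture(self, tmp_path):
        gen = ResNetGenerator(ResNetGeneratorConfig(n_channels=2, base_filters=4, n_blocks=2),
                              rng=np.random.default_rng(8))
        save_model(gen, tmp_path / "r")
        back = load_model(tmp_path / "r")
        assert back.config == gen.config
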