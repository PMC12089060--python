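import numpy as np
import pytest

from eegadvdenoise import autodiff as ad
from eegadvdenoise.autodiff import Tensor
from eegadvdenoise.exceptions import DivergenceError, ShapeError, UsageError
from eegadvdenoise.io import EEGRecording
from eegadvdenoise.models import (
    Discriminator,
    DiscriminatorConfig,
    LSTMGenerator,
    LSTMGeneratorConfig,
)
from eegadvdenoise.preprocess import minmax_normalize
from eegadvdenoise.synthetic import NoiseSpec, PairedEpochSet
from eegadvdenoise.training import (
    Adam,
    TrainingConfig,
    content_loss,
    denoise,
    gradient_penalty,
    lsgan_discriminator_loss,
    lsgan_generator_loss,
    train,
    wgan_critic_loss,
    wgan_generator_loss,
)

SMALL_DISC = dict(base_filters=4, n_layers=4, proj_filters=8)


def _tiny_pairs(rng, n=8, C=1, L=16):
    clean = rng.uniform(0.2, 0.8, size=(n, C, L))
    noisy = clean + rng.standard_normal((n, C, L)) * 0.1
    return PairedEpochSet(clean=clean, noisy=noisy,
                          specs=[NoiseSpec("white", 0.0, 0)] * n, epoch_len=L)


class TestLossFunctions:
    def test_content_loss_values(self, rng):
        a = rng.standard_normal((3, 4))
        assert content_loss(Tensor(a), Tensor(a.copy())).data == 0.0
        assert content_loss(Tensor(a + 0.5), Tensor(a)).data == pytest.approx(0.25)
        b = rng.standard_normal((3, 4))
        assert content_loss(Tensor(a), Tensor(b)).data == pytest.approx(np.mean((a - b) ** 2))

    def test_content_loss_shape_mismatch(self, rng):
        with pytest.raises(ShapeError):
            content_loss(Tensor(np.zeros((2, 3))), Tensor(np.zeros((3, 2))))

    def test_lsgan_discriminator_loss(self, rng):
        assert lsgan_discriminator_loss(Tensor([1.0]), Tensor([0.0])).data == 0.0
        assert lsgan_discriminator_loss(Tensor([0.5]), Tensor([0.5])).data == pytest.approx(0.25)
        dr, df = rng.uniform(0, 1, 8), rng.uniform(0, 1, 8)
        expected = 0.5 * (np.mean((dr - 1) ** 2) + np.mean(df**2))
        assert lsgan_discriminator_loss(Tensor(dr), Tensor(df)).data == pytest.approx(expected)

    def test_lsgan_generator_loss(self, rng):
        out = rng.uniform(0, 1, (2, 3))
        clean = out.copy()
        assert lsgan_generator_loss(Tensor([1.0]), Tensor(out), Tensor(clean)).data == 0.0
        # adv_weight 0 reduces to the content term alone
        df = Tensor(rng.uniform(0, 1, 4))
        other = rng.uniform(0, 1, (2, 3))
        l0 = lsgan_generator_loss(df, Tensor(out), Tensor(other), adv_weight=0.0)
        assert l0.data == pytest.approx(np.mean((out - other) ** 2))
        l1 = lsgan_generator_loss(Tensor([0.5]), Tensor(out), Tensor(clean), adv_weight=1.0)
        assert l1.data == pytest.approx(0.25)

    def test_wgan_losses(self, rng):
        assert wgan_critic_loss(Tensor([2.0, 2.0]), Tensor([2.0, 2.0])).data == 0.0
        assert wgan_critic_loss(Tensor([2.0]), Tensor([-1.0])).data == pytest.approx(-3.0)
        assert wgan_critic_loss(Tensor([2.0]), Tensor([-1.0]), gp=40.0).data == pytest.approx(37.0)
        d = rng.standard_normal(16)
        assert wgan_generator_loss(Tensor(d)).data == pytest.approx(-d.mean())


class _LinearCritic:
    """D(x) = <w, x> flattened; closed-form gradient norm ||w||."""

    def __init__(self, w):
        self.w = Tensor(np.asarray(w, float), requires_grad=True)

    def forward(self, x, training=False):
        B = x.shape[0]
        return ad.matmul(x.reshape(B, -1), ad.transpose(self.w.reshape(1, -1), (1, 0))).reshape(B)


class TestGradientPenalty:
    def test_unit_norm_linear_critic_gives_zero(self, rng):
        w = rng.standard_normal(12)
        critic = _LinearCritic(w / np.linalg.norm(w))
        x_real = rng.standard_normal((4, 1, 12))
        x_fake = rng.standard_normal((4, 1, 12))
        gp = gradient_penalty(critic, x_real, x_fake, lambda_gp=10.0, seed=0)
        assert gp.data == pytest.approx(0.0, abs=1e-9)

    def test_norm_three_linear_critic(self, rng):
        w = rng.standard_normal(12)
        critic = _LinearCritic(3.0 * w / np.linalg.norm(w))
        gp = gradient_penalty(
            critic, rng.standard_normal((4, 1, 12)), rng.standard_normal((4, 1, 12)),
            lambda_gp=10.0, seed=0,
        )
        assert gp.data == pytest.approx(10.0 * (3.0 - 1.0) ** 2, rel=1e-9)

    def test_interpolate_gradient_matches_finite_difference(self, rng):
        """Analytic input-gradient of a small nonlinear critic at the
        interpolates, against central differences."""
        w1 = rng.standard_normal((5, 8)) * 0.5
        w2 = rng.standard_normal((1, 5)) * 0.5

        class MLP:
            def forward(self, x, training=False):
                B = x.shape[0]
                h = ad.tanh(ad.matmul(x.reshape(B, 8), Tensor(w1.T)))
                return ad.matmul(h, Tensor(w2.T)).reshape(B)

        x = rng.standard_normal((3, 1, 8))
        xt = Tensor(x, requires_grad=True)
        critic = MLP()
        (gx,) = ad.grad(critic.forward(xt).sum(), [xt])

        def f(v):
            return float(critic.forward(Tensor(v)).sum().data)

        num = np.zeros_like(x)
        eps = 1e-5
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            num[i] = (f(xp) - f(xm)) / (2 * eps)
        np.testing.assert_allclose(gx.data, num, atol=1e-4)

    def test_penalty_drops_to_zero_with_lambda(self, rng):
        critic = _LinearCritic(rng.standard_normal(6))
        x = rng.standard_normal((2, 1, 6))
        gp = gradient_penalty(critic, x, x + 0.1, lambda_gp=0.0, seed=1)
        assert gp.data == 0.0


class TestAdam:
    def test_single_step_descends(self, rng):
        w = Tensor(rng.standard_normal(5), requires_grad=True)
        target = rng.standard_normal(5)

        def loss_t():
            return ((w - Tensor(target)) ** 2).sum()

        l0 = float(loss_t().data)
        opt = Adam([w], lr=1e-3)
        opt.step(ad.grad(loss_t(), [w]))
        assert float(loss_t().data) < l0


class TestTrainLoop:
    def test_smoke_lsgan_finite_trace(self, rng):
        pairs = _tiny_pairs(rng, n=4, L=16)
        cfg = TrainingConfig.lsgan(epochs=1, batch_size=4, seed=0, lr_g=1e-3, lr_d=1e-3)
        gen, disc, trace = train(
            pairs, g_arch="lstm", cfg=cfg,
            generator_kwargs={"hidden_size": 4},
            discriminator_config=DiscriminatorConfig(in_channels=1, **SMALL_DISC),
        )
        assert np.all(np.isfinite(trace.g_loss))
        assert np.all(np.isfinite(trace.d_loss))
        assert len(trace.d_loss) == 1

    def test_same_seed_identical_parameters(self, rng):
        pairs = _tiny_pairs(rng, n=8, L=16)
        cfg = TrainingConfig.wgan_gp(epochs=1, batch_size=4, seed=3, lr_g=1e-3, lr_d=1e-3,
                                     n_critic=2)
        disc_cfg = DiscriminatorConfig(in_channels=1, head="linear", **SMALL_DISC)
        outs = []
        for _ in range(2):
            gen, disc, _ = train(pairs, g_arch="lstm", cfg=cfg,
                                 generator_kwargs={"hidden_size": 4},
                                 discriminator_config=disc_cfg)
            outs.append((gen.state(), disc.state()))
        for k in outs[0][0]:
            np.testing.assert_array_equal(outs[0][0][k], outs[1][0][k])
        for k in outs[0][1]:
            np.testing.assert_array_equal(outs[0][1][k], outs[1][1][k])

    def test_wgan_lambda_zero_walks_nogp_trajectory(self, rng):
        """Continuity at lambda -> 0: with the penalty coefficient zeroed,
        wgan_gp and wgan_nogp produce identical parameter trajectories
        because the epsilon stream is segregated from the shuffle stream."""
        pairs = _tiny_pairs(rng, n=8, L=16)
        disc_cfg = DiscriminatorConfig(in_channels=1, head="linear", **SMALL_DISC)
        common = dict(epochs=1, batch_size=4, seed=5, lr_g=1e-3, lr_d=1e-3, n_critic=2)
        gen_a, disc_a, _ = train(
            pairs, cfg=TrainingConfig.wgan_gp(lambda_gp=0.0, **common),
            generator_kwargs={"hidden_size": 4}, discriminator_config=disc_cfg,
        )
        gen_b, disc_b, _ = train(
            pairs, cfg=TrainingConfig.wgan_nogp(**common),
            generator_kwargs={"hidden_size": 4}, discriminator_config=disc_cfg,
        )
        for k in gen_a.state():
            np.testing.assert_allclose(gen_a.state()[k], gen_b.state()[k], atol=1e-12)
        for k in disc_a.state():
            np.testing.assert_allclose(disc_a.state()[k], disc_b.state()[k], atol=1e-12)

    def test_single_lsgan_step_decreases_both_losses(self, rng):
        """One alternating update at a small learning rate moves both
        networks downhill on their own objectives for a fixed batch."""
        pairs = _tiny_pairs(rng, n=4, L=16)
        disc_cfg = DiscriminatorConfig(in_channels=1, **SMALL_DISC)
        root = np.random.SeedSequence(9)
        init_rng = np.random.default_rng(root.spawn(1)[0])
        gen = LSTMGenerator(LSTMGeneratorConfig(input_size=1, hidden_size=4), rng=init_rng)
        disc = Discriminator(disc_cfg, rng=init_rng).build(16, rng=init_rng)
        xb, yb = Tensor(pairs.noisy), Tensor(pairs.clean)

        def d_loss_value():
            fake = gen.forward_epochs(xb)
            return lsgan_discriminator_loss(disc.forward(yb), disc.forward(Tensor(fake.data)))

        def g_loss_value():
            fake = gen.forward_epochs(xb)
            return lsgan_generator_loss(disc.forward(fake), fake, yb)

        d0 = float(d_loss_value().data)
        Adam(disc.parameters(), lr=1e-4).step(ad.grad(d_loss_value(), disc.parameters()))
        assert float(d_loss_value().data) < d0

        g0 = float(g_loss_value().data)
        Adam(gen.parameters(), lr=1e-4).step(ad.grad(g_loss_value(), gen.parameters()))
        assert float(g_loss_value().data) < g0

    def test_resnet_generator_trains(self, rng):
        pairs = _tiny_pairs(rng, n=4, L=16)
        cfg = TrainingConfig.lsgan(epochs=1, batch_size=4, seed=0, lr_g=1e-3, lr_d=1e-3)
        gen, _, trace = train(
            pairs, g_arch="resnet", cfg=cfg,
            generator_kwargs={"base_filters": 4, "n_blocks": 1},
            discriminator_config=DiscriminatorConfig(in_channels=1, **SMALL_DISC),
        )
        assert np.all(np.isfinite(trace.g_loss))
        out = gen.forward_epochs(Tensor(pairs.noisy)).data
        assert out.shape == pairs.noisy.shape

    def test_early_stopping_records_validation_curve(self, rng):
        pairs = _tiny_pairs(rng, n=20, L=16)
        cfg = TrainingConfig.lsgan(epochs=6, batch_size=8, seed=1, lr_g=1e-3, lr_d=1e-3,
                                   early_stop_patience=1)
        _, _, trace = train(pairs, cfg=cfg, generator_kwargs={"hidden_size": 4},
                            discriminator_config=DiscriminatorConfig(in_channels=1, **SMALL_DISC))
        assert 1 <= len(trace.val_content) <= 6

    def test_epoch_length_must_match_discriminator(self, rng):
        pairs = _tiny_pairs(rng, n=4, L=18)  # 18 not divisible by 4
        with pytest.raises(ShapeError):
            train(pairs, cfg=TrainingConfig.lsgan(epochs=1, seed=0),
                  discriminator_config=DiscriminatorConfig(in_channels=1, **SMALL_DISC))

    def test_empty_pairs_rejected(self):
        pairs = PairedEpochSet(clean=np.zeros((0, 1, 16)), noisy=np.zeros((0, 1, 16)),
                               specs=[], epoch_len=16)
        with pytest.raises(UsageError):
            train(pairs, cfg=TrainingConfig.lsgan(seed=0))


class TestDenoise:
    def _norm_rec(self, rng, C=1, n=100):
        rec = EEGRecording([f"C{i}" for i in range(C)], 128.0,
                           rng.standard_normal((C, n)))
        out, state = minmax_normalize(rec)
        return out, state

    def test_output_shape_equals_input_shape(self, rng):
        rec, _ = self._norm_rec(rng, C=2, n=100)
        gen = LSTMGenerator(LSTMGeneratorConfig(input_size=2, hidden_size=4),
                            rng=np.random.default_rng(0))
        out = denoise(gen, rec, epoch_len=32)
        assert out.data.shape == rec.data.shape

    def test_zero_weight_generator_outputs_half(self, rng):
        rec, _ = self._norm_rec(rng)
        gen = LSTMGenerator(LSTMGeneratorConfig(input_size=1, hidden_size=4))
        out = denoise(gen, rec, epoch_len=50)
        np.testing.assert_allclose(out.data, 0.5)

    def test_unnormalized_input_rejected(self, rng):
        rec = EEGRecording(["C3"], 128.0, rng.standard_normal((1, 64)) * 10)
        gen = LSTMGenerator(LSTMGeneratorConfig(input_size=1, hidden_size=4))
        with pytest.raises(UsageError, match="normalized"):
            denoise(gen, rec, epoch_len=32)

    def test_inverse_normalization_applied(self, rng):
        rec, state = self._norm_rec(rng)
        gen = LSTMGenerator(LSTMGeneratorConfig(input_size=1, hidden_size=4))
        out = denoise(gen, rec, norm=state, epoch_len=50)
        # constant 0.5 maps back to the channel midpoint
        mid = (state.per_channel_min + state.per_channel_max) / 2
        np.testing.assert_allclose(out.data[0], mid[0])


class TestDivergenceHandling:
    def test_divergence_error_carries_trace(self):
        from eegadvdenoise.training import TrainingTrace, _check_finite

        trace = TrainingTrace(g_loss=[0.1], d_loss=[np.nan], gp=[0.0])
        with pytest.raises(DivergenceError) as exc:
            _check_finite(trace, np.nan)
        assert exc.value.trace is trace
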