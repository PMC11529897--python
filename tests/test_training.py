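"""Transition schedule, loss structure and the training loops."""

import numpy as np
import pytest

from beetlegan import (DiscriminatorOutput, GANConfig, OptimConfig,
                       TransitionSchedule, apply_lr_decay,
                       discriminator_loss, generator_loss, train_baseline,
                       train_gan, transition_lambda)
from beetlegan import nn

TINY = GANConfig(ngf=8, ndf=8)
SCHEDULE = TransitionSchedule(500, 600, 1250)


def tiny_data(rng, n_per_class=3):
    x = rng.uniform(-1, 1, (3 * n_per_class, 3, 64, 64)).astype(np.float32)
    y = np.repeat(np.arange(3), n_per_class)
    return x, y


def fake_output(rng, n=8, realness=None):
    r = realness if realness is not None else rng.uniform(0.1, 0.9, n)
    logits = rng.standard_normal((n, 3))
    return DiscriminatorOutput(np.asarray(r, dtype=np.float64),
                               nn.log_softmax(logits))


class TestTransitionLambda:
    @pytest.mark.parametrize("t,expected", [
        (0, 0.0), (500, 0.0), (550, 0.5), (600, 1.0), (1250, 1.0),
    ])
    def test_closed_form(self, t, expected):
        assert transition_lambda(t, SCHEDULE) == pytest.approx(expected)

    def test_matches_clamped_linear_everywhere(self, rng):
        for _ in range(1000):
            t_s = int(rng.integers(0, 500))
            t_e = int(rng.integers(t_s + 1, 1000))
            t_m = int(rng.integers(t_e, 2000))
            t = int(rng.integers(0, t_m + 1))
            sched = TransitionSchedule(t_s, t_e, t_m)
            expected = min(max((t - t_s) / (t_e - t_s), 0.0), 1.0)
            assert transition_lambda(t, sched) == expected

    def test_nondecreasing_piecewise_linear(self):
        vals = [transition_lambda(t, SCHEDULE) for t in range(0, 1251, 10)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[0] == 0.0 and vals[-1] == 1.0

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            transition_lambda(-1, SCHEDULE)

    def test_degenerate_schedule_rejected(self):
        with pytest.raises(ValueError):
            TransitionSchedule(500, 500, 1250)


class TestLRDecay:
    OPT = OptimConfig()

    def test_no_decay_off_milestone(self):
        lrs = {"lr_D": 0.001, "lr_G": 0.01}
        assert apply_lr_decay(59, self.OPT, lrs) == lrs

    def test_halves_both_rates_at_milestone(self):
        out = apply_lr_decay(60, self.OPT, {"lr_D": 0.001, "lr_G": 0.01})
        assert out == {"lr_D": 0.0005, "lr_G": 0.005}

    def test_compounds_over_all_milestones(self):
        lrs = {"lr_D": 0.001, "lr_G": 0.01}
        for epoch in range(1250):
            lrs = apply_lr_decay(epoch, self.OPT, lrs)
        assert lrs["lr_G"] == pytest.approx(0.01 * 2 ** -6)
        assert lrs["lr_D"] == pytest.approx(0.001 * 2 ** -6)


class TestLossStructure:
    def test_lambda_zero_is_pure_adversarial(self, rng):
        real, fake = fake_output(rng), fake_output(rng)
        y = rng.integers(0, 3, 8)
        l0 = discriminator_loss(real, fake, y, 0.0)
        l_real, _ = nn.bce_loss(real.realness, 1.0)
        l_fake, _ = nn.bce_loss(fake.realness, 0.0)
        assert l0 == pytest.approx(l_real + l_fake)

    def test_perfect_discriminator_loss_vanishes(self, rng):
        n = 8
        real = DiscriminatorOutput(
            np.full(n, 1 - 1e-7),
            np.log(np.full((n, 3), 1e-7) + np.eye(3)[np.zeros(n, int)]))
        fake = DiscriminatorOutput(np.full(n, 1e-7), real.class_logprobs)
        loss = discriminator_loss(real, fake, np.zeros(n, int), 1.0)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_linear_decomposition_in_lambda(self, rng):
        """L(lam) = L(0) + lam * conditional term, for both players."""
        real, fake = fake_output(rng), fake_output(rng)
        y = rng.integers(0, 3, 8)
        for lossfn, args in ((discriminator_loss, (real, fake, y)),
                             (generator_loss, (fake, y))):
            l0 = lossfn(*args, 0.0)
            l1 = lossfn(*args, 1.0)
            lh = lossfn(*args, 0.5)
            assert lh == pytest.approx(l0 + 0.5 * (l1 - l0), rel=1e-9)

    def test_nondecreasing_in_lambda(self, rng):
        real, fake = fake_output(rng), fake_output(rng)
        y = rng.integers(0, 3, 8)
        assert discriminator_loss(real, fake, y, 0.8) >= \
            discriminator_loss(real, fake, y, 0.2)
        assert generator_loss(fake, y, 1.0) >= generator_loss(fake, y, 0.0)

    def test_fooled_discriminator_generator_loss_vanishes(self):
        n = 4
        out = DiscriminatorOutput(
            np.full(n, 1 - 1e-7),
            np.log(np.full((n, 3), 1e-7) + np.eye(3)[np.ones(n, int)]))
        assert generator_loss(out, np.ones(n, int), 1.0) == \
            pytest.approx(0.0, abs=1e-5)

    def test_missing_sigmoid_is_hard_error(self, rng):
        bad = fake_output(rng, realness=np.array([1.5, 0.3]))
        with pytest.raises(ValueError, match="sigmoid"):
            generator_loss(bad, np.zeros(2, int), 0.5)

    def test_lambda_out_of_range_rejected(self, rng):
        fake = fake_output(rng)
        with pytest.raises(ValueError):
            generator_loss(fake, np.zeros(8, int), 1.5)


class TestTrainGAN:
    def test_smoke_run_records_history(self, rng):
        data = tiny_data(rng)
        opt = OptimConfig(batch_size=4, pretrain_epochs=1, seed=0)
        res = train_gan(data, TINY, opt, TransitionSchedule(0, 1, 2))
        assert len(res.history) == 2
        for key in ("lam", "loss_D_uncond", "loss_G_uncond", "lr_D"):
            assert key in res.history.rows[0]

    def test_lambda_column_tracks_schedule(self, rng):
        data = tiny_data(rng)
        opt = OptimConfig(batch_size=4, pretrain_epochs=1, seed=0)
        res = train_gan(data, TINY, opt, TransitionSchedule(1, 2, 4))
        lam = res.history.column("lam")
        assert lam == [0.0, 0.0, 1.0, 1.0]
        assert all(b >= a for a, b in zip(lam, lam[1:]))

    def test_learning_rates_nonincreasing(self, rng):
        data = tiny_data(rng)
        opt = OptimConfig(batch_size=4, pretrain_epochs=1, seed=0,
                          decay_epochs=(1, 3))
        res = train_gan(data, TINY, opt, TransitionSchedule(0, 1, 4))
        for col in ("lr_D", "lr_G"):
            vals = res.history.column(col)
            assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_missing_class_is_hard_error(self, rng):
        x = rng.uniform(-1, 1, (6, 3, 64, 64)).astype(np.float32)
        y = np.array([0, 0, 0, 1, 1, 1])
        opt = OptimConfig(batch_size=4, seed=0)
        with pytest.raises(ValueError, match="class"):
            train_gan((x, y), TINY, opt, TransitionSchedule(0, 1, 2))

    def test_discriminator_step_descends_on_fixed_batch(self, rng):
        """One update at a small learning rate lowers that batch's loss."""
        from beetlegan.models import Discriminator, Generator, \
            make_generator_input
        disc = Discriminator(TINY, np.random.default_rng(0))
        disc.set_dropout_rng(np.random.default_rng(1))
        x, y = tiny_data(rng, 4)
        noise = rng.standard_normal((12, TINY.nz)).astype(np.float32)
        fake = Generator(TINY, np.random.default_rng(2)).forward(
            make_generator_input(noise, y, 3, 0.0))

        def batch_loss():
            out_r = disc.forward(x, training=False)
            out_f = disc.forward(fake, training=False)
            return discriminator_loss(out_r, out_f, y, 1.0)

        before = batch_loss()
        opt = nn.Adam(disc.params(), lr=1e-4)
        disc.zero_grad()
        out_r = disc.forward(x, training=False)
        _, g_real = nn.bce_loss(out_r.realness, 1.0)
        _, g_cls = nn.nll_loss(out_r.class_logprobs, y)
        disc.backward_heads(g_real, g_cls)
        out_f = disc.forward(fake, training=False)
        _, g_fake = nn.bce_loss(out_f.realness, 0.0)
        disc.backward_heads(g_fake, None)
        opt.step()
        assert batch_loss() < before


class TestTrainBaseline:
    def test_deterministic_under_seed(self, rng):
        data = tiny_data(rng)
        opt = OptimConfig(batch_size=4, seed=7)
        d1, _ = train_baseline(data, TINY, opt, augment=False, epochs=2)
        d2, _ = train_baseline(data, TINY, opt, augment=False, epochs=2)
        for a, b in zip(d1.state_arrays(), d2.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_augmentation_preserves_labels_and_shapes(self, rng):
        from beetlegan.training import _augment_batch
        x = rng.uniform(-1, 1, (6, 3, 64, 64)).astype(np.float32)
        out = _augment_batch(x, np.random.default_rng(0))
        assert out.shape == x.shape
        # flips/rotations permute pixels: per-image multisets unchanged
        for i in range(6):
            np.testing.assert_allclose(np.sort(out[i].ravel()),
                                       np.sort(x[i].ravel()))

    def test_learns_above_chance_on_separable_data(self):
        """NLL training on well-separated synthetic classes beats 1/3."""
        from beetlegan import make_dataset, split_dataset, to_ndi_stack
        from beetlegan.preprocess import to_training_array
        crops = make_dataset(20, seed=5)
        tr, te = split_dataset(crops, 0.25, seed=5)
        train = to_training_array([to_ndi_stack(c) for c in tr])
        test = to_training_array([to_ndi_stack(c) for c in te])
        opt = OptimConfig(batch_size=16, seed=5)
        _, hist = train_baseline(train, TINY, opt, augment=False,
                                 epochs=25, test_set=test)
        assert max(r["test_accuracy"] for r in hist.rows) > 1 / 3
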