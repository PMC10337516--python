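import numpy as np
import pytest

from ehrgan import autodiff as ad
from ehrgan.autodiff import Tensor
from ehrgan.gan import (GanConfig, build_discriminator, build_generator,
                        critic_score, export_last_layer, generate_samples,
                        load_model, loss_entropy, loss_semisupervised,
                        predict_proba, pull_away_term, save_model, train,
                        wgan_gp_terms)


def _rng():
    return np.random.default_rng(0)


class TestBuilders:
    def test_generator_shape_and_determinism(self):
        cfg = GanConfig(z_dim=100, gen_layers=(32,), seed=0)
        gen = build_generator(cfg, out_dim=21, rng=_rng())
        z = Tensor(np.random.default_rng(1).standard_normal((4, 100)))
        a = gen.forward(z, training=False).data
        b = gen.forward(z, training=False).data
        assert a.shape == (4, 21)
        assert np.array_equal(a, b)

    def test_generator_varies_with_z(self):
        cfg = GanConfig(z_dim=16, gen_layers=(32,), seed=0)
        gen = build_generator(cfg, out_dim=5, rng=_rng())
        rng = np.random.default_rng(2)
        outs = [gen.forward(Tensor(rng.standard_normal((1, 16))), training=False).data
                for _ in range(10)]
        assert len({tuple(o.ravel().round(12)) for o in outs}) == 10

    def test_discriminator_outputs(self):
        cfg = GanConfig(disc_layers=(16, 8))
        disc = build_discriminator(cfg, in_dim=7, M=2, rng=_rng())
        x = Tensor(np.random.default_rng(3).standard_normal((5, 7)))
        logits, h = disc.forward(x, training=False, return_hidden=True)
        assert logits.shape == (5, 3)
        assert h.shape == (5, 8)
        probs = ad.softmax(logits, axis=1).data
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestSemisupervisedLoss:
    def test_perfect_supervised_prediction_gives_zero(self):
        logits = np.array([[50.0, -50.0, 0.0]])
        l_sup, _ = loss_semisupervised(logits, [0], np.zeros((0, 3)), np.zeros((0, 3)))
        assert l_sup.item() == pytest.approx(0.0, abs=1e-12)

    def test_perfect_real_fake_separation_gives_zero_unsup(self):
        unl = np.array([[0.0, 0.0, -100.0]])  # P(fake)≈0
        fake = np.array([[-100.0, -100.0, 0.0]])  # P(fake)≈1
        _, l_un = loss_semisupervised(np.zeros((0, 3)), [], unl, fake)
        assert l_un.item() == pytest.approx(0.0, abs=1e-12)

    def test_uniform_logits_closed_form(self):
        # M=2: renormalized uniform -> loss_sup = ln 2; P(fake)=1/3 each
        lab = np.zeros((1, 3))
        unl = np.zeros((1, 3))
        fake = np.zeros((1, 3))
        l_sup, l_un = loss_semisupervised(lab, [1], unl, fake)
        assert l_sup.item() == pytest.approx(np.log(2))
        assert l_un.item() == pytest.approx(-np.log(2 / 3) - np.log(1 / 3))


class TestEntropyLoss:
    def test_one_hot_is_zero(self):
        logits = np.array([[100.0, -100.0, 0.0]])
        assert loss_entropy(logits).item() == pytest.approx(0.0, abs=1e-12)

    def test_uniform_is_ln2(self):
        assert loss_entropy(np.zeros((1, 3))).item() == pytest.approx(np.log(2))

    def test_direct_formula(self):
        # Q = (0.9, 0.1) over real classes
        logits = np.array([[np.log(0.9), np.log(0.1), -50.0]])
        expected = -0.9 * np.log(0.9) - 0.1 * np.log(0.1)
        assert loss_entropy(logits).item() == pytest.approx(expected, abs=1e-9)

    def test_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            logits = rng.normal(size=(8, 4)) * 3
            v = loss_entropy(logits).item()
            assert 0.0 <= v <= np.log(3) + 1e-12


class TestPullAway:
    def test_identical_pair_is_one(self):
        f = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert pull_away_term(f).item() == pytest.approx(1.0)

    def test_orthogonal_pair_is_zero(self):
        f = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert pull_away_term(f).item() == pytest.approx(0.0, abs=1e-9)

    def test_hand_case_half(self):
        f = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert pull_away_term(f).item() == pytest.approx(0.5, abs=1e-9)

    def test_bounds_on_random_batches(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            v = pull_away_term(rng.normal(size=(12, 5))).item()
            assert -1e-9 <= v <= 1.0 + 1e-9

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError):
            pull_away_term(np.ones((1, 3)))


class TestWganGp:
    def test_identical_batches_zero_wasserstein(self):
        disc = build_discriminator(GanConfig(disc_layers=(16,)), in_dim=4, M=2, rng=_rng())
        x = np.random.default_rng(7).standard_normal((8, 4))
        l_d, l_g = wgan_gp_terms(lambda t: disc(t, training=False), x, x, lam_gp=0.0,
                                 rng=np.random.default_rng(0))
        assert l_d.item() == pytest.approx(0.0, abs=1e-9)

    def test_unit_gradient_linear_critic_zero_penalty(self):
        # logits = [u.x, u.x, 0] -> s(x) = u.x + ln 2, grad = u with |u| = 1
        u = np.array([0.6, 0.8])

        def logits_fn(t):
            ux = ad.matmul(t, Tensor(u[:, None]))
            zeros = Tensor(np.zeros((t.shape[0], 1)))
            return ad.concatenate([ux, ux, zeros], axis=1)

        real = np.random.default_rng(8).standard_normal((6, 2))
        fake = np.random.default_rng(9).standard_normal((6, 2))
        lam = 100.0
        l_d_pen, _ = wgan_gp_terms(logits_fn, real, fake, lam_gp=lam,
                                   rng=np.random.default_rng(1))
        l_d_none, _ = wgan_gp_terms(logits_fn, real, fake, lam_gp=0.0,
                                    rng=np.random.default_rng(1))
        assert l_d_pen.item() == pytest.approx(l_d_none.item(), abs=1e-9)

    def test_critic_gradient_matches_finite_differences(self):
        disc = build_discriminator(GanConfig(disc_layers=(8,)), in_dim=3, M=2, rng=_rng())
        rng = np.random.default_rng(10)
        for _ in range(5):
            x0 = rng.standard_normal(3)
            xt = Tensor(x0[None, :], requires_grad=True)
            s = ad.sum_(critic_score(disc(xt, training=False)))
            (g,) = ad.grad(s, [xt])
            num = np.zeros(3)
            eps = 1e-6
            for i in range(3):
                xp, xm = x0.copy(), x0.copy()
                xp[i] += eps
                xm[i] -= eps
                with ad.no_grad():
                    sp = critic_score(disc(Tensor(xp[None]), training=False)).item()
                    sm = critic_score(disc(Tensor(xm[None]), training=False)).item()
                num[i] = (sp - sm) / (2 * eps)
            assert np.allclose(g.data.ravel(), num, atol=1e-4)


class TestTraining:
    def test_same_seed_identical_history(self, mixture_ds):
        from ehrgan.data import mask_labels

        ds = mask_labels(mixture_ds, 0.2, seed=1)
        cfg = GanConfig(z_dim=8, gen_layers=(16,), disc_layers=(16,), batch=64,
                        max_epochs=2, seed=7)
        h1 = train(ds.X, ds.y, ds.mask, cfg).history
        h2 = train(ds.X, ds.y, ds.mask, cfg).history
        assert [vars(a) for a in h1] == [vars(b) for b in h2]

    def test_supervised_loss_decreases(self, mixture_ds):
        from ehrgan.data import mask_labels

        ds = mask_labels(mixture_ds, 0.2, seed=2)
        cfg = GanConfig(z_dim=16, gen_layers=(32,), disc_layers=(32,), batch=64,
                        max_epochs=15, seed=3)
        model = train(ds.X, ds.y, ds.mask, cfg)
        assert model.history[-1].loss_sup < model.history[0].loss_sup

    def test_missing_labeled_class_rejected(self, mixture_ds):
        mask = mixture_ds.y == 0  # class 1 entirely unlabeled
        with pytest.raises(ValueError, match="class 1"):
            train(mixture_ds.X, mixture_ds.y, mask, GanConfig(max_epochs=1))


class TestInference:
    def test_predict_rows_sum_to_one(self, tiny_gan_model, mixture_ds):
        probs = predict_proba(tiny_gan_model, mixture_ds.X[:20])
        assert probs.shape == (20, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_symmetric_logits_give_half(self):
        # renormalized softmax over 2 equal real logits is (0.5, 0.5)
        logits = Tensor(np.array([[3.0, 3.0, -1.0]]))
        probs = ad.softmax(logits[:, :2], axis=1).data
        assert np.allclose(probs, 0.5)

    def test_width_mismatch_names_expected(self, tiny_gan_model):
        with pytest.raises(ValueError, match=str(tiny_gan_model.input_width)):
            predict_proba(tiny_gan_model, np.zeros((2, tiny_gan_model.input_width + 1)))

    def test_argmax_matches_renormalized_softmax_oracle(self, tiny_gan_model, mixture_ds):
        probs = predict_proba(tiny_gan_model, mixture_ds.X[:30])
        with ad.no_grad():
            logits = tiny_gan_model.discriminator(Tensor(mixture_ds.X[:30]), training=False).data
        brute = np.exp(logits[:, :2])
        brute /= brute.sum(axis=1, keepdims=True)
        assert np.array_equal(probs.argmax(axis=1), brute.argmax(axis=1))

    def test_generate_shapes_and_determinism(self, tiny_gan_model):
        assert generate_samples(tiny_gan_model, 0).shape == (0, tiny_gan_model.input_width)
        a = generate_samples(tiny_gan_model, 5, seed=4)
        b = generate_samples(tiny_gan_model, 5, seed=4)
        assert a.shape == (5, tiny_gan_model.input_width)
        assert np.array_equal(a, b)

    def test_export_last_layer_shape(self, tiny_gan_model, mixture_ds):
        h = export_last_layer(tiny_gan_model, mixture_ds.X[:9])
        assert h.shape == (9, tiny_gan_model.config.disc_layers[-1])
        assert np.allclose(h[0], export_last_layer(tiny_gan_model, mixture_ds.X[:1])[0],
                           atol=1e-12)


def test_checkpoint_roundtrip_bit_identical(tmp_path, tiny_gan_model, mixture_ds):
    path = tmp_path / "model.npz"
    save_model(tiny_gan_model, path)
    back = load_model(path)
    p1 = predict_proba(tiny_gan_model, mixture_ds.X[:25])
    p2 = predict_proba(back, mixture_ds.X[:25])
    assert np.array_equal(p1, p2)
    g1 = generate_samples(tiny_gan_model, 7, seed=1)
    g2 = generate_samples(back, 7, seed=1)
    assert np.array_equal(g1, g2)
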