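"""Generator/discriminator architecture contracts."""

import numpy as np
import pytest

from sketchct._nn import Tensor, conv2d, leaky_relu, modulated_conv2d
from sketchct.networks import (GeneratorConfig, build_discriminator,
                               build_generator, build_model_bundle,
                               build_style_generator, draw_style_latents,
                               generate, load_bundle, map_latent,
                               save_bundle, summary)

CFG128 = GeneratorConfig(depth=7, base_channels=2, image_size=128,
                         latent_dim=16)
SCFG128 = GeneratorConfig(depth=7, base_channels=2, image_size=128,
                          use_style=True, latent_dim=16)
CFG32 = GeneratorConfig(depth=5, base_channels=4, image_size=32,
                        latent_dim=16)
SCFG32 = GeneratorConfig(depth=5, base_channels=4, image_size=32,
                         use_style=True, latent_dim=16)


def sketches(n, size, seed=0):
    return (np.random.default_rng(seed)
            .random((n, 1, size, size)).astype(np.float32))


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(depth=7, image_size=100)
    with pytest.raises(ValueError):
        GeneratorConfig(latent_dim=0)


class TestBaselineGenerator:
    def test_output_shape_matches_input(self):
        gen = build_generator(CFG128, seed=0)
        out = gen(Tensor(sketches(1, 128)))
        assert out.shape == (1, 1, 128, 128)
        assert np.abs(out.data).max() <= 1.0

    def test_depth7_bottleneck_is_one_by_one(self):
        gen = build_generator(CFG128, seed=0)
        h = Tensor(sketches(1, 128))
        for conv, norm in zip(gen.enc_convs, gen.enc_norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = leaky_relu(h, 0.2)
        assert h.shape[2:] == (1, 1)

    def test_no_cross_batch_leakage(self):
        gen = build_generator(CFG32, seed=0)
        batch = sketches(2, 32)
        out_a = gen(Tensor(batch)).data
        batch2 = batch.copy()
        batch2[1] = 0.0                      # perturb only sample 1
        out_b = gen(Tensor(batch2)).data
        assert np.array_equal(out_a[0], out_b[0])
        assert not np.array_equal(out_a[1], out_b[1])


class TestStyleGenerator:
    def test_distinct_latents_give_distinct_images(self):
        gen, mapping = build_style_generator(SCFG32, seed=0)
        sketch = sketches(1, 32)
        rng = np.random.default_rng(1)
        z = draw_style_latents(2, 16, rng)
        w = map_latent(z, mapping)
        img0 = gen(Tensor(sketch), Tensor(w[:1])).data
        img1 = gen(Tensor(sketch), Tensor(w[1:])).data
        assert np.abs(img0 - img1).max() > 0

    def test_same_latent_is_deterministic(self):
        gen, mapping = build_style_generator(SCFG32, seed=0)
        sketch = sketches(1, 32)
        w = map_latent(draw_style_latents(1, 16, np.random.default_rng(2)),
                       mapping)
        a = gen(Tensor(sketch), Tensor(w)).data
        b = gen(Tensor(sketch), Tensor(w)).data
        assert np.array_equal(a, b)

    def test_output_shape_equals_baseline(self):
        gen, mapping = build_style_generator(SCFG128, seed=0)
        base = build_generator(CFG128, seed=0)
        sketch = sketches(1, 128)
        w = map_latent(draw_style_latents(1, 16, np.random.default_rng(0)),
                       mapping)
        assert gen(Tensor(sketch), Tensor(w)).shape \
            == base(Tensor(sketch)).shape

    def test_style_has_more_parameters_than_baseline(self):
        style = build_model_bundle(SCFG128, seed=0)
        base = build_model_bundle(CFG128, seed=0)
        n_style = style.generator.n_parameters() \
            + style.mapping.n_parameters()
        assert n_style > base.generator.n_parameters()

    def test_requires_use_style_flag(self):
        with pytest.raises(ValueError):
            build_style_generator(CFG128)

    def test_latent_length_mismatch_rejected(self):
        gen, _ = build_style_generator(SCFG32, seed=0)
        with pytest.raises(ValueError):
            gen(Tensor(sketches(1, 32)), Tensor(np.zeros((1, 7))))


class TestMapLatent:
    def test_deterministic_and_finite(self):
        _, mapping = build_style_generator(SCFG32, seed=0)
        z = np.zeros(16)
        w1, w2 = map_latent(z, mapping), map_latent(z, mapping)
        assert np.array_equal(w1, w2)
        assert np.all(np.isfinite(w1))
        assert w1.shape == (16,)

    def test_orthogonal_latents_map_to_distinct_styles(self):
        _, mapping = build_style_generator(SCFG32, seed=0)
        z = np.eye(16)[:2]
        w = map_latent(z, mapping)
        assert not np.allclose(w[0], w[1])

    def test_wrong_length_rejected(self):
        _, mapping = build_style_generator(SCFG32, seed=0)
        with pytest.raises(ValueError):
            map_latent(np.zeros(9), mapping)

    def test_non_finite_rejected(self):
        _, mapping = build_style_generator(SCFG32, seed=0)
        with pytest.raises(ValueError):
            map_latent(np.full(16, np.nan), mapping)


class TestModulatedConv:
    def test_identity_style_no_demod_equals_plain_conv(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 5, 5)))
        w = Tensor(rng.normal(size=(4, 3, 3, 3)))
        ones = Tensor(np.ones((2, 3)))
        plain = conv2d(x, w, None, 1, 1).data
        mod = modulated_conv2d(x, w, ones, demodulate=False).data
        assert np.allclose(plain, mod, atol=1e-12)

    def test_scalar_style_scales_output_linearly(self, rng):
        x = Tensor(rng.normal(size=(1, 3, 5, 5)))
        w = Tensor(rng.normal(size=(4, 3, 3, 3)))
        base = modulated_conv2d(x, w, Tensor(np.ones((1, 3))),
                                demodulate=False).data
        scaled = modulated_conv2d(x, w, Tensor(np.full((1, 3), 2.5)),
                                  demodulate=False).data
        assert np.allclose(scaled, 2.5 * base, atol=1e-10)

    def test_scale_length_mismatch_rejected(self, rng):
        x = Tensor(rng.normal(size=(1, 3, 5, 5)))
        w = Tensor(rng.normal(size=(4, 3, 3, 3)))
        with pytest.raises(ValueError):
            modulated_conv2d(x, w, Tensor(np.ones((1, 2))))


class TestDiscriminator:
    def test_patch_scores_are_probabilities(self):
        disc = build_discriminator(CFG32, seed=0)
        s, img = sketches(2, 32, 0), sketches(2, 32, 1) * 2 - 1
        out = disc(Tensor(s), Tensor(img)).data
        assert out.shape[0] == 2 and out.shape[1] == 1
        assert np.all((out > 0) & (out < 1))

    def test_batch_order_permutes_outputs(self):
        disc = build_discriminator(CFG32, seed=0)
        s, img = sketches(2, 32, 0), sketches(2, 32, 1)
        fwd = disc(Tensor(s), Tensor(img)).data
        rev = disc(Tensor(s[::-1].copy()), Tensor(img[::-1].copy())).data
        assert np.allclose(fwd, rev[::-1], atol=1e-6)

    def test_conditioning_is_live(self):
        disc = build_discriminator(CFG32, seed=0)
        s, img = sketches(1, 32, 0), sketches(1, 32, 1)
        a = disc(Tensor(s), Tensor(img)).data
        b = disc(Tensor(np.zeros_like(s)), Tensor(img)).data
        assert not np.allclose(a, b)

    def test_shape_mismatch_rejected(self):
        disc = build_discriminator(CFG32, seed=0)
        with pytest.raises(ValueError):
            disc(Tensor(sketches(1, 32)), Tensor(sketches(1, 16)))


class TestGenerate:
    def test_baseline_one_to_one(self):
        bundle = build_model_bundle(CFG32, seed=0)
        imgs = generate(bundle, sketches(1, 32)[0, 0], n=5)
        assert len(imgs) == 5
        assert all(np.array_equal(imgs[0], im) for im in imgs[1:])

    def test_style_one_to_many_and_seeded(self):
        bundle = build_model_bundle(SCFG32, seed=0)
        sketch = sketches(1, 32)[0, 0]
        imgs = generate(bundle, sketch, n=5, seed=3)
        again = generate(bundle, sketch, n=5, seed=3)
        for i in range(5):
            assert np.array_equal(imgs[i], again[i])
            for j in range(i + 1, 5):
                assert not np.array_equal(imgs[i], imgs[j])

    def test_interlatent_pixel_variance_positive_iff_style(self):
        sketch = sketches(1, 32)[0, 0]
        style = build_model_bundle(SCFG32, seed=0)
        base = build_model_bundle(CFG32, seed=0)
        sd_style = np.stack(generate(style, sketch, n=10, seed=0)) \
            .astype(np.float64).std(axis=0)
        base_imgs = np.stack(generate(base, sketch, n=10))
        assert sd_style.mean() > 0
        # baseline outputs are bit-identical, so their variance is exactly 0
        assert np.all(base_imgs == base_imgs[0])

    def test_invalid_n_rejected(self):
        bundle = build_model_bundle(CFG32, seed=0)
        with pytest.raises(ValueError):
            generate(bundle, sketches(1, 32)[0, 0], n=0)


def test_bundle_save_load_round_trip(tmp_path):
    bundle = build_model_bundle(SCFG32, seed=0)
    sketch = sketches(1, 32)[0, 0]
    before = generate(bundle, sketch, n=2, seed=9)
    path = tmp_path / "bundle.zip"
    save_bundle(bundle, path)
    reloaded = load_bundle(path)
    after = generate(reloaded, sketch, n=2, seed=9)
    assert reloaded.config == bundle.config
    for a, b in zip(before, after):
        assert np.array_equal(a, b)


def test_summary_lists_parameter_counts():
    text = summary(SCFG32)
    assert "generator" in text and "mapping" in text
    assert "discriminator" in text
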