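"""Generator/discriminator architecture, losses, normalisation, training."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import synthdetect as sd
from synthdetect.dcgan import (BatchNorm, Conv2D, Conv2DTranspose, Dense,
                               Generator, UnsupportedConfigurationError)

GENERATOR_ROWS = [
    ("Dense", (12544,), 1_266_944),
    ("BatchNormalization", (12544,), 50_176),
    ("ReLU", (12544,), 0),
    ("Reshape", (7, 7, 256), 0),
    ("Conv2DTranspose", (14, 14, 128), 819_328),
    ("BatchNormalization", (14, 14, 128), 512),
    ("ReLU", (14, 14, 128), 0),
    ("Conv2DTranspose", (28, 28, 64), 204_864),
    ("BatchNormalization", (28, 28, 64), 256),
    ("ReLU", (28, 28, 64), 0),
    ("Conv2D", (28, 28, 1), 1601),
]

DISCRIMINATOR_ROWS = [
    ("Conv2D", (14, 14, 64), 1664),
    ("BatchNormalization", (14, 14, 64), 256),
    ("LeakyReLU", (14, 14, 64), 0),
    ("Conv2D", (7, 7, 128), 204_928),
    ("BatchNormalization", (7, 7, 128), 512),
    ("LeakyReLU", (7, 7, 128), 0),
    ("Flatten", (6272,), 0),
    ("Dropout", (6272,), 0),
    ("Dense", (1,), 6273),
]


class TestArchitecture:
    def test_generator_layer_rows(self):
        spec = sd.build_generator()
        rows = [(l.label, l.out_shape, l.n_params) for l in spec.layers]
        assert rows == GENERATOR_ROWS
        assert spec.total_params == 2_343_681
        assert spec.trainable_params == 2_318_209
        assert spec.non_trainable_params == 25_472

    def test_discriminator_layer_rows(self):
        spec = sd.build_discriminator()
        rows = [(l.label, l.out_shape, l.n_params) for l in spec.layers]
        assert rows == DISCRIMINATOR_ROWS
        assert spec.total_params == 213_633
        assert spec.trainable_params == 213_249
        assert spec.non_trainable_params == 384

    @pytest.mark.parametrize("spec_fn", [sd.build_generator,
                                         sd.build_discriminator])
    def test_totals_are_layer_sums(self, spec_fn):
        spec = spec_fn()
        assert spec.total_params == sum(l.n_params for l in spec.layers)
        bn_params = sum(l.n_params for l in spec.layers
                        if l.kind == "batch-normalization")
        assert spec.non_trainable_params == bn_params // 2

    def test_batchnorm_parameter_accounting(self):
        bn = BatchNorm(64, conv=True)
        assert bn.n_trainable + bn.n_non_trainable == 256
        assert bn.n_trainable == 128

    def test_nonstandard_latent_dimension_rejected(self):
        with pytest.raises(UnsupportedConfigurationError):
            Generator(sd.GanConfig(latent_dim=64))

    def test_discriminator_rejects_wrong_image_shape(self):
        disc = sd.Discriminator(sd.GanConfig(seed=0))
        with pytest.raises(ValueError, match="28x28"):
            disc.forward(np.zeros((2, 1, 14, 14), dtype=np.float32),
                         training=False)


class TestNormalization:
    def test_bounds_and_derived_value(self):
        batch = sd.ImageBatch(np.array([[[0, 255], [51, 128]]],
                                       dtype=np.uint8).repeat(14, 1).repeat(14, 2),
                              "raw")
        out = sd.normalize_images(batch)
        assert out.domain == "normalized"
        px = out.pixels[0]
        assert px[0, 0] == -1.0
        assert px[0, 14] == 1.0
        assert np.isclose(px[14, 0], -0.6)

    def test_bijection_over_all_byte_values(self):
        values = np.arange(256, dtype=np.uint8).reshape(1, 16, 16)
        normed = sd.normalize_images(sd.ImageBatch(values, "raw"))
        pts = np.sort(np.unique(normed.pixels))
        assert pts.size == 256
        spacing = np.diff(pts.astype(np.float64))
        assert np.allclose(spacing, 2.0 / 255.0, atol=1e-6)
        back = sd.denormalize_images(normed)
        assert np.array_equal(back.pixels, values)

    def test_double_normalization_guard(self):
        batch = sd.normalize_images(
            sd.ImageBatch(np.zeros((1, 28, 28), dtype=np.uint8), "raw"))
        with pytest.raises(ValueError, match="already normalized"):
            sd.normalize_images(batch)


class TestLosses:
    @pytest.mark.parametrize("d_real, d_fake, expected", [
        ([1.0], [0.0], 0.0),
        ([0.5], [0.5], 2 * math.log(2)),
        ([0.9, 0.8], [0.1, 0.2], 0.328504),
    ])
    def test_discriminator_loss_closed_forms(self, d_real, d_fake, expected):
        assert sd.discriminator_loss(d_real, d_fake) == pytest.approx(
            expected, abs=1e-6)

    @pytest.mark.parametrize("d_fake, expected", [
        ([1.0], 0.0),
        ([0.5], math.log(2)),
        ([0.25], math.log(4)),
    ])
    def test_generator_loss_closed_forms(self, d_fake, expected):
        assert sd.generator_loss(d_fake) == pytest.approx(expected, abs=1e-6)

    def test_empty_batches_rejected(self):
        with pytest.raises(ValueError):
            sd.discriminator_loss([], [0.5])
        with pytest.raises(ValueError):
            sd.generator_loss([])

    @given(st.floats(0.01, 0.99))
    def test_symmetric_scalar_identity(self, p):
        # D([p], [1-p]) = -ln p - ln(1-(1-p)) = 2 * (-ln p)
        assert sd.discriminator_loss([p], [1 - p]) == pytest.approx(
            2 * -math.log(p), rel=1e-9)

    @given(st.lists(st.floats(0.02, 0.97), min_size=1, max_size=6),
           st.data())
    def test_generator_loss_strictly_decreasing_in_each_score(self, probs, data):
        i = data.draw(st.integers(0, len(probs) - 1))
        bumped = list(probs)
        bumped[i] += 0.01
        assert sd.generator_loss(bumped) < sd.generator_loss(probs)


class TestLayerGradients:
    """Backpropagation vs central finite differences on tiny float64 layers."""

    @staticmethod
    def _numeric(f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = x[i]
            x[i] = old + eps
            fp = f()
            x[i] = old - eps
            fm = f()
            x[i] = old
            g[i] = (fp - fm) / (2 * eps)
        return g

    @pytest.mark.parametrize("make_layer, in_shape", [
        (lambda rng: Dense(5, 4, rng, dtype=np.float64), (3, 5)),
        (lambda rng: Dense(5, 1, rng, activation="sigmoid",
                           dtype=np.float64), (3, 5)),
        (lambda rng: Conv2D(3, 4, k=5, stride=2, in_size=6, rng=rng,
                            dtype=np.float64), (2, 3, 6, 6)),
        (lambda rng: Conv2D(3, 2, k=5, stride=1, in_size=6, rng=rng,
                            activation="tanh", dtype=np.float64), (2, 3, 6, 6)),
        (lambda rng: Conv2DTranspose(3, 2, k=5, stride=2, in_size=4, rng=rng,
                                     dtype=np.float64), (2, 3, 4, 4)),
        (lambda rng: BatchNorm(3, conv=True, dtype=np.float64), (4, 3, 5, 5)),
        (lambda rng: BatchNorm(4, conv=False, dtype=np.float64), (6, 4)),
    ], ids=["dense", "dense-sigmoid", "conv-s2", "conv-s1-tanh",
            "transposed-conv", "batchnorm-conv", "batchnorm-dense"])
    def test_backward_matches_finite_differences(self, make_layer, in_shape):
        rng = np.random.default_rng(0)
        layer = make_layer(rng)
        x = rng.standard_normal(in_shape)
        weight = rng.standard_normal(layer.forward(x, True).shape)

        def loss():
            return float((layer.forward(x, True) * weight).sum())

        layer.forward(x, True)
        for g in layer.grads:
            g.fill(0)
        dx = layer.backward(weight)
        assert np.abs(self._numeric(loss, x) - dx).max() < 1e-7
        for p, g in zip(layer.params, layer.grads):
            assert np.abs(self._numeric(loss, p) - g).max() < 1e-7

    def test_transposed_conv_is_conv_adjoint(self):
        rng = np.random.default_rng(1)
        conv = Conv2D(3, 2, k=5, stride=2, in_size=8, rng=rng, dtype=np.float64)
        tconv = Conv2DTranspose(2, 3, k=5, stride=2, in_size=4, rng=rng,
                                dtype=np.float64)
        tconv.W[...] = conv.W
        conv.b.fill(0)
        tconv.b.fill(0)
        x = rng.standard_normal((2, 3, 8, 8))
        y = rng.standard_normal((2, 2, 4, 4))
        lhs = float((conv.forward(x, True) * y).sum())
        rhs = float((x * tconv.forward(y, True)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestSampling:
    def test_shape_range_and_determinism(self):
        gen = Generator(sd.GanConfig(seed=3))
        imgs = sd.sample(gen, 3, seed=0)
        assert imgs.pixels.shape == (3, 28, 28)
        assert imgs.pixels.min() >= -1.0 and imgs.pixels.max() <= 1.0
        again = sd.sample(gen, 3, seed=0)
        assert np.array_equal(imgs.pixels, again.pixels)
        other = sd.sample(gen, 3, seed=1)
        assert not np.array_equal(imgs.pixels, other.pixels)

    def test_nonpositive_count_rejected(self):
        gen = Generator(sd.GanConfig(seed=3))
        with pytest.raises(ValueError):
            sd.sample(gen, 0, seed=0)


class TestTraining:
    def test_snapshot_contract_at_toy_scale(self, tiny_training_run):
        result = tiny_training_run
        assert len(result.snapshots) == 1
        snap = result.snapshots[0]
        assert snap.epoch == 0
        assert len(snap.images) == 10
        assert snap.images.pixels.min() >= -1.0
        assert snap.images.pixels.max() <= 1.0
        assert all(np.isfinite(result.d_losses))
        assert all(np.isfinite(result.g_losses))

    def test_bitwise_reproducibility(self):
        reals = sd.make_fixture_dataset(
            sd.FixtureSpec(kind="rings", n=16, seed=2))
        config = sd.GanConfig(epochs=1, snapshot_size=5, batch_size=16, seed=9)
        batch = sd.normalize_images(sd.ImageBatch(reals, "raw"))
        a = sd.train(batch, config)
        b = sd.train(batch, config)
        assert np.array_equal(a.snapshots[0].images.pixels,
                              b.snapshots[0].images.pixels)
        assert a.d_losses == b.d_losses

    def test_unnormalized_input_rejected(self, blob_images):
        with pytest.raises(ValueError, match="normalized"):
            sd.train(sd.ImageBatch(blob_images, "raw"), sd.GanConfig(epochs=1))
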