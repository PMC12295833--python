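"""Deep convolutional GAN for 28x28 single-channel bioimages.

The generator maps a 100-dimensional standard-normal latent vector to a
28x28x1 image in [-1, 1]; the discriminator maps an image to a single
probability of being real.  Both networks follow the classic DCGAN recipe
(strided transposed convolutions for upsampling, batch normalisation,
ReLU / LeakyReLU activations, tanh output, sigmoid critic) with 5x5
kernels, stride 2 and "same" padding throughout, and are trained with the
modified (non-saturating) minimax objective:

    L_D = BCE(D(x_real), 1) + BCE(D(G(z)), 0)
    L_G = BCE(D(G(z)), 1)

optimised by Adam (lr = 2e-4, beta1 = 0.5).

Everything here — layers, backpropagation, Adam — is implemented directly
on NumPy arrays.  All randomness (weight init, batching, dropout, latent
draws) flows from the single seed in :class:`GanConfig`, so training runs
are bitwise reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("synthdetect")

LATENT_DIM = 100
IMAGE_SIDE = 28
IMAGE_SHAPE = (28, 28, 1)
#: probabilities are clipped to [BCE_EPS, 1 - BCE_EPS] inside the losses
BCE_EPS = 1e-7


class UnsupportedConfigurationError(ValueError):
    """Raised for configurations the fixed architecture cannot honour."""


# ---------------------------------------------------------------------------
# configuration and image containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GanConfig:
    """Training configuration; defaults are the study conditions.

    epochs / snapshot_size: 50 epochs, 1000 generated images per epoch.
    learning_rate / beta1: Adam settings 0.0002 and 0.5.
    Remaining knobs (batch size 256, LeakyReLU slope 0.2, dropout 0.3)
    follow DCGAN convention and are configurable.
    """

    epochs: int = 50
    snapshot_size: int = 1000
    batch_size: int = 256
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    latent_dim: int = LATENT_DIM
    leaky_slope: float = 0.2
    dropout_rate: float = 0.3
    bn_momentum: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.snapshot_size < 1:
            raise ValueError("snapshot_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class ImageBatch:
    """A batch of 2-D grayscale images with an explicit intensity domain.

    ``raw`` images are uint8 grids in [0, 255]; ``normalized`` images are
    floats in [-1, 1] (the generator/discriminator domain).
    """

    pixels: np.ndarray  # (n, H, W)
    domain: str  # "raw" | "normalized"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim == 4 and self.pixels.shape[-1] == 1:
            self.pixels = self.pixels[..., 0]
        if self.pixels.ndim != 3:
            raise ValueError(f"expected (n, H, W) images, got {self.pixels.shape}")
        if self.domain == "raw":
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("raw images must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        elif self.domain == "normalized":
            self.pixels = self.pixels.astype(np.float32)
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < -1.0 - 1e-5 or hi > 1.0 + 1e-5:
                raise ValueError("normalized images must lie in [-1, 1]")
        else:
            raise ValueError(f"unknown domain {self.domain!r}")

    def __len__(self) -> int:
        return self.pixels.shape[0]


def normalize_images(batch: ImageBatch) -> ImageBatch:
    """Map raw uint8 intensities to the generator domain: v -> v/127.5 - 1.

    This is a bijection between {0..255} and 256 evenly spaced points of
    [-1, 1].  Raises if the batch is already normalized (double-normalisation
    guard).
    """
    if batch.domain != "raw":
        raise ValueError("images are already normalized")
    values = batch.pixels.astype(np.float32) / np.float32(127.5) - np.float32(1.0)
    return ImageBatch(values, "normalized")


def denormalize_images(batch: ImageBatch) -> ImageBatch:
    """Inverse of :func:`normalize_images` up to rounding."""
    if batch.domain != "normalized":
        raise ValueError("images are not in the normalized domain")
    values = (batch.pixels.astype(np.float64) + 1.0) * 127.5
    values = np.clip(np.rint(values), 0, 255).astype(np.uint8)
    return ImageBatch(values, "raw")


# ---------------------------------------------------------------------------
# architecture description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # dense | transposed-convolution | convolution | batch-normalization
    #        | activation | reshape | flatten | dropout
    label: str
    out_shape: tuple  # HWC convention, batch axis omitted
    n_trainable: int
    n_non_trainable: int

    @property
    def n_params(self) -> int:
        return self.n_trainable + self.n_non_trainable


@dataclass(frozen=True)
class NetworkSpec:
    role: str  # "generator" | "discriminator"
    layers: tuple

    @property
    def total_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    @property
    def trainable_params(self) -> int:
        return sum(l.n_trainable for l in self.layers)

    @property
    def non_trainable_params(self) -> int:
        return sum(l.n_non_trainable for l in self.layers)


# ---------------------------------------------------------------------------
# layers (NCHW internally)
# ---------------------------------------------------------------------------


def _same_pads(size: int, k: int, s: int) -> tuple[int, int, int]:
    """TensorFlow-style SAME padding: (pad_before, pad_after, out_size)."""
    out = -(-size // s)
    pad_total = max((out - 1) * s + k - size, 0)
    before = pad_total // 2
    return before, pad_total - before, out


def _im2col(x: np.ndarray, k: int, s: int, pads: tuple[int, int]):
    """(B,C,H,W) -> columns (C*k*k, B*Ho*Wo) for a k x k / stride-s window."""
    pb, pa = pads
    xp = np.pad(x, ((0, 0), (0, 0), (pb, pa), (pb, pa)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s]  # (B, C, Ho, Wo, k, k)
    B, C, Ho, Wo = win.shape[:4]
    cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(C * k * k, B * Ho * Wo)
    return np.ascontiguousarray(cols), (B, Ho, Wo)


def _col2im(cols: np.ndarray, B: int, C: int, k: int, s: int,
            Ho: int, Wo: int, Hp: int, Wp: int, dtype) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add columns back onto the padded grid."""
    cols = cols.reshape(C, k, k, B, Ho, Wo).transpose(3, 0, 1, 2, 4, 5)
    out = np.zeros((B, C, Hp, Wp), dtype=dtype)
    for u in range(k):
        for v in range(k):
            out[:, :, u:u + s * Ho:s, v:v + s * Wo:s] += cols[:, :, u, v]
    return out


class _Layer:
    kind = "activation"
    label = ""
    params: list = []
    grads: list = []
    n_trainable = 0
    n_non_trainable = 0
    out_shape: tuple = ()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def spec(self) -> LayerSpec:
        return LayerSpec(self.kind, self.label, self.out_shape,
                         self.n_trainable, self.n_non_trainable)


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense(_Layer):
    kind = "dense"

    def __init__(self, fan_in, units, rng, activation=None, dtype=np.float32):
        self.label = "Dense"
        self.activation = activation
        self.W = _glorot(rng, (fan_in, units), fan_in, units, dtype)
        self.b = np.zeros(units, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.n_trainable = fan_in * units + units
        self.out_shape = (units,)

    def forward(self, x, training):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "sigmoid":
            z = 1.0 / (1.0 + np.exp(-z))
        elif self.activation == "tanh":
            z = np.tanh(z)
        self._y = z if self.activation else None
        return z

    def backward(self, dy):
        if self.activation == "sigmoid":
            dy = dy * self._y * (1.0 - self._y)
        elif self.activation == "tanh":
            dy = dy * (1.0 - self._y ** 2)
        self.grads[0] += self._x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.W.T


class BatchNorm(_Layer):
    """Batch normalisation; 4 parameters per channel, exactly half trainable
    (gamma/beta) and half moving statistics (mean/var)."""

    kind = "batch-normalization"

    def __init__(self, channels, conv, momentum=0.99, eps=1e-3, dtype=np.float32):
        self.label = "BatchNormalization"
        self.conv = conv  # True: (B,C,H,W) over axes (0,2,3); False: (B,F) over 0
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.moving_mean = np.zeros(channels, dtype=dtype)
        self.moving_var = np.ones(channels, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.n_trainable = 2 * channels
        self.n_non_trainable = 2 * channels

    def _shape(self, v):
        return v.reshape(1, -1, 1, 1) if self.conv else v.reshape(1, -1)

    def forward(self, x, training):
        axes = (0, 2, 3) if self.conv else (0,)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean *= m
            self.moving_mean += (1 - m) * mean
            self.moving_var *= m
            self.moving_var += (1 - m) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mean)) * self._shape(ivar)
        if training:
            self._xhat, self._ivar, self._axes = xhat, ivar, axes
        return self._shape(self.gamma) * xhat + self._shape(self.beta)

    def backward(self, dy):
        axes = self._axes
        m = float(np.prod([dy.shape[a] for a in axes]))
        xhat, ivar = self._xhat, self._ivar
        self.grads[0] += (dy * xhat).sum(axis=axes)
        self.grads[1] += dy.sum(axis=axes)
        dxhat = dy * self._shape(self.gamma)
        term = dxhat - dxhat.mean(axis=axes, keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m
        return term * self._shape(ivar)


class ReLU(_Layer):
    label = "ReLU"

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(_Layer):
    label = "LeakyReLU"

    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Reshape(_Layer):
    kind = "reshape"
    label = "Reshape"

    def __init__(self, target_chw):
        self.target = target_chw  # (C, H, W)
        c, h, w = target_chw
        self.out_shape = (h, w, c)

    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Flatten(_Layer):
    kind = "flatten"
    label = "Flatten"

    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dropout(_Layer):
    kind = "dropout"
    label = "Dropout"

    def __init__(self, rate):
        self.rate = rate
        self.rng: np.random.Generator | None = None  # set by the training loop

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without an RNG")
        keep = (self.rng.random(x.shape) >= self.rate).astype(x.dtype)
        self._mask = keep / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Conv2D(_Layer):
    """Cross-correlation with SAME padding; weights (Cout, Cin*k*k)."""

    kind = "convolution"

    def __init__(self, cin, cout, k, stride, in_size, rng,
                 activation=None, dtype=np.float32):
        self.label = "Conv2D"
        self.cin, self.cout, self.k, self.s = cin, cout, k, stride
        self.activation = activation
        pb, pa, out = _same_pads(in_size, k, stride)
        self.pads = (pb, pa)
        self.out_size = out
        fan_in, fan_out = cin * k * k, cout * k * k
        self.W = _glorot(rng, (cout, cin * k * k), fan_in, fan_out, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.n_trainable = cout * cin * k * k + cout
        self.out_shape = (out, out, cout)

    def forward(self, x, training):
        cols, (B, Ho, Wo) = _im2col(x, self.k, self.s, self.pads)
        self._cols, self._dims = cols, (B, Ho, Wo, x.shape[2])
        y = (self.W @ cols + self.b[:, None]).reshape(self.cout, B, Ho, Wo)
        y = y.transpose(1, 0, 2, 3)
        if self.activation == "tanh":
            y = np.tanh(y)
            self._y = y
        return y

    def backward(self, dy):
        if self.activation == "tanh":
            dy = dy * (1.0 - self._y ** 2)
        B, Ho, Wo, Hin = self._dims
        dy_flat = dy.transpose(1, 0, 2, 3).reshape(self.cout, -1)
        self.grads[0] += dy_flat @ self._cols.T
        self.grads[1] += dy_flat.sum(axis=1)
        dcols = self.W.T @ dy_flat
        pb, pa = self.pads
        dxp = _col2im(dcols, B, self.cin, self.k, self.s, Ho, Wo,
                      Hin + pb + pa, Hin + pb + pa, dy.dtype)
        return dxp[:, :, pb:pb + Hin, pb:pb + Hin]


class Conv2DTranspose(_Layer):
    """Fractionally strided convolution (the adjoint of a SAME stride-s conv),
    doubling spatial size for stride 2; weights (Cin, Cout*k*k)."""

    kind = "transposed-convolution"

    def __init__(self, cin, cout, k, stride, in_size, rng, dtype=np.float32):
        self.label = "Conv2DTranspose"
        self.cin, self.cout, self.k, self.s = cin, cout, k, stride
        self.out_size = in_size * stride
        pb, pa, back = _same_pads(self.out_size, k, stride)
        assert back == in_size
        self.pads = (pb, pa)
        fan_in, fan_out = cin * k * k, cout * k * k
        self.W = _glorot(rng, (cin, cout * k * k), fan_in, fan_out, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.n_trainable = cin * cout * k * k + cout
        self.out_shape = (self.out_size, self.out_size, cout)

    def forward(self, x, training):
        B, _, Hi, Wi = x.shape
        x_flat = x.transpose(1, 0, 2, 3).reshape(self.cin, -1)
        self._x_flat, self._B = x_flat, B
        cols = self.W.T @ x_flat
        pb, pa = self.pads
        H = self.out_size
        ypad = _col2im(cols, B, self.cout, self.k, self.s, Hi, Wi,
                       H + pb + pa, H + pb + pa, x.dtype)
        return ypad[:, :, pb:pb + H, pb:pb + H] + self.b.reshape(1, -1, 1, 1)

    def backward(self, dy):
        cols_dy, (B, Hi, Wi) = _im2col(dy, self.k, self.s, self.pads)
        self.grads[0] += self._x_flat @ cols_dy.T
        self.grads[1] += dy.sum(axis=(0, 2, 3))
        dx = (self.W @ cols_dy).reshape(self.cin, B, Hi, Wi)
        return dx.transpose(1, 0, 2, 3)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class _Network:
    role = ""

    def __init__(self, layers: list[_Layer]):
        self.layers = layers
        self._adam_m = [np.zeros_like(p) for l in layers for p in l.params]
        self._adam_v = [np.zeros_like(p) for l in layers for p in l.params]
        self._adam_t = 0

    # -- description -------------------------------------------------------
    @property
    def spec(self) -> NetworkSpec:
        return NetworkSpec(self.role, tuple(l.spec() for l in self.layers))

    # -- computation -------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grads(self) -> None:
        for layer in self.layers:
            for g in layer.grads:
                g.fill(0)

    def adam_step(self, lr: float, b1: float, b2: float, eps: float = 1e-7) -> None:
        self._adam_t += 1
        t = self._adam_t
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                m, v = self._adam_m[i], self._adam_v[i]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1 ** t)
                vhat = v / (1 - b2 ** t)
                p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)
                i += 1

    # -- weight (de)serialisation -----------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
            if isinstance(layer, BatchNorm):
                out.extend([layer.moving_mean, layer.moving_var])
        return out

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for p in layer.params:
                p[...] = next(it)
            if isinstance(layer, BatchNorm):
                layer.moving_mean[...] = next(it)
                layer.moving_var[...] = next(it)


class Generator(_Network):
    """Latent (100,) -> image (28, 28, 1) in [-1, 1]; 2,343,681 parameters."""

    role = "generator"

    def __init__(self, config: GanConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        config = config or GanConfig()
        if config.latent_dim != LATENT_DIM:
            raise UnsupportedConfigurationError(
                f"the architecture is fixed to a {LATENT_DIM}-dimensional latent "
                f"vector; got {config.latent_dim}")
        rng = rng or np.random.default_rng(config.seed)
        m = config.bn_momentum
        dense = Dense(LATENT_DIM, 7 * 7 * 256, rng, dtype=dtype)
        layers = [
            dense,
            BatchNorm(7 * 7 * 256, conv=False, momentum=m, dtype=dtype),
            ReLU(),
            Reshape((256, 7, 7)),
            Conv2DTranspose(256, 128, k=5, stride=2, in_size=7, rng=rng, dtype=dtype),
            BatchNorm(128, conv=True, momentum=m, dtype=dtype),
            ReLU(),
            Conv2DTranspose(128, 64, k=5, stride=2, in_size=14, rng=rng, dtype=dtype),
            BatchNorm(64, conv=True, momentum=m, dtype=dtype),
            ReLU(),
            Conv2D(64, 1, k=5, stride=1, in_size=28, rng=rng,
                   activation="tanh", dtype=dtype),
        ]
        # activation/reshape output shapes mirror the preceding layer
        layers[1].out_shape = layers[2].out_shape = dense.out_shape
        layers[5].out_shape = layers[6].out_shape = layers[4].out_shape
        layers[8].out_shape = layers[9].out_shape = layers[7].out_shape
        super().__init__(layers)
        self.config = config


class Discriminator(_Network):
    """Image (28, 28, 1) -> probability of being real; 213,633 parameters."""

    role = "discriminator"

    def __init__(self, config: GanConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        config = config or GanConfig()
        rng = rng or np.random.default_rng(config.seed)
        m = config.bn_momentum
        layers = [
            Conv2D(1, 64, k=5, stride=2, in_size=28, rng=rng, dtype=dtype),
            BatchNorm(64, conv=True, momentum=m, dtype=dtype),
            LeakyReLU(config.leaky_slope),
            Conv2D(64, 128, k=5, stride=2, in_size=14, rng=rng, dtype=dtype),
            BatchNorm(128, conv=True, momentum=m, dtype=dtype),
            LeakyReLU(config.leaky_slope),
            Flatten(),
            Dropout(config.dropout_rate),
            Dense(7 * 7 * 128, 1, rng, activation="sigmoid", dtype=dtype),
        ]
        layers[1].out_shape = layers[2].out_shape = layers[0].out_shape
        layers[4].out_shape = layers[5].out_shape = layers[3].out_shape
        layers[6].out_shape = layers[7].out_shape = (7 * 7 * 128,)
        super().__init__(layers)
        self.config = config

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[1:] != (1, IMAGE_SIDE, IMAGE_SIDE):
            raise ValueError(
                f"discriminator input must be 28x28x1 images, got {x.shape[1:]}")
        return super().forward(x, training)


def build_generator(config: GanConfig | None = None) -> NetworkSpec:
    """Architecture description (layer sequence and parameter accounting)."""
    return Generator(config).spec


def build_discriminator(config: GanConfig | None = None) -> NetworkSpec:
    return Discriminator(config).spec


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _as_probs(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError(f"{name}: empty probability batch")
    if p.min() < 0 or p.max() > 1:
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    return np.clip(p, BCE_EPS, 1.0 - BCE_EPS)


def discriminator_loss(d_real, d_fake) -> float:
    """BCE(D(x_real), 1) + BCE(D(G(z)), 0), each term a batch mean."""
    pr = _as_probs(d_real, "d_real")
    pf = _as_probs(d_fake, "d_fake")
    return float(-np.mean(np.log(pr)) - np.mean(np.log1p(-pf)))


def generator_loss(d_fake) -> float:
    """Non-saturating objective BCE(D(G(z)), 1) = mean of -ln D(G(z))."""
    pf = _as_probs(d_fake, "d_fake")
    return float(-np.mean(np.log(pf)))


# ---------------------------------------------------------------------------
# sampling and training
# ---------------------------------------------------------------------------


@dataclass
class EpochSnapshot:
    """The images sampled from the generator after one training epoch."""

    epoch: int
    images: ImageBatch  # normalized domain
    seed: int


@dataclass
class GanTrainingResult:
    snapshots: list
    generator: Generator
    discriminator: Discriminator
    d_losses: list
    g_losses: list


def _derived_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2 ** 31))


def sample(generator: Generator, n: int, seed: int, chunk: int = 128) -> ImageBatch:
    """Draw n images from the generator (inference mode), seeded latents."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, LATENT_DIM)).astype(np.float32)
    out = np.empty((n, IMAGE_SIDE, IMAGE_SIDE), dtype=np.float32)
    for start in range(0, n, chunk):
        y = generator.forward(z[start:start + chunk], training=False)
        out[start:start + chunk] = y[:, 0]
    return ImageBatch(np.clip(out, -1.0, 1.0), "normalized")


def _bce_grad(p: np.ndarray, target: float) -> np.ndarray:
    """d/dp of mean BCE(p, target); p is the sigmoid output of the critic."""
    pc = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return ((pc - target) / (pc * (1.0 - pc))) / p.shape[0]


def train(real_images: ImageBatch, config: GanConfig | None = None) -> GanTrainingResult:
    """Adversarial training loop: one discriminator step then one generator
    step per minibatch, Adam for both networks, and a seeded snapshot of
    ``config.snapshot_size`` generated images after every epoch.
    """
    config = config or GanConfig()
    if real_images.domain != "normalized":
        raise ValueError("training images must be normalized to [-1, 1]")
    x_all = real_images.pixels.astype(np.float32)
    n = x_all.shape[0]
    if n < 1:
        raise ValueError("need at least one training image")
    if x_all.shape[1:] != (IMAGE_SIDE, IMAGE_SIDE):
        raise ValueError(f"training images must be 28x28, got {x_all.shape[1:]}")

    ss = np.random.SeedSequence(config.seed)
    rng_g, rng_d, rng_train = (np.random.default_rng(c) for c in ss.spawn(3))
    G = Generator(config, rng_g)
    D = Discriminator(config, rng_d)
    for layer in D.layers:
        if isinstance(layer, Dropout):
            layer.rng = rng_train

    lr, b1, b2 = config.learning_rate, config.beta1, config.beta2
    snapshots: list[EpochSnapshot] = []
    d_losses: list[float] = []
    g_losses: list[float] = []

    for epoch in range(config.epochs):
        perm = rng_train.permutation(n)
        for step, start in enumerate(range(0, n, config.batch_size)):
            xb = x_all[perm[start:start + config.batch_size]]
            B = xb.shape[0]

            # --- discriminator step (generator fixed) ---------------------
            D.zero_grads()
            p_real = D.forward(xb, training=True)
            D.backward(_bce_grad(p_real, 1.0).astype(np.float32))
            z = rng_train.standard_normal((B, LATENT_DIM)).astype(np.float32)
            x_fake = G.forward(z, training=True)
            p_fake = D.forward(x_fake[:, 0], training=True)
            D.backward(_bce_grad(p_fake, 0.0).astype(np.float32))
            d_loss = discriminator_loss(p_real, p_fake)
            if not math.isfinite(d_loss):
                raise RuntimeError(
                    f"non-finite discriminator loss at epoch {epoch}, step {step}")
            D.adam_step(lr, b1, b2)

            # --- generator step (discriminator fixed) ---------------------
            G.zero_grads()
            D.zero_grads()
            z = rng_train.standard_normal((B, LATENT_DIM)).astype(np.float32)
            x_fake = G.forward(z, training=True)
            p_fake = D.forward(x_fake[:, 0], training=True)
            g_loss = generator_loss(p_fake)
            if not math.isfinite(g_loss):
                raise RuntimeError(
                    f"non-finite generator loss at epoch {epoch}, step {step}")
            dx = D.backward(_bce_grad(p_fake, 1.0).astype(np.float32))
            G.backward(dx)
            G.adam_step(lr, b1, b2)

            d_losses.append(d_loss)
            g_losses.append(g_loss)

        snap_seed = _derived_seed(config.seed, 1_000_000 + epoch)
        snapshots.append(EpochSnapshot(
            epoch=epoch,
            images=sample(G, config.snapshot_size, snap_seed),
            seed=snap_seed,
        ))
        logger.debug("epoch %d: d_loss=%.4f g_loss=%.4f",
                     epoch, d_losses[-1], g_losses[-1])

    return GanTrainingResult(snapshots, G, D, d_losses, g_losses)
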