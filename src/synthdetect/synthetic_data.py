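"""Seeded synthetic 28x28 grayscale fixtures.

Six fixture families emulate the morphological variety of small biomedical
image collections — cell-like Gaussian blobs, annular rings, oriented
stripe textures, high-variance speckle fields, smooth organ-like lobed
gradients, and a mixed family — so that generation, feature extraction and
detection can all be exercised without downloading real data.  No claim of
statistical fidelity to any real dataset is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FIXTURE_KINDS = ("blobs", "rings", "stripes", "speckle", "gradient_organs",
                 "mixed")

_YY, _XX = np.mgrid[0:28, 0:28].astype(np.float64)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str = "blobs"
    n: int = 1000
    seed: int = 0
    noise_sigma: float = 8.0  # additive Gaussian noise, intensity units
    structure_scale: float = 4.0  # characteristic feature size, pixels

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {FIXTURE_KINDS}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _blobs(rng: np.random.Generator, scale: float) -> np.ndarray:
    img = np.full((28, 28), 30.0)
    for _ in range(rng.integers(2, 6)):
        cy, cx = rng.uniform(4, 24, size=2)
        sigma = rng.uniform(0.5, 1.0) * scale
        amp = rng.uniform(120, 220)
        img += amp * np.exp(-((_YY - cy) ** 2 + (_XX - cx) ** 2) / (2 * sigma ** 2))
    return img


def _rings(rng: np.random.Generator, scale: float) -> np.ndarray:
    img = np.full((28, 28), 40.0)
    cy, cx = rng.uniform(10, 18, size=2)
    radius = rng.uniform(1.2, 2.5) * scale
    thickness = rng.uniform(1.0, 2.5)
    r = np.sqrt((_YY - cy) ** 2 + (_XX - cx) ** 2)
    img += rng.uniform(140, 210) * np.exp(-((r - radius) ** 2) / (2 * thickness ** 2))
    return img


def _stripes(rng: np.random.Generator, scale: float) -> np.ndarray:
    theta = rng.uniform(0, np.pi)
    freq = 2 * np.pi / rng.uniform(0.8, 2.0) / scale
    phase = rng.uniform(0, 2 * np.pi)
    proj = _YY * np.sin(theta) + _XX * np.cos(theta)
    return 127.5 + rng.uniform(60, 110) * np.sin(freq * proj + phase)


def _speckle(rng: np.random.Generator, scale: float) -> np.ndarray:
    base = rng.uniform(60, 180)
    field = rng.normal(0.0, 90.0, size=(28, 28))
    # coarse speckle grains: average over scale-sized cells
    g = max(1, int(round(scale / 2)))
    coarse = field[: 28 - 28 % g or None, : 28 - 28 % g or None]
    if g > 1:
        h = coarse.shape[0] // g
        coarse = coarse[: h * g, : h * g].reshape(h, g, h, g).mean(axis=(1, 3))
        coarse = np.kron(coarse, np.ones((g, g)))
        field = np.pad(coarse, ((0, 28 - coarse.shape[0]),
                                (0, 28 - coarse.shape[1])), mode="edge")
    return base + field


def _gradient_organs(rng: np.random.Generator, scale: float) -> np.ndarray:
    gy, gx = rng.uniform(-3, 3, size=2)
    img = 90.0 + gy * (_YY - 14) + gx * (_XX - 14)
    for _ in range(rng.integers(1, 3)):
        cy, cx = rng.uniform(8, 20, size=2)
        ay = rng.uniform(1.0, 2.0) * scale
        ax = rng.uniform(1.0, 2.0) * scale
        lobes = 1 + 0.3 * np.sin(3 * np.arctan2(_YY - cy, _XX - cx))
        d = ((_YY - cy) / ay) ** 2 + ((_XX - cx) / ax) ** 2
        img += rng.uniform(80, 150) * (d < lobes).astype(float)
    return img


_GENERATORS = {"blobs": _blobs, "rings": _rings, "stripes": _stripes,
               "speckle": _speckle, "gradient_organs": _gradient_organs}


def make_fixture_dataset(spec: FixtureSpec) -> np.ndarray:
    """Generate ``spec.n`` uint8 28x28 images: structured signal plus
    additive Gaussian noise of standard deviation ``spec.noise_sigma``,
    clipped to [0, 255].  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    kinds = list(_GENERATORS) if spec.kind == "mixed" else [spec.kind]
    out = np.empty((spec.n, 28, 28), dtype=np.uint8)
    for i in range(spec.n):
        kind = kinds[rng.integers(len(kinds))] if len(kinds) > 1 else kinds[0]
        img = _GENERATORS[kind](rng, spec.structure_scale)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=(28, 28))
        out[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return out


def make_morphed_fakes(reals: np.ndarray, lam: float, seed: int = 0) -> np.ndarray:
    """Fakes of tunable realism: pixelwise lam*real + (1-lam)*noise.

    lam = 0 gives pure seeded uniform noise, lam = 1 reproduces the real
    images exactly.  Drives the detection-monotonicity property: detection
    accuracy should fall towards 0.5 as lam -> 1.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    reals = np.asarray(reals)
    noise = np.random.default_rng(seed).integers(
        0, 256, size=reals.shape).astype(np.float64)
    mixed = lam * reals.astype(np.float64) + (1.0 - lam) * noise
    return np.clip(np.rint(mixed), 0, 255).astype(np.uint8)
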