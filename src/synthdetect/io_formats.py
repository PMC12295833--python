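"""Reading and writing the pipeline's on-disk formats.

NPZ archives for image sets (MedMNIST-style split archives and the
package's own flat archives), NPZ checkpoints for trained network weights,
CSV for feature tables and results, and PNG grids for qualitative
inspection of generated images.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .dcgan import (Discriminator, GanConfig, Generator, ImageBatch,
                    denormalize_images)

logger = logging.getLogger("synthdetect")

#: ITU-R 601 luminance weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class DatasetArchive:
    name: str
    images: np.ndarray  # (n, 28, 28) uint8
    source: str  # "medmnist" | "fixture" | "generated"

    def __post_init__(self):
        self.images = np.asarray(self.images)
        if self.images.ndim != 3 or self.images.shape[1:] != (28, 28):
            raise ValueError(
                f"archive images must be (n, 28, 28), got {self.images.shape}")
        if self.images.dtype != np.uint8:
            raise ValueError("archive images must be uint8")

    def __len__(self) -> int:
        return len(self.images)


def _to_gray(images: np.ndarray) -> np.ndarray:
    """Collapse any trailing channel axis; RGB via ITU-R 601 luminance."""
    if images.ndim == 4 and images.shape[-1] == 3:
        gray = np.tensordot(images.astype(np.float64), _LUMA, axes=([-1], [0]))
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    if images.ndim == 4 and images.shape[-1] == 1:
        return images[..., 0].astype(np.uint8)
    if images.ndim == 3:
        return images.astype(np.uint8)
    raise ValueError(f"cannot interpret image array of shape {images.shape}")


def load_medmnist(path, n: int, seed: int = 0, name: str | None = None
                  ) -> DatasetArchive:
    """Load a MedMNIST-style NPZ archive and sample ``n`` images.

    All arrays whose key matches ``*_images`` (train/val/test splits across
    releases) are concatenated, RGB content is converted to grayscale by
    luminance, and ``n`` images are sampled without replacement under
    ``seed``.
    """
    path = Path(path)
    with np.load(path) as npz:
        keys = [k for k in npz.files if k.endswith("_images")]
        if not keys:
            raise ValueError(f"{path}: no '*_images' arrays found "
                             f"(keys: {npz.files})")
        logger.info("loading %s: using arrays %s", path, keys)
        images = np.concatenate([_to_gray(npz[k]) for k in sorted(keys)])
    if images.shape[1:] != (28, 28):
        raise ValueError(f"{path}: expected 28x28 images, got {images.shape[1:]}")
    if len(images) < n:
        raise ValueError(f"{path}: requested {n} images but archive has "
                         f"only {len(images)}")
    idx = np.random.default_rng(seed).choice(len(images), size=n, replace=False)
    return DatasetArchive(name or path.stem, images[idx], "medmnist")


def save_archive(images: np.ndarray, path, *, name: str = "archive",
                 source: str = "fixture") -> Path:
    """Write a flat uint8 image archive; round-trips bitwise with
    :func:`load_archive`."""
    images = np.asarray(images)
    if images.size == 0:
        raise ValueError("refusing to save an empty image archive")
    archive = DatasetArchive(name, images, source)  # validates
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, images=archive.images,
                        name=np.array(archive.name),
                        source=np.array(archive.source))
    return path


def load_archive(path) -> DatasetArchive:
    path = Path(path)
    try:
        with np.load(path) as npz:
            images = npz["images"]
            name = str(npz["name"]) if "name" in npz.files else path.stem
            source = str(npz["source"]) if "source" in npz.files else "fixture"
    except Exception as exc:
        raise ValueError(f"cannot read image archive {path}: {exc}") from exc
    return DatasetArchive(name, images, source)


# ---------------------------------------------------------------------------
# snapshot grids (qualitative inspection)
# ---------------------------------------------------------------------------


def export_snapshot_grid(sources, epochs=(0, 24, 49), path="grid.png",
                         tile: int = 28, margin: int = 2) -> Path:
    """PNG grid: one row per source, columns = original then the snapshots
    at the requested epochs.

    ``sources`` is a sequence of (original raw image, snapshots) pairs,
    where ``snapshots`` is the per-epoch snapshot list of one training run.
    """
    epochs = list(epochs)
    rows = []
    for original, snapshots in sources:
        by_epoch = {s.epoch: s for s in snapshots}
        missing = [e for e in epochs if e not in by_epoch]
        if missing:
            raise ValueError(f"missing snapshot for epoch(s) {missing}")
        tiles = [np.asarray(original, dtype=np.uint8)]
        for e in epochs:
            img = denormalize_images(by_epoch[e].images).pixels[0]
            tiles.append(img)
        rows.append(tiles)

    n_rows, n_cols = len(rows), 1 + len(epochs)
    canvas = np.full((n_rows * (tile + margin) + margin,
                      n_cols * (tile + margin) + margin), 255, dtype=np.uint8)
    for i, tiles in enumerate(rows):
        for j, img in enumerate(tiles):
            y = margin + i * (tile + margin)
            x = margin + j * (tile + margin)
            canvas[y:y + tile, x:x + tile] = img
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(canvas, mode="L").save(path)
    return path


# ---------------------------------------------------------------------------
# feature and results CSV
# ---------------------------------------------------------------------------


def save_features_csv(features: np.ndarray, filter_id: str, path) -> Path:
    """One row per image: image_id, filter, v0..v{L-1}."""
    features = np.atleast_2d(features)
    cols = {"image_id": np.arange(len(features)),
            "filter": [filter_id] * len(features)}
    for j in range(features.shape[1]):
        cols[f"v{j}"] = features[:, j]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def load_features_csv(path) -> tuple[np.ndarray, str]:
    df = pd.read_csv(path)
    filters = df["filter"].unique()
    if len(filters) != 1:
        raise ValueError(f"{path}: expected a single filter id, got {filters}")
    vcols = [c for c in df.columns if c.startswith("v")]
    vcols.sort(key=lambda c: int(c[1:]))
    return df[vcols].to_numpy(dtype=np.float64), str(filters[0])


def save_results_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(generator: Generator, discriminator: Discriminator,
                    config: GanConfig, path) -> Path:
    """Single-file NPZ archive holding both networks' weights and the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"g{i}": w for i, w in enumerate(generator.get_weights())}
    arrays.update({f"d{i}": w for i, w in enumerate(discriminator.get_weights())})
    arrays["config"] = np.array(json.dumps(config.__dict__))
    np.savez_compressed(path, **arrays)
    return path


def load_checkpoint(path) -> tuple[Generator, Discriminator, GanConfig]:
    with np.load(Path(path)) as npz:
        config = GanConfig(**json.loads(str(npz["config"])))
        g = Generator(config)
        d = Discriminator(config)
        g.set_weights([npz[f"g{i}"] for i in range(
            sum(1 for k in npz.files if k.startswith("g")))])
        d.set_weights([npz[f"d{i}"] for i in range(
            sum(1 for k in npz.files if k.startswith("d")))])
    return g, d, config
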