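"""Orchestration of the full detection grid.

A case study = one image collection: train the GAN once on its real images,
then for every (filter, classifier, epoch) cell build a balanced real-vs-
generated feature set from that epoch's snapshot, run the seeded evaluation
protocol, and record the confusion matrix and metrics.  The reference grid
is 3 filters x 4 classifiers x 50 epochs = 600 evaluations per case study
(3600 over six collections) with 1000 images per side, i.e. 50,000 generated
images per case study and 300,000 overall.

Per-cell seeds are derived deterministically from (master seed, dataset,
filter, classifier, epoch), so any single cell is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dcgan import GanConfig, ImageBatch, denormalize_images, normalize_images, train
from .descriptors import FILTER_IDS, extract_features, resolve_filter_id
from .detection import (ClassifierSpec, ConfusionMatrix, MetricsRecord,
                        assemble_dataset, resolve_classifier_family,
                        train_and_evaluate)

RESULTS_COLUMNS = ["dataset", "filter", "classifier", "epoch",
                   "tp", "fp", "fn", "tn",
                   "precision", "recall", "f_measure", "accuracy", "seed"]

#: the headline combination: best-performing in the reference study
DEFAULT_COMBINATION = ("random_forest", "colour_layout")
DEFAULT_SUMMARY_EPOCHS = (0, 24, 49)


@dataclass(frozen=True)
class ExperimentPlan:
    datasets: tuple = ("blood", "breast", "tissue", "organ_s", "organ_c",
                       "organ_a")
    filters: tuple = FILTER_IDS
    classifiers: tuple = ("c45_tree", "rep_tree", "random_forest",
                          "logistic_model_tree")
    epochs: int = 50
    images_per_side: int = 1000
    master_seed: int = 0
    protocol: str = "cv10"
    batch_size: int = 256

    def __post_init__(self):
        for name, dim in (("datasets", self.datasets), ("filters", self.filters),
                          ("classifiers", self.classifiers)):
            if len(dim) == 0:
                raise ValueError(f"plan dimension {name!r} is empty")
        if self.epochs < 1 or self.images_per_side < 1:
            raise ValueError("epochs and images_per_side must be >= 1")
        object.__setattr__(self, "filters",
                           tuple(resolve_filter_id(f) for f in self.filters))
        object.__setattr__(self, "classifiers",
                           tuple(resolve_classifier_family(c)
                                 for c in self.classifiers))


def cell_seed(master_seed: int, dataset: str, filter_id: str,
              classifier: str, epoch: int) -> int:
    """Stable per-cell seed; independent of evaluation order."""
    tags = [zlib.crc32(s.encode()) for s in (dataset, filter_id, classifier)]
    ss = np.random.SeedSequence([master_seed, *tags, epoch])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def dry_run(plan: ExperimentPlan) -> dict:
    """Bookkeeping only: scheduled evaluation and image counts."""
    per_dataset = len(plan.filters) * len(plan.classifiers) * plan.epochs
    images_per_dataset = plan.epochs * plan.images_per_side
    return {
        "evaluations_per_dataset": {d: per_dataset for d in plan.datasets},
        "evaluations_per_case_study": per_dataset,
        "total_evaluations": per_dataset * len(plan.datasets),
        "generated_images_per_case_study": images_per_dataset,
        "total_generated_images": images_per_dataset * len(plan.datasets),
    }


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class ResultsTable:
    records: list = field(default_factory=list)

    def add(self, record: MetricsRecord) -> None:
        key = (record.dataset, record.filter_id, record.classifier, record.epoch)
        if key in self._index():
            raise ValueError(f"duplicate record for cell {key}")
        self.records.append(record)

    def _index(self) -> dict:
        return {(r.dataset, r.filter_id, r.classifier, r.epoch): r
                for r in self.records}

    def get(self, dataset: str, filter_id: str, classifier: str,
            epoch: int) -> MetricsRecord:
        key = (dataset, filter_id, classifier, epoch)
        try:
            return self._index()[key]
        except KeyError:
            raise KeyError(f"no record for cell {key}") from None

    def datasets(self) -> list:
        return sorted({r.dataset for r in self.records})

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{
            "dataset": r.dataset, "filter": r.filter_id,
            "classifier": r.classifier, "epoch": r.epoch,
            "tp": r.cm.tp, "fp": r.cm.fp, "fn": r.cm.fn, "tn": r.cm.tn,
            "precision": r.precision, "recall": r.recall,
            "f_measure": r.f_measure, "accuracy": r.accuracy, "seed": r.seed,
        } for r in self.records]
        return pd.DataFrame(rows, columns=RESULTS_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResultsTable":
        table = cls()
        for row in df.itertuples(index=False):
            cm = ConfusionMatrix(int(row.tp), int(row.fp), int(row.fn),
                                 int(row.tn))
            table.add(MetricsRecord.from_confusion(
                cm, dataset=row.dataset, filter_id=row.filter,
                classifier=row.classifier, epoch=int(row.epoch),
                seed=int(row.seed)))
        return table


def accuracy_curve(table: ResultsTable, dataset: str) -> list:
    """Mean accuracy over all (filter, classifier) cells, per epoch."""
    records = [r for r in table.records if r.dataset == dataset]
    if not records:
        raise ValueError(f"no records for dataset {dataset!r}")
    epochs = sorted({r.epoch for r in records})
    curve = []
    for e in epochs:
        accs = [r.accuracy for r in records if r.epoch == e]
        curve.append((e, float(np.mean(accs))))
    return curve


def final_epoch_comparison(table: ResultsTable) -> dict:
    """Per-dataset mean accuracy at the last epoch (cross-dataset summary)."""
    out = {}
    for dataset in table.datasets():
        curve = accuracy_curve(table, dataset)
        out[dataset] = curve[-1][1]
    return out


def summarize_epochs(table: ResultsTable,
                     epochs=DEFAULT_SUMMARY_EPOCHS,
                     combination=DEFAULT_COMBINATION) -> list:
    """Per dataset and epoch, the four metrics of one (classifier, filter)
    combination, rounded to 2 decimals."""
    classifier, filter_id = combination
    rows = []
    for dataset in table.datasets():
        for epoch in epochs:
            r = table.get(dataset, filter_id, classifier, epoch)
            rows.append({
                "dataset": dataset, "epoch": epoch,
                "precision": round(r.precision, 2),
                "recall": round(r.recall, 2),
                "f_measure": round(r.f_measure, 2),
                "accuracy": round(r.accuracy, 2),
            })
    return rows


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


def _content_key(images: np.ndarray, filter_id: str) -> str:
    h = hashlib.sha1()
    h.update(filter_id.encode())
    h.update(np.ascontiguousarray(images).tobytes())
    return h.hexdigest()


def _features_cached(images: np.ndarray, filter_id: str,
                     cache_dir: Path | None) -> np.ndarray:
    if cache_dir is None:
        return extract_features(images, filter_id)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{_content_key(images, filter_id)}.npz"
    if path.exists():
        return np.load(path)["features"]
    feats = extract_features(images, filter_id)
    np.savez_compressed(path, features=feats)
    return feats


def run_case_study(dataset_name: str, real_images: np.ndarray,
                   plan: ExperimentPlan, *, cache_dir=None,
                   snapshots=None) -> ResultsTable:
    """Run the full grid for one image collection.

    ``real_images`` must hold exactly ``plan.images_per_side`` raw uint8
    28x28 images.  Pass ``snapshots`` to reuse a previous training run's
    per-epoch generated images instead of retraining.
    """
    real_images = np.asarray(real_images)
    if len(real_images) != plan.images_per_side:
        raise ValueError(
            f"expected exactly {plan.images_per_side} real images, "
            f"got {len(real_images)}")
    cache_dir = Path(cache_dir) if cache_dir is not None else None

    if snapshots is None:
        gan_seed = cell_seed(plan.master_seed, dataset_name, "gan", "train", 0)
        config = GanConfig(epochs=plan.epochs,
                           snapshot_size=plan.images_per_side,
                           batch_size=plan.batch_size, seed=gan_seed)
        result = train(normalize_images(ImageBatch(real_images, "raw")), config)
        snapshots = result.snapshots
    by_epoch = {s.epoch: s for s in snapshots}
    missing = [e for e in range(plan.epochs) if e not in by_epoch]
    if missing:
        raise ValueError(f"missing snapshot for scheduled epoch(s) {missing}")

    real_feats = {f: _features_cached(real_images, f, cache_dir)
                  for f in plan.filters}

    table = ResultsTable()
    for epoch in range(plan.epochs):
        fake_raw = denormalize_images(by_epoch[epoch].images).pixels
        fake_feats = {f: _features_cached(fake_raw, f, cache_dir)
                      for f in plan.filters}
        for filter_id in plan.filters:
            for classifier in plan.classifiers:
                seed = cell_seed(plan.master_seed, dataset_name, filter_id,
                                 classifier, epoch)
                data = assemble_dataset(
                    real_feats[filter_id], fake_feats[filter_id], filter_id,
                    seed=seed,
                    provenance={"dataset": dataset_name, "epoch": epoch})
                cm = train_and_evaluate(
                    data, ClassifierSpec(classifier, seed=seed), plan.protocol)
                table.add(MetricsRecord.from_confusion(
                    cm, dataset=dataset_name, filter_id=filter_id,
                    classifier=classifier, epoch=epoch, seed=seed))
    return table


def run_experiment(plan: ExperimentPlan, datasets: dict, *,
                   cache_dir=None) -> ResultsTable:
    """Run every case study of the plan; ``datasets`` maps dataset name to
    its raw image array."""
    missing = [d for d in plan.datasets if d not in datasets]
    if missing:
        raise ValueError(f"no images supplied for dataset(s) {missing}")
    combined = ResultsTable()
    for name in plan.datasets:
        table = run_case_study(name, datasets[name], plan, cache_dir=cache_dir)
        for record in table.records:
            combined.add(record)
    return combined
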