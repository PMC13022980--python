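"""End-to-end orchestration: generate, preprocess, search, train, evaluate.

A single global seed is fanned out to per-stage child seeds through a
counter-based ``SeedSequence`` scheme, so every stage is independently
reproducible.  Augmentation is applied to training folds only; the harness
asserts that no test-fold sample id ever enters an augmented training
batch (leak check).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .backbone import BackboneConfig, extract_features, init_backbone_weights
from .ckan import CkanConfig, ckan_forward, train_head
from .evaluation import (FoldAssignment, confusion, fold_summary,
                         multiclass_metrics, auroc_auprc, stratified_kfold)
from .preprocessing import (AugmentationParams, FundusImage, augment,
                            clahe_enhance, normalize_to_signed_range)
from .synthetic import DatasetSpec, LesionModel, generate_dataset

__all__ = [
    "RunConfig", "CVReport", "stage_seed", "preprocess_images",
    "cross_validate", "run_end_to_end",
]

log = logging.getLogger("retikan")

_MAX_SEED = 2 ** 31


def stage_seed(global_seed: int, stage: int) -> int:
    """Counter-based child seed below 2^31 for one pipeline stage."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(stage,))
    return int(ss.generate_state(1, np.uint64)[0] % _MAX_SEED)


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs; loadable from YAML."""

    dataset: DatasetSpec = field(default_factory=DatasetSpec)
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)
    n_augment: int = 1
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    head: CkanConfig = field(default_factory=CkanConfig)
    epochs: int = 3
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 16
    k_folds: int = 5
    val_fraction: float = 0.1
    seed: int = 0
    out_dir: str = "runs/latest"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "dataset" in raw:
            ds = dict(raw["dataset"])
            for key in ("class_counts", "class_probs"):
                if ds.get(key) is not None:
                    ds[key] = tuple(ds[key])
            kwargs["dataset"] = DatasetSpec(**ds)
        if "augmentation" in raw:
            kwargs["augmentation"] = AugmentationParams(**raw["augmentation"])
        if "backbone" in raw:
            kwargs["backbone"] = BackboneConfig(**raw["backbone"])
        if "head" in raw:
            head = dict(raw["head"])
            if "spline_interval" in head:
                head["spline_interval"] = tuple(head["spline_interval"])
            kwargs["head"] = CkanConfig(**head)
        if "clahe_tile_grid" in raw:
            kwargs["clahe_tile_grid"] = tuple(raw["clahe_tile_grid"])
        return cls(**kwargs)


def preprocess_images(images: list[FundusImage], clip_limit: float = 2.0,
                      tile_grid: tuple[int, int] = (8, 8)
                      ) -> list[FundusImage]:
    """CLAHE enhancement followed by [-1, 1] normalization."""
    return [normalize_to_signed_range(
        clahe_enhance(img, clip_limit, tile_grid)) for img in images]


@dataclass
class CVReport:
    """Per-fold and summary results of a stratified cross-validation run."""

    fold_confusions: list[np.ndarray]
    fold_tables: list[pd.DataFrame]
    fold_overall_accuracy: list[float]
    fold_macro_accuracy: list[float]
    fold_macro_f1: list[float]
    fold_kappa: list[float]
    auroc_tables: list[pd.DataFrame]
    summary: dict[str, dict[str, float]]
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "fold_confusions": [c.tolist() for c in self.fold_confusions],
            "fold_overall_accuracy": self.fold_overall_accuracy,
            "fold_macro_accuracy": self.fold_macro_accuracy,
            "fold_macro_f1": self.fold_macro_f1,
            "fold_kappa": self.fold_kappa,
            "summary": self.summary,
        }
        return json.dumps(payload, indent=2)


def _augment_training_set(images: list[FundusImage], train_idx: np.ndarray,
                          test_ids: set[str], params: AugmentationParams,
                          n_augment: int, rng: np.random.Generator
                          ) -> list[FundusImage]:
    """Fresh augmented copies of the training images (leak-checked)."""
    out: list[FundusImage] = []
    for idx in train_idx:
        img = images[idx]
        if img.id in test_ids:
            raise RuntimeError(
                f"augmentation leak: test sample {img.id!r} reached an "
                "augmented training batch")
        for _ in range(n_augment):
            out.append(augment(img, params, rng))
    return out


def cross_validate(images: list[FundusImage], cfg: RunConfig,
                   folds: FoldAssignment | None = None) -> CVReport:
    """Stratified k-fold training/evaluation of the head on frozen features.

    Backbone weights are drawn once from the run seed and shared across
    folds; features of the unaugmented images are computed once and reused.
    Training folds are augmented (``n_augment`` fresh copies per image);
    validation and test folds are never augmented.
    """
    labels = np.array([img.grade for img in images])
    seed_folds = stage_seed(cfg.seed, 1)
    seed_backbone = stage_seed(cfg.seed, 2)
    seed_train = stage_seed(cfg.seed, 3)
    folds = folds or stratified_kfold(labels, cfg.k_folds,
                                      cfg.val_fraction, seed_folds)

    weights = init_backbone_weights(cfg.backbone, seed_backbone)
    t0 = time.time()
    base_feats = extract_features(images, cfg.backbone, weights)
    log.info("extracted base features for %d images in %.1fs",
             len(images), time.time() - t0)

    report = CVReport([], [], [], [], [], [], [], {}, cfg.seed)
    for f, (train_idx, val_idx, test_idx) in enumerate(folds.splits):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed_train, spawn_key=(f,)))
        test_ids = {images[i].id for i in test_idx}
        train_feats = [base_feats[train_idx]]
        train_labels = [labels[train_idx]]
        if cfg.n_augment > 0:
            aug_imgs = _augment_training_set(
                images, train_idx, test_ids, cfg.augmentation,
                cfg.n_augment, rng)
            train_feats.append(
                extract_features(aug_imgs, cfg.backbone, weights))
            train_labels.append(
                np.repeat(labels[train_idx], cfg.n_augment))
        x_train = np.concatenate(train_feats)
        y_train = np.concatenate(train_labels)

        params, history = train_head(
            x_train, y_train, cfg.head,
            val_features=base_feats[val_idx], val_labels=labels[val_idx],
            epochs=cfg.epochs, lr=cfg.learning_rate,
            weight_decay=cfg.weight_decay, batch_size=cfg.batch_size,
            patience=max(2, cfg.epochs), seed=stage_seed(seed_train, 100 + f))

        probs = []
        for i in range(0, len(test_idx), 64):
            probs.append(ckan_forward(
                base_feats[test_idx[i:i + 64]], cfg.head, params))
        probs = np.concatenate(probs)
        preds = probs.argmax(axis=1)
        cm = confusion(labels[test_idx], preds)
        table = multiclass_metrics(cm)
        report.fold_confusions.append(cm.counts)
        report.fold_tables.append(table)
        report.fold_overall_accuracy.append(table.attrs["overall_accuracy"])
        report.fold_macro_accuracy.append(float(table.loc["macro", "accuracy"]))
        report.fold_macro_f1.append(float(table.loc["macro", "f1"]))
        report.fold_kappa.append(table.attrs["multiclass_kappa"])
        report.auroc_tables.append(auroc_auprc(labels[test_idx], probs))
        log.info("fold %d: overall acc %.3f, macro acc %.3f, kappa %.3f",
                 f, report.fold_overall_accuracy[-1],
                 report.fold_macro_accuracy[-1], report.fold_kappa[-1])

    for name, values in (
            ("overall_accuracy", report.fold_overall_accuracy),
            ("macro_accuracy", report.fold_macro_accuracy),
            ("macro_f1", report.fold_macro_f1),
            ("kappa", report.fold_kappa)):
        report.summary[name] = fold_summary(values)
    return report


def build_search_data(n_train: int = 120, val_fraction: float = 0.25,
                      input_size: int = 64, seed: int = 0,
                      balanced: bool = True):
    """Small preprocessed synthetic train/val split for candidate scoring.

    Balanced classes by default (candidate ranking, not epidemiology), at a
    reduced image size to keep a whole IWO search affordable on one CPU.
    """
    from .search import SearchData

    n_val = max(5, int(round(n_train * val_fraction)))
    n = n_train + n_val
    if balanced:
        base = n // 5
        counts = [base] * 5
        for i in range(n - 5 * base):
            counts[i] += 1
        spec = DatasetSpec(n_images=n, image_size=input_size, seed=seed,
                           class_counts=tuple(counts))
    else:
        spec = DatasetSpec(n_images=n, image_size=input_size, seed=seed)
    images, _ = generate_dataset(spec, LesionModel())
    images = preprocess_images(images)
    labels = np.array([img.grade for img in images])
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tr, va = order[:n_train], order[n_train:]
    pixels = np.stack([img.pixels for img in images]).astype(np.float32)
    return SearchData(train_images=pixels[tr], train_labels=labels[tr],
                      val_images=pixels[va], val_labels=labels[va])


def run_end_to_end(cfg: RunConfig) -> CVReport:
    """generate -> preprocess -> 5-fold train/evaluate -> persist report.

    Creates ``cfg.out_dir`` if missing and writes the report JSON, the
    per-fold confusion matrices (CSV) and the manifest.  Any stage failure
    aborts with the stage name while partial artifacts remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        seed_data = stage_seed(cfg.seed, 0)
        spec = dataclasses.replace(cfg.dataset, seed=seed_data)
        images, manifest = generate_dataset(spec, LesionModel())
        manifest.to_csv(out / "manifest.csv", index=False)
        log.info("generated %d images (seed %d)", len(images), seed_data)

        stage = "preprocess"
        images = preprocess_images(images, cfg.clahe_clip_limit,
                                   cfg.clahe_tile_grid)

        stage = "train/evaluate"
        report = cross_validate(images, cfg)

        stage = "report"
        (out / "report.json").write_text(report.to_json())
        for f, cm in enumerate(report.fold_confusions):
            pd.DataFrame(cm).to_csv(out / f"confusion_fold{f}.csv",
                                    index=False)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
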