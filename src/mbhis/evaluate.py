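"""Repeated stratified cross-validation, metrics, and the scenario runners.

The evaluation protocol is stratified 5-fold cross-validation repeated 5
times (fold seeds are ``base_seed + repeat``, so any repeat is reproducible
in isolation). Accuracy, sensitivity, specificity and precision derive from
per-class one-vs-rest confusion counts:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)

Multiclass values are macro-averaged over classes; a zero denominator yields
NaN (with a logged note), never a silent 0. Fold-level metrics are averaged
across folds; the pooled confusion matrix is also reported.

Four scenario runners cover the cascade:

* **I**   — per fold, train the backbone head and predict end-to-end;
* **II**  — spatial (GAP) features per backbone into the classical classifiers;
* **III** — wavelet detail (stf) features per backbone into the classifiers;
* **IV**  — concatenate the three stf sets, reduce with DCT or PCA fitted on
  the training fold (retained dimension fixed or from the sequential forward
  search), then classify.

Everything fitted (head, reduction, scaler, classifier) sees training-fold
rows only; optional augmentation is applied to training folds only, and a
lineage audit verifies both claims on every fold.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .backbones import (
    BackboneSpec,
    TrainConfig,
    build_backbone,
    extract_gap_features,
    fine_tune,
    predict_end_to_end,
)
from .classify import ClassifierSpec, FittedClassifier, fit as fit_classifier, predict as predict_classifier
from .data import AugmentationPolicy, LabeledImageSet, augment
from .exceptions import ConfigurationError, DataError
from .features import FeatureMatrix
from .fusion import (
    FUSION_ORDER,
    ReductionModel,
    apply_reduction,
    concat_fused,
    fit_pca,
    reduce_dct,
    sequential_forward_search,
)
from .wavelet import WaveletFilter, stf_transform

logger = logging.getLogger(__name__)

SCENARIOS = ("I", "II", "III", "IV")


@dataclass
class CVConfig:
    k: int = 5
    repeats: int = 5
    stratified: bool = True
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")


@dataclass
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def split_folds(labels, cfg: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train, test) index pairs: ``repeats`` stratified ``k``-fold partitions."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < cfg.k]
    if len(small):
        raise ConfigurationError(
            f"class {small[0]} has {counts[counts < cfg.k][0]} samples, fewer than k={cfg.k}"
        )
    pairs = []
    for r in range(cfg.repeats):
        skf = StratifiedKFold(n_splits=cfg.k, shuffle=True, random_state=cfg.base_seed + r)
        for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
            pairs.append((train_idx, test_idx))
    return pairs


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy/sensitivity/specificity/precision from one-vs-rest counts."""

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.info("%s undefined (zero denominator); reporting NaN", name)
            return float("nan")
        return num / den

    return {
        "accuracy": ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        "specificity": ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        "precision": ratio(counts.tp, counts.tp + counts.fp, "precision"),
    }


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)):
        cm[t, p] += 1
    return cm


def counts_per_class(cm: np.ndarray) -> list[ConfusionCounts]:
    """One-vs-rest counts for every class of a square confusion matrix."""
    total = int(cm.sum())
    out = []
    for c in range(cm.shape[0]):
        tp = int(cm[c, c])
        fn = int(cm[c].sum() - tp)
        fp = int(cm[:, c].sum() - tp)
        tn = total - tp - fn - fp
        out.append(ConfusionCounts(tp, fp, tn, fn))
    return out


def macro_metrics(cm: np.ndarray) -> dict[str, float]:
    """Overall accuracy + macro-averaged one-vs-rest metrics."""
    per_class = [compute_metrics(c) for c in counts_per_class(cm)]
    out = {"accuracy": float(np.trace(cm) / cm.sum()) if cm.sum() else float("nan")}
    for key in ("sensitivity", "specificity", "precision"):
        vals = np.array([m[key] for m in per_class])
        out[key] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
    return out


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    confusion: np.ndarray
    accuracy: float
    metrics: dict[str, float]


@dataclass
class PipelineResult:
    """Per-(pipeline, classifier) cross-validation outcome."""

    name: str
    folds: list[FoldRecord]
    mean_accuracy: float
    sd_accuracy: float
    pooled_confusion: np.ndarray
    mean_metrics: dict[str, float]
    pooled_metrics: dict[str, float]

    @classmethod
    def from_folds(cls, name: str, folds: list[FoldRecord]) -> "PipelineResult":
        accs = np.array([f.accuracy for f in folds])
        pooled = np.sum([f.confusion for f in folds], axis=0)
        mean_m = {
            k: float(np.nanmean([f.metrics[k] for f in folds]))
            for k in ("accuracy", "sensitivity", "specificity", "precision")
        }
        return cls(
            name,
            folds,
            float(accs.mean()),
            float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
            pooled,
            mean_m,
            macro_metrics(pooled),
        )


@dataclass
class CVReport:
    scenario: str
    level: str
    class_names: list[str]
    results: list[PipelineResult]
    config: dict
    search_profiles: dict = field(default_factory=dict)
    leakage_audit: str = "passed"
    wall_time_s: dict = field(default_factory=dict)

    def best(self) -> PipelineResult:
        return max(self.results, key=lambda r: r.mean_accuracy)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "level": self.level,
            "class_names": self.class_names,
            "config": self.config,
            "search_profiles": self.search_profiles,
            "leakage_audit": self.leakage_audit,
            "wall_time_s": self.wall_time_s,
            "results": [
                {
                    "name": r.name,
                    "mean_accuracy": r.mean_accuracy,
                    "sd_accuracy": r.sd_accuracy,
                    "mean_metrics": r.mean_metrics,
                    "pooled_metrics": r.pooled_metrics,
                    "pooled_confusion": r.pooled_confusion.tolist(),
                    "folds": [
                        {
                            "repeat": f.repeat,
                            "fold": f.fold,
                            "accuracy": f.accuracy,
                            "confusion": f.confusion.tolist(),
                        }
                        for f in r.folds
                    ],
                }
                for r in self.results
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class ScenarioConfig:
    """Configuration bundle for :func:`run_scenario`."""

    cv: CVConfig = field(default_factory=CVConfig)
    backbones: tuple[str, ...] = FUSION_ORDER
    classifiers: list[ClassifierSpec] = field(
        default_factory=lambda: [ClassifierSpec("lda")]
    )
    wavelet: str = "dmey"
    fusion_method: str = "pca"
    fusion_n: int | None = None
    fusion_grid: tuple[int, ...] | None = None
    train: TrainConfig = field(default_factory=TrainConfig)
    augmentation: AugmentationPolicy | None = None
    backbone_seed: int = 0
    pretrained: bool = False


def _audit_disjoint(fit_ids: list[str], test_ids: set[str]) -> None:
    """No fitted component may have seen a test row or an augmented copy of one."""
    for sid in fit_ids:
        parent = sid.split("#aug")[0]
        if sid in test_ids or parent in test_ids:
            raise DataError(f"leakage: fitted component saw test sample {sid}")


def _fold_record(repeat: int, fold: int, y_true, y_pred, n_classes: int) -> FoldRecord:
    cm = confusion_matrix(y_true, y_pred, n_classes)
    m = macro_metrics(cm)
    return FoldRecord(repeat, fold, cm, m["accuracy"], m)


class _StageExtractor:
    """Frozen-backbone feature extraction for a scenario.

    The backbones are frozen during feature extraction (head training does not
    alter the trunk), so features for the full set are computed once; no
    fold-dependent fitting happens here. The extractor is kept around so that
    augmented training copies can be embedded per fold when an augmentation
    policy is configured.
    """

    def __init__(self, config: ScenarioConfig, stf: bool):
        self.stf = stf
        self.filt = WaveletFilter(config.wavelet) if stf else None
        self.models = {}
        for i, name in enumerate(config.backbones):
            spec = BackboneSpec(
                name, pretrained=config.pretrained, num_classes=2,
                seed=config.backbone_seed + i,
            )
            self.models[name] = build_backbone(spec)

    def features(self, data: LabeledImageSet) -> dict[str, FeatureMatrix]:
        out: dict[str, FeatureMatrix] = {}
        for name, model in self.models.items():
            feats = extract_gap_features(model, data)
            out[name] = stf_transform(feats, self.filt) if self.stf else feats
            logger.info(
                "extracted %s features from %s: %s",
                out[name].provenance, name, out[name].values.shape,
            )
        return out


def _stack_train_features(
    fm: FeatureMatrix, train_idx: np.ndarray, aug_fm: FeatureMatrix | None
) -> FeatureMatrix:
    base = fm.rows(train_idx)
    if aug_fm is None:
        return base
    return FeatureMatrix(
        np.concatenate([base.values, aug_fm.values]),
        base.sample_ids + aug_fm.sample_ids,
        fm.provenance,
        fm.backbone,
    )


def _augmented_train(
    data: LabeledImageSet, train_idx: np.ndarray, policy: AugmentationPolicy | None,
    repeat: int, fold: int,
) -> LabeledImageSet:
    sub = data.subset(train_idx)
    if policy is None:
        return sub
    fold_policy = AugmentationPolicy(
        flip_x=policy.flip_x,
        flip_y=policy.flip_y,
        translation_px=policy.translation_px,
        scale=policy.scale,
        shear_deg=policy.shear_deg,
        per_image_copies=policy.per_image_copies,
        seed=policy.seed + 1000 * repeat + fold,
    )
    return augment(sub, fold_policy)


def run_scenario(scenario: str, data: LabeledImageSet, config: ScenarioConfig) -> CVReport:
    """Execute one of the four cascade scenarios under repeated stratified CV."""
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    t0 = time.perf_counter()
    folds = split_folds(data.labels, config.cv)
    n_classes = data.n_classes
    wall: dict[str, float] = {}
    search_profiles: dict = {}

    if scenario == "I":
        results = _run_scenario_end_to_end(data, config, folds, wall)
    else:
        t_feat = time.perf_counter()
        extractor = _StageExtractor(config, stf=scenario in ("III", "IV"))
        feats = extractor.features(data)
        wall["feature_extraction"] = time.perf_counter() - t_feat
        if scenario == "IV":
            fused = concat_fused([feats[b] for b in config.backbones])
            results = _run_scenario_fused(
                data, config, folds, fused, extractor, search_profiles, wall
            )
        else:
            results = _run_scenario_per_backbone(data, config, folds, feats, extractor)

    wall["total"] = time.perf_counter() - t0
    return CVReport(
        scenario=scenario,
        level=data.level,
        class_names=list(data.class_names),
        results=results,
        config=_config_echo(config),
        search_profiles=search_profiles,
        wall_time_s={k: round(v, 3) for k, v in wall.items()},
    )


def _run_scenario_end_to_end(data, config, folds, wall) -> list[PipelineResult]:
    if data.n_classes not in (2, 4):
        raise ConfigurationError(
            f"end-to-end scenario needs 2 or 4 classes, dataset has {data.n_classes}"
        )
    per_backbone: dict[str, list[FoldRecord]] = {b: [] for b in config.backbones}
    k = config.cv.k
    for fi, (train_idx, test_idx) in enumerate(folds):
        repeat, fold = divmod(fi, k)
        train_set = _augmented_train(data, train_idx, config.augmentation, repeat, fold)
        test_ids = set(data.subset(test_idx).sample_ids)
        _audit_disjoint(train_set.sample_ids, test_ids)
        for i, name in enumerate(config.backbones):
            spec = BackboneSpec(
                name,
                pretrained=config.pretrained,
                num_classes=data.n_classes,
                seed=config.backbone_seed + i,
            )
            model = build_backbone(spec)
            cfg = TrainConfig(
                epochs=config.train.epochs,
                initial_lr=config.train.initial_lr,
                batch_size=config.train.batch_size,
                momentum=config.train.momentum,
                seed=config.train.seed + fi,
            )
            fine_tune(model, train_set, cfg)
            pred = predict_end_to_end(model, data.subset(test_idx))
            per_backbone[name].append(
                _fold_record(repeat, fold, data.labels[test_idx], pred, data.n_classes)
            )
    return [PipelineResult.from_folds(b, recs) for b, recs in per_backbone.items()]


def _aug_copies(data, train_idx, policy, repeat, fold) -> LabeledImageSet | None:
    """Augmented copies only (not the originals) of a training fold."""
    if policy is None:
        return None
    full = _augmented_train(data, train_idx, policy, repeat, fold)
    return full.subset(np.arange(len(train_idx), len(full)))


def _run_scenario_per_backbone(data, config, folds, feats, extractor) -> list[PipelineResult]:
    results = []
    k = config.cv.k
    # per-fold augmented-copy features, computed once and shared by classifiers
    aug_feats: list[dict[str, FeatureMatrix] | None] = []
    aug_labels: list[np.ndarray | None] = []
    for fi, (train_idx, _) in enumerate(folds):
        repeat, fold = divmod(fi, k)
        copies = _aug_copies(data, train_idx, config.augmentation, repeat, fold)
        aug_feats.append(extractor.features(copies) if copies is not None else None)
        aug_labels.append(copies.labels if copies is not None else None)
    for name, fm in feats.items():
        for cspec in config.classifiers:
            recs = []
            for fi, (train_idx, test_idx) in enumerate(folds):
                repeat, fold = divmod(fi, k)
                aug_fm = aug_feats[fi][name] if aug_feats[fi] is not None else None
                xtr = _stack_train_features(fm, train_idx, aug_fm)
                ytr = data.labels[train_idx]
                if aug_labels[fi] is not None:
                    ytr = np.concatenate([ytr, aug_labels[fi]])
                clf = fit_classifier(cspec, xtr, ytr)
                test_ids = set(fm.rows(test_idx).sample_ids)
                _audit_disjoint(clf.fit_sample_ids, test_ids)
                pred = predict_classifier(clf, fm.rows(test_idx))
                recs.append(
                    _fold_record(repeat, fold, data.labels[test_idx], pred, data.n_classes)
                )
            results.append(PipelineResult.from_folds(f"{name}/{cspec.kind}", recs))
    return results


def _run_scenario_fused(data, config, folds, fused, extractor, search_profiles, wall) -> list[PipelineResult]:
    results = []
    k = config.cv.k
    method = config.fusion_method
    for cspec in config.classifiers:
        fusion_grid = config.fusion_grid
        if fusion_grid is None and config.fusion_n is None:
            # paper-style default: pick the retained dimension by the search
            from .fusion import DEFAULT_DCT_GRID, DEFAULT_PCA_GRID

            fusion_grid = DEFAULT_DCT_GRID if method == "dct" else DEFAULT_PCA_GRID
        if fusion_grid:
            t_s = time.perf_counter()
            grid = sequential_forward_search(
                fused, data.labels, method, fusion_grid, config.cv, cspec
            )
            wall[f"search/{cspec.kind}"] = time.perf_counter() - t_s
            search_profiles[cspec.kind] = {
                "candidates": grid.candidates,
                "scores": grid.scores,
                "chosen": grid.chosen,
            }
            n = grid.chosen
        elif config.fusion_n:
            n = config.fusion_n
        else:
            raise ConfigurationError("scenario IV needs fusion_n or fusion_grid")
        recs = []
        for fi, (train_idx, test_idx) in enumerate(folds):
            repeat, fold = divmod(fi, k)
            copies = _aug_copies(data, train_idx, config.augmentation, repeat, fold)
            if copies is not None:
                copy_feats = extractor.features(copies)
                aug_fused = concat_fused([copy_feats[b] for b in config.backbones])
                xtr = _stack_train_features(fused, train_idx, aug_fused)
                ytr_full = np.concatenate([data.labels[train_idx], copies.labels])
            else:
                xtr = fused.rows(train_idx)
                ytr_full = data.labels[train_idx]
            if method == "dct":
                _, model = reduce_dct(xtr, n)
            else:
                model = fit_pca(xtr, n)
            test_ids = set(fused.rows(test_idx).sample_ids)
            _audit_disjoint(model.fit_sample_ids, test_ids)
            clf = fit_classifier(cspec, apply_reduction(model, xtr), ytr_full)
            _audit_disjoint(clf.fit_sample_ids, test_ids)
            pred = predict_classifier(clf, apply_reduction(model, fused.rows(test_idx)))
            recs.append(
                _fold_record(repeat, fold, data.labels[test_idx], pred, data.n_classes)
            )
        results.append(PipelineResult.from_folds(f"fused-{method}/{cspec.kind}", recs))
    return results


def _config_echo(config: ScenarioConfig) -> dict:
    echo = {
        "cv": asdict(config.cv),
        "backbones": list(config.backbones),
        "classifiers": [asdict(c) for c in config.classifiers],
        "wavelet": config.wavelet,
        "fusion_method": config.fusion_method,
        "fusion_n": config.fusion_n,
        "fusion_grid": list(config.fusion_grid) if config.fusion_grid else None,
        "train": asdict(config.train),
        "augmentation": asdict(config.augmentation) if config.augmentation else None,
        "backbone_seed": config.backbone_seed,
        "pretrained": config.pretrained,
    }
    return echo
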