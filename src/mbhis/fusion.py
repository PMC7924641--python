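"""Fusion and reduction of the three wavelet feature sets.

The detail-coefficient matrices of the three backbones are concatenated
column-wise in the fixed order ResNet-50, DenseNet-201, MobileNet
(1074 + 1010 + 690 = 2774 columns) and then reduced either by truncating an
orthonormal row-wise DCT-II to its first ``n`` (lowest-frequency)
coefficients or by projecting onto the top ``n`` principal components fitted
on training rows only.

The retained dimension is chosen by a sequential forward search: an
increasing grid of candidate dimensions is scored by mean repeated
cross-validated accuracy, and the smallest candidate achieving the maximum
score wins (dimension parsimony is the point of the reduction stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, idct
from sklearn.decomposition import PCA

from .exceptions import ConfigurationError, DataError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

FUSION_ORDER = ("resnet50", "densenet201", "mobilenet")

DEFAULT_DCT_GRID = tuple(range(100, 2701, 100))
DEFAULT_PCA_GRID = (2, 5, 15, 25, 35, 45, 55, 65, 75, 85, 95)


def concat_fused(stf_sets: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation; rows must share order and sample ids."""
    if not stf_sets:
        raise DataError("nothing to concatenate")
    ids = stf_sets[0].sample_ids
    for fm in stf_sets[1:]:
        if fm.sample_ids != ids:
            raise DataError("feature sets disagree on row order (sample ids differ)")
    order = {b: i for i, b in enumerate(FUSION_ORDER)}
    if all(fm.backbone in order for fm in stf_sets):
        stf_sets = sorted(stf_sets, key=lambda fm: order[fm.backbone])
    if len(stf_sets) == 1:
        fm = stf_sets[0]
        return FeatureMatrix(fm.values.copy(), list(ids), fm.provenance, fm.backbone)
    values = np.concatenate([fm.values for fm in stf_sets], axis=1)
    return FeatureMatrix(values, list(ids), "fused")


def dct2_rows(x: np.ndarray | FeatureMatrix) -> np.ndarray:
    """Orthonormal DCT-II applied to each row; energy-preserving."""
    vals = x.values if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=np.float64)
    return dct(vals, type=2, norm="ortho", axis=-1)


def idct2_rows(x: np.ndarray) -> np.ndarray:
    return idct(np.asarray(x, dtype=np.float64), type=2, norm="ortho", axis=-1)


@dataclass
class ReductionModel:
    """Fitted DCT-truncation or PCA transform.

    ``fit_sample_ids`` records which rows the model was fitted on (empty for
    DCT, which has no data-dependent parameters) so leakage audits can verify
    that no test row influenced a fitted component.
    """

    method: str
    retained: int
    input_dim: int
    mean: np.ndarray | None = None
    components: np.ndarray | None = None
    explained_variance: np.ndarray | None = None
    fit_sample_ids: list[str] = field(default_factory=list)
    top_energy: bool = False
    kept_indices: np.ndarray | None = None

    def transform(self, x: FeatureMatrix) -> FeatureMatrix:
        return apply_reduction(self, x)


def reduce_dct(
    x: FeatureMatrix, n: int, top_energy: bool = False
) -> tuple[FeatureMatrix, ReductionModel]:
    """Row-wise DCT, keep the first ``n`` (lowest-frequency) coefficients.

    ``top_energy=True`` instead keeps the ``n`` coefficient indices with the
    largest mean squared magnitude across rows (research mode; the default
    low-frequency truncation is the standard reading of DCT reduction).
    """
    d = x.width
    if not 1 <= n <= d:
        raise ConfigurationError(f"retained dimension {n} outside [1, {d}]")
    coeffs = dct2_rows(x)
    if top_energy:
        energy = (coeffs**2).mean(axis=0)
        kept = np.sort(np.argsort(-energy)[:n])
        model = ReductionModel("dct", n, d, top_energy=True, kept_indices=kept,
                               fit_sample_ids=list(x.sample_ids))
        vals = coeffs[:, kept]
    else:
        model = ReductionModel("dct", n, d)
        vals = coeffs[:, :n]
    return FeatureMatrix(vals, list(x.sample_ids), "fused"), model


def fit_pca(x_train: FeatureMatrix, n: int) -> ReductionModel:
    """Centre on the training mean; top-``n`` covariance eigenvectors."""
    rows, d = x_train.values.shape
    if not 1 <= n <= min(rows - 1, d):
        raise ConfigurationError(
            f"retained dimension {n} outside [1, min(rows-1={rows - 1}, d={d})]"
        )
    pca = PCA(n_components=n, svd_solver="full")
    pca.fit(x_train.values)
    return ReductionModel(
        "pca",
        n,
        d,
        mean=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        fit_sample_ids=list(x_train.sample_ids),
    )


def apply_reduction(model: ReductionModel, x: FeatureMatrix) -> FeatureMatrix:
    """Deterministic projection with a fitted model; never refits."""
    if x.width != model.input_dim:
        raise DataError(f"input width {x.width} != model input dim {model.input_dim}")
    if model.method == "dct":
        coeffs = dct2_rows(x)
        vals = coeffs[:, model.kept_indices] if model.top_energy else coeffs[:, : model.retained]
    elif model.method == "pca":
        vals = (x.values - model.mean) @ model.components.T
    else:
        raise ConfigurationError(f"unknown reduction method {model.method!r}")
    return FeatureMatrix(vals, list(x.sample_ids), "fused")


@dataclass
class SearchGrid:
    """Score profile of a sequential forward search over retained dimensions."""

    candidates: list[int]
    scores: list[float]
    chosen: int

    def to_records(self) -> list[dict]:
        return [
            {"candidate": c, "mean_accuracy": s} for c, s in zip(self.candidates, self.scores)
        ]


def choose_smallest_argmax(candidates: list[int], scores: list[float]) -> int:
    """Smallest candidate achieving the maximum score (ties -> parsimony)."""
    best = max(scores)
    for c, s in sorted(zip(candidates, scores)):
        if s >= best:
            return c
    raise ConfigurationError("empty search profile")  # pragma: no cover


def sequential_forward_search(
    x: FeatureMatrix,
    labels: np.ndarray,
    method: str,
    grid,
    eval_cfg,
    classifier_spec,
) -> SearchGrid:
    """Score an increasing grid of retained dimensions by repeated-CV accuracy.

    For every candidate the reduction is fitted inside each training fold and
    applied to that fold's test rows; the candidate's score is the mean
    accuracy over all folds and repeats. Infeasible candidates (larger than
    the data allows) are skipped with a warning.
    """
    from .classify import fit as fit_clf
    from .classify import predict as predict_clf
    from .evaluate import split_folds

    if method not in ("dct", "pca"):
        raise ConfigurationError(f"unknown reduction method {method!r}")
    labels = np.asarray(labels)
    candidates = sorted(set(int(c) for c in grid))
    if not candidates:
        raise ConfigurationError("search grid is empty")
    folds = split_folds(labels, eval_cfg)
    kept: list[int] = []
    scores: list[float] = []
    for cand in candidates:
        accs = []
        feasible = True
        for train_idx, test_idx in folds:
            xtr, xte = x.rows(train_idx), x.rows(test_idx)
            try:
                if method == "dct":
                    _, model = reduce_dct(xtr, cand)
                elif method == "pca":
                    model = fit_pca(xtr, cand)
                else:
                    raise ConfigurationError(f"unknown reduction method {method!r}")
            except ConfigurationError as exc:
                logger.warning("skipping candidate %d: %s", cand, exc)
                feasible = False
                break
            clf = fit_clf(classifier_spec, apply_reduction(model, xtr), labels[train_idx])
            pred = predict_clf(clf, apply_reduction(model, xte))
            accs.append(float(np.mean(pred == labels[test_idx])))
        if feasible:
            kept.append(cand)
            scores.append(float(np.mean(accs)))
    if not kept:
        raise ConfigurationError("no feasible candidate in the search grid")
    return SearchGrid(kept, scores, choose_smallest_argmax(kept, scores))
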