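"""Leakage-safe nested cross-validated SVM classification.

The outer loop is leave-one-out over subjects: for every held-out subject,
ROI screening (the voxelwise group contrast and clustering) is re-run on
the remaining subjects only, features are the cluster means of those
train-derived ROIs, feature scaling uses train statistics only, and an
inner stratified k-fold grid search picks the RBF-SVM hyperparameters
(C, gamma). Nothing derived from the held-out subject enters screening,
scaling, tuning or fitting — the property that keeps the outer accuracy an
unbiased estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import MetricMap
from .inference import (GroupDesign, estimate_smoothness, fit_group_glm,
                        threshold_and_cluster)

logger = logging.getLogger(__name__)


def _pow4_grid(lo_exp: int, hi_exp: int) -> tuple[float, ...]:
    return tuple(2.0 ** e for e in range(lo_exp, hi_exp + 1, 2))


@dataclass
class SvmSettings:
    """RBF-SVM hyperparameter search space (classical coarse power-of-4 grid)."""

    kernel: str = "rbf"
    c_grid: tuple[float, ...] = field(default_factory=lambda: _pow4_grid(-5, 15))
    g_grid: tuple[float, ...] = field(default_factory=lambda: _pow4_grid(-15, 3))
    inner_folds: int = 5
    scale_features: bool = True

    def __post_init__(self) -> None:
        if not self.c_grid or not self.g_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass
class FeatureMatrix:
    """Subjects x ROI-mean features with group labels."""

    features: pd.DataFrame
    labels: np.ndarray
    subject_ids: list[str]
    fold_tag: str = "all"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.labels):
            raise ValueError("one label per feature row required")
        if len(set(self.features.columns)) != len(self.features.columns):
            raise ValueError("feature column names must be unique")
        if not np.all(np.isfinite(self.features.to_numpy(dtype=float))):
            raise ValueError("features contain non-finite entries")


def extract_cluster_means(maps: list[MetricMap], cluster_labels: np.ndarray,
                          metric_name: str | None = None) -> pd.DataFrame:
    """Mean map value over every labeled cluster, one row per subject.

    Column (s, k) is the mean of subject s's map over voxels labeled k;
    columns are named ``<metric>_cluster<k>``.
    """
    cluster_labels = np.asarray(cluster_labels)
    ids = sorted(int(k) for k in np.unique(cluster_labels) if k != 0)
    if not ids:
        raise ValueError("cluster label volume contains no clusters")
    name = metric_name or (maps[0].metric if maps else "metric")
    rows = []
    for m in maps:
        if m.values.shape != cluster_labels.shape:
            raise ValueError("label volume grid does not match maps")
        rows.append([float(m.values[cluster_labels == k].mean()) for k in ids])
    return pd.DataFrame(rows, columns=[f"{name}_cluster{k}" for k in ids])


def _make_estimator(settings: SvmSettings, c: float, g: float) -> Pipeline:
    steps = []
    if settings.scale_features:
        steps.append(("scale", StandardScaler()))
    steps.append(("svc", SVC(C=c, gamma=g, kernel=settings.kernel)))
    return Pipeline(steps)


def inner_grid_search(X: np.ndarray, y: np.ndarray, settings: SvmSettings,
                      seed: int = 0) -> tuple[float, float, float]:
    """Stratified k-fold grid search over (C, gamma).

    Returns (best_c, best_g, best_mean_accuracy). Ties favor the smaller C,
    then the smaller gamma (the simplest model), which the ascending scan
    with a strict improvement test guarantees.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the training fold")
    n_splits = min(settings.inner_folds, int(min(np.bincount(_encode(y)))))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = (None, None, -1.0)
    for c, g in product(sorted(settings.c_grid), sorted(settings.g_grid)):
        correct = total = 0
        for tr, va in folds:
            est = _make_estimator(settings, c, g)
            est.fit(X[tr], y[tr])
            correct += int((est.predict(X[va]) == y[va]).sum())
            total += len(va)
        acc = correct / total
        if acc > best[2]:
            best = (c, g, acc)
    return best


def _encode(y: np.ndarray) -> np.ndarray:
    _, inv = np.unique(y, return_inverse=True)
    return inv


class PerFoldScreeningSource:
    """Feature source that re-runs ROI screening inside each training fold.

    Holds every subject's (standardized, smoothed) metric maps; given the
    training subject indices it fits the group GLM on those subjects only,
    clusters the t map, and returns cluster-mean features for all subjects
    computed from the train-derived ROI labels. Folds in which screening
    finds no cluster fall back to one whole-mask mean feature per metric
    (logged, not fatal).
    """

    def __init__(self, maps_by_metric: dict[str, list[MetricMap]],
                 design: GroupDesign, voxel_p: float = 0.01,
                 cluster_p: float = 0.01, min_extent: int = 100,
                 connectivity: int = 26):
        self.maps_by_metric = maps_by_metric
        self.design = design
        self.voxel_p = voxel_p
        self.cluster_p = cluster_p
        self.min_extent = min_extent
        self.connectivity = connectivity

    def features_for_fold(self, train_idx: np.ndarray) -> pd.DataFrame:
        train_idx = np.asarray(train_idx)
        blocks = []
        for metric, maps in self.maps_by_metric.items():
            train_maps = [maps[i] for i in train_idx]
            sub_design = GroupDesign(
                subject_ids=[self.design.subject_ids[i] for i in train_idx],
                groups=[self.design.groups[i] for i in train_idx],
                patient_label=self.design.patient_label,
                covariates=None if self.design.covariates is None
                else self.design.covariates.iloc[train_idx].reset_index(drop=True),
            )
            result = fit_group_glm(train_maps, sub_design)
            ct = threshold_and_cluster(
                result, voxel_p=self.voxel_p, cluster_p=self.cluster_p,
                min_extent=self.min_extent, connectivity=self.connectivity,
                smoothness=estimate_smoothness(result))
            if len(ct) == 0:
                logger.warning("fold screening found no %s cluster; "
                               "falling back to whole-mask mean", metric)
                mask = maps[0].mask
                col = [float(m.values[mask].mean()) for m in maps]
                blocks.append(pd.DataFrame({f"{metric}_maskmean": col}))
            else:
                blocks.append(extract_cluster_means(maps, ct.labels, metric_name=metric))
        return pd.concat(blocks, axis=1)


def outer_loocv(features_source, design: GroupDesign, settings: SvmSettings,
                screening: str = "per_fold_rois", seed: int = 0) -> pd.DataFrame:
    """Leave-one-out outer loop of the nested CV.

    ``features_source`` is a :class:`FeatureMatrix` when ``screening`` is
    ``fixed_rois`` or a :class:`PerFoldScreeningSource` when it is
    ``per_fold_rois``. Returns one row per subject: true label, predicted
    label, signed decision value (positive = patient side) and the
    hyperparameters chosen by that fold's inner search.
    """
    if screening not in ("fixed_rois", "per_fold_rois"):
        raise ValueError("screening must be 'fixed_rois' or 'per_fold_rois'")
    n = len(design.subject_ids)
    y = np.asarray([1 if g == design.patient_label else 0 for g in design.groups])
    if y.sum() < 2 or (n - y.sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    rows = []
    for i in range(n):
        train_idx = np.array([j for j in range(n) if j != i])
        if screening == "per_fold_rois":
            feats = features_source.features_for_fold(train_idx)
        else:
            feats = features_source.features
        X = feats.to_numpy(dtype=float)
        c, g, inner_acc = inner_grid_search(X[train_idx], y[train_idx], settings,
                                            seed=seed + i)
        est = _make_estimator(settings, c, g)
        est.fit(X[train_idx], y[train_idx])
        pred = int(est.predict(X[i:i + 1])[0])
        decision = float(est.decision_function(X[i:i + 1])[0])
        rows.append({
            "subject_id": design.subject_ids[i],
            "true": design.groups[i],
            "predicted": design.patient_label if pred == 1 else _control_label(design),
            "decision_value": decision,
            "inner_c": c, "inner_g": g, "inner_accuracy": inner_acc,
            "n_features": X.shape[1],
        })
    return pd.DataFrame(rows)


def _control_label(design: GroupDesign) -> str:
    others = sorted({g for g in design.groups if g != design.patient_label})
    return others[0] if others else "control"


def auc_rank(decision_values: np.ndarray, y_positive: np.ndarray) -> float:
    """AUC as the rank statistic: probability that a random positive's
    decision value exceeds a random negative's, ties counted half."""
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(y_positive, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(d)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ClassificationReport:
    """Confusion counts (patient = positive) and derived percentages."""

    tp: int
    fp: int
    fn: int
    tn: int
    auc: float

    @property
    def accuracy(self) -> float:
        return round((self.tp + self.tn) / self.total * 100.0, 2)

    @property
    def sensitivity(self) -> float:
        return round(self.tp / (self.tp + self.fn) * 100.0, 2)

    @property
    def specificity(self) -> float:
        return round(self.tn / (self.tn + self.fp) * 100.0, 2)

    @property
    def precision(self) -> float:
        return round(self.tp / (self.tp + self.fp) * 100.0, 2) if self.tp + self.fp else 0.0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "auc": round(self.auc, 4),
        }


def classification_report(predicted, decision_values, labels,
                          patient_label: str = "MHE") -> ClassificationReport:
    """Confusion counts and AUC from pooled outer-fold predictions."""
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    if len(predicted) != len(labels) or len(predicted) != len(decision_values):
        raise ValueError("predictions, decisions and labels must align")
    pos = labels == patient_label
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    pred_pos = predicted == patient_label
    tp = int((pos & pred_pos).sum())
    fp = int((~pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    return ClassificationReport(tp=tp, fp=fp, fn=fn, tn=tn,
                                auc=auc_rank(np.asarray(decision_values), pos))


def roc_points(decision_values, labels, patient_label: str = "MHE") -> pd.DataFrame:
    """Monotone ROC staircase from (0,0) to (1,1); its trapezoidal area
    equals the rank-statistic AUC."""
    labels = np.asarray(labels)
    pos = labels == patient_label
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(pos.astype(int), np.asarray(decision_values, dtype=float),
                                drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def counts_from_rates(sensitivity_pct: float, specificity_pct: float,
                      n_patients: int, n_controls: int) -> tuple[int, int, int, int]:
    """Recover integer confusion counts (TP, FP, FN, TN) from printed
    sensitivity/specificity percentages at known group sizes."""
    tp = round(sensitivity_pct / 100.0 * n_patients)
    tn = round(specificity_pct / 100.0 * n_controls)
    return int(tp), int(n_controls - tn), int(n_patients - tp), int(tn)
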