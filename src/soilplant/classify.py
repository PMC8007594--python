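"""Supervised plant/soil classification on attribute-profile features.

The classifier is an RBF-kernel support vector machine; with two classes
the one-against-one multiclass scheme reduces to a single binary machine.
Features are z-scored with statistics estimated on the training samples
only (the scaler travels inside the fitted pipeline, so no test-fold
information leaks into standardization). Accuracy reporting follows the
usual remote-sensing conventions: per-class accuracy, overall accuracy,
and Cohen's kappa, averaged over stratified k-fold with their
fold-to-fold standard deviations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grids import GeoGrid
from .morphology import AttributeProfileStack

LABELS = ("soil", "plant")  # encoded 0 / 1
UNCLASSIFIED = 2


@dataclass
class TrainingSet:
    """Labeled feature vectors with pixel provenance."""

    features: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray    # 0 = soil, 1 = plant
    pixel_rows: np.ndarray | None = None
    pixel_cols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, float)
        self.labels = np.asarray(self.labels, int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree in length")
        if np.unique(self.labels).size < 2:
            raise ValueError("training set must contain both classes")


def extract_training_samples(profile: AttributeProfileStack,
                             truth_mask: GeoGrid,
                             n_per_class: int = 1000,
                             seed: int = 0) -> TrainingSet:
    """Randomly subsample labeled pixels, stratified per class."""
    rng = np.random.default_rng(seed)
    table = profile.as_table()
    labels = truth_mask.values.ravel()
    idx = []
    for cls in (0, 1):
        pool = np.flatnonzero(labels == cls)
        if pool.size == 0:
            raise ValueError(f"no pixels labeled {LABELS[cls]!r}")
        take = min(n_per_class, pool.size)
        idx.append(rng.choice(pool, size=take, replace=False))
    idx = np.concatenate(idx)
    rows, cols = np.unravel_index(idx, profile.shape)
    return TrainingSet(table[idx], labels[idx].astype(int), rows, cols)


def _make_pipeline(c: float, gamma) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(C=c, gamma=gamma, kernel="rbf", cache_size=500)),
    ])


def train_svm(train: TrainingSet, rbf_gamma="scale", c: float = 10.0) -> Pipeline:
    """Fit the scaler + RBF-SVM pipeline on a training set.

    ``rbf_gamma="scale"`` is the 1 / (n_features * feature_variance)
    heuristic; pass a float to override.
    """
    counts = np.bincount(train.labels, minlength=2)
    if (counts < 10).any():
        raise ValueError("need at least 10 samples per class")
    model = _make_pipeline(c, rbf_gamma)
    model.fit(train.features, train.labels)
    return model


def predict_mask(model: Pipeline, profile: AttributeProfileStack,
                 valid: np.ndarray | None = None,
                 chunk: int = 200_000,
                 margin_threshold: float | None = None) -> GeoGrid:
    """Classify every pixel of a profile into a binary plant mask.

    ``valid`` marks pixels to classify; the rest propagate as nodata.
    When ``margin_threshold`` is set, pixels whose absolute SVM decision
    value falls below it are labeled UNCLASSIFIED (2) instead of being
    forced into a class.
    """
    n_feat = model.named_steps["svm"].n_features_in_
    if profile.n_features != n_feat:
        raise ValueError(
            f"profile has {profile.n_features} features, model expects {n_feat}")
    table = profile.as_table()
    n = table.shape[0]
    out = np.full(n, 255, dtype=np.uint8)
    sel = np.arange(n) if valid is None else np.flatnonzero(np.ravel(valid))
    for start in range(0, sel.size, chunk):
        part = sel[start:start + chunk]
        block = table[part]
        pred = model.predict(block).astype(np.uint8)
        if margin_threshold is not None:
            dec = np.abs(model.decision_function(block))
            pred[dec < margin_threshold] = UNCLASSIFIED
        out[part] = pred
    return GeoGrid(out.reshape(profile.shape), cell_size=1.0, origin=(0, 0),
                   nodata=255)


def predict_mask_like(model, profile, template: GeoGrid,
                      valid=None, **kw) -> GeoGrid:
    """predict_mask with georeferencing copied from a template grid."""
    raw = predict_mask(model, profile, valid=valid, **kw)
    return template.like(raw.values, nodata=255)


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from a confusion
    matrix with rows = true, columns = predicted."""
    cm = np.asarray(confusion, float)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=0) * cm.sum(axis=1)).sum()) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class ClassificationReport:
    """k-fold accuracy summary (means and across-fold standard deviations)."""

    per_class_accuracy: dict
    per_class_sd: dict
    overall_accuracy: float
    overall_sd: float
    kappa: float
    kappa_sd: float
    folds: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def __str__(self) -> str:
        lines = [f"{'class':<8}{'accuracy':>10}{'sd':>8}"]
        for cls in LABELS:
            lines.append(f"{cls:<8}{self.per_class_accuracy[cls]:>10.4f}"
                         f"{self.per_class_sd[cls]:>8.4f}")
        lines.append(f"{'OA':<8}{self.overall_accuracy:>10.4f}{self.overall_sd:>8.4f}")
        lines.append(f"{'kappa':<8}{self.kappa:>10.4f}{self.kappa_sd:>8.4f}")
        return "\n".join(lines)


def kfold_report(train: TrainingSet, k: int = 5, seed: int = 0,
                 c: float = 10.0, rbf_gamma="scale") -> ClassificationReport:
    """Stratified k-fold accuracy assessment of the SVM classifier."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(train.labels, minlength=2)
    if (counts < k).any():
        raise ValueError("every class needs at least k samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = {cls: [] for cls in LABELS}
    oas, kappas = [], []
    for tr, te in skf.split(train.features, train.labels):
        model = _make_pipeline(c, rbf_gamma)
        model.fit(train.features[tr], train.labels[tr])
        pred = model.predict(train.features[te])
        truth = train.labels[te]
        cm = np.zeros((2, 2))
        np.add.at(cm, (truth, pred), 1)
        for ci, cls in enumerate(LABELS):
            row = cm[ci]
            accs[cls].append(row[ci] / row.sum() if row.sum() else np.nan)
        oas.append(np.trace(cm) / cm.sum())
        kappas.append(cohen_kappa(cm))
    return ClassificationReport(
        per_class_accuracy={c_: float(np.mean(a)) for c_, a in accs.items()},
        per_class_sd={c_: float(np.std(a)) for c_, a in accs.items()},
        overall_accuracy=float(np.mean(oas)), overall_sd=float(np.std(oas)),
        kappa=float(np.mean(kappas)), kappa_sd=float(np.std(kappas)),
        folds=k)
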