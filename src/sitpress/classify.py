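"""Min-max normalisation, RBF-SVM training with inner grid search, and
leave-one-subject-out (LOSO) evaluation with confusion-matrix metrics.

Conventions fixed here for determinism:

* features are min-max scaled to [0, 1] on the training set only;
  constant features map to 0.5, unseen values are *not* clipped;
* multiclass SVM uses one-vs-one voting with ties broken by the class
  order NC < TR < TLF < SE (labels are encoded as integers in that
  order, so the lowest-index winner is deterministic);
* (C, gamma) are chosen by an inner stratified 5-fold cross-validation
  maximising macro-F1 of the pooled inner predictions, first best wins;
* macro-F1 is the unweighted mean of the per-class F1 scores; the
  pooled (micro) F1 is reported alongside.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from sitpress.features import FEATURE_NAMES
from sitpress.io import CLASS_ORDER, MotionClass

__all__ = [
    "DEFAULT_HYPER_GRID",
    "MinMaxNormalizer",
    "TrainedModel",
    "CVResult",
    "fit_normalizer",
    "confusion_matrix",
    "precision_recall_f1",
    "macro_f1",
    "micro_f1",
    "train_model",
    "predict",
    "decision_confidence",
    "loso_cv",
    "save_model",
    "load_model",
]

CLASS_NAMES: tuple[str, ...] = tuple(c.value for c in CLASS_ORDER)

# Powers-of-two grid over C in [2^-3, 2^7], gamma in [2^-7, 2^3].
# Exponent step 2 keeps the inner search tractable on one CPU; pass a
# finer grid for exhaustive search.
DEFAULT_HYPER_GRID: dict[str, tuple[float, ...]] = {
    "C": tuple(2.0**e for e in range(-3, 8, 2)),
    "gamma": tuple(2.0**e for e in range(-7, 4, 2)),
}


@dataclasses.dataclass
class MinMaxNormalizer:
    """Per-feature (min, max) learned on training data."""

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.maxs - self.mins
        out = np.empty_like(X)
        const = span <= 0
        out[:, const] = 0.5
        out[:, ~const] = (X[:, ~const] - self.mins[~const]) / span[~const]
        return out


def fit_normalizer(X: np.ndarray | Sequence) -> MinMaxNormalizer:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a non-empty 2-D feature matrix")
    return MinMaxNormalizer(mins=X.min(axis=0), maxs=X.max(axis=0))


@dataclasses.dataclass
class TrainedModel:
    """Fitted RBF-SVM bundle: scaler, hyperparameters, class/feature order."""

    svc: SVC
    normalizer: MinMaxNormalizer
    C: float
    gamma: float
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    inner_cv_f1: float
    train_hash: str

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


class ArityError(ValueError):
    pass


def _check_X(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ArityError(
            f"model expects {model.n_features} features, got {X.shape[1]}"
        )
    return X


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str] = CLASS_NAMES
) -> np.ndarray:
    """Integer count matrix, rows = actual class, columns = predicted."""
    index = {c: k for k, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        cm[index[str(t)], index[str(p)]] += 1
    return cm


def precision_recall_f1(
    cm: np.ndarray, cls: str, classes: Sequence[str] = CLASS_NAMES
) -> tuple[float, float, float]:
    """One-vs-rest precision, recall and F1 for one class of a count matrix.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2*precision*recall/(precision+recall); every 0/0 is 0 by
    convention.
    """
    classes = list(classes)
    if cls not in classes:
        raise ValueError(f"unknown class {cls!r}")
    k = classes.index(cls)
    cm = np.asarray(cm)
    tp = float(cm[k, k])
    fp = float(cm[:, k].sum() - cm[k, k])
    fn = float(cm[k, :].sum() - cm[k, k])
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def macro_f1(cm: np.ndarray, classes: Sequence[str] = CLASS_NAMES) -> float:
    """Unweighted mean of the per-class F1 scores."""
    return float(np.mean([precision_recall_f1(cm, c, classes)[2] for c in classes]))


def micro_f1(cm: np.ndarray) -> float:
    """Pooled (micro-averaged) F1 = overall accuracy for single-label data."""
    cm = np.asarray(cm)
    total = cm.sum()
    return float(np.trace(cm) / total) if total > 0 else 0.0


def _encode(y: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    index = {c: k for k, c in enumerate(classes)}
    try:
        return np.array([index[str(v)] for v in y])
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}") from exc


def _grid_pairs(hyper_grid: dict) -> list[tuple[float, float]]:
    Cs, gammas = hyper_grid["C"], hyper_grid["gamma"]
    if len(Cs) == 0 or len(gammas) == 0:
        raise ValueError("degenerate hyperparameter grid")
    return [(float(C), float(g)) for C in Cs for g in gammas]


def inner_cv_f1(
    X: np.ndarray,
    y: Sequence[str],
    C: float,
    gamma: float,
    seed: int = 0,
    n_folds: int = 5,
    classes: Sequence[str] = CLASS_NAMES,
) -> float:
    """Macro-F1 of pooled stratified k-fold predictions for one (C, gamma).

    The normalizer is refit inside every fold so held-in statistics never
    see the validation split.
    """
    X = np.asarray(X, dtype=float)
    y_enc = _encode(y, classes)
    present = sorted(set(y_enc))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    for tr, va in skf.split(X, y_enc):
        norm = fit_normalizer(X[tr])
        svc = SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovo")
        svc.fit(norm.transform(X[tr]), y_enc[tr])
        pred = svc.predict(norm.transform(X[va]))
        for t, p in zip(y_enc[va], pred):
            pooled[t, p] += 1
    # Score only over classes present in the data (matters for 2-class tests).
    return float(
        np.mean([precision_recall_f1(pooled, classes[k], classes)[2] for k in present])
    )


def train_model(
    features: pd.DataFrame,
    hyper_grid: dict | None = None,
    seed: int = 0,
    label_col: str = "label",
    feature_names: Sequence[str] = FEATURE_NAMES,
    classes: Sequence[str] = CLASS_NAMES,
) -> TrainedModel:
    """Grid-search (C, gamma) by inner stratified 5-fold CV, then fit.

    ``features`` is a dataframe with one row per trial, a ``label``
    column and the ten feature columns.  Rows are shuffled with ``seed``
    before fitting.  Deterministic given (features, grid, seed).
    """
    hyper_grid = hyper_grid or DEFAULT_HYPER_GRID
    df = features.reset_index(drop=True)
    present = sorted(df[label_col].unique())
    if len(present) < 2:
        raise ValueError("need at least 2 classes to train")
    counts = df[label_col].value_counts()
    if counts.min() < 5:
        raise ValueError(
            f"need >= 5 examples per class, got {counts.min()} for {counts.idxmin()!r}"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)

    X = df[list(feature_names)].to_numpy(dtype=float)
    y = df[label_col].to_numpy()

    best: tuple[float, float, float] | None = None  # (score, C, gamma)
    for C, gamma in _grid_pairs(hyper_grid):
        score = inner_cv_f1(X, y, C, gamma, seed=seed, classes=classes)
        if best is None or score > best[0]:
            best = (score, C, gamma)
    best_score, best_C, best_gamma = best

    normalizer = fit_normalizer(X)
    svc = SVC(
        kernel="rbf", C=best_C, gamma=best_gamma, decision_function_shape="ovo"
    )
    svc.fit(normalizer.transform(X), _encode(y, classes))

    digest = hashlib.sha256(
        np.ascontiguousarray(X).tobytes() + "".join(map(str, y)).encode()
    ).hexdigest()[:16]
    return TrainedModel(
        svc=svc,
        normalizer=normalizer,
        C=best_C,
        gamma=best_gamma,
        classes=tuple(classes),
        feature_names=tuple(feature_names),
        inner_cv_f1=best_score,
        train_hash=digest,
    )


def predict(model: TrainedModel, X: np.ndarray | Sequence) -> list[str]:
    """Class labels for rows of ``X`` (raw feature scale). Deterministic."""
    X = _check_X(model, X)
    codes = model.svc.predict(model.normalizer.transform(X))
    return [model.classes[int(k)] for k in codes]


def decision_confidence(model: TrainedModel, X: np.ndarray | Sequence) -> np.ndarray:
    """One-vs-one vote share of the winning class, in [0, 1] per row."""
    X = _check_X(model, X)
    dec = model.svc.decision_function(model.normalizer.transform(X))
    if dec.ndim == 1:  # binary model: single pairwise margin
        dec = dec[:, None]
    present = model.svc.classes_
    n_cls = len(present)
    votes = np.zeros((len(X), n_cls))
    k = 0
    for a in range(n_cls):
        for b in range(a + 1, n_cls):
            wins_a = dec[:, k] > 0
            votes[wins_a, a] += 1
            votes[~wins_a, b] += 1
            k += 1
    return votes.max(axis=1) / max(n_cls - 1, 1)


@dataclasses.dataclass
class CVResult:
    """Leave-one-subject-out result: per-fold and pooled confusion counts."""

    fold_subjects: list[str]
    fold_matrices: list[np.ndarray]
    fold_hyperparams: list[tuple[float, float]]
    pooled: np.ndarray
    classes: tuple[str, ...]

    @property
    def per_class(self) -> dict[str, tuple[float, float, float]]:
        return {
            c: precision_recall_f1(self.pooled, c, self.classes) for c in self.classes
        }

    @property
    def macro_f1(self) -> float:
        return macro_f1(self.pooled, self.classes)

    @property
    def micro_f1(self) -> float:
        return micro_f1(self.pooled)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, "precision": p, "recall": r, "f1": f}
            for c, (p, r, f) in self.per_class.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "folds": [
                {
                    "subject": s,
                    "confusion": m.tolist(),
                    "C": hp[0],
                    "gamma": hp[1],
                }
                for s, m, hp in zip(
                    self.fold_subjects, self.fold_matrices, self.fold_hyperparams
                )
            ],
            "pooled_confusion": self.pooled.tolist(),
            "per_class": {
                c: {"precision": p, "recall": r, "f1": f}
                for c, (p, r, f) in self.per_class.items()
            },
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
        }


def loso_cv(
    features: pd.DataFrame,
    hyper_grid: dict | None = None,
    seed: int = 0,
    classes: Sequence[str] = CLASS_NAMES,
) -> CVResult:
    """Leave-one-subject-out cross-validation.

    One fold per subject; the held-out subject's rows contribute nothing
    to that fold's normalizer, hyperparameter choice, or fit.
    """
    subjects = sorted(features["subject_id"].astype(str).unique())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    counts = features["subject_id"].value_counts()
    if counts.min() < 1:
        raise ValueError("every subject needs at least 1 trial")

    fold_matrices, fold_hyper = [], []
    for subject in subjects:
        held = features["subject_id"].astype(str) == subject
        model = train_model(features[~held], hyper_grid=hyper_grid, seed=seed)
        X_te = features.loc[held, list(model.feature_names)].to_numpy(dtype=float)
        y_te = features.loc[held, "label"].tolist()
        pred = predict(model, X_te)
        fold_matrices.append(confusion_matrix(y_te, pred, classes))
        fold_hyper.append((model.C, model.gamma))

    pooled = np.sum(fold_matrices, axis=0)
    return CVResult(
        fold_subjects=subjects,
        fold_matrices=fold_matrices,
        fold_hyperparams=fold_hyper,
        pooled=pooled,
        classes=tuple(classes),
    )


def save_model(model: TrainedModel, path: str | Path) -> Path:
    path = Path(path)
    joblib.dump(model, path)
    return path


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not contain a TrainedModel bundle")
    return model
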