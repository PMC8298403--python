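"""Six-class finger-movement classification and macro-averaged metrics.

Flexion and extension sessions are separate problems.  The feature matrix
(88 columns) is split by repetition: repetitions 1, 2, 4, 5 of every
movement from all participants train the model; repetition 3 is the held-
out test set.  Three classifier families are compared — discriminant
analysis (linear/quadratic), SVM (linear/polynomial/RBF kernels), and
k-nearest neighbours (k = 1..25) — with hyperparameters chosen by 10-fold
cross-validated accuracy on the training set over a fixed documented grid.

Evaluation metrics are macro-averaged over the C = 6 classes:

    accuracy  = (1/C) sum_i (tp_i + tn_i) / (tp_i + fn_i + fp_i + tn_i)
    precision = (1/C) sum_i tp_i / (tp_i + fp_i)
    recall    = (1/C) sum_i tp_i / (tp_i + fn_i)
    macro F1  = 2 p_M r_M / (p_M + r_M)

Distance- and margin-based models (SVM, kNN) see z-scored features
(training-set statistics only); discriminant analysis runs on the raw
features, whose within-class covariance it models directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FeatureMatrix


@dataclass
class SplitSpec:
    """Leave-repetition-3-out split."""

    train_repetitions: frozenset[int] = frozenset({1, 2, 4, 5})
    test_repetitions: frozenset[int] = frozenset({3})

    def __post_init__(self) -> None:
        if self.train_repetitions & self.test_repetitions:
            raise ValueError("train and test repetitions must be disjoint")
        if not self.test_repetitions or not self.train_repetitions:
            raise ValueError("train and test repetition sets must be non-empty")
        if not (self.train_repetitions | self.test_repetitions) <= set(range(1, 6)):
            raise ValueError("repetitions must be within 1..5")


@dataclass
class ClassifierSpec:
    """Classifier family plus its hyperparameter search space."""

    kind: Literal["DA", "SVM", "kNN"] = "DA"
    cv_folds: int = 10
    tuning_seed: int = 0
    knn_k_max: int = 25
    svm_box_constraints: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.kind not in ("DA", "SVM", "kNN"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class ClassificationReport:
    """Confusion matrix plus macro metrics for one classifier run."""

    classifier: str
    classes: list[str]
    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    macro_f1: float
    overall_accuracy: float  # trace / total, for context
    per_class_precision: np.ndarray = field(default_factory=lambda: np.array([]))
    per_class_recall: np.ndarray = field(default_factory=lambda: np.array([]))
    hyperparameters: dict = field(default_factory=dict)


def split(fm: FeatureMatrix, spec: SplitSpec | None = None) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split by repetition index; every (participant, movement) must carry
    all repetitions named in the spec."""
    spec = spec or SplitSpec()
    needed = spec.train_repetitions | spec.test_repetitions
    for (pid, code), grp in fm.df.groupby(["participant_id", "movement_code"]):
        have = set(grp["repetition_index"].unique())
        if not needed <= have:
            raise ValueError(
                f"participant {pid} movement {code}: missing repetitions "
                f"{sorted(needed - have)}"
            )
    train = fm.select(repetition_index=spec.train_repetitions)
    test = fm.select(repetition_index=spec.test_repetitions)
    assert len(train) + len(test) <= len(fm)
    return train, test


def _estimator_and_grid(spec: ClassifierSpec):
    if spec.kind == "DA":
        est = Pipeline([("clf", LinearDiscriminantAnalysis())])
        grid = [
            {"clf": [LinearDiscriminantAnalysis()]},
            {"clf": [QuadraticDiscriminantAnalysis(reg_param=1e-3)]},
        ]
    elif spec.kind == "SVM":
        est = Pipeline([("scale", StandardScaler()), ("clf", SVC())])
        grid = [
            {
                "clf__kernel": ["linear"],
                "clf__C": list(spec.svm_box_constraints),
            },
            {
                "clf__kernel": ["poly"],
                "clf__degree": [2, 3],
                "clf__C": list(spec.svm_box_constraints),
            },
            {
                "clf__kernel": ["rbf"],
                "clf__gamma": ["scale", 0.01, 0.1],
                "clf__C": list(spec.svm_box_constraints),
            },
        ]
    else:  # kNN
        est = Pipeline([("scale", StandardScaler()), ("clf", KNeighborsClassifier())])
        grid = {
            "clf__n_neighbors": list(range(1, spec.knn_k_max + 1)),
            "clf__metric": ["euclidean"],
        }
    return est, grid


def tune_fit(train: FeatureMatrix, spec: ClassifierSpec):
    """Grid search by mean 10-fold CV accuracy; refit on the full training set.

    Returns ``(fitted_estimator, chosen_hyperparameters)``; deterministic
    given ``tuning_seed``.
    """
    X = train.values
    y = train.df["movement_code"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < spec.cv_folds:
        raise ValueError(
            f"class {classes[counts.argmin()]} has {counts.min()} rows; "
            f"need >= {spec.cv_folds} for {spec.cv_folds}-fold CV"
        )
    est, grid = _estimator_and_grid(spec)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.tuning_seed)
    search = GridSearchCV(est, grid, scoring="accuracy", cv=cv, n_jobs=None, refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QDA collinearity warnings on folds
        search.fit(X, y)
    chosen = {
        k: (type(v).__name__ if k == "clf" else v)
        for k, v in search.best_params_.items()
    }
    chosen["cv_accuracy"] = float(search.best_score_)
    return search.best_estimator_, chosen


def macro_metrics(confusion: np.ndarray, printed_precision_form: bool = False):
    """Macro-averaged accuracy / precision / recall / F1 from a confusion matrix.

    ``printed_precision_form=True`` swaps precision for the per-class error
    rate ``(fp+fn)/total`` (a historically printed variant, kept only for
    fidelity experiments).
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {c.shape}")
    if np.any(c < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix is all zero")
    tp = np.diag(c)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = total - tp - fn - fp

    accuracy = float(np.mean((tp + tn) / total))
    denom_p = tp + fp
    if np.any(denom_p == 0):
        warnings.warn(
            "class never predicted: its precision contributes 0", stacklevel=2
        )
    per_precision = np.divide(tp, denom_p, out=np.zeros_like(tp), where=denom_p > 0)
    if printed_precision_form:
        per_precision = (fp + fn) / total
    denom_r = tp + fn
    per_recall = np.divide(tp, denom_r, out=np.zeros_like(tp), where=denom_r > 0)
    p_m = float(per_precision.mean())
    r_m = float(per_recall.mean())
    f1 = 2 * p_m * r_m / (p_m + r_m) if (p_m + r_m) > 0 else 0.0
    return accuracy, p_m, r_m, f1, per_precision, per_recall


def evaluate(model, test: FeatureMatrix, classifier_name: str = "",
             hyperparameters: dict | None = None) -> ClassificationReport:
    """Confusion matrix and macro metrics on the held-out test set."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    y_true = test.df["movement_code"].to_numpy()
    classes = sorted(np.unique(y_true))
    if len(classes) < 2:
        raise ValueError("test set must contain all classes")
    y_pred = model.predict(test.values)
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx.get(p, -1)] += 1
    acc, prec, rec, f1, pp, pr = macro_metrics(conf)
    return ClassificationReport(
        classifier=classifier_name,
        classes=list(classes),
        confusion=conf,
        accuracy=acc,
        precision=prec,
        recall=rec,
        macro_f1=f1,
        overall_accuracy=float(np.trace(conf) / conf.sum()),
        per_class_precision=pp,
        per_class_recall=pr,
        hyperparameters=hyperparameters or {},
    )


def run_classification(
    fm: FeatureMatrix,
    kinds: tuple[str, ...] = ("DA", "SVM", "kNN"),
    split_spec: SplitSpec | None = None,
    tuning_seed: int = 0,
) -> dict[str, ClassificationReport]:
    """Split, tune, fit, and evaluate each requested classifier family.

    Control movements (codes 7-8) are excluded before splitting.
    """
    task = fm.df[~fm.df["movement_code"].str[1:].astype(int).isin([7, 8])]
    train, test = split(FeatureMatrix(task), split_spec)
    out = {}
    for kind in kinds:
        spec = ClassifierSpec(kind=kind, tuning_seed=tuning_seed)  # type: ignore[arg-type]
        model, chosen = tune_fit(train, spec)
        out[kind] = evaluate(model, test, classifier_name=kind, hyperparameters=chosen)
    return out
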