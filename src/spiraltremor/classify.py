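"""ET-phenotype classification with leave-one-out cross-validated SVMs.

The classification grid evaluates linear and RBF-kernel SVMs on the feature
sets {T}, {rho} and {T, rho} for two problems: ET versus control (2-class)
and control / ET-0 / ET+1 / ET+2 (4-class).  With 35 subjects, leave-one-out
cross-validation (LOOCV) is used: each subject is predicted by a model
trained on the remaining n-1.  Features are z-scored inside each training
fold only — never using the held-out subject — because T (seconds) and rho
(dimensionless) are incommensurate and RBF kernels are scale sensitive.
For each (feature set, problem), the better of the two kernels is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateInputError, InvalidParameterError

KERNELS = ("linear", "rbf")
FEATURE_SETS = (("task_time",), ("psd_ratio",), ("task_time", "psd_ratio"))

ET_LABEL = "ET"
CONTROL_LABEL = "control"


@dataclass(frozen=True)
class ClassifierSpec:
    """One cell of the classification grid."""

    kernel: str = "linear"
    feature_set: tuple[str, ...] = ("task_time", "psd_ratio")
    n_classes: int = 2
    C: float = 1.0
    rbf_scale: str | float = "scale"

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise InvalidParameterError(f"kernel must be one of {KERNELS}")
        if not self.feature_set:
            raise InvalidParameterError("feature_set must be non-empty")
        if self.n_classes not in (2, 4):
            raise InvalidParameterError("n_classes must be 2 or 4")
        if self.C <= 0:
            raise InvalidParameterError("C must be positive")


@dataclass
class ClassificationResult:
    """LOOCV outcome for one classifier spec."""

    spec: ClassifierSpec
    accuracy: float  # percent in [0, 100]
    per_fold_predictions: list[tuple[str, str]]
    confusion: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.per_fold_predictions)
        trace = float(np.trace(self.confusion))
        if n and abs(self.accuracy - 100.0 * trace / n) > 1e-9:
            raise InvalidParameterError("accuracy inconsistent with confusion matrix")


def loocv_accuracy(features, labels, spec: ClassifierSpec) -> ClassificationResult:
    """Leave-one-out cross-validated SVM accuracy.

    For each instance i the remaining n-1 instances are z-scored, the SVM is
    fitted on them, and instance i (transformed with the training-fold
    statistics) is predicted.  Multiclass problems use the SVM's standard
    one-vs-one decomposition; decision-value ties resolve to the
    lexicographically first class (scikit-learn's deterministic behaviour).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(labels).size > 1:
        X = X.T
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise InvalidParameterError("features and labels disagree in length")
    if not np.all(np.isfinite(X)):
        raise InvalidParameterError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DegenerateInputError("LOOCV needs at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt == 1:
            warnings.warn(
                f"class {cls!r} has a single member; its fold trains without it",
                stacklevel=2,
            )

    preds: list[tuple[str, str]] = []
    n = X.shape[0]
    for i in range(n):
        train = np.delete(np.arange(n), i)
        if np.unique(y[train]).size < 2:
            # the held-out subject was a class's only member: the fold
            # degenerates to a constant classifier on the remaining class
            preds.append((str(y[i]), str(y[train][0])))
            continue
        model = make_pipeline(
            StandardScaler(),
            SVC(kernel=spec.kernel, C=spec.C, gamma=spec.rbf_scale),
        )
        model.fit(X[train], y[train])
        pred = model.predict(X[i : i + 1])[0]
        preds.append((str(y[i]), str(pred)))

    true = [t for t, _ in preds]
    hat = [p for _, p in preds]
    label_order = sorted(set(true) | set(hat))
    conf = confusion_matrix(true, hat, labels=label_order)
    accuracy = 100.0 * float(np.trace(conf)) / n
    return ClassificationResult(
        spec=spec,
        accuracy=accuracy,
        per_fold_predictions=preds,
        confusion=conf,
        classes=tuple(label_order),
    )


def _labels_for(cohort_site: pd.DataFrame, n_classes: int) -> np.ndarray:
    groups = cohort_site["group"].astype(str).to_numpy()
    if n_classes == 4:
        return groups
    return np.where(groups == CONTROL_LABEL, CONTROL_LABEL, ET_LABEL)


def run_classification_grid(
    cohort: pd.DataFrame,
    site: str = "S2",
    C: float = 1.0,
    rbf_scale: str | float = "scale",
) -> list[ClassificationResult]:
    """Evaluate the full (feature set x kernel x problem) LOOCV grid.

    ``cohort`` is the joined cohort table (one row per subject x site with
    columns group, site, task_time, psd_ratio).  4-class runs are skipped
    with a warning when a phenotype group is absent.  Returns one result per
    evaluated cell; see :func:`grid_table` for the best-kernel summary.
    """
    sub = cohort[cohort["site"] == site].drop_duplicates("subject_id")
    if sub.empty:
        raise InvalidParameterError(f"no rows for site {site!r}")
    results: list[ClassificationResult] = []
    for n_classes in (2, 4):
        labels = _labels_for(sub, n_classes)
        if n_classes == 4 and len(np.unique(labels)) < 4:
            warnings.warn(
                "cohort lacks all four phenotype groups; skipping 4-class runs",
                stacklevel=2,
            )
            continue
        for feature_set in FEATURE_SETS:
            X = sub[list(feature_set)].to_numpy(dtype=float)
            for kernel in KERNELS:
                spec = ClassifierSpec(
                    kernel=kernel,
                    feature_set=feature_set,
                    n_classes=n_classes,
                    C=C,
                    rbf_scale=rbf_scale,
                )
                results.append(loocv_accuracy(X, labels, spec))
    return results


def grid_table(results: list[ClassificationResult]) -> pd.DataFrame:
    """Best-kernel accuracy per (feature set, problem): the reported grid.

    Ties between kernels resolve to the linear kernel (simpler model first).
    """
    rows = []
    seen: dict[tuple[tuple[str, ...], int], ClassificationResult] = {}
    for res in results:
        key = (res.spec.feature_set, res.spec.n_classes)
        best = seen.get(key)
        if (
            best is None
            or res.accuracy > best.accuracy
            or (res.accuracy == best.accuracy and res.spec.kernel == "linear")
        ):
            seen[key] = res
    for (feature_set, n_classes), res in sorted(
        seen.items(), key=lambda kv: (kv[0][1], kv[0][0])
    ):
        rows.append(
            {
                "feature_set": "+".join(feature_set),
                "n_classes": n_classes,
                "best_kernel": res.spec.kernel,
                "accuracy_percent": res.accuracy,
            }
        )
    return pd.DataFrame(rows)
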