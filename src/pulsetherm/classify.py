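"""Leave-one-out cross-validated classification of thermography features.

Two tasks: *detection* (two classes — cotton lint versus any foreign matter)
and *identification* (all twelve classes). Two classifiers: classical LDA
with pooled within-class covariance, and a linear soft-margin SVM (C = 1,
one-vs-one for the multiclass task). Each held-out sample is predicted by a
model trained on the remaining n - 1 samples, with feature standardisation
parameters estimated on the training fold only.

Named feature sets mirror the study grid: the two waveform gains and the ten
lowest-frequency amplitudes of the whole, rising and falling spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .stats import feature_matrix
from .synthdata import CLASS_NAMES

TASKS = ("detection", "identification")
CLASSIFIERS = ("lda", "svm")

COTTON_LABEL = "cotton"
FOREIGN_LABEL = "foreign_matter"

#: Table-layout feature sets: name -> (column prefix, count).
FEATURE_SETS = {
    "waveform": (["wf_peak_minus_rest", "wf_final_minus_rest"], 2),
    "whole_amp_1_10": ([f"amp_whole_{k}" for k in range(10)], 10),
    "rising_amp_1_10": ([f"amp_rising_{k}" for k in range(10)], 10),
    "falling_amp_1_10": ([f"amp_falling_{k}" for k in range(10)], 10),
}


@dataclass(frozen=True)
class TaskSpec:
    """One classification run: task, classifier and named feature set."""

    task: str
    classifier: str
    feature_set: str = "whole_amp_1_10"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")


@dataclass
class ClassificationReport:
    """LOOCV predictions, accuracy and confusion matrix for one task."""

    spec: TaskSpec
    predictions: np.ndarray
    true_labels: np.ndarray
    classes: list[str]
    confusion: pd.DataFrame = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracy = float(np.mean(self.predictions == self.true_labels))
        counts = pd.DataFrame(0, index=self.classes, columns=self.classes, dtype=int)
        for t, p in zip(self.true_labels, self.predictions):
            counts.loc[t, p] += 1
        self.confusion = counts


def detection_labels(labels) -> np.ndarray:
    """Collapse the 12-class vocabulary to cotton vs foreign matter."""
    labels = np.asarray(labels, dtype=object)
    unknown = set(labels) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    return np.where(labels == COTTON_LABEL, COTTON_LABEL, FOREIGN_LABEL)


def _make_estimator(classifier: str) -> Pipeline:
    if classifier == "lda":
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
    else:
        clf = SVC(kernel="linear", C=1.0, decision_function_shape="ovo")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def loocv(table: pd.DataFrame, spec: TaskSpec,
          columns: list[str] | None = None) -> ClassificationReport:
    """Leave-one-out cross-validated classification of a feature table.

    Deterministic for a given table and spec, and invariant to the order of
    the rows. The LDA falls back to shrinkage if the pooled covariance of a
    training fold is singular.
    """
    if columns is None:
        columns, _ = FEATURE_SETS[spec.feature_set]
    X, labels, _ = feature_matrix(table, columns)
    y = detection_labels(labels) if spec.task == "detection" else labels.astype(object)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("classification requires at least 2 classes")
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples for LOOCV")

    preds = np.empty(len(y), dtype=object)
    for train, test in LeaveOneOut().split(X):
        est = _make_estimator(spec.classifier)
        try:
            est.fit(X[train], y[train])
        except np.linalg.LinAlgError:
            warnings.warn("singular LDA covariance; refitting with shrinkage")
            est = Pipeline([
                ("scale", StandardScaler()),
                ("clf", LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")),
            ])
            est.fit(X[train], y[train])
        preds[test[0]] = est.predict(X[test])[0]
    return ClassificationReport(
        spec=spec, predictions=preds, true_labels=np.asarray(y, dtype=object),
        classes=classes,
    )


def feature_count_sweep(table: pd.DataFrame, spec: TaskSpec,
                        k_max: int = 15, mode: str = "whole") -> list[float]:
    """LOOCV accuracy for the k lowest-frequency amplitudes, k = 1..k_max.

    Used to pick the working amplitude-feature count before the main
    classification grid.
    """
    all_cols = [c for c in table.columns if c.startswith(f"amp_{mode}_")]
    all_cols.sort(key=lambda c: int(c.rsplit("_", 1)[1]))
    if k_max > len(all_cols):
        raise ValueError(
            f"k_max={k_max} exceeds the {len(all_cols)} available amplitude features"
        )
    accuracies = []
    for k in range(1, k_max + 1):
        report = loocv(table, spec, columns=all_cols[:k])
        accuracies.append(report.accuracy)
    return accuracies


def run_table1(table: pd.DataFrame) -> pd.DataFrame:
    """The full 4 feature sets x 2 tasks x 2 classifiers LOOCV accuracy grid.

    Returns a DataFrame indexed by feature set with a ``n_features`` column
    and one accuracy column per (task, classifier) cell, accuracies as
    fractions.
    """
    missing = [
        name for name, (cols, _) in FEATURE_SETS.items()
        if any(c not in table.columns for c in cols)
    ]
    if missing:
        raise ValueError(f"feature table lacks columns for sets: {missing}")
    rows = {}
    for name, (cols, n_feat) in FEATURE_SETS.items():
        row: dict[str, float] = {"n_features": n_feat}
        for task in TASKS:
            for classifier in CLASSIFIERS:
                report = loocv(table, TaskSpec(task, classifier, name), columns=cols)
                row[f"{task}_{classifier}"] = round(report.accuracy, 4)
        rows[name] = row
    grid = pd.DataFrame.from_dict(rows, orient="index")
    grid.index.name = "feature_set"
    return grid
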