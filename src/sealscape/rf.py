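"""Random-forest validation of the call-type classification.

Out-of-bag predictions of a 500-tree forest are aggregated into a
class-labeled confusion matrix; accuracy is defined as ``1 - OOB error``
and variable importance as the mean decrease in Gini impurity.  Raw class
frequencies are kept (no rebalancing) so correct-classification rates are
comparable with chance rates (class n / total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .repertoire import RF_MTRY, RF_VARIABLES

__all__ = [
    "RFConfig",
    "ConfusionMatrix",
    "RFResult",
    "rf_validate",
    "per_class_error",
    "overall_error",
    "accuracy",
    "chance_rate",
]


@dataclass
class RFConfig:
    """Forest settings: variable set, trees, variables per split, seed."""

    variables: tuple[str, ...]
    mtry: int
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.mtry <= len(self.variables):
            raise ValueError(f"mtry {self.mtry} not in [1, "
                             f"{len(self.variables)}]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    @classmethod
    def for_category(cls, category: str, seed: int = 0,
                     n_trees: int = 500) -> "RFConfig":
        """Category defaults: 6/5/2 variables and mtry 2/2/1."""
        return cls(variables=RF_VARIABLES[category], mtry=RF_MTRY[category],
                   n_trees=n_trees, seed=seed)


@dataclass
class ConfusionMatrix:
    """Count matrix, rows = true class, columns = predicted class."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != ({k},{k})")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype,
                                                        np.integer):
            raise ValueError("counts must be non-negative integers")

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         labels: tuple[str, ...] | None = None
                         ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if labels is None:
            labels = tuple(sorted(set(y_true) | set(y_pred)))
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(labels, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def row_sum(self, label: str) -> int:
        return int(self.counts[self.labels.index(label)].sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


def per_class_error(matrix: ConfusionMatrix, label: str) -> float:
    """(row sum - diagonal) / row sum for one true class."""
    i = matrix.labels.index(label)
    row = matrix.counts[i]
    total = row.sum()
    if total == 0:
        raise ValueError(f"class {label!r} has no samples")
    return float((total - row[i]) / total)


def overall_error(matrix: ConfusionMatrix) -> float:
    """Overall out-of-bag error as a percentage: 100 (total - trace)/total."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (matrix.total - matrix.trace) / matrix.total


def accuracy(matrix: ConfusionMatrix) -> float:
    """Global accuracy in percent: 100 - overall error."""
    return 100.0 - overall_error(matrix)


def chance_rate(matrix: ConfusionMatrix, label: str) -> float:
    """Chance correct-classification rate: class row sum / total."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return matrix.row_sum(label) / matrix.total


@dataclass
class RFResult:
    """Out-of-bag validation summary for one call category."""

    confusion: ConfusionMatrix
    oob_error: float          # fraction
    accuracy: float           # fraction, == 1 - oob_error
    per_class_errors: dict[str, float] = field(default_factory=dict)
    gini_importance: list[tuple[str, float]] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "overall_error_pct": round(self.oob_error * 100.0, 2),
            "accuracy_pct": round(self.accuracy * 100.0, 2),
            "per_class_error": {k: round(v, 3)
                                for k, v in self.per_class_errors.items()},
            "gini_importance": [(v, round(g, 4))
                                for v, g in self.gini_importance],
        }


def rf_validate(features: pd.DataFrame, config: RFConfig,
                label_column: str = "type") -> RFResult:
    """Out-of-bag random-forest validation of a labeled feature table.

    ``features`` must contain ``label_column`` plus every configured
    variable with no missing values.  Importances are reported in
    descending Gini order.
    """
    missing_cols = [v for v in config.variables if v not in features.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks columns {missing_cols}")
    X = features[list(config.variables)].to_numpy(dtype=float)
    y = features[label_column].to_numpy()
    bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if bad.size:
        ids = (features["call_id"].iloc[bad].tolist()
               if "call_id" in features.columns else bad.tolist())
        raise ValueError(f"missing values in rows: {ids[:20]}"
                         + ("..." if bad.size > 20 else ""))
    labels = tuple(sorted(set(y)))
    if len(labels) < 2:
        raise ValueError(f"need >= 2 classes, got {labels}")

    clf = RandomForestClassifier(
        n_estimators=config.n_trees, max_features=config.mtry,
        oob_score=True, bootstrap=True, random_state=config.seed, n_jobs=1)
    clf.fit(X, y)
    oob = clf.oob_decision_function_
    # samples never out of bag (vanishingly rare at 500 trees) fall back to
    # the in-bag prediction
    never = ~np.isfinite(oob).all(axis=1) | (oob.sum(axis=1) <= 0)
    y_pred = np.array(clf.classes_)[np.argmax(np.nan_to_num(oob), axis=1)]
    if never.any():
        y_pred[never] = clf.predict(X[never])

    cm = ConfusionMatrix.from_predictions(y, y_pred, labels)
    err = overall_error(cm) / 100.0
    gini = sorted(zip(config.variables, clf.feature_importances_),
                  key=lambda kv: -kv[1])
    return RFResult(
        confusion=cm, oob_error=err, accuracy=1.0 - err,
        per_class_errors={lab: per_class_error(cm, lab) for lab in labels},
        gini_importance=[(v, float(g)) for v, g in gini])
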