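"""Leave-one-out cross-validated SVM classification of lesion feature tables.

Each lesion is held out in turn; the remaining lesions are standardized
(training-fold mean/SD only — the held-out lesion never contributes, so
there is no information leakage), an SVM is trained, and the held-out
lesion's signed decision value and hard label are recorded. With n lesions
this is n folds / n fits.

Defaults: linear kernel, cost C = 1 (the common "default parameters"
configuration for a soft-margin SVM). Per-fold z-scoring is applied by
default because the texture features span several orders of magnitude; it
can be switched off. A decision score of exactly 0 predicts negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import read_feature_table

__all__ = ["SvmSettings", "FeatureTable", "CVResult", "fit_predict_once", "loocv_svm"]


@dataclass(frozen=True)
class SvmSettings:
    kernel: str = "linear"
    C: float = 1.0
    standardize: bool = True


@dataclass(frozen=True)
class FeatureTable:
    """n_lesions x n_features matrix with ids, binary labels, combination id."""

    lesion_ids: tuple[str, ...]
    matrix: np.ndarray
    labels: np.ndarray
    combination_id: str
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.lesion_ids)
        if self.matrix.shape[0] != n or len(self.labels) != n:
            raise ValueError("inconsistent row counts")
        if n < 4:
            raise ValueError("need at least 4 lesions")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")
        if not (np.any(self.labels == 1) and np.any(self.labels == 0)):
            raise ValueError("both classes must be present")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        feature_cols = [
            c for c in df.columns if c not in ("lesion_id", "combination_id", "label")
        ]
        return cls(
            lesion_ids=tuple(df["lesion_id"].astype(str)),
            matrix=df[feature_cols].to_numpy(dtype=np.float64),
            labels=df["label"].to_numpy(dtype=np.int64),
            combination_id=str(df["combination_id"].iloc[0]),
            feature_names=tuple(feature_cols),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_dataframe(read_feature_table(path))


@dataclass(frozen=True)
class CVResult:
    """Per-lesion LOOCV outcome: true label, hard prediction, decision score."""

    lesion_ids: tuple[str, ...]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    scores: np.ndarray
    combination_id: str = ""
    settings: SvmSettings = field(default_factory=SvmSettings)

    @property
    def n_folds(self) -> int:
        return len(self.lesion_ids)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.true_labels == self.predicted_labels))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lesion_id": self.lesion_ids,
                "true": self.true_labels,
                "pred": self.predicted_labels,
                "score": self.scores,
            }
        )

    def save(self, csv_path: str | Path, seed: int | None = None) -> None:
        """Write predictions CSV plus a JSON sidecar with run metadata."""
        csv_path = Path(csv_path)
        self.to_dataframe().to_csv(csv_path, index=False)
        meta = {
            "combination_id": self.combination_id,
            "kernel": self.settings.kernel,
            "C": self.settings.C,
            "standardize": self.settings.standardize,
            "n_folds": self.n_folds,
            "seed": seed,
        }
        csv_path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # zero-SD features pass through centered
    return (train - mu) / sd, (test - mu) / sd


def fit_predict_once(
    X_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    settings: SvmSettings = SvmSettings(),
) -> tuple[int, float]:
    """Train on one fold and score a single held-out feature vector.

    Returns ``(label, score)``; score > 0 predicts positive (GIST).
    """
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise ValueError("training fold contains a single class")
    x_test = np.atleast_2d(np.asarray(x_test, dtype=np.float64))
    if settings.standardize:
        X_train, x_test = _standardize(X_train, x_test)
    clf = SVC(kernel=settings.kernel, C=settings.C)
    clf.fit(X_train, y_train)
    score = float(clf.decision_function(x_test)[0])
    return (1 if score > 0 else 0), score


def loocv_svm(
    table: FeatureTable, seed: int = 0, settings: SvmSettings = SvmSettings()
) -> CVResult:
    """Leave-one-out cross-validation over a feature table.

    Deterministic given the table; ``seed`` is reserved for solver
    randomization and recorded in run metadata.
    """
    n = len(table.lesion_ids)
    preds = np.empty(n, dtype=np.int64)
    scores = np.empty(n, dtype=np.float64)
    for i in range(n):
        keep = np.arange(n) != i
        y_train = table.labels[keep]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"fold {i} (held-out lesion {table.lesion_ids[i]}) leaves a "
                "single-class training set"
            )
        preds[i], scores[i] = fit_predict_once(
            table.matrix[keep], y_train, table.matrix[i], settings
        )
    return CVResult(
        lesion_ids=table.lesion_ids,
        true_labels=table.labels.copy(),
        predicted_labels=preds,
        scores=scores,
        combination_id=table.combination_id,
        settings=settings,
    )
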