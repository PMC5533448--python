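"""Dataset container, CSV I/O, class accounting and fold splitting.

The central object is :class:`LabeledDataset`: a numeric feature matrix with
binary labels where 1 marks the positive class — by convention the *minority*
(patients, active compounds).  Row order is significant: the windowed adaptive
balancer treats rows as a stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "LabeledDataset",
    "ClassCounts",
    "DegenerateInputError",
    "load_csv",
    "write_csv",
    "imbalance_ratio",
    "kfold_splits",
]


class DegenerateInputError(ValueError):
    """Raised when a dataset cannot support the requested operation
    (single class, empty class, too few rows)."""


@dataclass(frozen=True)
class ClassCounts:
    """Per-class row counts; ``positive`` is the minority by convention."""

    positive: int
    negative: int

    @property
    def total(self) -> int:
        return self.positive + self.negative


@dataclass
class LabeledDataset:
    """Numeric feature matrix with binary labels (1 = positive = minority).

    Parameters
    ----------
    features : (n, d) float array
    labels : (n,) integer array over {0, 1}
    feature_names : length-d list of column names
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, d = self.features.shape
        if n < 2 or d < 1:
            raise ValueError(f"need n >= 2 rows and d >= 1 features, got {n}x{d}")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must contain only 0 and 1")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must match feature count")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> ClassCounts:
        pos = int(np.count_nonzero(self.labels == 1))
        return ClassCounts(positive=pos, negative=self.n_rows - pos)

    def minority_count(self) -> int:
        """Size of the rarer class, verified rather than assumed to be label 1."""
        c = self.class_counts()
        return min(c.positive, c.negative)

    def majority_count(self) -> int:
        c = self.class_counts()
        return max(c.positive, c.negative)

    def subset(self, index: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(index)
        return LabeledDataset(
            self.features[idx], self.labels[idx], list(self.feature_names)
        )


def load_csv(
    path,
    label_column: str | int | None = None,
    positive_label=None,
    allow_majority_positive: bool = False,
) -> LabeledDataset:
    """Read a labeled table from CSV.

    ``label_column`` defaults to the last column.  ``positive_label`` is the
    raw value mapped to 1; it defaults to the rarer label.  Unless
    ``allow_majority_positive`` is set, declaring the majority class as
    positive is an error — the positive class is the minority by convention.
    """
    df = pd.read_csv(path)
    if df.shape[0] < 2:
        raise DegenerateInputError(f"{path}: need at least 2 rows")
    if label_column is None:
        label_column = df.columns[-1]
    elif isinstance(label_column, int):
        label_column = df.columns[label_column]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")

    raw_labels = df[label_column]
    feat_df = df.drop(columns=[label_column])
    numeric = feat_df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~feat_df.isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise ValueError(
            f"{path}: non-numeric value {feat_df.at[row, col]!r} "
            f"in row {row}, column {col!r}"
        )
    if numeric.isna().any().any():
        row = int(numeric.isna().any(axis=1).idxmax())
        col = numeric.columns[numeric.loc[row].isna().to_numpy().argmax()]
        raise ValueError(f"{path}: missing value in row {row}, column {col!r}")

    values, counts = np.unique(raw_labels.to_numpy(), return_counts=True)
    if len(values) < 2:
        raise DegenerateInputError(
            f"{path}: label column {label_column!r} holds a single class"
        )
    if len(values) > 2:
        raise ValueError(
            f"{path}: expected binary labels, found {len(values)} classes"
        )
    if positive_label is None:
        positive_label = values[counts.argmin()]
    elif positive_label not in values:
        raise ValueError(f"positive label {positive_label!r} not present in data")
    labels = (raw_labels.to_numpy() == positive_label).astype(int)
    n_pos = int(labels.sum())
    if n_pos > len(labels) - n_pos and not allow_majority_positive:
        raise ValueError(
            f"declared positive class {positive_label!r} is the majority "
            f"({n_pos}/{len(labels)}); pass allow_majority_positive=True to override"
        )
    return LabeledDataset(numeric.to_numpy(dtype=float), labels,
                          list(numeric.columns))


def write_csv(ds: LabeledDataset, path, label_column: str = "label") -> None:
    """Write the dataset back out in the loader's dialect (header, comma, '.')."""
    df = pd.DataFrame(ds.features, columns=ds.feature_names)
    df[label_column] = ds.labels
    df.to_csv(path, index=False)


def imbalance_ratio(ds: LabeledDataset, direction: str = "maj_over_min") -> float:
    """Quotient of class sizes, ``maj_over_min`` or ``min_over_maj``."""
    c = ds.class_counts()
    if c.positive == 0 or c.negative == 0:
        raise DegenerateInputError("imbalance ratio undefined with an empty class")
    maj, mino = max(c.positive, c.negative), min(c.positive, c.negative)
    if direction == "maj_over_min":
        return maj / mino
    if direction == "min_over_maj":
        return mino / maj
    raise ValueError(f"unknown direction {direction!r}")


def kfold_splits(
    ds: LabeledDataset,
    folds: int = 10,
    stratified: bool = True,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (train, test) index pairs for k-fold cross validation.

    Stratified by default so every fold keeps minority presence; degrades to
    plain k-fold with a warning when a class has fewer members than folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > ds.n_rows:
        raise ValueError(f"folds ({folds}) exceeds number of rows ({ds.n_rows})")
    if stratified and ds.minority_count() < folds:
        warnings.warn(
            f"minority class has {ds.minority_count()} rows < {folds} folds; "
            "falling back to unstratified k-fold",
            stacklevel=2,
        )
        stratified = False
    if stratified:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        it = splitter.split(ds.features, ds.labels)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        it = splitter.split(ds.features)
    return [(tr, te) for tr, te in it]
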