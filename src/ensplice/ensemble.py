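"""Stacking: sub-model binary predictions -> logistic-regression meta-model.

Row *i* of the stacked matrix holds every member's hard 0/1 prediction for
record *i* (for members predicting [1], [1], [1], [0], [1] the row reads
``[1, 1, 1, 0, 1]``); the meta-model is a plain logistic regression over
these rows and never sees the raw sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .data_io import OneHotBatch
from .errors import DegenerateDataError, InputShapeError
from .submodels import predict_binary

#: The six published ensemble membership presets.
ENSEMBLE_PRESETS: dict[str, tuple[str, ...]] = {
    "ENS1": ("DNN1", "DNN2", "DNN3", "DNN4"),
    "ENS2": ("CNN1", "CNN2", "CNN3", "CNN4"),
    "ENS3": ("DNN1", "DNN2", "DNN3", "DNN4", "CNN1", "CNN2", "CNN3", "CNN4"),
    "ENS4": ("CNN1", "CNN2", "CNN3", "DNN1", "DNN3"),
    "ENS5": ("DNN1", "DNN3", "DNN4", "CNN1", "CNN2", "CNN3"),
    "ENS6": ("DNN1", "DNN3", "DNN4", "CNN1", "CNN2"),
}


@dataclass(frozen=True)
class EnsemblePreset:
    name: str
    members: tuple[str, ...]


def preset_members(name: str) -> EnsemblePreset:
    """Look up one of ENS1..ENS6."""
    try:
        return EnsemblePreset(name=name, members=ENSEMBLE_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown ensemble {name!r}; valid names: {', '.join(ENSEMBLE_PRESETS)}"
        ) from None


@dataclass
class StackedMatrix:
    """N x M binary matrix; column j is member j's prediction vector."""

    matrix: np.ndarray
    member_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.member_order):
            raise InputShapeError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.member_order)} members"
            )
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise InputShapeError("stacked entries must be binary")


@dataclass
class MetaModel:
    """Logistic-regression weights over the stacked member predictions."""

    coefficients: np.ndarray
    intercept: float
    member_order: tuple[str, ...]

    @property
    def n_members(self) -> int:
        return len(self.coefficients)


def stack_predictions(
    models: list, batch: OneHotBatch, member_order: tuple[str, ...] | None = None
) -> StackedMatrix:
    """Collect every member's hard predictions into the meta-dataset."""
    if len(models) < 2:
        raise InputShapeError("stacking needs at least 2 member models")
    if member_order is None:
        member_order = tuple(
            getattr(m, "name", f"member{i}") for i, m in enumerate(models)
        )
    columns = [predict_binary(m, batch) for m in models]
    lengths = {len(c) for c in columns}
    if len(lengths) != 1:
        raise InputShapeError(f"inconsistent prediction lengths: {sorted(lengths)}")
    return StackedMatrix(
        matrix=np.column_stack(columns), member_order=tuple(member_order)
    )


def fit_meta(
    stacked: StackedMatrix,
    labels: np.ndarray,
    seed: int = 0,
    c: float = 1.0,
) -> MetaModel:
    """Fit the logistic-regression meta-model on stacked binary predictions.

    A weak ridge penalty (sklearn's default C=1) keeps the fit stable when
    members agree perfectly with the labels.
    """
    labels = np.asarray(labels)
    if len(labels) != len(stacked.matrix):
        raise InputShapeError(
            f"{len(labels)} labels for {len(stacked.matrix)} stacked rows"
        )
    if np.unique(labels).size < 2:
        raise DegenerateDataError("meta-model labels contain a single class")
    lr = LogisticRegression(C=c, solver="lbfgs", max_iter=1000, random_state=seed)
    lr.fit(stacked.matrix, labels)
    return MetaModel(
        coefficients=lr.coef_.ravel().copy(),
        intercept=float(lr.intercept_[0]),
        member_order=stacked.member_order,
    )


def meta_probabilities(meta: MetaModel, stacked: StackedMatrix) -> np.ndarray:
    if stacked.matrix.shape[1] != meta.n_members:
        raise InputShapeError(
            f"stacked matrix has {stacked.matrix.shape[1]} columns for a "
            f"{meta.n_members}-member meta-model"
        )
    z = stacked.matrix @ meta.coefficients + meta.intercept
    return 1.0 / (1.0 + np.exp(-z))


def predict_ensemble(
    meta: MetaModel,
    members: list,
    batch: OneHotBatch,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Final ensemble labels and probabilities for a batch.

    Returns ``(labels, probabilities)``; a record is called a true site when
    its logistic probability is >= ``threshold``.
    """
    stacked = stack_predictions(members, batch, member_order=meta.member_order)
    proba = meta_probabilities(meta, stacked)
    return (proba >= threshold).astype(np.int64), proba
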