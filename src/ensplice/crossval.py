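"""Stratified five-fold cross-validation of ensemble presets and selection
of the representative ensemble by mean accuracy and diversity."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_io import OneHotBatch, SpliceDataset, encode_one_hot
from .ensemble import EnsemblePreset, fit_meta, predict_ensemble, stack_predictions
from .errors import InputShapeError, InsufficientDataError
from .metrics import (
    DiversityReport,
    MetricReport,
    confusion_counts,
    ensemble_diversity,
    metric_report,
)
from .submodels import (
    TrainConfig,
    build_submodel,
    default_schedule,
    predict_binary,
    preset_spec,
    train_submodel,
)


@dataclass
class FoldAssignment:
    """Per-record test-fold index, in [0, k)."""

    fold_index: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


@dataclass
class CVResult:
    ensemble: str
    fold_reports: list[MetricReport]
    member_fold_reports: dict[str, list[MetricReport]]
    fold_diversity: list[DiversityReport]
    mean_accuracy: float
    mean_diversity: DiversityReport


def stratified_folds(dataset: SpliceDataset, k: int, seed: int = 0) -> FoldAssignment:
    """Label-stratified k-fold split, deterministic under ``seed``."""
    labels = dataset.labels
    for cls in (0, 1):
        count = int((labels == cls).sum())
        if count < k:
            raise InsufficientDataError(
                f"class {cls} has {count} records, fewer than k={k}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.full(len(labels), -1, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return FoldAssignment(fold_index=assignment, k=k)


def _member_seed(base_seed: int, member: str, fold: int) -> int:
    # stable per (member, fold) so members are comparable across ensembles
    digest = sum(ord(ch) * (i + 1) for i, ch in enumerate(member))
    return int(np.random.SeedSequence((base_seed, digest, fold)).generate_state(1)[0])


def cross_validate_ensemble(
    preset: EnsemblePreset,
    dataset: SpliceDataset,
    k: int,
    train_config: TrainConfig,
    seed: int = 0,
    use_default_schedules: bool = True,
) -> CVResult:
    """Train and evaluate one ensemble preset across k stratified folds.

    Per fold: every member is trained on the k-1 training folds, the
    meta-model is fitted on that same training portion's stacked
    predictions, and both the ensemble and the members are scored on the
    held-out fold; diversity comes from member correctness on the held-out
    fold.  The fold RNG (``seed``) is independent of the weight RNG
    (``train_config.seed``).
    """
    folds = stratified_folds(dataset, k, seed)
    batch = encode_one_hot(dataset)
    labels = dataset.labels

    fold_reports: list[MetricReport] = []
    member_fold_reports: dict[str, list[MetricReport]] = {
        m: [] for m in preset.members
    }
    fold_diversity: list[DiversityReport] = []

    for fold in range(k):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        train_batch = OneHotBatch(tensor=batch.tensor[tr])
        test_batch = OneHotBatch(tensor=batch.tensor[te])
        y_tr, y_te = labels[tr], labels[te]

        members = []
        correctness = []
        for member in preset.members:
            spec = preset_spec(member)
            cfg = TrainConfig(
                batch_size=train_config.batch_size,
                max_epochs=train_config.max_epochs,
                schedule=default_schedule(member)
                if use_default_schedules
                else train_config.schedule,
                early_stop_patience=train_config.early_stop_patience,
                validation_fraction=train_config.validation_fraction,
                seed=_member_seed(train_config.seed, member, fold),
            )
            try:
                model = build_submodel(spec, dataset.window_length, seed=cfg.seed)
                train_submodel(model, train_batch, y_tr, cfg)
            except Exception as exc:
                raise type(exc)(f"fold {fold}, member {member}: {exc}") from exc
            members.append(model)
            pred = predict_binary(model, test_batch)
            member_fold_reports[member].append(
                metric_report(confusion_counts(pred, y_te))
            )
            correctness.append((pred == y_te).astype(int))

        stacked = stack_predictions(members, train_batch, member_order=preset.members)
        meta = fit_meta(stacked, y_tr, seed=seed)
        ens_pred, _ = predict_ensemble(meta, members, test_batch)
        fold_reports.append(metric_report(confusion_counts(ens_pred, y_te)))
        fold_diversity.append(ensemble_diversity(correctness))

    mean_diversity = DiversityReport(
        correlation=float(np.mean([d.correlation for d in fold_diversity])),
        double_fault=float(np.mean([d.double_fault for d in fold_diversity])),
        disagreement=float(np.mean([d.disagreement for d in fold_diversity])),
        q_statistic=float(np.mean([d.q_statistic for d in fold_diversity])),
        degenerate=frozenset().union(*(d.degenerate for d in fold_diversity)),
    )
    return CVResult(
        ensemble=preset.name,
        fold_reports=fold_reports,
        member_fold_reports=member_fold_reports,
        fold_diversity=fold_diversity,
        mean_accuracy=float(np.mean([r.accuracy for r in fold_reports])),
        mean_diversity=mean_diversity,
    )


def select_best_ensemble(results: list[CVResult]) -> tuple[str, list[dict]]:
    """Rank by mean accuracy, then lower double fault, then lower Q.

    Returns the winning ensemble name and the full ranking table so callers
    can apply their own criterion.
    """
    if not results:
        raise InputShapeError("no cross-validation results to rank")
    ranked = sorted(
        results,
        key=lambda r: (
            -r.mean_accuracy,
            r.mean_diversity.double_fault,
            r.mean_diversity.q_statistic,
        ),
    )
    table = [
        {
            "ensemble": r.ensemble,
            "accuracy": r.mean_accuracy,
            "double_fault": r.mean_diversity.double_fault,
            "correlation": r.mean_diversity.correlation,
            "q_statistic": r.mean_diversity.q_statistic,
            "disagreement": r.mean_diversity.disagreement,
        }
        for r in ranked
    ]
    return ranked[0].ensemble, table
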