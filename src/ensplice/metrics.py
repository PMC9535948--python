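"""Evaluation metrics from confusion counts and pairwise diversity metrics
from classifier-correctness contingency counts.

Seven scalar metrics (accuracy, precision, sensitivity, specificity, MCC,
F1, error rate) are computed from TP/TN/FP/FN.  Four diversity measures
(correlation, double fault, disagreement, Q-statistic) are computed from the
K11/K10/K01/K00 contingency of two classifiers' correctness indicators; the
Q-statistic is Yule's Q, (K11*K00 - K01*K10) / (K11*K00 + K01*K10).

Any ratio with a zero denominator is reported as 0 and recorded in the
report's ``degenerate`` set rather than raising, so cross-validation
aggregation never aborts.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputShapeError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputShapeError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PairContingency:
    """Counts over two classifiers' correctness indicators (1 = right)."""

    k11: int
    k10: int
    k01: int
    k00: int

    def __post_init__(self) -> None:
        if min(self.k11, self.k10, self.k01, self.k00) < 0:
            raise InputShapeError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.k11 + self.k10 + self.k01 + self.k00


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    mcc: float
    f1: float
    error_rate: float
    degenerate: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "degenerate"
        }


@dataclass
class DiversityReport:
    correlation: float
    double_fault: float
    disagreement: float
    q_statistic: float
    degenerate: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "degenerate"
        }


def confusion_counts(pred: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Standard 2x2 tabulation with label 1 as the positive class."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) == 0:
        raise InputShapeError(
            f"pred and truth must be equal-length non-empty vectors, got "
            f"{pred.shape} and {truth.shape}"
        )
    return ConfusionCounts(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )


def _ratio(num: int, den: int, name: str, degenerate: set[str]) -> Fraction:
    if den == 0:
        degenerate.add(name)
        return Fraction(0)
    return Fraction(num, den)


def metric_report(c: ConfusionCounts) -> MetricReport:
    """All seven metrics; exact rational arithmetic except the MCC root."""
    if c.total == 0:
        raise InputShapeError("confusion counts are all zero")
    degenerate: set[str] = set()
    acc = Fraction(c.tp + c.tn, c.total)
    pre = _ratio(c.tp, c.tp + c.fp, "precision", degenerate)
    sn = _ratio(c.tp, c.tp + c.fn, "sensitivity", degenerate)
    sp = _ratio(c.tn, c.tn + c.fp, "specificity", degenerate)
    f1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1", degenerate)
    mcc_den_sq = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if mcc_den_sq == 0:
        degenerate.add("mcc")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_den_sq)
    return MetricReport(
        accuracy=float(acc),
        precision=float(pre),
        sensitivity=float(sn),
        specificity=float(sp),
        mcc=mcc,
        f1=float(f1),
        error_rate=float(1 - acc),
        degenerate=frozenset(degenerate),
    )


def pair_contingency(
    correct_a: Sequence[int], correct_b: Sequence[int]
) -> PairContingency:
    """K^ij counts from two correctness-indicator vectors."""
    a = np.asarray(correct_a)
    b = np.asarray(correct_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise InputShapeError(
            f"correctness vectors must be equal-length non-empty, got "
            f"{a.shape} and {b.shape}"
        )
    return PairContingency(
        k11=int(((a == 1) & (b == 1)).sum()),
        k10=int(((a == 1) & (b == 0)).sum()),
        k01=int(((a == 0) & (b == 1)).sum()),
        k00=int(((a == 0) & (b == 0)).sum()),
    )


def pairwise_diversity(k: PairContingency) -> DiversityReport:
    """Correlation, double fault, disagreement and Yule's Q for one pair."""
    n = k.total
    if n == 0:
        raise InputShapeError("contingency counts are all zero")
    degenerate: set[str] = set()
    df = Fraction(k.k00, n)
    dis = Fraction(k.k01 + k.k10, n)
    num = k.k11 * k.k00 - k.k01 * k.k10
    corr_den_sq = (
        (k.k11 + k.k10) * (k.k01 + k.k00) * (k.k11 + k.k01) * (k.k10 + k.k00)
    )
    if corr_den_sq == 0:
        degenerate.add("correlation")
        corr = 0.0
    else:
        corr = num / math.sqrt(corr_den_sq)
    q_den = k.k11 * k.k00 + k.k01 * k.k10
    if q_den == 0:
        degenerate.add("q_statistic")
        q = Fraction(0)
    else:
        q = Fraction(num, q_den)
    return DiversityReport(
        correlation=corr,
        double_fault=float(df),
        disagreement=float(dis),
        q_statistic=float(q),
        degenerate=frozenset(degenerate),
    )


def ensemble_diversity(
    members_correctness: Sequence[Sequence[int]],
) -> DiversityReport:
    """Unweighted mean of the pairwise diversities over all unordered pairs."""
    if len(members_correctness) < 2:
        raise InputShapeError("ensemble diversity needs >= 2 members")
    reports = [
        pairwise_diversity(pair_contingency(a, b))
        for a, b in combinations(members_correctness, 2)
    ]
    degenerate = frozenset().union(*(r.degenerate for r in reports))
    return DiversityReport(
        correlation=float(np.mean([r.correlation for r in reports])),
        double_fault=float(np.mean([r.double_fault for r in reports])),
        disagreement=float(np.mean([r.disagreement for r in reports])),
        q_statistic=float(np.mean([r.q_statistic for r in reports])),
        degenerate=degenerate,
    )


# -- report writers --------------------------------------------------------

def write_report_csv(rows: list[dict], path: str | Path) -> None:
    """One row per (dataset, site_type, ensemble, metric) record."""
    if not rows:
        raise InputShapeError("nothing to write")
    keys = list(rows[0])
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(rows)


def write_report_json(rows: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(rows, indent=2, sort_keys=True) + "\n")
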