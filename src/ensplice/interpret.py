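"""Interpretability exports: class-conditional position-frequency matrices
(sequence-logo input) and occlusion-based per-position importance."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal

import numpy as np

from .data_io import BASE_ORDER, OneHotBatch, SpliceDataset, encode_one_hot
from .errors import EmptyInputError, InputShapeError
from . import nn
from .ensemble import MetaModel, predict_ensemble


@dataclass
class PositionFrequencyMatrix:
    """Per-position empirical base frequencies (rows) over a record subset."""

    frequencies: np.ndarray  # L x 4, rows sum to 1 given no unknown bases
    counts: np.ndarray  # L x 4 integer counts
    label_filter: str
    site_type: str

    @property
    def window_length(self) -> int:
        return len(self.frequencies)


def position_frequencies(
    dataset: SpliceDataset,
    label_filter: Literal["positive", "negative", "all"] = "all",
) -> PositionFrequencyMatrix:
    """Empirical per-position base frequencies of the filtered records.

    Unknown bases are excluded from the per-position denominator, so rows
    always sum to 1 wherever at least one known base was observed.
    """
    wanted = {"positive": (1,), "negative": (0,), "all": (0, 1)}[label_filter]
    records = [r for r in dataset.records if r.label in wanted]
    if not records:
        raise EmptyInputError(f"no records with label filter {label_filter!r}")
    sub = SpliceDataset(
        records=records,
        window_length=dataset.window_length,
        consensus_positions=dataset.consensus_positions,
        site_type=dataset.site_type,
    )
    counts = encode_one_hot(sub).tensor.sum(axis=0).astype(np.int64)
    denom = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(denom > 0, counts / denom, 0.0)
    return PositionFrequencyMatrix(
        frequencies=freqs,
        counts=counts,
        label_filter=label_filter,
        site_type=dataset.site_type,
    )


def write_pfm(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    """Tab-separated position x (A, C, G, T) frequency matrix, 1-based."""
    with Path(path).open("w") as fh:
        fh.write("# site_type=%s label_filter=%s\n" % (pfm.site_type, pfm.label_filter))
        fh.write("position\t" + "\t".join(BASE_ORDER) + "\n")
        for i, row in enumerate(pfm.frequencies, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_pfm(path: str | Path) -> PositionFrequencyMatrix:
    lines = Path(path).read_text().splitlines()
    meta = {"site_type": "acceptor", "label_filter": "all"}
    body = []
    for ln in lines:
        if ln.startswith("#"):
            for tok in ln[1:].split():
                key, _, val = tok.partition("=")
                if key in meta:
                    meta[key] = val
        elif ln and not ln.startswith("position"):
            body.append([float(v) for v in ln.split("\t")[1:]])
    freqs = np.asarray(body)
    return PositionFrequencyMatrix(
        frequencies=freqs,
        counts=np.zeros_like(freqs, dtype=np.int64),
        label_filter=meta["label_filter"],
        site_type=meta["site_type"],
    )


def _as_probability_fn(predictor) -> Callable[[OneHotBatch], np.ndarray]:
    """Normalize the accepted predictor forms to batch -> P(true site)."""
    if isinstance(predictor, nn.Network):
        return lambda batch: predictor.predict_proba(batch.tensor)[:, 1]
    if (
        isinstance(predictor, tuple)
        and len(predictor) == 2
        and isinstance(predictor[0], MetaModel)
    ):
        meta, members = predictor
        return lambda batch: predict_ensemble(meta, members, batch)[1]
    if callable(predictor):
        return predictor
    raise InputShapeError(
        "predictor must be a Network, a (MetaModel, members) pair, or a callable"
    )


def occlusion_importance(
    predictor,
    batch: OneHotBatch,
    window: int = 1,
) -> np.ndarray:
    """Mean drop in P(true site) when a span centred at each position is zeroed.

    Returns one score per sequence position, averaged over the batch.  The
    occluded span has length ``window`` and is clipped at the sequence ends.
    """
    length = batch.window_length
    if window < 1:
        raise InputShapeError("window must be >= 1")
    if window > length:
        raise InputShapeError(
            f"occlusion window {window} exceeds sequence length {length}"
        )
    prob_fn = _as_probability_fn(predictor)
    baseline = np.asarray(prob_fn(batch), dtype=float)
    half = (window - 1) // 2
    scores = np.empty(length)
    for pos in range(length):
        lo = max(0, pos - half)
        hi = min(length, lo + window)
        lo = max(0, hi - window)
        occluded = batch.tensor.copy()
        occluded[:, lo:hi, :] = 0.0
        drop = baseline - np.asarray(prob_fn(OneHotBatch(tensor=occluded)), dtype=float)
        scores[pos] = float(drop.mean())
    return scores
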