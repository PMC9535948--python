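"""Reading, validation, balancing and one-hot encoding of splice-window datasets.

A dataset is a list of fixed-length DNA windows labelled 1 (true site) or
0 (false site), handled separately for acceptor (consensus AG) and donor
(consensus GT) sites.  Two real-data dialects are supported out of the box:
140-nt windows with the consensus at 69-70 (acceptor) / 71-72 (donor), and
602-nt windows with the consensus at 301-302 for both site types.  Consensus
positions are 1-based inclusive everywhere in configs and messages.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    DatasetIntegrityError,
    EmptyInputError,
    EncodingCorruptionError,
    InsufficientDataError,
)

SiteType = Literal["acceptor", "donor"]

#: Column order of the one-hot encoding; fixed everywhere in the package.
BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

#: Consensus dinucleotide per site type.
CONSENSUS = {"acceptor": "AG", "donor": "GT"}

#: Default seed used when subsampling the negative class of real datasets.
DEFAULT_SUBSAMPLE_SEED = 123454

#: (window_length, {site_type: (pos, pos)}) per named input dialect.
DIALECTS = {
    "hs3d_140": (140, {"acceptor": (69, 70), "donor": (71, 72)}),
    "splicedeep_602": (602, {"acceptor": (301, 302), "donor": (301, 302)}),
}


@dataclass(frozen=True)
class SpliceRecord:
    """One labelled DNA window."""

    sequence: str
    label: int
    site_type: SiteType

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise DatasetIntegrityError(f"label must be 0 or 1, got {self.label!r}")
        if self.site_type not in ("acceptor", "donor"):
            raise DatasetIntegrityError(f"unknown site_type {self.site_type!r}")


@dataclass
class SpliceDataset:
    """Ordered collection of equal-length windows of a single site type."""

    records: list[SpliceRecord]
    window_length: int
    consensus_positions: tuple[int, int]
    site_type: SiteType

    def __post_init__(self) -> None:
        lo, hi = self.consensus_positions
        if not (1 <= lo <= self.window_length - 1 and 2 <= hi <= self.window_length):
            raise DatasetIntegrityError(
                f"consensus positions {self.consensus_positions} outside "
                f"window of length {self.window_length}"
            )
        if hi != lo + 1:
            raise DatasetIntegrityError(
                f"consensus positions must be adjacent, got {self.consensus_positions}"
            )
        for i, rec in enumerate(self.records):
            if len(rec.sequence) != self.window_length:
                raise DatasetIntegrityError(
                    f"record {i}: sequence length {len(rec.sequence)} != "
                    f"declared window length {self.window_length}"
                )
            if rec.site_type != self.site_type:
                raise DatasetIntegrityError(
                    f"record {i}: site_type {rec.site_type!r} != {self.site_type!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)


@dataclass
class OneHotBatch:
    """N x L x 4 binary encoding; row order matches the source dataset."""

    tensor: np.ndarray

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3 or self.tensor.shape[-1] != 4:
            raise EncodingCorruptionError(
                f"expected an N x L x 4 tensor, got shape {self.tensor.shape}"
            )

    @property
    def n_records(self) -> int:
        return self.tensor.shape[0]

    @property
    def window_length(self) -> int:
        return self.tensor.shape[1]


def encode_one_hot(dataset: SpliceDataset) -> OneHotBatch:
    """Encode every record as an L x 4 indicator matrix.

    Mapping is exactly A->[1,0,0,0], C->[0,1,0,0], G->[0,0,1,0],
    T->[0,0,0,1]; any other symbol (N, IUPAC ambiguity codes) becomes an
    all-zero row so that it contributes nothing downstream.
    """
    n, length = len(dataset), dataset.window_length
    out = np.zeros((n, length, 4), dtype=np.float32)
    for i, rec in enumerate(dataset.records):
        if len(rec.sequence) != length:
            raise DatasetIntegrityError(
                f"record {i}: length {len(rec.sequence)} != {length}"
            )
        for j, base in enumerate(rec.sequence):
            k = _BASE_INDEX.get(base)
            if k is not None:
                out[i, j, k] = 1.0
    return OneHotBatch(tensor=out)


def decode_one_hot(batch: OneHotBatch) -> list[str]:
    """Invert :func:`encode_one_hot`; all-zero rows decode to ``"N"``."""
    tensor = batch.tensor
    if tensor.size and (
        not np.isin(tensor, (0.0, 1.0)).all() or (tensor.sum(axis=2) > 1).any()
    ):
        raise EncodingCorruptionError(
            "batch contains rows that are neither one-hot nor all-zero"
        )
    sequences = []
    for mat in tensor:
        chars = []
        for row in mat:
            hits = np.flatnonzero(row)
            chars.append(BASE_ORDER[hits[0]] if hits.size else "N")
        sequences.append("".join(chars))
    return sequences


def _read_sequences(path: Path) -> list[str]:
    """Read FASTA or one-sequence-per-line text, auto-detected by leading '>'."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"no sequences in {path}")
    if lines[0].startswith(">"):
        seqs: list[str] = []
        current: list[str] = []
        for ln in lines:
            if ln.startswith(">"):
                if current:
                    seqs.append("".join(current))
                    current = []
            else:
                current.append(ln)
        if current:
            seqs.append("".join(current))
    else:
        seqs = lines
    if not seqs:
        raise EmptyInputError(f"no sequences in {path}")
    return [s.upper() for s in seqs]


def _resolve_dialect(
    dialect: str,
    site_type: SiteType,
    window_length: int | None,
    consensus_positions: tuple[int, int] | None,
) -> tuple[int, tuple[int, int]]:
    if dialect in DIALECTS:
        length, per_site = DIALECTS[dialect]
        return length, per_site[site_type]
    if dialect == "generic":
        if window_length is None or consensus_positions is None:
            raise EmptyInputError(
                "generic dialect requires window_length and consensus_positions"
            )
        return window_length, tuple(consensus_positions)
    raise KeyError(
        f"unknown dialect {dialect!r}; expected one of "
        f"{sorted(DIALECTS)} or 'generic'"
    )


def read_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    dialect: str = "hs3d_140",
    site_type: SiteType = "acceptor",
    window_length: int | None = None,
    consensus_positions: tuple[int, int] | None = None,
) -> SpliceDataset:
    """Read positive and negative sequence files into one labelled dataset.

    Both FASTA and plain one-sequence-per-line files are accepted.  The
    dialect fixes the expected window length and consensus positions; use
    ``"generic"`` with explicit ``window_length``/``consensus_positions``
    for anything else.
    """
    length, consensus = _resolve_dialect(
        dialect, site_type, window_length, consensus_positions
    )
    records = []
    for path, label in ((pos_path, 1), (neg_path, 0)):
        for i, seq in enumerate(_read_sequences(Path(path))):
            if len(seq) != length:
                raise DatasetIntegrityError(
                    f"{path}: sequence {i} has length {len(seq)}, expected {length}"
                )
            records.append(SpliceRecord(sequence=seq, label=label, site_type=site_type))
    return SpliceDataset(
        records=records,
        window_length=length,
        consensus_positions=consensus,
        site_type=site_type,
    )


def read_dataset_csv(
    csv_path: str | Path,
    site_type: SiteType,
    window_length: int,
    consensus_positions: tuple[int, int],
) -> SpliceDataset:
    """Read a combined CSV with header ``sequence,label``."""
    path = Path(csv_path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"sequence", "label"} <= set(
            reader.fieldnames
        ):
            raise EmptyInputError(f"{path}: expected a header with sequence,label")
        for i, row in enumerate(reader):
            seq = row["sequence"].strip().upper()
            if len(seq) != window_length:
                raise DatasetIntegrityError(
                    f"{path}: row {i} has length {len(seq)}, expected {window_length}"
                )
            records.append(
                SpliceRecord(sequence=seq, label=int(row["label"]), site_type=site_type)
            )
    if not records:
        raise EmptyInputError(f"{path}: no data rows")
    return SpliceDataset(
        records=records,
        window_length=window_length,
        consensus_positions=tuple(consensus_positions),
        site_type=site_type,
    )


def validate_consensus(dataset: SpliceDataset) -> dict[int, list[int]]:
    """Report record indices whose consensus dinucleotide is wrong.

    Both classes are checked: in these datasets false sites also carry the
    consensus (they are decoys).  Returns ``{1: [...], 0: [...]}`` with the
    violating indices per label; empty lists mean a clean dataset.
    """
    if not dataset.records:
        raise EmptyInputError("cannot validate an empty dataset")
    lo, hi = dataset.consensus_positions
    expected = CONSENSUS[dataset.site_type]
    report: dict[int, list[int]] = {1: [], 0: []}
    for i, rec in enumerate(dataset.records):
        if rec.sequence[lo - 1 : hi] != expected:
            report[rec.label].append(i)
    return report


def subsample_balance(
    dataset: SpliceDataset,
    n_per_class: int,
    seed: int = DEFAULT_SUBSAMPLE_SEED,
) -> SpliceDataset:
    """Deterministically subsample to exactly ``n_per_class`` records per class.

    Shuffles the whole record list with a dedicated RNG seeded by ``seed``
    and takes the first ``n_per_class`` of each class in shuffled order.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset.records))
    kept: dict[int, list[SpliceRecord]] = {0: [], 1: []}
    for idx in order:
        rec = dataset.records[idx]
        if len(kept[rec.label]) < n_per_class:
            kept[rec.label].append(rec)
    for label in (1, 0):
        if len(kept[label]) < n_per_class:
            raise InsufficientDataError(
                f"class {label} has only {len(kept[label])} records; "
                f"{n_per_class} requested (short by {n_per_class - len(kept[label])})"
            )
    return SpliceDataset(
        records=kept[1] + kept[0],
        window_length=dataset.window_length,
        consensus_positions=dataset.consensus_positions,
        site_type=dataset.site_type,
    )


def write_fasta(sequences: Iterable[str], path: str | Path, prefix: str = "seq") -> None:
    """Write sequences as a minimal multi-record FASTA file."""
    with Path(path).open("w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">{prefix}_{i}\n{seq}\n")


def write_dataset_fasta(
    dataset: SpliceDataset, pos_path: str | Path, neg_path: str | Path
) -> None:
    """Write a dataset back out as a positives/negatives FASTA pair."""
    write_fasta(
        (r.sequence for r in dataset.records if r.label == 1), pos_path, "pos"
    )
    write_fasta(
        (r.sequence for r in dataset.records if r.label == 0), neg_path, "neg"
    )
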