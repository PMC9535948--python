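"""Synthetic splice-window generator.

Emulates the structure of the real training data: fixed-length windows, a
mandatory consensus dinucleotide at declared positions in BOTH classes
(negatives are decoys), PWM-shaped flanking signal in positives and plain
background flanks in negatives, with exact class balance.

The positive flank model is a per-position mixture
``signal_strength * pwm + (1 - signal_strength) * background`` so that the
expected per-position base frequencies are available in closed form for
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import BASE_ORDER, CONSENSUS, SiteType, SpliceDataset, SpliceRecord
from .errors import ConfigError

_UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass
class MotifModel:
    """Per-position base probabilities with a hard consensus dinucleotide."""

    pwm: np.ndarray  # L x 4, rows sum to 1
    consensus_positions: tuple[int, int]  # 1-based inclusive
    consensus_dinucleotide: str  # "AG" or "GT"

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ConfigError(f"pwm must be L x 4, got shape {self.pwm.shape}")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("every pwm row must sum to 1")
        lo, hi = self.consensus_positions
        if not (1 <= lo < hi <= len(self.pwm)) or hi != lo + 1:
            raise ConfigError(
                f"consensus positions {self.consensus_positions} invalid for "
                f"motif of length {len(self.pwm)}"
            )
        for pos, base in zip((lo, hi), self.consensus_dinucleotide):
            if self.pwm[pos - 1, BASE_ORDER.index(base)] != 1.0:
                raise ConfigError(
                    f"pwm row at position {pos} must put probability 1 on {base!r}"
                )

    @property
    def window_length(self) -> int:
        return len(self.pwm)


@dataclass
class SyntheticConfig:
    n_per_class: int
    window_length: int
    site_type: SiteType
    signal_strength: float = 1.0
    background: tuple[float, float, float, float] = _UNIFORM
    seed: int = 0
    decoy_consensus: bool = True  # negatives carry the consensus too

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ConfigError("signal_strength must lie in [0, 1]")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ConfigError("background must be a length-4 probability vector")


def default_motif(
    site_type: SiteType,
    window_length: int,
    consensus_positions: tuple[int, int],
    sharpness: float = 1.0,
) -> MotifModel:
    """Build a simple enriched-flank motif around the consensus.

    Rows are uniform except a +/-6-nt neighbourhood of the consensus, where
    one deterministic base per position is boosted to ``0.25 + 0.75 * sharpness``
    (remaining mass split evenly); the consensus rows themselves are
    deterministic.
    """
    if not 0.0 <= sharpness <= 1.0:
        raise ConfigError("sharpness must lie in [0, 1]")
    lo, hi = consensus_positions
    if not (1 <= lo < hi <= window_length):
        raise ConfigError(
            f"consensus positions {consensus_positions} outside window "
            f"of length {window_length}"
        )
    pwm = np.full((window_length, 4), 0.25)
    p_major = 0.25 + 0.75 * sharpness
    p_minor = (1.0 - p_major) / 3.0
    for pos in range(max(1, lo - 6), min(window_length, hi + 6) + 1):
        if pos in (lo, hi):
            continue
        major = (pos * 2654435761) % 4  # deterministic but position-varying base
        row = np.full(4, p_minor)
        row[major] = p_major
        pwm[pos - 1] = row
    consensus = CONSENSUS[site_type]
    for pos, base in zip((lo, hi), consensus):
        row = np.zeros(4)
        row[BASE_ORDER.index(base)] = 1.0
        pwm[pos - 1] = row
    return MotifModel(
        pwm=pwm,
        consensus_positions=(lo, hi),
        consensus_dinucleotide=consensus,
    )


def _sample_class(
    rng: np.random.Generator,
    probs: np.ndarray,
    n: int,
    consensus_positions: tuple[int, int],
    consensus: str | None,
) -> list[str]:
    """Vectorised per-position categorical sampling of n windows."""
    length = len(probs)
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n, length))
    idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    base_arr = np.frombuffer(BASE_ORDER.encode(), dtype=np.uint8)
    chars = base_arr[idx]
    if consensus is not None:
        lo, hi = consensus_positions
        for pos, base in zip((lo, hi), consensus):
            chars[:, pos - 1] = ord(base)
    return [row.tobytes().decode() for row in chars]


def generate_dataset(config: SyntheticConfig, motif: MotifModel) -> SpliceDataset:
    """Generate a balanced labelled dataset under the given config and motif.

    Deterministic under ``config.seed``; per-class RNG streams are derived
    from the master seed so each class's draw is independent of the other's
    sample size.
    """
    if motif.window_length != config.window_length:
        raise ConfigError(
            f"motif length {motif.window_length} != window_length "
            f"{config.window_length}"
        )
    if motif.consensus_dinucleotide != CONSENSUS[config.site_type]:
        raise ConfigError(
            f"motif consensus {motif.consensus_dinucleotide!r} does not match "
            f"site type {config.site_type!r}"
        )
    bg = np.asarray(config.background, dtype=float)
    pos_probs = config.signal_strength * motif.pwm + (1 - config.signal_strength) * bg
    neg_probs = np.tile(bg, (config.window_length, 1))

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    consensus = motif.consensus_dinucleotide
    pos_seqs = _sample_class(
        np.random.default_rng(seeds[0]),
        pos_probs,
        config.n_per_class,
        motif.consensus_positions,
        consensus,
    )
    neg_seqs = _sample_class(
        np.random.default_rng(seeds[1]),
        neg_probs,
        config.n_per_class,
        motif.consensus_positions,
        consensus if config.decoy_consensus else None,
    )
    records = [
        SpliceRecord(sequence=s, label=1, site_type=config.site_type)
        for s in pos_seqs
    ] + [
        SpliceRecord(sequence=s, label=0, site_type=config.site_type)
        for s in neg_seqs
    ]
    return SpliceDataset(
        records=records,
        window_length=config.window_length,
        consensus_positions=motif.consensus_positions,
        site_type=config.site_type,
    )
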