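"""Masked-language-model pre-training corpus construction.

The corpus is built by tiling each reference sequence with fixed-width
windows (default 510 bp) at a fixed stride (default 255 bp, i.e. 50%
overlap between adjacent chunks), then corrupting tokenized chunks with
the standard BERT masking recipe: each non-special token is selected
independently with probability ``mask_rate`` (default 15%); a selected
token is replaced by [MASK] with probability 0.8, by a random k-mer with
probability 0.1, and left unchanged with probability 0.1.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .tokenization import MASK_ID, SPECIAL_TOKENS, TokenizerSpec

__all__ = [
    "ChunkerConfig",
    "MaskingConfig",
    "MaskedBatch",
    "IGNORE_LABEL",
    "chunk_genome",
    "apply_mlm_mask",
    "write_corpus_tsv",
    "read_corpus_tsv",
]

logger = logging.getLogger(__name__)

IGNORE_LABEL = -100  # label value for positions not selected for prediction

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ChunkerConfig:
    """Genome chunking parameters; defaults give 50% window overlap."""

    window_bp: int = 510
    stride_bp: int = 255
    drop_if_non_acgt_fraction_above: float = 0.1

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.stride_bp <= 0:
            raise ValueError("window_bp and stride_bp must be positive")
        if self.stride_bp > self.window_bp:
            raise ValueError("stride_bp must not exceed window_bp")
        if not 0.0 <= self.drop_if_non_acgt_fraction_above <= 1.0:
            raise ValueError("drop threshold must be a fraction in [0, 1]")


@dataclass(frozen=True)
class MaskingConfig:
    """MLM corruption parameters (BERT-standard 80/10/10 split)."""

    mask_rate: float = 0.15
    replace_with_mask: float = 0.8
    replace_with_random: float = 0.1
    keep_original: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must be in [0, 1]")
        total = self.replace_with_mask + self.replace_with_random + self.keep_original
        if abs(total - 1.0) > 1e-9:
            raise ValueError("replacement fractions must sum to 1")


@dataclass
class MaskedBatch:
    """Corrupted token ids with prediction targets.

    ``labels`` holds the original id at selected positions and
    :data:`IGNORE_LABEL` elsewhere.
    """

    input_ids: np.ndarray
    labels: np.ndarray
    selected_positions: np.ndarray


def chunk_genome(
    reference: Mapping[str, str], config: ChunkerConfig = ChunkerConfig()
) -> list[tuple[str, int, str]]:
    """Tile each record with windows at starts 0, stride, 2*stride, ...

    Records shorter than the window are skipped with a warning.  Windows
    whose non-ACGT fraction exceeds the configured threshold are dropped.
    Output order is deterministic: record order, then start.
    """
    if not reference:
        raise ValueError("empty reference: no records to chunk")
    chunks: list[tuple[str, int, str]] = []
    for name, seq in reference.items():
        if len(seq) < config.window_bp:
            logger.warning(
                "record %s (%d bp) shorter than window (%d bp); skipped",
                name, len(seq), config.window_bp,
            )
            continue
        for start in range(0, len(seq) - config.window_bp + 1, config.stride_bp):
            window = seq[start : start + config.window_bp]
            non_acgt = sum(1 for c in window if c not in _ACGT)
            if non_acgt / config.window_bp > config.drop_if_non_acgt_fraction_above:
                continue
            chunks.append((name, start, window))
    return chunks


def expected_chunk_count(record_length: int, config: ChunkerConfig) -> int:
    """Closed-form chunk count: floor((R - window)/stride) + 1 for R >= window."""
    if record_length < config.window_bp:
        return 0
    return (record_length - config.window_bp) // config.stride_bp + 1


def apply_mlm_mask(
    token_ids: Sequence[int] | np.ndarray,
    spec: TokenizerSpec,
    config: MaskingConfig,
    rng: np.random.Generator,
) -> MaskedBatch:
    """Corrupt a token-id sequence (or a batch of them) for MLM training.

    Accepts a 1-D sequence or a 2-D ``(batch, length)`` array.  Special
    tokens ([PAD]/[MASK]/[CLS]/[SEP]/[UNK]) are never selected.  The
    random-replacement pool is the plain k-mer vocabulary.  Deterministic
    given the generator state.
    """
    ids = np.asarray(token_ids, dtype=np.int64)
    squeeze = ids.ndim == 1
    if squeeze:
        ids = ids[None, :]

    maskable = ids >= len(SPECIAL_TOKENS)
    if not maskable.any():
        logger.warning("no maskable (non-special) tokens in input")
    selected = maskable & (rng.random(ids.shape) < config.mask_rate)

    labels = np.full_like(ids, IGNORE_LABEL)
    labels[selected] = ids[selected]

    input_ids = ids.copy()
    action = rng.random(ids.shape)
    to_mask = selected & (action < config.replace_with_mask)
    to_random = selected & ~to_mask & (
        action < config.replace_with_mask + config.replace_with_random
    )
    input_ids[to_mask] = MASK_ID
    content = spec.content_ids()
    if to_random.any():
        input_ids[to_random] = rng.integers(
            content.start, content.stop, size=int(to_random.sum())
        )
    # remaining selected positions keep their original token

    positions = np.argwhere(selected)
    if squeeze:
        input_ids, labels = input_ids[0], labels[0]
        positions = positions[:, 1]
    return MaskedBatch(input_ids=input_ids, labels=labels, selected_positions=positions)


def write_corpus_tsv(chunks: Iterable[tuple[str, int, str]], path: str | Path) -> None:
    """Write chunks as TSV rows (record, start, sequence)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["record", "start", "sequence"])
        for record, start, seq in chunks:
            writer.writerow([record, start, seq])


def read_corpus_tsv(path: str | Path) -> list[tuple[str, int, str]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != ["record", "start", "sequence"]:
            raise ValueError(f"unexpected corpus header in {path}: {header}")
        return [(rec, int(start), seq) for rec, start, seq in reader]
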