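"""Desk-scale end-to-end study: genome -> corpus -> MLM -> splice model.

This module wires the package's pieces into the full experimental loop at
laptop scale: generate a synthetic genome with planted GT..AG introns,
build an MLM corpus and pre-train a tiny encoder, construct the
chromosome-split splice dataset, fine-tune a 3-class splice classifier,
evaluate it (with a label-shuffled control), and localize a planted donor
by sliding-window annotation inference.

The study conditions are fixed as package defaults: a 5-chromosome,
50 kb/chromosome genome with 67 introns per chromosome (about 2,000
labelled windows after 2:1 negative sampling), a 3-mer overlapping
tokenizer, 500 MLM pre-training steps, and 5 fine-tuning epochs.  All
randomness derives from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import junctions as jx
from .annotation import ScanConfig, scan_region
from .corpus import ChunkerConfig, MaskingConfig, chunk_genome
from .metrics import mcc as binary_mcc
from .model.encoder import (
    CLASS_TO_INDEX,
    EncoderConfig,
    TrainConfig,
    finetune,
    init_encoder,
    predict_logits,
    pretrain_mlm,
)
from .synthetic import SyntheticGenomeSpec, generate_genome_with_junctions
from .tokenization import TokenizerSpec, build_vocab, tokenize

__all__ = ["StudyConfig", "StudyResult", "run_desk_scale_study", "multiclass_mcc"]


@dataclass(frozen=True)
class StudyConfig:
    """Fixed conditions of the desk-scale end-to-end run."""

    k: int = 3
    scheme: str = "overlapping"
    n_chroms: int = 5
    chrom_length_bp: int = 50_000
    introns_per_chrom: int = 67
    pretrain_steps: int = 500
    pretrain_batch: int = 16
    pretrain_chunk_bp: int = 160   # corpus window for the desk-scale run
    pretrain_stride_bp: int = 80
    finetune_epochs: int = 8
    finetune_batch: int = 32
    learning_rate: float = 1e-3
    neg_ratio: float = 2.0
    flank_bp: int = 80
    scan_margin_bp: int = 200


@dataclass
class StudyResult:
    """Quantities computed by the end-to-end run."""

    validation_mcc: float
    shuffled_validation_mcc: float
    donor_localization_error_bp: int
    n_windows: int
    n_train: int
    n_validation: int
    pretrain_initial_loss: float
    pretrain_final_loss: float
    negative_to_positive_ratio: float


def multiclass_mcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Multiclass MCC (generalized correlation of the confusion matrix)."""
    from sklearn.metrics import matthews_corrcoef

    return float(matthews_corrcoef(y_true, y_pred))


def _window_labels(windows) -> np.ndarray:
    return np.array([CLASS_TO_INDEX[w.label] for w in windows], dtype=np.int64)


def run_desk_scale_study(
    seed: int, config: StudyConfig = StudyConfig()
) -> StudyResult:
    """Run the full desk-scale pipeline; deterministic given the seed.

    The label-shuffled control re-runs fine-tuning from the same
    pre-trained weights with permuted training labels; its validation MCC
    should sit near zero while the real model's should not.
    """
    rng = np.random.default_rng(seed)
    genome_seed, neg_seed, mask_seed, train_seed, shuffle_seed = (
        int(x) for x in rng.integers(0, 2**31 - 1, size=5)
    )

    genome, truth = generate_genome_with_junctions(
        SyntheticGenomeSpec(
            n_chroms=config.n_chroms,
            chrom_length_bp=config.chrom_length_bp,
            n_introns=config.introns_per_chrom,
            seed=genome_seed,
        )
    )
    spec = build_vocab(config.k, config.scheme)

    # corpus + MLM pre-training
    chunks = chunk_genome(
        genome,
        ChunkerConfig(
            window_bp=config.pretrain_chunk_bp, stride_bp=config.pretrain_stride_bp
        ),
    )
    corpus_ids = np.array(
        [tokenize(c[2], spec, add_sentinels=True).token_ids for c in chunks],
        dtype=np.int64,
    )
    encoder = init_encoder(
        EncoderConfig(vocab_size=spec.vocab_size, seed=train_seed)
    )
    encoder, losses = pretrain_mlm(
        encoder,
        corpus_ids,
        MaskingConfig(seed=mask_seed),
        TrainConfig(
            learning_rate=config.learning_rate,
            max_steps=config.pretrain_steps,
            batch_size=config.pretrain_batch,
            seed=train_seed,
            task_kind="mlm",
        ),
        spec,
    )

    # splice dataset from the truth junction table
    merged = jx.merge_junctions(truth)
    positives = jx.extract_site_windows(merged, genome, flank_bp=config.flank_bp)
    negatives = jx.sample_negatives(
        genome,
        merged,
        ratio=config.neg_ratio,
        window_bp=2 * config.flank_bp,
        rng=np.random.default_rng(neg_seed),
        n_positive_windows=len(positives),
    )
    dataset = jx.split_by_chromosome(positives + negatives)

    ft_config = TrainConfig(
        learning_rate=config.learning_rate,
        epochs=config.finetune_epochs,
        batch_size=config.finetune_batch,
        seed=train_seed,
    )
    model = finetune(encoder.copy(), dataset.train, spec, ft_config, head=3)
    val_true = _window_labels(dataset.validation)
    val_pred = predict_logits(model, dataset.validation).argmax(axis=1)
    validation_mcc = multiclass_mcc(val_true, val_pred)

    # label-shuffled control: same recipe, permuted training labels
    shuffle_rng = np.random.default_rng(shuffle_seed)
    shuffled_labels = shuffle_rng.permutation(_window_labels(dataset.train))
    shuffled_train = [
        (w.sequence, int(lab)) for w, lab in zip(dataset.train, shuffled_labels)
    ]
    shuffled_model = finetune(encoder.copy(), shuffled_train, spec, ft_config, head=3)
    shuffled_pred = predict_logits(shuffled_model, dataset.validation).argmax(axis=1)
    shuffled_mcc = multiclass_mcc(val_true, shuffled_pred)

    # annotation scan around an isolated planted donor on a test chromosome:
    # the region must contain exactly one true donor, otherwise the argmax
    # legitimately lands on a neighbouring site
    test_chrom = f"chr{config.n_chroms}"
    donors = sorted(
        m.representative.donor_pos
        for m in merged
        if m.representative.chrom == test_chrom and m.representative.strand == "+"
    )
    isolated = [
        d for i, d in enumerate(donors)
        if (i == 0 or d - donors[i - 1] > config.scan_margin_bp)
        and (i == len(donors) - 1 or donors[i + 1] - d > config.scan_margin_bp)
    ]
    candidates = isolated or donors
    target_pos = candidates[len(candidates) // 2]
    region = (
        test_chrom,
        target_pos - config.scan_margin_bp,
        target_pos + config.scan_margin_bp,
    )
    track = scan_region(
        model, spec, genome, ScanConfig(region=region, window_bp=2 * config.flank_bp)
    )
    localization_error = abs(track.argmax_position("donor") - target_pos)

    return StudyResult(
        validation_mcc=validation_mcc,
        shuffled_validation_mcc=shuffled_mcc,
        donor_localization_error_bp=int(localization_error),
        n_windows=len(positives) + len(negatives),
        n_train=len(dataset.train),
        n_validation=len(dataset.validation),
        pretrain_initial_loss=float(losses[0]),
        pretrain_final_loss=float(np.mean(losses[-20:])),
        negative_to_positive_ratio=len(negatives) / len(positives),
    )
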