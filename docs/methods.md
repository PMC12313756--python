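# Methods

This note documents the models, procedures, parameter choices and known
limitations of `plantglm`.

## k-mer tokenization

A genomic sequence over {A, C, G, T, N} is segmented into k-mer tokens
under one of three schemes:

- **overlapping** — a k-mer at every 1-bp offset; a sequence of length L
  yields `L − k + 1` content tokens (`L − k + 3` with [CLS]/[SEP]).
  Consecutive tokens share k − 1 bases, so local context is redundantly
  encoded; tokenizing a sequence and its 1-bp-shifted suffix produces
  identical tokens except the first.
- **non-overlapping** — consecutive disjoint k-blocks, `ceil(L/k)`
  content tokens. The trailing `L mod k` remainder is emitted as a single
  [UNK] token spanning the leftover bases. This choice keeps both the
  token-count formula `ceil(L/k) + 2` and the vocabulary size `4^k + 5`
  simultaneously exact; representing remainders with shorter k-mer tokens
  would break one or the other.
- **agront6** — greedy non-overlapping 6-mers with single-nucleotide
  fallback (A, C, G, T, N) whenever fewer than six bases remain or the
  next six bases contain an N. Only the non-formable stretch is split
  into singles; 6-mer segmentation resumes as soon as a clean window is
  available. The five single-character tokens are appended after the
  4^6 k-mers, giving 4101 + 5 entries.

Vocabularies are deterministic: the five special tokens [PAD], [MASK],
[CLS], [SEP], [UNK] occupy ids 0–4, followed by all k-mers in
lexicographic order. In the generic schemes any window containing N maps
to [UNK] with its span retained (the explicit single-base fallback exists
only in the agront6 scheme). All coordinates are 0-based half-open;
per-token spans make token↔base mapping exact in both directions, which
the attention analysis relies on.

## Pre-training corpus and masking

Reference sequences are tiled with 510 bp windows at a 255 bp stride
(50% overlap between adjacent chunks); windows with more than 10% non-ACGT
bases are dropped so the corpus is not dominated by [UNK] runs (the 0.1
threshold is a package choice). Masked-language-model corruption selects
each non-special token independently with probability 0.15 and applies the
standard BERT 80/10/10 recipe: replace with [MASK], replace with a random
k-mer from the content vocabulary, or keep unchanged. Independent
Bernoulli selection (rather than exact-count sampling) is the simplest
model of random token masking and its empirical rate concentrates tightly
at n = 10^5 tokens. Span-style masking of whole overlapping k-mer
neighbourhoods is not implemented.

## Splice-junction dataset construction

Junctions are read from STAR `SJ.out.tab` (1-based inclusive intron
coordinates, strand coded 0/1/2) or BED6 (0-based half-open) and
normalized to 0-based `donor_pos` (first intronic base) / `acceptor_pos`
(last intronic base). Near-duplicate junctions are merged by
single-linkage clustering within each (chromosome, strand) group: two
junctions link iff both coordinate differences are ≤ 2 bp (the tolerance
applies to each coordinate independently). Single linkage makes the merge
order-independent and idempotent; the cluster representative is the
member with the highest unique-read support (ties break toward smaller
coordinates) rather than an averaged pseudo-junction, so every emitted
coordinate is an observed one. Unknown-strand junctions (STAR code 0)
are kept and treated as plus strand.

Each merged junction produces one donor and one acceptor window of
160 bp (80 bp per side): the splice boundary sits between window offsets
79 and 80, so a plus-strand donor window reads GT at offsets 80–81 and an
acceptor window reads AG at offsets 78–79. Minus-strand windows are
reverse-complemented so the motifs always read 5'→3'. Negative windows
are placed uniformly at random (chromosomes weighted by length) and
rejection-sampled so that no negative interval contains any donor or
acceptor position and no window contains N; the default negative:positive
ratio is 2:1. Splits are by chromosome: chr1–3 train, chr4 validation,
chr5 and anything else test; windows are deduplicated on
(chrom, start, end, label).

## Synthetic data generators

The generators provide exact truth tables so every downstream stage is
testable without external data:

- **Genome** — i.i.d. background at 36% GC (Arabidopsis-like) with
  non-overlapping planted introns (default 60–200 bp, 40 per 30 kb
  chromosome, ≥ 200 bp from contig ends). Each intron's boundaries are
  overwritten with fixed consensus context (`CAGGTAAGT` at the donor,
  `TTTGCAGGT` at the acceptor; reverse-complemented for minus-strand
  introns), so the classification signal is clean and near-deterministic.
- **splice398** — 398 bp binary records; positives carry the donor or
  acceptor consensus at the central boundary (offset 199), negatives are
  background with accidental exact-consensus hits resampled away.
- **apa400** — 400 bp records with the polyadenylation site at 1-based
  position 301 and an AATAAA signal ending 25 bp upstream; each negative
  is the same sequence frame shifted by a caller-chosen `shift_bp`, so
  the site no longer aligns with position 301. The shift magnitude is a
  required explicit parameter.
- **strength170** — 170 bp records whose strength is additive in motif
  occurrence counts plus Gaussian noise (default SD 0.1). The linear
  model is deliberately simple so ordinary least squares on the true
  design matrix recovers the planted weights; it does not emulate
  STARR-seq noise structure. Geometry tags record what the window stands
  for (promoter −165..+5 around a TSS, terminator −150..+20 around a
  cleavage site).

What these generators do **not** emulate: real splice-site degeneracy and
non-canonical junctions, read-support noise, genomic repeat structure,
isochore GC variation, and assay-specific measurement noise. Passing
tests therefore demonstrate that the machinery is correct and that the
models can learn planted, high-signal motifs — not that the desk-scale
models would reach the reported accuracy of full-scale genomic language
models on real benchmarks.

## Encoder

The encoder is a pre-LN transformer (default 2 layers, 4 heads, 64
hidden dimensions, 256 FFN, 512 positions) implemented directly in NumPy
with a small reverse-mode autodiff; weights are initialized N(0, 0.02)
from a seeded generator. The pooled representation for
classification/regression heads is the final-layer [CLS] vector.
Training uses Adam with global-norm gradient clipping (default 1.0;
small-batch Adam on a model this size is occasionally unstable without
it). Fine-tuning updates all parameters (full fine-tuning);
parameter-efficient adapters are not implemented, though the
hyperparameters of the full-scale reference setups (learning rates,
epochs per task, LoRA/(IA)³ settings) are recorded in
`plantglm.model.REFERENCE_HYPERPARAMETERS` as metadata. The desk-scale
learning rate default is 1e-3, appropriate for a model this small;
training at the reference rates would be needlessly slow here.

Attention tensors are exposed as (layer, head, query, key) arrays aligned
with token indices, sentinels included and flagged; every row is a
softmax distribution (sums to 1 within 1e-5).

## Attention localization statistic

For one input, the localization score is the mean final-layer attention
*received by* the tokens overlapping a true splice site: the last layer's
weights averaged over heads, over all non-sentinel query positions, and
over the target key positions. Received attention is the standard
localization reading; [CLS]/[SEP] carry no genomic position and are
excluded from both query and target sets. Scores from overlapping vs
non-overlapping tokenizers are compared per (model, k) group with Welch's
two-sided t-test (unequal variances, Welch–Satterthwaite df), oriented so
a positive statistic means the non-overlapping scheme localizes more
attention. The Benjamini–Hochberg step-up adjustment is applied exactly
once across the whole model×k family. Whether to average over heads or
select specific heads is genuinely open; averaging is the default and the
aggregation is configurable via the raw tensor interface.

## Evaluation metrics

MCC uses the 2×2 confusion-count formula with the degenerate-denominator
convention of 0 (a complete one-class failure scores 0.000). The 3-class
splice task is summarized by one-vs-rest average precision (step-wise
interpolation, i.e. area under the PR curve) and trapezoidal ROC AUC,
macro-averaged over the donor and acceptor classes by default with an
option to include all classes. R² is `1 − SS_res/SS_tot` against the
mean-of-truth baseline and may be negative.

## Annotation scan

A fine-tuned 3-class model is slid across a region (default 160 bp
window, stride 1); each window's logits are assigned to the window's
splice-boundary coordinate (start + 80), matching the training-time site
placement, so a donor directly at a window's boundary produces the
maximal response at its own coordinate. Raw logits are emitted as one
bedGraph per class plus a TSV; no peak calling or thresholding is applied
because the false-positive behaviour depends on the negative-sampling
ratio and is left to the user.

## Desk-scale end-to-end study

`plantglm.workflow.run_desk_scale_study` fixes the full-loop conditions:
a 5-chromosome, 50 kb/chromosome genome with 67 introns per chromosome
(≈ 2,010 labelled windows after 2:1 negative sampling), a 3-mer
overlapping tokenizer, 500 MLM pre-training steps (batch 16) on 160 bp
corpus chunks, and 8 fine-tuning epochs (batch 32) at learning rate 1e-3
with global-norm gradient clipping at 1.0 (small-batch Adam on a tiny
transformer is otherwise occasionally unstable).
The 160 bp pre-training chunk width for this run matches the downstream
window length and keeps the quadratic attention cost proportionate to the
tiny model; the corpus chunker's general default remains 510/255. The
label-shuffled control re-runs fine-tuning from the same pre-trained
weights with permuted training labels. The annotation-scan check targets
a donor on the held-out test chromosome whose scan region contains no
other planted donor — localization against a region holding several true
donors would be ill-posed, since the argmax may legitimately land on a
neighbouring site. All randomness (genome, negative sampling, masking,
initialization, batch order, shuffling) derives from a single seed.
Typical results: validation MCC ≈ 0.99 vs ≈ 0.0 for the control, and
exact (0 bp) donor localization in the annotation scan.

## Numerical choices and limitations

- float32 throughout the encoder; batched and record-by-record inference
  agree within 1e-5.
- Tokenization-count and merge properties are exercised exhaustively at
  desk scale (L ≤ 200, thousands of random junctions) rather than proved.
- The negative sampler aborts when the rejection rate exceeds its attempt
  budget instead of looping forever on infeasible references.
- Welch's test refuses samples with n < 2 or zero variance in both
  groups; BH validates p ∈ [0, 1].
- The encoder has no dropout and no padding/attention masking: batches
  are formed from equal-length sequences, which all pipeline datasets
  guarantee by construction.
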