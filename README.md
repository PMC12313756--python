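# plantglm

Desk-scale tooling for studying **k-mer tokenization strategies in plant
genomic language models**: how the choice of window size *k* (3–8) and
overlap scheme (overlapping, non-overlapping, AgroNT-style 6-mer) affects
transformer-based models for genome annotation tasks such as splice-site
and polyadenylation-site prediction.

For a sequence of length *L*, the vocabulary and token counts obey

- vocabulary size: `V_k = 4^k + 5` (all k-mers over {A,C,G,T} plus the
  special tokens [PAD], [MASK], [CLS], [SEP], [UNK]) — 69 entries at
  k = 3, 65,541 at k = 8;
- non-overlapping: `T_k = ceil(L/k) + 2`;
- overlapping: `T_k = L − k + 1 + 2`,

with the +2 accounting for [CLS]/[SEP]. The package implements the three
tokenizers with exact per-token genomic spans, masked-language-model
corpus construction (510 bp windows, 255 bp stride, 15% masking), an
RNA-seq splice-site dataset builder (±2 bp junction merging, 160 bp
site-centered windows, 2:1 negative sampling, chromosome-partitioned
splits), a small NumPy transformer encoder with full attention
extraction, attention-localization statistics (Welch's two-sided t-test
with Benjamini–Hochberg FDR control), standard evaluation metrics (MCC,
macro PR/ROC, R²), and sliding-window genome annotation producing
bedGraph logit tracks. Synthetic generators with exact truth tables
(planted GT..AG introns, 398 bp splice records, 400 bp APA records with
the site at position 301, 170 bp regulatory-strength records) make the
whole loop runnable on one CPU without any download.

## Worked example

```python
from plantglm import build_vocab, tokenize

over = build_vocab(3, "overlapping")     # 69 tokens
non = build_vocab(3, "nonoverlapping")

print([over.id_to_token[i] for i in tokenize("ATGCCT", over).token_ids])
print([non.id_to_token[i] for i in tokenize("ATGCCT", non).token_ids])
```

```
['ATG', 'TGC', 'GCC', 'CCT']
['ATG', 'CCT']
```

The overlapping scheme slides by one base (tokens share two of three
bases — local context is preserved redundantly); the non-overlapping
scheme partitions the sequence into disjoint blocks.

The full desk-scale experiment — synthetic genome → MLM pre-training →
splice dataset → fine-tuning → label-shuffled control → annotation scan —
is one call:

```python
from plantglm.workflow import run_desk_scale_study

result = run_desk_scale_study(seed=1)
print(result.validation_mcc)             # 0.9900359949423436
print(result.shuffled_validation_mcc)    # 0.0
print(result.donor_localization_error_bp)  # 0
```

A validation MCC near 0.99 on ~2,000 windows shows the tiny encoder
learns the planted splice signal; the shuffled control at 0.0 confirms
the signal is in the labels, not the pipeline; and the annotation scan
pinpoints a held-out planted donor to the exact base.

A command-line interface mirrors the library
(`plantglm tokenize | corpus | build-splice-dataset | synth | attention-stats | evaluate | annotate`);
run `plantglm --help` for the subcommands.

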