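"""Desk-scale transformer encoder for genomic language modeling.

A small pre-LN BERT-style encoder (defaults: 2 layers, 4 heads, 64-dim)
built on the package's numpy autodiff, supporting masked-language-model
pre-training, full fine-tuning with a classification or regression head on
the [CLS] representation, batched logit prediction, and extraction of the
full (layer, head, query, key) attention tensor.  Everything runs on one
CPU and is deterministic given the configured seeds.

The model size here is deliberately tiny: the object of study is the
tokenization scheme, whose effects are observable at this scale; the
hyperparameters used for full-scale fine-tuning of BERT-family models are
kept as reference metadata in :data:`REFERENCE_HYPERPARAMETERS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ..corpus import IGNORE_LABEL, MaskingConfig, apply_mlm_mask
from ..tokenization import TokenizerSpec, tokenize
from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "EncoderConfig",
    "TrainConfig",
    "AttentionTensor",
    "Encoder",
    "TaskModel",
    "init_encoder",
    "pretrain_mlm",
    "finetune",
    "predict_logits",
    "get_attention",
    "REFERENCE_HYPERPARAMETERS",
    "CLASS_TO_INDEX",
]

# fine-tuning hyperparameters of the full-scale reference setups, recorded
# as documentation/config metadata only (the desk-scale defaults differ)
REFERENCE_HYPERPARAMETERS: dict[str, object] = {
    "full_finetune": {
        "learning_rate_bert": 2e-5,
        "learning_rate_dnabert": 3e-5,
        "epochs": {"splicing": 3, "polyadenylation": 5, "promoter": 10, "terminator": 10},
        "optimizer": "AdamW",
        "precision": "mixed",
    },
    "rnaseq_splice_dataset": {
        "batch_size": 128,
        "learning_rate_full": 3e-3,
        "learning_rate_peft": 1e-2,
        "max_steps": 300,
        "optimizer": "schedule-free RAdam",
        "precision": "bfloat16",
    },
    "lora": {"learning_rate": 2e-4, "rank": 8, "alpha": 16, "epochs": 4,
             "targets": ["W_q", "W_k", "W_v", "W_o"]},
    "ia3": {"learning_rate": 3e-3, "epochs": 4, "targets": ["W_q", "W_v", "W_o"]},
    "pretraining": {"steps": "50k-80k", "mask_rate": 0.15,
                    "window_bp": 510, "stride_bp": 255},
}

CLASS_TO_INDEX = {"donor": 0, "acceptor": 1, "negative": 2}


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the desk-scale encoder."""

    vocab_size: int
    n_layers: int = 2
    n_heads: int = 4
    hidden_dim: int = 64
    ffn_dim: int | None = None
    max_positions: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if min(self.vocab_size, self.n_layers, self.n_heads, self.max_positions) < 1:
            raise ValueError("all dimensions must be positive")

    @property
    def ffn(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 4 * self.hidden_dim


@dataclass(frozen=True)
class TrainConfig:
    """Desk-scale training settings.

    ``epochs`` and ``max_steps`` are alternatives; if both are given,
    max_steps caps the run.
    """

    learning_rate: float = 1e-3
    epochs: int | None = None
    max_steps: int | None = None
    batch_size: int = 32
    seed: int = 0
    task_kind: str = "classify"  # mlm | classify | regress

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.task_kind not in ("mlm", "classify", "regress"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")


@dataclass
class AttentionTensor:
    """Full attention weights aligned with a tokenized input.

    ``weights`` has shape (n_layers, n_heads, T, T) where axis -2 indexes
    queries and axis -1 keys; sentinel ([CLS]/[SEP]) positions are listed
    in ``sentinel_indices``.
    """

    weights: np.ndarray
    token_ids: np.ndarray
    sentinel_indices: tuple[int, ...]
    spans: list[tuple[int, int] | None]

    def check_normalized(self, tol: float = 1e-5) -> bool:
        rows = self.weights.sum(axis=-1)
        return bool(np.abs(rows - 1.0).max() <= tol)


class Encoder:
    """Pre-LN transformer encoder with an MLM head."""

    def __init__(self, config: EncoderConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, f, v = config.hidden_dim, config.ffn, config.vocab_size

        def w(*shape: int) -> Tensor:
            return Tensor(rng.normal(0, 0.02, shape), requires_grad=True)

        def zeros(*shape: int) -> Tensor:
            return Tensor(np.zeros(shape), requires_grad=True)

        def ones(*shape: int) -> Tensor:
            return Tensor(np.ones(shape), requires_grad=True)

        p: dict[str, Tensor] = {
            "tok_emb": w(v, d),
            "pos_emb": w(config.max_positions, d),
        }
        for i in range(config.n_layers):
            p[f"l{i}.ln1.g"], p[f"l{i}.ln1.b"] = ones(d), zeros(d)
            p[f"l{i}.wq"], p[f"l{i}.bq"] = w(d, d), zeros(d)
            p[f"l{i}.wk"], p[f"l{i}.bk"] = w(d, d), zeros(d)
            p[f"l{i}.wv"], p[f"l{i}.bv"] = w(d, d), zeros(d)
            p[f"l{i}.wo"], p[f"l{i}.bo"] = w(d, d), zeros(d)
            p[f"l{i}.ln2.g"], p[f"l{i}.ln2.b"] = ones(d), zeros(d)
            p[f"l{i}.w1"], p[f"l{i}.b1"] = w(d, f), zeros(f)
            p[f"l{i}.w2"], p[f"l{i}.b2"] = w(f, d), zeros(d)
        p["lnf.g"], p["lnf.b"] = ones(d), zeros(d)
        p["mlm.w"], p["mlm.b"] = w(d, v), zeros(v)
        self.params = p

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def copy(self) -> "Encoder":
        clone = Encoder.__new__(Encoder)
        clone.config = self.config
        clone.params = {
            k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.params.items()
        }
        return clone

    def forward(
        self, ids: np.ndarray, collect_attention: bool = False
    ) -> tuple[Tensor, list[np.ndarray]]:
        """Run the encoder; returns final hidden states (B, T, D) and,
        optionally, per-layer attention arrays of shape (B, H, T, T)."""
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        B, T = ids.shape
        cfg = self.config
        if T > cfg.max_positions:
            raise ValueError(
                f"input length {T} exceeds max_positions {cfg.max_positions}"
            )
        if ids.max() >= cfg.vocab_size or ids.min() < 0:
            raise ValueError("token id outside encoder vocabulary")

        p = self.params
        H, d = cfg.n_heads, cfg.hidden_dim
        dh = d // H
        x = ag.add(ag.embedding(p["tok_emb"], ids),
                   ag.embedding(p["pos_emb"], np.arange(T)))
        attentions: list[np.ndarray] = []
        for i in range(cfg.n_layers):
            h = ag.layer_norm(x, p[f"l{i}.ln1.g"], p[f"l{i}.ln1.b"])

            def heads(t: Tensor) -> Tensor:
                return ag.transpose(ag.reshape(t, (B, T, H, dh)), (0, 2, 1, 3))

            q = heads(ag.add(ag.matmul(h, p[f"l{i}.wq"]), p[f"l{i}.bq"]))
            k = heads(ag.add(ag.matmul(h, p[f"l{i}.wk"]), p[f"l{i}.bk"]))
            v = heads(ag.add(ag.matmul(h, p[f"l{i}.wv"]), p[f"l{i}.bv"]))
            scores = ag.scale(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), dh**-0.5)
            att = ag.softmax_lastdim(scores)
            if collect_attention:
                attentions.append(att.data.copy())
            ctx = ag.reshape(ag.transpose(ag.matmul(att, v), (0, 2, 1, 3)), (B, T, d))
            x = ag.add(x, ag.add(ag.matmul(ctx, p[f"l{i}.wo"]), p[f"l{i}.bo"]))

            h2 = ag.layer_norm(x, p[f"l{i}.ln2.g"], p[f"l{i}.ln2.b"])
            inner = ag.gelu(ag.add(ag.matmul(h2, p[f"l{i}.w1"]), p[f"l{i}.b1"]))
            x = ag.add(x, ag.add(ag.matmul(inner, p[f"l{i}.w2"]), p[f"l{i}.b2"]))
        x = ag.layer_norm(x, p["lnf.g"], p["lnf.b"])
        return x, attentions

    def mlm_logits(self, hidden: Tensor) -> Tensor:
        return ag.add(ag.matmul(hidden, self.params["mlm.w"]), self.params["mlm.b"])

    def save(self, path: str | Path) -> None:
        """Save weights as .npz with a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **{k: v.data for k, v in self.params.items()})
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(asdict(self.config), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Encoder":
        path = Path(path)
        config = EncoderConfig(**json.loads(path.with_suffix(".json").read_text()))
        enc = cls(config)
        with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
            for k in enc.params:
                enc.params[k].data = data[k].astype(np.float32)
        return enc


def init_encoder(config: EncoderConfig) -> Encoder:
    """Seed-deterministic encoder initialization."""
    return Encoder(config)


def pretrain_mlm(
    encoder: Encoder,
    corpus: Sequence[Sequence[int]] | np.ndarray,
    masking: MaskingConfig,
    train: TrainConfig,
    spec: TokenizerSpec,
) -> tuple[Encoder, list[float]]:
    """Masked-language-model pre-training; returns (encoder, loss trace).

    ``corpus`` is a collection of equal-length token-id chunks (sentinels
    included).  Each step draws a batch with the training seed, corrupts
    it with the masking seed, and takes one Adam step on the MLM
    cross-entropy.  Zero steps leaves the encoder unchanged.
    """
    chunks = np.asarray(corpus, dtype=np.int64)
    if chunks.ndim != 2 or chunks.size == 0:
        raise ValueError("corpus must be a non-empty set of equal-length id chunks")
    if chunks.max() >= encoder.config.vocab_size:
        raise ValueError("corpus token ids exceed encoder vocabulary")
    if spec.vocab_size != encoder.config.vocab_size:
        raise ValueError("tokenizer and encoder vocabulary sizes differ")
    steps = train.max_steps if train.max_steps is not None else 0
    losses: list[float] = []
    if steps == 0:
        return encoder, losses
    batch_rng = np.random.default_rng(train.seed)
    mask_rng = np.random.default_rng(masking.seed)
    opt = ag.Adam(encoder.parameters(), lr=train.learning_rate)
    n = chunks.shape[0]
    for _ in range(steps):
        idx = batch_rng.integers(0, n, size=min(train.batch_size, n))
        batch = apply_mlm_mask(chunks[idx], spec, masking, mask_rng)
        hidden, _ = encoder.forward(batch.input_ids)
        logits = encoder.mlm_logits(hidden)
        flat = ag.reshape(logits, (-1, encoder.config.vocab_size))
        loss = ag.cross_entropy_logits(flat, batch.labels.reshape(-1), IGNORE_LABEL)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return encoder, losses


@dataclass
class TaskModel:
    """Fine-tuned encoder plus a task head on the [CLS] representation."""

    encoder: Encoder
    head_w: Tensor
    head_b: Tensor
    tokenizer: TokenizerSpec
    task_kind: str  # classify | regress
    n_classes: int | None = None
    trained: bool = False

    def head_logits(self, hidden: Tensor) -> Tensor:
        pooled = ag.take_position(hidden, 0)  # [CLS]
        return ag.add(ag.matmul(pooled, self.head_w), self.head_b)

    def save(self, path: str | Path) -> None:
        """Save encoder (.npz + .json sidecar) and head (.head.npz)."""
        path = Path(path)
        self.encoder.save(path)
        np.savez(path.with_suffix(".head.npz"),
                 head_w=self.head_w.data, head_b=self.head_b.data)
        meta = {"task_kind": self.task_kind, "n_classes": self.n_classes,
                "k": self.tokenizer.k, "scheme": self.tokenizer.scheme,
                "trained": self.trained}
        path.with_suffix(".task.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TaskModel":
        from ..tokenization import build_vocab

        path = Path(path)
        encoder = Encoder.load(path)
        meta = json.loads(path.with_suffix(".task.json").read_text())
        with np.load(path.with_suffix(".head.npz")) as data:
            head_w = Tensor(data["head_w"], requires_grad=True)
            head_b = Tensor(data["head_b"], requires_grad=True)
        return cls(
            encoder=encoder, head_w=head_w, head_b=head_b,
            tokenizer=build_vocab(meta["k"], meta["scheme"]),
            task_kind=meta["task_kind"], n_classes=meta["n_classes"],
            trained=meta["trained"],
        )


def _record_to_pair(record) -> tuple[str, object]:
    if isinstance(record, tuple):
        return record
    if hasattr(record, "sequence") and hasattr(record, "label"):
        label = record.label
        if isinstance(label, str):
            label = CLASS_TO_INDEX[label]
        return record.sequence, label
    raise TypeError(f"cannot interpret training record {record!r}")


def encode_records(
    records: Iterable, tokenizer: TokenizerSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Tokenize (sequence, label) records into equal-length id/label arrays."""
    ids, labels = [], []
    for rec in records:
        seq, label = _record_to_pair(rec)
        ids.append(tokenize(seq, tokenizer, add_sentinels=True).token_ids)
        labels.append(label)
    lengths = {len(row) for row in ids}
    if len(lengths) != 1:
        raise ValueError(f"records tokenize to unequal lengths: {sorted(lengths)}")
    return np.asarray(ids, dtype=np.int64), np.asarray(labels)


def finetune(
    encoder: Encoder,
    dataset: Sequence,
    tokenizer: TokenizerSpec,
    train: TrainConfig,
    head: int | str,
) -> TaskModel:
    """Full fine-tuning: every encoder parameter plus a fresh task head.

    ``head`` is the number of classes, or ``"regression"`` for a scalar
    output.  ``dataset`` holds (sequence, label) pairs, LabeledWindow
    objects (labels mapped through :data:`CLASS_TO_INDEX`) or
    BenchmarkRecord objects.  The encoder is updated in place; use
    :meth:`Encoder.copy` first to preserve the pre-trained weights.
    """
    regression = head == "regression"
    n_out = 1 if regression else int(head)
    if not regression and n_out < 2:
        raise ValueError("classification head needs at least 2 classes")
    ids, labels = encode_records(dataset, tokenizer)
    if regression:
        labels = labels.astype(np.float32)
    else:
        labels = labels.astype(np.int64)
        if labels.min() < 0 or labels.max() >= n_out:
            raise ValueError(
                f"labels outside [0, {n_out}) do not fit a {n_out}-class head"
            )

    rng = np.random.default_rng(train.seed)
    d = encoder.config.hidden_dim
    model = TaskModel(
        encoder=encoder,
        head_w=Tensor(rng.normal(0, 0.02, (d, n_out)), requires_grad=True),
        head_b=Tensor(np.zeros(n_out), requires_grad=True),
        tokenizer=tokenizer,
        task_kind="regress" if regression else "classify",
        n_classes=None if regression else n_out,
    )
    opt = ag.Adam(
        encoder.parameters() + [model.head_w, model.head_b], lr=train.learning_rate
    )
    n = ids.shape[0]
    epochs = train.epochs if train.epochs is not None else 1
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, train.batch_size):
            if train.max_steps is not None and step >= train.max_steps:
                break
            sel = order[lo : lo + train.batch_size]
            hidden, _ = encoder.forward(ids[sel])
            out = model.head_logits(hidden)
            if regression:
                loss = ag.mse_loss(out, labels[sel])
            else:
                loss = ag.cross_entropy_logits(out, labels[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            step += 1
    model.trained = True
    return model


def predict_logits(model: TaskModel, records: Sequence, batch_size: int = 64) -> np.ndarray:
    """Batched logits (n_records, n_classes), or scalars for regression."""
    if not model.trained:
        raise RuntimeError("model head has not been trained; call finetune first")
    sequences = [
        r if isinstance(r, str) else _record_to_pair(r)[0] for r in records
    ]
    ids = np.asarray(
        [tokenize(s, model.tokenizer, add_sentinels=True).token_ids for s in sequences],
        dtype=np.int64,
    )
    outputs = []
    for lo in range(0, ids.shape[0], batch_size):
        hidden, _ = model.encoder.forward(ids[lo : lo + batch_size])
        outputs.append(model.head_logits(hidden).data)
    out = np.concatenate(outputs, axis=0)
    return out[:, 0] if model.task_kind == "regress" else out


def get_attention(
    model: TaskModel | Encoder, record, tokenizer: TokenizerSpec
) -> AttentionTensor:
    """Extract the full attention tensor for one input sequence."""
    encoder = model.encoder if isinstance(model, TaskModel) else model
    seq = record if isinstance(record, str) else _record_to_pair(record)[0]
    tok = tokenize(seq, tokenizer, add_sentinels=True)
    ids = np.asarray(tok.token_ids, dtype=np.int64)
    _, attentions = encoder.forward(ids, collect_attention=True)
    weights = np.stack([a[0] for a in attentions], axis=0)  # (L, H, T, T)
    sentinels = (0, len(tok.token_ids) - 1)
    return AttentionTensor(
        weights=weights,
        token_ids=ids,
        sentinel_indices=sentinels,
        spans=tok.spans,
    )
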