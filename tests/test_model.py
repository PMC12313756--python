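"""Desk-scale encoder: determinism, attention contract, trainability."""

import numpy as np
import pytest

from plantglm.corpus import MaskingConfig
from plantglm.model import autograd as ag
from plantglm.model.autograd import Tensor
from plantglm.model.encoder import (
    EncoderConfig,
    TrainConfig,
    finetune,
    get_attention,
    init_encoder,
    predict_logits,
    pretrain_mlm,
)
from plantglm.tokenization import build_vocab, expected_token_count, tokenize

SPEC = build_vocab(3, "overlapping")


def tiny_config(**kw):
    defaults = dict(vocab_size=SPEC.vocab_size, n_layers=2, n_heads=2,
                    hidden_dim=32, max_positions=64, seed=0)
    defaults.update(kw)
    return EncoderConfig(**defaults)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def encoder():
    return init_encoder(tiny_config())


class TestAutograd:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(0, 1, (2, 4, 8)).astype(np.float32), requires_grad=True)
        w = Tensor(rng.normal(0, 0.5, (8, 8)).astype(np.float32), requires_grad=True)
        labels = rng.integers(0, 8, 8)

        def loss_value():
            h = ag.gelu(ag.matmul(ag.softmax_lastdim(x), w))
            return ag.cross_entropy_logits(ag.reshape(h, (8, 8)), labels)

        loss = loss_value()
        loss.backward()
        eps = 1e-3
        for t in (x, w):
            flat = t.data.reshape(-1)
            for idx in (0, flat.size // 2, flat.size - 1):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(loss_value().data)
                flat[idx] = orig - eps
                down = float(loss_value().data)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert t.grad.reshape(-1)[idx] == pytest.approx(numeric, abs=5e-3)


class TestForwardContract:
    def test_same_seed_identical_outputs(self):
        rng = np.random.default_rng(1)
        ids = rng.integers(5, SPEC.vocab_size, (2, 20))
        h1, _ = init_encoder(tiny_config()).forward(ids)
        h2, _ = init_encoder(tiny_config()).forward(ids)
        assert (h1.data == h2.data).all()

    def test_input_longer_than_max_positions_rejected(self, encoder):
        with pytest.raises(ValueError, match="max_positions"):
            encoder.forward(np.zeros((1, 65), dtype=np.int64))

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            EncoderConfig(vocab_size=69, hidden_dim=30, n_heads=4)

    def test_attention_tensor_shape_and_normalization(self, encoder):
        seq = random_dna(np.random.default_rng(2), 40)
        att = get_attention(encoder, seq, SPEC)
        T = expected_token_count(40, 3, "overlapping", with_sentinels=True)
        assert att.weights.shape == (2, 2, T, T)
        assert att.check_normalized(tol=1e-5)
        assert att.weights.min() >= 0 and att.weights.max() <= 1
        assert att.sentinel_indices == (0, T - 1)

    def test_attention_is_deterministic(self, encoder):
        seq = random_dna(np.random.default_rng(3), 30)
        a = get_attention(encoder, seq, SPEC)
        b = get_attention(encoder, seq, SPEC)
        assert (a.weights == b.weights).all()


class TestPretrain:
    def corpus_ids(self, n=64, length=30):
        rng = np.random.default_rng(7)
        return np.array([
            tokenize(random_dna(rng, length), SPEC, add_sentinels=True).token_ids
            for _ in range(n)
        ])

    def test_zero_steps_leaves_encoder_unchanged(self):
        enc = init_encoder(tiny_config())
        before = {k: v.data.copy() for k, v in enc.params.items()}
        _, losses = pretrain_mlm(
            enc, self.corpus_ids(), MaskingConfig(seed=0),
            TrainConfig(max_steps=0, task_kind="mlm"), SPEC,
        )
        assert losses == []
        assert all((enc.params[k].data == v).all() for k, v in before.items())

    def test_initial_loss_near_log_vocab_size(self):
        enc = init_encoder(tiny_config())
        _, losses = pretrain_mlm(
            enc, self.corpus_ids(), MaskingConfig(seed=0),
            TrainConfig(max_steps=1, batch_size=32, task_kind="mlm"), SPEC,
        )
        assert losses[0] == pytest.approx(np.log(SPEC.vocab_size), rel=0.05)

    def test_loss_decreases_with_training(self):
        enc = init_encoder(tiny_config())
        _, losses = pretrain_mlm(
            enc, self.corpus_ids(), MaskingConfig(seed=0),
            TrainConfig(max_steps=60, batch_size=32, learning_rate=1e-3,
                        task_kind="mlm", seed=0),
            SPEC,
        )
        assert np.mean(losses[-10:]) < losses[0]

    def test_vocab_mismatch_rejected(self):
        enc = init_encoder(tiny_config(vocab_size=100))
        with pytest.raises(ValueError, match="vocabulary"):
            pretrain_mlm(enc, self.corpus_ids(), MaskingConfig(),
                         TrainConfig(max_steps=1, task_kind="mlm"), SPEC)


class TestFinetune:
    def toy_dataset(self, n=30, length=30):
        """Two classes separated by a planted central motif."""
        rng = np.random.default_rng(11)
        data = []
        for i in range(n):
            seq = list(random_dna(rng, length))
            label = i % 2
            if label:
                seq[12:18] = "GTAAGT"
            data.append(("".join(seq), label))
        return data

    def test_overfit_small_dataset(self):
        data = self.toy_dataset()
        enc = init_encoder(tiny_config())
        model = finetune(enc, data, SPEC,
                         TrainConfig(epochs=40, batch_size=30, learning_rate=1e-3,
                                     seed=0),
                         head=2)
        pred = predict_logits(model, data).argmax(axis=1)
        truth = np.array([lab for _, lab in data])
        assert (pred == truth).mean() == 1.0

    def test_three_class_head_logit_width(self):
        data = [(s, lab % 3) for i, (s, lab) in enumerate(self.toy_dataset(12))
                for lab in [i]]
        model = finetune(init_encoder(tiny_config()), data, SPEC,
                         TrainConfig(epochs=1, batch_size=4, seed=0), head=3)
        assert predict_logits(model, data).shape == (12, 3)

    def test_batching_invariance(self):
        data = self.toy_dataset(9)
        model = finetune(init_encoder(tiny_config()), data, SPEC,
                         TrainConfig(epochs=2, batch_size=4, seed=0), head=2)
        one = predict_logits(model, data, batch_size=1)
        many = predict_logits(model, data, batch_size=32)
        assert np.abs(one - many).max() < 1e-5

    def test_duplicated_record_duplicated_logits(self):
        data = self.toy_dataset(4)
        model = finetune(init_encoder(tiny_config()), data, SPEC,
                         TrainConfig(epochs=1, batch_size=4, seed=0), head=2)
        logits = predict_logits(model, [data[0][0], data[0][0]])
        assert (logits[0] == logits[1]).all()

    def test_regression_head_finite_predictions(self):
        rng = np.random.default_rng(0)
        data = [(random_dna(rng, 30), float(rng.normal())) for _ in range(8)]
        model = finetune(init_encoder(tiny_config()), data, SPEC,
                         TrainConfig(epochs=2, batch_size=4, seed=0),
                         head="regression")
        pred = predict_logits(model, data)
        assert pred.shape == (8,) and np.isfinite(pred).all()

    def test_label_head_mismatch_rejected(self):
        data = [(s, lab + 5) for s, lab in self.toy_dataset(4)]
        with pytest.raises(ValueError, match="head"):
            finetune(init_encoder(tiny_config()), data, SPEC,
                     TrainConfig(epochs=1, seed=0), head=2)

    def test_untrained_head_rejected_at_predict(self):
        from plantglm.model.encoder import TaskModel
        enc = init_encoder(tiny_config())
        model = TaskModel(encoder=enc, head_w=Tensor(np.zeros((32, 2))),
                          head_b=Tensor(np.zeros(2)), tokenizer=SPEC,
                          task_kind="classify", n_classes=2)
        with pytest.raises(RuntimeError, match="finetune"):
            predict_logits(model, ["ACGTACGT"])


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, encoder):
        path = tmp_path / "enc.npz"
        encoder.save(path)
        loaded = type(encoder).load(path)
        ids = np.random.default_rng(0).integers(5, 60, (1, 10))
        h1, _ = encoder.forward(ids)
        h2, _ = loaded.forward(ids)
        assert np.allclose(h1.data, h2.data)
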