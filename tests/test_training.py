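import numpy as np
import pytest

from cnnfold.core import RnaSequence, SecondaryStructure
from cnnfold.io import StructureRecord
from cnnfold.network import CNNFoldNet, ModelConfig, forward
from cnnfold.synthetic import SyntheticConfig, make_dataset
from cnnfold.training import (
    TrainConfig,
    VARIANT_PRESETS,
    _batch_loss_and_grads,
    make_batches,
    mix_predict,
    train,
)

TINY_MODEL = dict(channels=8, kernel=3)


def _record_of_length(L: int, id: str = "r") -> StructureRecord:
    # hairpin: (1, L) stem of 3 pairs
    pairs = {(1 + d, L - d) for d in range(3)}
    q = ["A"] * L
    for i, j in pairs:
        q[i - 1], q[j - 1] = "G", "C"
    return StructureRecord(RnaSequence(id, "".join(q)), SecondaryStructure(L, pairs))


class TestVariantPresets:
    def test_published_variant_table(self):
        p = VARIANT_PRESETS
        assert (p["CNNFold"].M, p["CNNFold"].N, p["CNNFold"].epochs) == (2, 2, 30)
        assert p["CNNFold"].max_train_length is None
        assert (p["CNNFold-600"].M, p["CNNFold-600"].N, p["CNNFold-600"].epochs) == (2, 2, 400)
        assert p["CNNFold-600"].max_train_length == 600
        assert (
            p["CNNFold-600-big"].M,
            p["CNNFold-600-big"].N,
            p["CNNFold-600-big"].epochs,
        ) == (10, 2, 45)
        assert p["CNNFold-600-big"].max_train_length == 600


class TestMakeBatches:
    def test_long_sequences_isolated(self):
        records = [_record_of_length(L, f"r{L}") for L in (40, 45, 1200, 50)]
        batches = make_batches(records, TrainConfig(seed=0))
        sizes = sorted(len(b.ids) for b in batches)
        assert sizes == [1, 3]
        solo = next(b for b in batches if len(b.ids) == 1)
        assert solo.lengths == [1200]

    def test_chunking_respects_max_batch(self):
        records = [_record_of_length(30, f"r{i}") for i in range(20)]
        batches = make_batches(records, TrainConfig(seed=0, max_batch=16))
        assert sorted(len(b.ids) for b in batches) == [4, 16]

    def test_order_is_seed_reproducible(self):
        records = [_record_of_length(30 + i, f"r{i}") for i in range(40)]
        a = make_batches(records, TrainConfig(seed=3))
        b = make_batches(records, TrainConfig(seed=3))
        c = make_batches(records, TrainConfig(seed=4))
        assert [x.ids for x in a] == [x.ids for x in b]
        assert [x.ids for x in a] != [x.ids for x in c]

    def test_empty_dataset_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            make_batches([], TrainConfig())

    def test_max_train_length_filters_strictly(self):
        records = [_record_of_length(L, f"r{L}") for L in (40, 600, 599)]
        batches = make_batches(records, TrainConfig(seed=0, max_train_length=600))
        lengths = sorted(L for b in batches for L in b.lengths)
        assert lengths == [40, 599]


class TestPaddingExclusion:
    def test_padded_cells_outside_valid_mask_and_gradients_unaffected(self):
        records = [_record_of_length(20, "a"), _record_of_length(30, "b")]
        batches = make_batches(records, TrainConfig(seed=0))
        (batch,) = batches
        # the padded area of the shorter sample is excluded from V
        short = batch.lengths.index(20)
        assert not batch.v[short, 20:, :].any()
        assert not batch.v[short, :, 20:].any()

        model = CNNFoldNet(ModelConfig(M=1, N=1, seed=0, **TINY_MODEL))
        ys, tape = model.forward_batch(batch.x, mask=batch.bn_mask, training=True)
        loss_a, dys = _batch_loss_and_grads(ys, batch)
        for p in model.parameters():
            p.zero_grad()
        model.backward_batch(dys, tape)
        grads_a = [p.grad.copy() for p in model.parameters()]

        # perturb the padded input and target cells; nothing may change
        batch.x[short, 20:, :, :] += 7.0
        batch.x[short, :, 20:, :] += 7.0
        batch.t[short, 20:, :] += 5.0
        model2 = CNNFoldNet(ModelConfig(M=1, N=1, seed=0, **TINY_MODEL))
        ys2, tape2 = model2.forward_batch(batch.x, mask=batch.bn_mask, training=True)
        loss_b, dys2 = _batch_loss_and_grads(ys2, batch)
        for p in model2.parameters():
            p.zero_grad()
        model2.backward_batch(dys2, tape2)
        assert loss_b == pytest.approx(loss_a, rel=1e-6)
        for ga, p in zip(grads_a, model2.parameters()):
            assert np.allclose(ga, p.grad, atol=1e-6)


class TestTrain:
    def test_loss_decreases_when_overfitting_one_record(self):
        records = make_dataset(1, SyntheticConfig(length_range=(30, 40)), seed=2)
        result = train(
            records,
            ModelConfig(M=1, N=1, seed=0, **TINY_MODEL),
            TrainConfig(epochs=40, max_steps=40, seed=0),
        )
        assert result.history[-1]["loss"] < result.history[0]["loss"]

    def test_same_seed_gives_identical_loss_history(self):
        records = make_dataset(4, SyntheticConfig(length_range=(30, 40)), seed=2)
        cfg_m = ModelConfig(M=1, N=1, seed=1, **TINY_MODEL)
        cfg_t = TrainConfig(epochs=3, seed=5)
        a = train(records, cfg_m, cfg_t)
        b = train(records, cfg_m, cfg_t)
        assert [h["loss"] for h in a.history] == [h["loss"] for h in b.history]

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_nan_loss_aborts_with_diagnostics(self):
        records = make_dataset(1, SyntheticConfig(length_range=(30, 40)), seed=2)
        with pytest.raises(FloatingPointError, match="step"):
            # absurd learning rate drives the optimization to overflow
            train(
                records,
                ModelConfig(M=1, N=1, seed=0, **TINY_MODEL),
                TrainConfig(epochs=300, learning_rate=1e12, seed=0),
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(max_batch=0)


class TestMixPredict:
    def test_length_dispatch_inclusive_threshold(self):
        model_short = CNNFoldNet(ModelConfig(M=0, N=1, seed=1, channels=4))
        model_long = CNNFoldNet(ModelConfig(M=0, N=1, seed=2, channels=4))
        q_at = _record_of_length(40, "at").sequence
        q_over = _record_of_length(41, "over").sequence
        from cnnfold.encoding import encode_sequence

        y_at = mix_predict(q_at, model_short, model_long, threshold=40)
        y_over = mix_predict(q_over, model_short, model_long, threshold=40)
        assert np.array_equal(
            y_at.values, forward(encode_sequence(q_at), model_short)[-1].values
        )
        assert np.array_equal(
            y_over.values, forward(encode_sequence(q_over), model_long)[-1].values
        )

    def test_default_threshold_is_600(self):
        import inspect

        sig = inspect.signature(mix_predict)
        assert sig.parameters["threshold"].default == 600

    def test_missing_model_is_an_error(self):
        q = _record_of_length(30, "q").sequence
        with pytest.raises(ValueError):
            mix_predict(q, None, None)
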