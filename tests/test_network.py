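import numpy as np
import pytest

from cnnfold.core import RnaSequence
from cnnfold.encoding import encode_sequence, encode_target, valid_mask
from cnnfold.network import (
    CNNFoldNet,
    ModelConfig,
    ScoreMatrix,
    build_model,
    forward,
    load_checkpoint,
    loss,
    save_checkpoint,
)
from cnnfold.synthetic import SyntheticConfig, make_dataset
from cnnfold.training import Batch, _batch_loss_and_grads

TINY = dict(channels=4, kernel=3)  # fast configs for structural tests


def _n_params(cfg):
    return build_model(cfg).n_parameters()


class TestBuildModel:
    def test_shared_block_has_a_single_weight_set(self):
        # parameter count must not depend on N: one shared block reused N times
        assert _n_params(ModelConfig(M=2, N=2, **TINY)) == _n_params(
            ModelConfig(M=2, N=7, **TINY)
        )

    def test_same_seed_same_initial_parameters(self):
        a = build_model(ModelConfig(M=2, N=2, seed=3, **TINY))
        b = build_model(ModelConfig(M=2, N=2, seed=3, **TINY))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_more_distinct_blocks_more_parameters(self):
        assert _n_params(ModelConfig(M=10, N=2, **TINY)) > _n_params(
            ModelConfig(M=2, N=2, **TINY)
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(M=-1)
        with pytest.raises(ValueError):
            ModelConfig(N=0)
        with pytest.raises(ValueError):
            ModelConfig(kernel=2)


class TestForward:
    def test_n_score_matrices_of_matching_shape(self, worked_sequence):
        model = build_model(ModelConfig(M=1, N=2, **TINY))
        ys = forward(encode_sequence(worked_sequence), model)
        assert len(ys) == 2
        assert all(y.values.shape == (31, 31) for y in ys)
        assert [y.iteration for y in ys] == [1, 2]

    def test_eval_mode_is_deterministic(self, worked_sequence):
        model = build_model(ModelConfig(M=1, N=2, **TINY))
        X = encode_sequence(worked_sequence)
        a = forward(X, model)
        b = forward(X, model)
        for ya, yb in zip(a, b):
            assert np.array_equal(ya.values, yb.values)

    def test_fully_convolutional_contract(self):
        # one instance accepts very different lengths without rebuild
        model = build_model(ModelConfig(M=1, N=1, **TINY))
        for L in (20, 200):
            q = RnaSequence("x", "".join("ACGU"[i % 4] for i in range(L)))
            ys = forward(encode_sequence(q), model)
            assert ys[-1].values.shape == (L, L)

    def test_score_matrix_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            ScoreMatrix(np.full((3, 3), np.nan), 1)


class TestLoss:
    def test_zero_when_outputs_equal_target(self, worked_structure, worked_sequence):
        T = encode_target(worked_structure)
        V = valid_mask(worked_sequence)
        assert loss([T.values, T.values], T, V) == 0.0

    def test_single_cell_error_in_one_of_two_passes(self, worked_structure, worked_sequence):
        T = encode_target(worked_structure)
        V = valid_mask(worked_sequence)
        m = V.size
        y1 = T.values.copy()
        ii, jj = np.argwhere(V.array)[0]
        y1[ii, jj] += 1.0
        assert loss([y1, T.values], T, V) == pytest.approx(1.0 / (2 * m))

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(10):
            L = int(rng.integers(4, 9))
            N = int(rng.integers(1, 4))
            ys = [rng.normal(size=(L, L)) for _ in range(N)]
            t = rng.integers(0, 2, size=(L, L)).astype(float)
            v = rng.random((L, L)) < 0.6
            v[0, 0] = True
            expected = 0.0
            for y in ys:
                acc = 0.0
                for i in range(L):
                    for j in range(L):
                        if v[i, j]:
                            acc += (y[i, j] - t[i, j]) ** 2
                expected += acc / v.sum()
            expected /= N
            assert loss(ys, t, v) == pytest.approx(expected, rel=1e-12)

    def test_perturbation_outside_mask_never_changes_loss(self, rng):
        L = 10
        t = np.eye(L)
        v = np.zeros((L, L), dtype=bool)
        v[np.diag_indices(L)] = True
        v[0, 5] = v[5, 0] = True
        y = rng.normal(size=(L, L))
        base = loss([y], t, v)
        y2 = y.copy()
        y2[~v] += rng.normal(size=int((~v).sum())) * 100
        assert loss([y2], t, v) == base

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            loss([np.zeros((3, 3))], np.eye(3), np.zeros((3, 3), dtype=bool))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients of the full model agree with central differences."""
        cfg = ModelConfig(M=1, N=2, channels=4, kernel=3, seed=11)
        model = CNNFoldNet(cfg, dtype=np.float64)
        B, Lm = 2, 6
        x = rng.uniform(0, 1, (B, Lm, Lm, 8))
        t = rng.uniform(0, 1, (B, Lm, Lm))
        v = np.zeros((B, Lm, Lm), dtype=bool)
        v[0, :6, :6] = rng.random((6, 6)) < 0.7
        v[1, :4, :4] = rng.random((4, 4)) < 0.7
        v[0, 0, 0] = v[1, 0, 0] = True
        bn = np.zeros((B, Lm, Lm, 1))
        bn[0, :6, :6, 0] = 1
        bn[1, :4, :4, 0] = 1
        batch = Batch(["a", "b"], [6, 4], x, t, v, bn)

        def compute():
            ys, tape = model.forward_batch(batch.x, mask=batch.bn_mask, training=True)
            return (*_batch_loss_and_grads(ys, batch), tape)

        lv, dys, tape = compute()
        for p in model.parameters():
            p.zero_grad()
        model.backward_batch(dys, tape)

        eps = 1e-6
        for p in model.parameters():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = compute()[0]
                flat[i] = orig - eps
                lm = compute()[0]
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(num, rel=1e-4, abs=1e-8), p.name


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path, worked_sequence):
        model = build_model(ModelConfig(M=1, N=2, seed=5, **TINY))
        X = encode_sequence(worked_sequence)
        before = forward(X, model)[-1].values
        p = tmp_path / "model.npz"
        save_checkpoint(model, p)
        loaded = load_checkpoint(p)
        assert loaded.cfg == model.cfg
        assert np.array_equal(forward(X, loaded)[-1].values, before)

    def test_missing_checkpoint_is_an_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_checkpoint(tmp_path / "nope.npz")


def test_overfit_single_record_recovers_structure():
    """A small model memorizes one sample; argmax on Y_N reproduces it."""
    from cnnfold.decoding import argmax_decode
    from cnnfold.training import TrainConfig, train

    records = make_dataset(1, SyntheticConfig(length_range=(30, 40)), seed=2)
    cfg = ModelConfig(M=1, N=2, channels=8, seed=0)
    result = train(
        records, cfg,
        TrainConfig(epochs=200, max_steps=200, seed=0, f1_stop=1.0, f1_check_every=20),
    )
    rec = records[0]
    ys = forward(encode_sequence(rec.sequence), result.model)
    s, violations = argmax_decode(ys[-1], valid_mask(rec.sequence))
    assert s == rec.structure and violations == []
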