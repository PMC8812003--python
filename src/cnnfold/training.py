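"""Training loop: Adam, length-aware mini-batching, model-variant presets,
and the length-threshold model dispatch for mixed prediction.

Mini-batches hold up to ``max_batch`` samples padded to the longest member;
any sequence longer than ``solo_length_threshold`` (default 1000 nt) trains
alone. Padded cells carry all-zero input channels, sit outside every
sample's valid mask (so they never contribute to the loss), and are excluded
from batch-normalization statistics — gradients from padding are exactly
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RnaSequence
from .decoding import argmax_decode
from .encoding import encode_sequence, encode_target, valid_mask
from .io import StructureRecord
from .metrics import pair_metrics
from .network import CNNFoldNet, ModelConfig, ScoreMatrix, make_optimizer

__all__ = [
    "TrainConfig",
    "VariantPreset",
    "VARIANT_PRESETS",
    "Batch",
    "make_batches",
    "train",
    "TrainResult",
    "training_set_f1",
    "mix_predict",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings. Defaults follow the published training setup:
    Adam at learning rate 0.005, mini-batches of up to 16 samples, sequences
    longer than 1000 nt alone in their batch, fixed epoch budget."""

    learning_rate: float = 0.005
    epochs: int = 30
    max_batch: int = 16
    solo_length_threshold: int = 1000
    max_train_length: int | None = None
    seed: int = 0
    max_steps: int | None = None
    f1_stop: float | None = None  # stop once mean training F1 reaches this
    f1_check_every: int = 25

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_batch < 1:
            raise ValueError("max_batch must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class VariantPreset:
    """A published model variant: architecture + training length filter."""

    name: str
    M: int
    N: int
    epochs: int
    max_train_length: int | None


VARIANT_PRESETS: dict[str, VariantPreset] = {
    "CNNFold": VariantPreset("CNNFold", M=2, N=2, epochs=30, max_train_length=None),
    "CNNFold-600": VariantPreset("CNNFold-600", M=2, N=2, epochs=400, max_train_length=600),
    "CNNFold-600-big": VariantPreset(
        "CNNFold-600-big", M=10, N=2, epochs=45, max_train_length=600
    ),
}


@dataclass
class Batch:
    ids: list[str]
    lengths: list[int]
    x: np.ndarray  # (B, Lmax, Lmax, 8) channels-last
    t: np.ndarray  # (B, Lmax, Lmax)
    v: np.ndarray  # (B, Lmax, Lmax) bool: valid loss cells (padding excluded)
    bn_mask: np.ndarray  # (B, Lmax, Lmax, 1): real (non-padding) cells


def _encode_record(rec: StructureRecord):
    X = encode_sequence(rec.sequence).values  # (L, L, 8)
    T = encode_target(rec.structure).values
    V = valid_mask(rec.sequence).array
    return X, T, V


def make_batches(
    records: list[StructureRecord], cfg: TrainConfig, dtype=np.float32
) -> list[Batch]:
    """Group records into padded mini-batches.

    Records over the solo threshold get singleton batches; the rest are
    sorted by length (minimizing padding) and chunked to ``max_batch``.
    Batch order is shuffled with the config seed.
    """
    if not records:
        raise ValueError("empty dataset")
    if cfg.max_train_length is not None:
        records = [r for r in records if r.structure.length < cfg.max_train_length]
        if not records:
            raise ValueError("no records shorter than max_train_length")
    solo = [r for r in records if r.structure.length > cfg.solo_length_threshold]
    rest = sorted(
        (r for r in records if r.structure.length <= cfg.solo_length_threshold),
        key=lambda r: (r.structure.length, r.sequence.id),
    )
    groups = [[r] for r in solo]
    groups += [rest[i : i + cfg.max_batch] for i in range(0, len(rest), cfg.max_batch)]

    batches: list[Batch] = []
    for group in groups:
        lengths = [g.structure.length for g in group]
        Lm = max(lengths)
        B = len(group)
        x = np.zeros((B, Lm, Lm, 8), dtype=dtype)
        t = np.zeros((B, Lm, Lm), dtype=dtype)
        v = np.zeros((B, Lm, Lm), dtype=bool)
        bn = np.zeros((B, Lm, Lm, 1), dtype=dtype)
        for b, rec in enumerate(group):
            X, T, V = _encode_record(rec)
            L = rec.structure.length
            x[b, :L, :L, :] = X
            t[b, :L, :L] = T
            v[b, :L, :L] = V
            bn[b, :L, :L, 0] = 1.0
        batches.append(
            Batch([g.sequence.id for g in group], lengths, x, t, v, bn)
        )
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(batches))
    return [batches[i] for i in order]


def _batch_loss_and_grads(ys: list[np.ndarray], batch: Batch):
    """Masked intermediate MSE averaged over passes and batch members, plus
    the gradients with respect to each Y_n."""
    N = len(ys)
    B = batch.x.shape[0]
    sizes = batch.v.sum(axis=(1, 2)).astype(np.float64)  # |V_b| per sample
    total = 0.0
    dys = []
    for y in ys:
        diff = (y.astype(np.float64) - batch.t) * batch.v
        per_sample = (diff * diff).sum(axis=(1, 2)) / sizes
        total += per_sample.sum() / B
        dys.append((2.0 * diff / (sizes[:, None, None] * N * B)).astype(y.dtype))
    return total / N, dys


@dataclass
class TrainResult:
    model: CNNFoldNet
    history: list[dict]  # one entry per optimization step
    epochs_run: int
    steps_run: int
    final_f1: float | None = None


def training_set_f1(model: CNNFoldNet, records: list[StructureRecord]) -> float:
    """Mean exact-pair F1 of argmax-decoded predictions over the records."""
    f1s = []
    for rec in records:
        ys = forward_record(model, rec.sequence)
        s, _ = argmax_decode(ys[-1], valid_mask(rec.sequence))
        f1s.append(pair_metrics(s, rec.structure).f1)
    return float(np.mean(f1s))


def forward_record(model: CNNFoldNet, q: RnaSequence) -> list[ScoreMatrix]:
    from .network import forward as _forward

    return _forward(encode_sequence(q), model)


def train(
    records: list[StructureRecord],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> TrainResult:
    """Train a score network; fully seeded and deterministic.

    Raises on NaN loss with step diagnostics. If ``f1_stop`` is set, training
    halts as soon as the mean training-set F1 (argmax decoding) reaches it.
    """
    batches = make_batches(records, train_cfg)
    model = CNNFoldNet(model_cfg)
    opt = make_optimizer(model, train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed + 1)
    history: list[dict] = []
    step = 0
    final_f1: float | None = None
    for epoch in range(train_cfg.epochs):
        for bi in rng.permutation(len(batches)):
            batch = batches[bi]
            ys, tape = model.forward_batch(batch.x, mask=batch.bn_mask, training=True)
            loss_value, dys = _batch_loss_and_grads(ys, batch)
            if not np.isfinite(loss_value):
                raise FloatingPointError(
                    f"non-finite loss {loss_value} at step {step} "
                    f"(epoch {epoch}, batch ids {batch.ids[:3]}...)"
                )
            opt.zero_grad()
            model.backward_batch(dys, tape)
            opt.step()
            step += 1
            history.append({"step": step, "epoch": epoch, "loss": float(loss_value)})
            if (
                train_cfg.f1_stop is not None
                and step % train_cfg.f1_check_every == 0
            ):
                final_f1 = training_set_f1(model, records)
                if final_f1 >= train_cfg.f1_stop:
                    return TrainResult(model, history, epoch + 1, step, final_f1)
            if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
                return TrainResult(
                    model, history, epoch + 1, step,
                    training_set_f1(model, records) if train_cfg.f1_stop else None,
                )
    if train_cfg.f1_stop is not None and final_f1 is None:
        final_f1 = training_set_f1(model, records)
    return TrainResult(model, history, train_cfg.epochs, step, final_f1)


def mix_predict(
    q: RnaSequence,
    model_short: CNNFoldNet,
    model_long: CNNFoldNet,
    threshold: int = 600,
) -> ScoreMatrix:
    """Length dispatch between two trained models: sequences with
    L <= threshold go to ``model_short`` (the higher-capacity short-sequence
    model), longer ones to ``model_long``. Returns the final-pass scores."""
    if model_short is None or model_long is None:
        raise ValueError("both models must be provided")
    model = model_short if len(q) <= threshold else model_long
    return forward_record(model, q)[-1]
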