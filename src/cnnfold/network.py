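"""The convolutional score network.

Architecture: two conv blocks on the 8-channel pairwise input, M residual
blocks with distinct weights, then a single weight-shared residual block
applied N times like a recurrent model. After every shared pass a shared
readout (a 1x1 conv block plus a final 1x1 convolution with one output
channel) produces an L x L score matrix Y_n. Every conv block is
convolution -> batch normalization -> LeakyReLU, all with 32 output channels
except the final readout convolution; spatial size is preserved by padding,
so one model instance handles any sequence length.

Training penalizes each intermediate output with a masked mean-squared
error l_n = (1/|V|) sum_{ij in V} (y_ij^(n) - t_ij)^2 restricted to the
valid-cell set V, and averages them: l = (1/N) sum_n l_n. Supervising every
shared pass pushes the recurrence toward the fixed point early.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .encoding import PairTensor, TargetMatrix, ValidMask
from .nn import Adam, BatchNorm2d, Conv2d, LeakyReLU, Param

__all__ = [
    "ModelConfig",
    "ScoreMatrix",
    "CNNFoldNet",
    "build_model",
    "forward",
    "loss",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    M distinct residual blocks, N applications of the one shared residual
    block. The published variants use (M, N) = (2, 2) and (10, 2).
    """

    M: int = 2
    N: int = 2
    channels: int = 32
    kernel: int = 3
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 1")


@dataclass(frozen=True)
class ScoreMatrix:
    """L x L real-valued pairing scores from shared pass ``iteration`` (1-based)."""

    values: np.ndarray
    iteration: int

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"score matrix must be square, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("score matrix contains non-finite values")


class _ConvBlock:
    def __init__(self, cin, cout, k, slope, rng, name, dtype):
        self.conv = Conv2d(cin, cout, k, rng, name=f"{name}.conv", dtype=dtype)
        self.bn = BatchNorm2d(cout, name=f"{name}.bn", dtype=dtype)
        self.act = LeakyReLU(slope)

    def forward(self, x, mask, training):
        h, c1 = self.conv.forward(x)
        h, c2 = self.bn.forward(h, mask, training)
        h, c3 = self.act.forward(h)
        return h, (c1, c2, c3)

    def backward(self, g, cache):
        c1, c2, c3 = cache
        g = self.act.backward(g, c3)
        g = self.bn.backward(g, c2)
        return self.conv.backward(g, c1)

    def params(self):
        return self.conv.params() + self.bn.params()


class _ResidualBlock:
    """conv block -> conv -> batch-norm, identity skip added before the
    final LeakyReLU."""

    def __init__(self, c, k, slope, rng, name, dtype):
        self.cb = _ConvBlock(c, c, k, slope, rng, f"{name}.cb", dtype)
        self.conv2 = Conv2d(c, c, k, rng, name=f"{name}.conv2", dtype=dtype)
        self.bn2 = BatchNorm2d(c, name=f"{name}.bn2", dtype=dtype)
        self.act = LeakyReLU(slope)

    def forward(self, x, mask, training):
        h, c1 = self.cb.forward(x, mask, training)
        z, c2 = self.conv2.forward(h)
        z, c3 = self.bn2.forward(z, mask, training)
        out, c4 = self.act.forward(z + x)
        return out, (c1, c2, c3, c4)

    def backward(self, g, cache):
        c1, c2, c3, c4 = cache
        gz = self.act.backward(g, c4)
        gh = self.bn2.backward(gz, c3)
        gh = self.conv2.backward(gh, c2)
        return self.cb.backward(gh, c1) + gz

    def params(self):
        return self.cb.params() + self.conv2.params() + self.bn2.params()


class _Readout:
    """1x1 conv block then a 1x1 convolution to one channel; one weight set
    shared across all N shared passes."""

    def __init__(self, c, slope, rng, name, dtype):
        self.cb = _ConvBlock(c, c, 1, slope, rng, f"{name}.cb", dtype)
        self.out = Conv2d(c, 1, 1, rng, name=f"{name}.out", dtype=dtype)

    def forward(self, x, mask, training):
        h, c1 = self.cb.forward(x, mask, training)
        y, c2 = self.out.forward(h)
        return y[..., 0], (c1, c2)  # (B, H, W)

    def backward(self, g, cache):
        c1, c2 = cache
        gh = self.out.backward(g[..., None], c2)
        return self.cb.backward(gh, c1)

    def params(self):
        return self.cb.params() + self.out.params()


class CNNFoldNet:
    """Fully-convolutional pairing score network (see module docstring)."""

    def __init__(self, cfg: ModelConfig, dtype=np.float32) -> None:
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        c, k, s = cfg.channels, cfg.kernel, cfg.leaky_slope
        self.in1 = _ConvBlock(8, c, k, s, rng, "in1", dtype)
        self.in2 = _ConvBlock(c, c, k, s, rng, "in2", dtype)
        self.blocks = [
            _ResidualBlock(c, k, s, rng, f"res{m}", dtype) for m in range(cfg.M)
        ]
        self.shared = _ResidualBlock(c, k, s, rng, "shared", dtype)
        self.readout = _Readout(c, s, rng, "readout", dtype)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Param]:
        ps = self.in1.params() + self.in2.params()
        for b in self.blocks:
            ps += b.params()
        ps += self.shared.params() + self.readout.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def _bn_layers(self) -> list[tuple[str, BatchNorm2d]]:
        out = [("in1", self.in1.bn), ("in2", self.in2.bn)]
        for m, b in enumerate(self.blocks):
            out += [(f"res{m}.cb", b.cb.bn), (f"res{m}.bn2", b.bn2)]
        out += [("shared.cb", self.shared.cb.bn), ("shared.bn2", self.shared.bn2)]
        out += [("readout.cb", self.readout.cb.bn)]
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.parameters()}
        for prefix, bn in self._bn_layers():
            state[f"{prefix}.running_mean"] = bn.running_mean
            state[f"{prefix}.running_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for prefix, bn in self._bn_layers():
            bn.running_mean[...] = state[f"{prefix}.running_mean"]
            bn.running_var[...] = state[f"{prefix}.running_var"]

    # -- forward / backward -------------------------------------------------

    def forward_batch(
        self, x: np.ndarray, mask: np.ndarray | None = None, training: bool = False
    ):
        """x: (B, H, W, 8) channels-last; mask: (B, H, W, 1) of {0,1} or None.

        Returns (list of N (B, H, W) score arrays, tape for backward).
        """
        if mask is not None:
            # padded cells must be inert: zero them before the first
            # convolution so they cannot leak into real edge cells
            x = x * mask
        h, c_in1 = self.in1.forward(x, mask, training)
        h, c_in2 = self.in2.forward(h, mask, training)
        c_blocks = []
        for b in self.blocks:
            h, c = b.forward(h, mask, training)
            c_blocks.append(c)
        ys, c_shared, c_read = [], [], []
        s = h
        for _ in range(self.cfg.N):
            s, cs = self.shared.forward(s, mask, training)
            c_shared.append(cs)
            y, cr = self.readout.forward(s, mask, training)
            c_read.append(cr)
            ys.append(y)
        return ys, (c_in1, c_in2, c_blocks, c_shared, c_read)

    def backward_batch(self, dys: list[np.ndarray], tape) -> None:
        """Accumulate parameter gradients for upstream grads on each Y_n."""
        c_in1, c_in2, c_blocks, c_shared, c_read = tape
        gs = None
        for n in reversed(range(self.cfg.N)):
            gr = self.readout.backward(dys[n], c_read[n])
            gs = gr if gs is None else gs + gr
            gs = self.shared.backward(gs, c_shared[n])
        for b, c in zip(reversed(self.blocks), reversed(c_blocks)):
            gs = b.backward(gs, c)
        gs = self.in2.backward(gs, c_in2)
        self.in1.backward(gs, c_in1)


def build_model(cfg: ModelConfig) -> CNNFoldNet:
    """Build the score network with seeded parameter initialization."""
    return CNNFoldNet(cfg)


def forward(X: PairTensor, model: CNNFoldNet) -> list[ScoreMatrix]:
    """Run one sequence through the network in evaluation mode.

    Returns the N intermediate score matrices; the last one (Y_N) is the
    matrix the decoders consume.
    """
    x = X.values[None].astype(model.dtype)
    ys, _ = model.forward_batch(x, mask=None, training=False)
    return [ScoreMatrix(y[0].astype(np.float64), n + 1) for n, y in enumerate(ys)]


def loss(
    Ys: list[ScoreMatrix] | list[np.ndarray],
    T: TargetMatrix | np.ndarray,
    V: ValidMask | np.ndarray,
) -> float:
    """Averaged intermediate masked MSE: l = (1/N) sum_n (1/|V|) sum_V (y - t)^2."""
    t = T.values if isinstance(T, TargetMatrix) else np.asarray(T)
    v = V.array if isinstance(V, ValidMask) else np.asarray(V, dtype=bool)
    m = int(v.sum())
    if m == 0:
        raise ValueError("valid mask is empty")
    total = 0.0
    for Y in Ys:
        y = Y.values if isinstance(Y, ScoreMatrix) else np.asarray(Y)
        if y.shape != t.shape:
            raise ValueError(f"shape mismatch: {y.shape} vs {t.shape}")
        d = (y - t)[v]
        total += float(np.dot(d, d)) / m
    return total / len(Ys)


def make_optimizer(model: CNNFoldNet, lr: float) -> Adam:
    return Adam(model.parameters(), lr=lr)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: CNNFoldNet, path: str | Path) -> None:
    """Versioned .npz checkpoint: config JSON + parameters + BN statistics."""
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION, "config": asdict(model.cfg)}
    np.savez(
        path,
        __meta__=np.array(json.dumps(meta)),
        **model.state_dict(),
    )


def load_checkpoint(path: str | Path) -> CNNFoldNet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version in {path}")
        cfg = ModelConfig(**meta["config"])
        model = CNNFoldNet(cfg)
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return model
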