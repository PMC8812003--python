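"""Pairwise input/target encodings for the score network.

A sequence of length L becomes an L x L x 8 one-hot relation map: channels
0-5 mark the six canonical ordered pair classes (A,U), (U,A), (U,G), (G,U),
(G,C), (C,G) at cells where that pairing is geometrically allowed, channel 6
marks the main diagonal (i = j, the "unpaired" slot), and channel 7 marks
cells where pairing is impossible (non-canonical base combination, or
0 < |i - j| < MIN_PAIR_DISTANCE; the distance rule dominates).

The training target is a binary L x L matrix with t_ij = t_ji = 1 for each
pair and t_ii = 1 for each unpaired base, so every row sums to exactly 1.
The loss is restricted to the valid mask V: all cells except the impossible
ones — i.e. exactly the complement of channel 7, diagonal included.

Arrays are 0-based with layout row = i, column = j, channel-last; the
1-based convention of the domain types applies only at type boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    MIN_PAIR_DISTANCE,
    RnaSequence,
    SecondaryStructure,
    canonical_pair_type,
)

__all__ = [
    "N_CHANNELS",
    "DIAGONAL_CHANNEL",
    "INVALID_CHANNEL",
    "PairTensor",
    "TargetMatrix",
    "ValidMask",
    "encode_sequence",
    "encode_target",
    "decode_target",
    "valid_mask",
]

N_CHANNELS = 8
DIAGONAL_CHANNEL = 6
INVALID_CHANNEL = 7


@dataclass(frozen=True)
class PairTensor:
    """L x L x 8 one-hot relation map (model input)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[0] != v.shape[1] or v.shape[2] != N_CHANNELS:
            raise ValueError(f"expected (L, L, {N_CHANNELS}) array, got {v.shape}")
        if not np.array_equal(v.sum(axis=2), np.ones(v.shape[:2])):
            raise ValueError("relation map is not one-hot over channels")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TargetMatrix:
    """Binary L x L target: symmetric, each row sums to 1, diagonal = unpaired."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"expected square matrix, got {v.shape}")
        if not np.array_equal(v, v.T):
            raise ValueError("target matrix is not symmetric")
        if not np.array_equal(v.sum(axis=1), np.ones(v.shape[0])):
            raise ValueError("target rows must sum to exactly 1")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ValidMask:
    """Boolean L x L mask of loss cells: complement of the invalid channel."""

    array: np.ndarray

    def __post_init__(self) -> None:
        a = self.array
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.dtype != np.bool_:
            raise ValueError(f"expected square boolean mask, got {a.shape} {a.dtype}")

    @property
    def length(self) -> int:
        return self.array.shape[0]

    def __contains__(self, cell: tuple[int, int]) -> bool:
        """Membership test with 1-based (i, j)."""
        i, j = cell
        return bool(self.array[i - 1, j - 1])

    @property
    def size(self) -> int:
        return int(self.array.sum())


_BASE_CODE = {b: k for k, b in enumerate("ACGU")}
# 5x5 lookup of canonical class index by (base_i, base_j); slot 4 = ambiguity code.
_CLASS_LUT = np.full((5, 5), -1, dtype=np.int64)
for _a in "ACGU":
    for _b in "ACGU":
        _c = canonical_pair_type(_a, _b)
        if _c is not None:
            _CLASS_LUT[_BASE_CODE[_a], _BASE_CODE[_b]] = _c


def _pair_class_matrix(q: RnaSequence) -> np.ndarray:
    """(L, L) int matrix of canonical class indices, -1 where non-canonical.

    Ambiguity codes (when allowed at parse time) can pair with nothing.
    """
    codes = np.array([_BASE_CODE.get(b, 4) for b in q.residues], dtype=np.int64)
    return _CLASS_LUT[np.ix_(codes, codes)]


def encode_sequence(q: RnaSequence) -> PairTensor:
    """Encode a sequence as the L x L x 8 one-hot relation map."""
    L = len(q)
    classes = _pair_class_matrix(q)
    dist_ok = np.abs(np.subtract.outer(np.arange(L), np.arange(L))) >= MIN_PAIR_DISTANCE
    diag = np.eye(L, dtype=bool)

    X = np.zeros((L, L, N_CHANNELS), dtype=np.float32)
    pairable = (classes >= 0) & dist_ok & ~diag
    for c in range(6):
        X[:, :, c] = (pairable & (classes == c)).astype(np.float32)
    X[:, :, DIAGONAL_CHANNEL] = diag
    X[:, :, INVALID_CHANNEL] = (~pairable & ~diag).astype(np.float32)
    return PairTensor(X)


def valid_mask(q: RnaSequence) -> ValidMask:
    """Loss mask V: every cell whose invalid channel is 0 (diagonal included)."""
    X = encode_sequence(q).values
    return ValidMask(X[:, :, INVALID_CHANNEL] == 0)


def encode_target(s: SecondaryStructure) -> TargetMatrix:
    """Structure -> binary target matrix (errors on multi-paired input)."""
    if s.multi_paired_indices():
        raise ValueError("cannot encode a structure with multi-paired indices")
    L = s.length
    T = np.zeros((L, L), dtype=np.float32)
    paired = np.zeros(L, dtype=bool)
    for i, j in s.pairs:
        T[i - 1, j - 1] = T[j - 1, i - 1] = 1.0
        paired[i - 1] = paired[j - 1] = True
    idx = np.flatnonzero(~paired)
    T[idx, idx] = 1.0
    return TargetMatrix(T)


def decode_target(T: TargetMatrix | np.ndarray) -> SecondaryStructure:
    """Inverse of :func:`encode_target` (validates the matrix invariants)."""
    T = T if isinstance(T, TargetMatrix) else TargetMatrix(np.asarray(T))
    v = T.values
    ii, jj = np.nonzero(np.triu(v, k=1))
    return SecondaryStructure(T.length, {(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)})
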