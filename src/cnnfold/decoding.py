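"""Turn a score matrix into a secondary structure.

Two decoders:

* **Argmax** — each base i picks the best-scoring valid cell in row i (the
  diagonal meaning "unpaired"). O(L^2) and fast, but row choices need not be
  symmetric, so the result can contain conflicting pairings; conflicts are
  reported, never silently repaired.
* **Blossom** — maximum-weight matching. The symmetrized score matrix is read
  as a weighted graph on the bases with self-loop weights y_ii for staying
  unpaired. Since general matching implementations do not support self-loops,
  the graph is doubled: two copies of the pair-edge graph plus an edge
  (u_i, v_i) between each node and its copy carrying twice the self-loop
  weight. A maximum-weight (not necessarily perfect) matching is found with
  the Blossom algorithm and pairs are read off the u-copy. Keeping only the
  k best cells per row (default 3) bounds the edge count at O(kL). The
  output always satisfies every structural constraint.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import SecondaryStructure, Violation, ViolationKind
from .encoding import ValidMask

__all__ = [
    "DecodeMethod",
    "DecodeConfig",
    "RawPairingMap",
    "symmetrize",
    "raw_pairing_map",
    "argmax_decode",
    "blossom_decode",
    "structure_objective",
]


class DecodeMethod(enum.Enum):
    ARGMAX = "argmax"
    BLOSSOM = "blossom"


@dataclass(frozen=True)
class DecodeConfig:
    """method: which decoder; k: per-row candidate cap for the matching;
    symmetrize: average Y with its transpose before matching."""

    method: DecodeMethod = DecodeMethod.ARGMAX
    k: int = 3
    symmetrize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _as_array(Y) -> np.ndarray:
    y = np.asarray(getattr(Y, "values", Y), dtype=np.float64)
    if y.ndim != 2 or y.shape[0] != y.shape[1]:
        raise ValueError(f"score matrix must be square, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("score matrix contains non-finite values")
    return y


def symmetrize(Y) -> np.ndarray:
    """Elementwise mean of Y and its transpose (one weight per undirected edge)."""
    y = _as_array(Y)
    return (y + y.T) / 2.0


@dataclass(frozen=True)
class RawPairingMap:
    """Per-row winners of the masked score matrix, 1-based.

    ``choices[i-1] == j`` means row i prefers column j (j == i: unpaired).
    Row choices need not be mutually symmetric.
    """

    choices: tuple[int, ...]


def raw_pairing_map(Y, V: ValidMask) -> RawPairingMap:
    """For each row, the valid column with the largest score (ties break to
    the lowest column index); cells outside the mask are ignored."""
    y = _as_array(Y)
    mask = V.array
    if y.shape != mask.shape:
        raise ValueError("score/mask shape mismatch")
    scores = np.where(mask, y, -np.inf)
    if np.any(np.all(np.isneginf(scores), axis=1)):
        raise ValueError("a row has no valid cell (mask excludes its diagonal)")
    choice = np.argmax(scores, axis=1)  # first occurrence = lowest index tie-break
    return RawPairingMap(tuple(int(j) + 1 for j in choice))


def argmax_decode(
    Y, V: ValidMask
) -> tuple[SecondaryStructure, list[Violation]]:
    """Row-argmax decoding.

    Row i selects its maximum over valid cells (diagonal included); a
    diagonal winner means "unpaired". The pair set is
    {(i, j): i < j and (row i picked j or row j picked i)}. Ties break to the
    lowest column index. Indices that end up in more than one pair are
    reported as multi-pairing violations.
    """
    raw = raw_pairing_map(Y, V)
    L = len(raw.choices)
    pairs: set[tuple[int, int]] = set()
    for i1, j1 in enumerate(raw.choices, 1):
        if j1 != i1:
            pairs.add((min(i1, j1), max(i1, j1)))
    s = SecondaryStructure(L, pairs, allow_conflicts=True)
    violations = [
        Violation(ViolationKind.MULTI_PAIRING, (idx,))
        for idx in s.multi_paired_indices()
    ]
    return s, violations


def _topk_keep(y: np.ndarray, valid_offdiag: np.ndarray, k: int) -> np.ndarray:
    """Boolean matrix of cells kept by per-row top-k over valid off-diagonal
    cells; a cell survives if either endpoint's row kept it."""
    L = y.shape[0]
    keep = np.zeros((L, L), dtype=bool)
    masked = np.where(valid_offdiag, y, -np.inf)
    if k >= L:
        keep = valid_offdiag.copy()
    else:
        part = np.argpartition(-masked, kth=k - 1, axis=1)[:, :k]
        rows = np.repeat(np.arange(L), k)
        cols = part.ravel()
        sel = valid_offdiag[rows, cols]
        keep[rows[sel], cols[sel]] = True
    return keep | keep.T


def blossom_decode(
    Y, V: ValidMask, cfg: DecodeConfig | None = None
) -> SecondaryStructure:
    """Maximum-weight-matching decoding on the doubled graph (see module
    docstring). Always returns a structure with zero violations; degenerate
    inputs (no positive-weight edge) give the all-unpaired structure."""
    cfg = cfg or DecodeConfig(method=DecodeMethod.BLOSSOM)
    y = symmetrize(Y) if cfg.symmetrize else _as_array(Y)
    mask = V.array
    L = y.shape[0]
    valid_offdiag = mask & ~np.eye(L, dtype=bool)
    keep = _topk_keep(y, valid_offdiag, cfg.k)

    G = nx.Graph()
    # u-copy nodes: 0..L-1; v-copy nodes: L..2L-1
    ii, jj = np.nonzero(np.triu(keep, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        w = y[i, j]
        if w > 0:  # nonpositive edges can never be part of a maximum matching
            G.add_edge(i, j, weight=w)
            G.add_edge(L + i, L + j, weight=w)
    diag = np.diagonal(y)
    for i in range(L):
        w = 2.0 * diag[i]
        if w > 0 and mask[i, i]:
            G.add_edge(i, L + i, weight=w)

    matching = nx.max_weight_matching(G, maxcardinality=False)
    pairs = {
        (min(a, b) + 1, max(a, b) + 1)
        for a, b in matching
        if a < L and b < L  # read the pairing off the u-copy only
    }
    return SecondaryStructure(L, pairs)


def structure_objective(Y, s: SecondaryStructure) -> float:
    """Doubled-graph weight of a structure: sum over pairs of 2*y_ij plus sum
    over unpaired bases of 2*y_ii (each structure appears once per copy)."""
    y = _as_array(Y)
    paired = {x for p in s.pairs for x in p}
    total = sum(2.0 * y[i - 1, j - 1] for i, j in s.pairs)
    total += sum(2.0 * y[i - 1, i - 1] for i in range(1, s.length + 1) if i not in paired)
    return float(total)
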