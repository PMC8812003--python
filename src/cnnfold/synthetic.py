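"""Seeded generator of valid RNA secondary structures and compatible sequences.

The generator emulates the stem/loop composition of curated secondary
structure corpora: stems are runs of consecutive pairs (i+t, j-t), loops keep
at least ``min_loop`` unpaired bases between a pair's partners, pair bases are
drawn uniformly from the six canonical classes, and with probability
``pseudoknot_prob`` one extra stem crosses the nested skeleton, producing a
pseudoknot. Every emitted record passes :func:`cnnfold.core.validate`.

It is the fixture source for the test-suite and the overfit experiment; it
makes no claim of thermodynamic realism (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CANONICAL_PAIRS,
    RnaSequence,
    SecondaryStructure,
    is_pseudoknotted,
    validate,
)
from .io import StructureRecord

__all__ = ["SyntheticConfig", "sample_structure", "sample_sequence", "make_dataset", "corrupt"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    length_range
        Inclusive sequence-length bounds in nucleotides.
    stem_length
        Inclusive bounds on consecutive pairs per stem.
    min_loop
        Minimum unpaired bases between a pair's partners (>= 3, consistent
        with the minimum pairing distance).
    stems_per_structure
        Inclusive bounds on the number of nested stems attempted.
    pseudoknot_prob
        Probability that one extra crossing stem is added.
    """

    length_range: tuple[int, int] = (30, 120)
    stem_length: tuple[int, int] = (3, 8)
    min_loop: int = 3
    stems_per_structure: tuple[int, int] = (1, 4)
    pseudoknot_prob: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3 (minimum pairing distance)")
        for name in ("length_range", "stem_length", "stems_per_structure"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"empty or invalid range for {name}: ({lo}, {hi})")
        if not 0.0 <= self.pseudoknot_prob <= 1.0:
            raise ValueError("pseudoknot_prob must be in [0, 1]")


def _place_nested_stems(
    L: int, cfg: SyntheticConfig, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Nested skeleton by interval splitting (all indices 1-based)."""
    pairs: set[tuple[int, int]] = set()
    n_stems = int(rng.integers(cfg.stems_per_structure[0], cfg.stems_per_structure[1] + 1))
    intervals: list[tuple[int, int]] = [(1, L)]
    placed = 0
    while placed < n_stems and intervals:
        k = int(rng.integers(len(intervals)))
        a, b = intervals.pop(k)
        t_max_geom = (b - a + 1 - cfg.min_loop) // 2
        if t_max_geom < cfg.stem_length[0]:
            continue
        t = int(rng.integers(cfg.stem_length[0], min(cfg.stem_length[1], t_max_geom) + 1))
        slack = (b - a + 1) - (2 * t + cfg.min_loop)
        o1 = int(rng.integers(0, slack + 1))
        o2 = int(rng.integers(0, slack - o1 + 1))
        i0, j0 = a + o1, b - o2
        for d in range(t):
            pairs.add((i0 + d, j0 - d))
        placed += 1
        inner = (i0 + t, j0 - t)
        if inner[1] - inner[0] + 1 >= 2 * cfg.stem_length[0] + cfg.min_loop:
            intervals.append(inner)
        for side in ((a, i0 - 1), (j0 + 1, b)):
            if side[1] - side[0] + 1 >= 2 * cfg.stem_length[0] + cfg.min_loop:
                intervals.append(side)
    if placed == 0:
        raise ValueError(
            f"length {L} too small for a stem of {cfg.stem_length[0]} pairs "
            f"with min_loop {cfg.min_loop}"
        )
    return pairs


def _add_crossing_stem(
    L: int,
    pairs: set[tuple[int, int]],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> bool:
    """Try to add one stem from one loop into a downstream loop so that it
    crosses an existing pair; rejection-sampled. Returns success."""
    paired = {x for p in pairs for x in p}
    unpaired = [x for x in range(1, L + 1) if x not in paired]
    if len(unpaired) < 2:
        return False
    for t in range(min(cfg.stem_length), 0, -1):
        for _ in range(300):
            i = int(rng.choice(unpaired))
            j = int(rng.choice(unpaired))
            if i > j:
                i, j = j, i
            # candidate stem pairs (i+d, j-d), d = 0..t-1
            cells = [(i + d, j - d) for d in range(t)]
            if cells[-1][1] - cells[-1][0] - 1 < cfg.min_loop:
                continue
            flat = {x for c in cells for x in c}
            unpaired_set = set(unpaired)
            if len(flat) < 2 * t or not flat <= unpaired_set:
                continue
            # at least the outermost candidate pair must cross an existing pair
            crossing = any(k < i < l < j or i < k < j < l for k, l in pairs)
            if not crossing:
                continue
            pairs.update(cells)
            return True
    return False


def sample_structure(cfg: SyntheticConfig, rng: np.random.Generator) -> SecondaryStructure:
    """Draw one valid structure; crossing pairs present iff the pseudoknot
    branch fired."""
    want_pk = bool(rng.random() < cfg.pseudoknot_prob)
    for _attempt in range(50):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        pairs = _place_nested_stems(L, cfg, rng)
        if want_pk and not _add_crossing_stem(L, pairs, cfg, rng):
            continue
        s = SecondaryStructure(L, pairs)
        assert is_pseudoknotted(s) == want_pk
        return s
    raise RuntimeError("could not place a crossing stem; lengths too constrained")


def sample_sequence(s: SecondaryStructure, rng: np.random.Generator) -> RnaSequence:
    """Draw a sequence compatible with ``s``: each pair gets one of the six
    canonical classes uniformly, unpaired positions are uniform A/C/G/U."""
    res = [""] * s.length
    for i, j in sorted(s.pairs):
        a, b = CANONICAL_PAIRS[int(rng.integers(6))]
        res[i - 1], res[j - 1] = a, b
    for k in range(s.length):
        if not res[k]:
            res[k] = "ACGU"[int(rng.integers(4))]
    q = RnaSequence("synthetic", "".join(res))
    assert validate(s, q) == []
    return q


def make_dataset(
    n: int, cfg: SyntheticConfig | None = None, seed: int | None = None
) -> list[StructureRecord]:
    """Generate ``n`` reproducible (sequence, structure) records."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    out: list[StructureRecord] = []
    for k in range(n):
        s = sample_structure(cfg, rng)
        q = sample_sequence(s, rng)
        out.append(
            StructureRecord(
                RnaSequence(f"synth_{k:04d}", q.residues), s, source="synthetic"
            )
        )
    return out


def corrupt(
    record: StructureRecord, rng: np.random.Generator, kind: str = "non_canonical"
) -> StructureRecord:
    """Inject one violation into a valid record (negative-test helper).

    kind: 'non_canonical' mutates one paired base so the pair class becomes
    invalid; 'min_distance' adds a too-close pair; 'multi_pairing' adds a
    second partner to a paired base.
    """
    s, q = record.structure, record.sequence
    pairs = sorted(s.pairs)
    if kind == "non_canonical":
        if not pairs:
            raise ValueError("record has no pairs to corrupt")
        i, j = pairs[int(rng.integers(len(pairs)))]
        res = list(q.residues)
        partner = res[j - 1]
        choices = [b for b in "ACGU" if _is_non_canonical(b, partner)]
        res[i - 1] = choices[int(rng.integers(len(choices)))]
        return StructureRecord(
            RnaSequence(q.id, "".join(res)), s, source=record.source + "+non_canonical"
        )
    paired = {x for p in pairs for x in p}
    free = [x for x in range(1, s.length) if x not in paired and x + 2 not in paired and x + 2 <= s.length]
    if kind == "min_distance":
        if not free:
            raise ValueError("no room for a short-range pair")
        i = free[int(rng.integers(len(free)))]
        return StructureRecord(
            q,
            SecondaryStructure(s.length, set(pairs) | {(i, i + 2)}, allow_conflicts=True),
            source=record.source + "+min_distance",
        )
    if kind == "multi_pairing":
        if not pairs:
            raise ValueError("record has no pairs to corrupt")
        i, j = pairs[0]
        unpaired = [x for x in range(1, s.length + 1) if x not in paired and abs(x - i) >= 3]
        if not unpaired:
            raise ValueError("no free partner available")
        k = unpaired[int(rng.integers(len(unpaired)))]
        extra = (min(i, k), max(i, k))
        return StructureRecord(
            q,
            SecondaryStructure(s.length, set(pairs) | {extra}, allow_conflicts=True),
            source=record.source + "+multi_pairing",
        )
    raise ValueError(f"unknown corruption kind {kind!r}")


def _is_non_canonical(a: str, b: str) -> bool:
    from .core import canonical_pair_type

    return canonical_pair_type(a, b) is None
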