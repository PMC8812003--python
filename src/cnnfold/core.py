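"""Domain types for RNA sequences and secondary structures.

A secondary structure is a set of base pairs over a single strand. The
constraints enforced here are the usual ones for canonical structures:

* only the six canonical ordered pair classes (A·U, U·A, U·G, G·U, G·C, C·G)
  — Watson–Crick pairs plus the G·U wobble;
* each base pairs with at most one other base;
* paired bases are at least :data:`MIN_PAIR_DISTANCE` positions apart
  (``|i - j| >= 3``), since the backbone cannot bend back on itself faster.

Pairs are 1-based in every public interface (matching CT/BPSEQ conventions);
anything 0-based is an internal array detail of other modules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "MIN_PAIR_DISTANCE",
    "CANONICAL_PAIRS",
    "RnaSequence",
    "SecondaryStructure",
    "Violation",
    "ViolationKind",
    "canonical_pair_type",
    "is_pseudoknotted",
    "validate",
]

#: Minimum separation |i - j| between the two bases of a pair.
MIN_PAIR_DISTANCE = 3

#: The six canonical ordered pair classes, in a fixed documented order.
#: This order also defines the channel order of the pairwise input encoding.
CANONICAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("A", "U"),
    ("U", "A"),
    ("U", "G"),
    ("G", "U"),
    ("G", "C"),
    ("C", "G"),
)

_BASES = frozenset("ACGU")
_PAIR_INDEX = {p: i for i, p in enumerate(CANONICAL_PAIRS)}


class ViolationKind(enum.Enum):
    NON_CANONICAL = "non_canonical"
    MIN_DISTANCE = "min_distance"
    MULTI_PAIRING = "multi_pairing"
    OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class Violation:
    """A single constraint violation, locating the offending indices."""

    kind: ViolationKind
    indices: tuple[int, ...]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.kind.value} at {self.indices}"


def normalize_residues(residues: str, *, allow_ambiguous: bool = False) -> str:
    """Uppercase, map T->U, and check the alphabet.

    Ambiguity codes (N, R, ...) are rejected unless ``allow_ambiguous`` is
    set, in which case they are kept verbatim; the encoder treats them as
    bases that cannot pair with anything.
    """
    s = residues.strip().upper().replace("T", "U")
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - _BASES
    if bad and not allow_ambiguous:
        raise ValueError(
            f"illegal residue(s) {sorted(bad)}; expected A/C/G/U "
            "(pass allow_ambiguous=True to keep ambiguity codes)"
        )
    if bad - set("BDHKMNRSVWY"):
        raise ValueError(f"non-nucleotide symbol(s) {sorted(bad - set('BDHKMNRSVWY'))}")
    return s


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA sequence over {A, C, G, U}.

    Input is normalized on construction: lowercase is uppercased and DNA-style
    T becomes U.
    """

    id: str
    residues: str
    allow_ambiguous: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "residues",
            normalize_residues(self.residues, allow_ambiguous=self.allow_ambiguous),
        )

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """1-based residue access."""
        if not 1 <= i <= len(self):
            raise IndexError(f"position {i} outside 1..{len(self)}")
        return self.residues[i - 1]


class SecondaryStructure:
    """A set of 1-based base pairs (i, j), i < j, over a strand of given length.

    By default each index may occur in at most one pair; decoders that are
    allowed to emit conflicting pairings (row-argmax decoding) construct with
    ``allow_conflicts=True`` and report the conflicts separately.
    """

    __slots__ = ("length", "pairs")

    def __init__(
        self,
        length: int,
        pairs: Iterable[tuple[int, int]] = (),
        *,
        allow_conflicts: bool = False,
    ) -> None:
        if length < 1:
            raise ValueError("length must be >= 1")
        self.length = int(length)
        normed = set()
        for i, j in pairs:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-pair ({i},{j})")
            if i > j:
                i, j = j, i
            if not (1 <= i < j <= length):
                raise ValueError(f"pair ({i},{j}) outside 1..{length}")
            normed.add((i, j))
        self.pairs: frozenset[tuple[int, int]] = frozenset(normed)
        if not allow_conflicts:
            seen: set[int] = set()
            for i, j in sorted(self.pairs):
                if i in seen or j in seen:
                    raise ValueError(f"index in more than one pair: ({i},{j})")
                seen.update((i, j))

    def partner_map(self) -> dict[int, int]:
        """i -> j for both orientations; errors on conflicting structures."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            if i in out or j in out:
                raise ValueError("structure has multi-paired indices")
            out[i] = j
            out[j] = i
        return out

    def multi_paired_indices(self) -> list[int]:
        counts: dict[int, int] = {}
        for i, j in self.pairs:
            counts[i] = counts.get(i, 0) + 1
            counts[j] = counts.get(j, 0) + 1
        return sorted(k for k, c in counts.items() if c > 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SecondaryStructure):
            return NotImplemented
        return self.length == other.length and self.pairs == other.pairs

    def __hash__(self) -> int:
        return hash((self.length, self.pairs))

    def __repr__(self) -> str:
        return f"SecondaryStructure(length={self.length}, pairs={sorted(self.pairs)})"


def canonical_pair_type(a: str, b: str) -> int | None:
    """Return the ordered canonical class index of (a, b), or None.

    The six classes are indexed in the order of :data:`CANONICAL_PAIRS`;
    the remaining ten ordered base combinations return None.
    """
    a, b = a.upper(), b.upper()
    if a not in _BASES or b not in _BASES:
        raise ValueError(f"non-base symbol in pair ({a!r}, {b!r})")
    return _PAIR_INDEX.get((a, b))


def is_pseudoknotted(s: SecondaryStructure) -> bool:
    """True iff two pairs (i,j), (k,l) cross: i < k < j < l.

    This is the direct O(P^2) crossing enumeration over the pair set.
    """
    ps = sorted(s.pairs)
    for a in range(len(ps)):
        i, j = ps[a]
        for b in range(a + 1, len(ps)):
            k, l = ps[b]
            if i < k < j < l:
                return True
    return False


def validate(s: SecondaryStructure, q: RnaSequence) -> list[Violation]:
    """Check a structure against a sequence; empty list means fully valid.

    Checks, in order: index range, single-partner, minimum pairing distance
    (|i-j| >= MIN_PAIR_DISTANCE), and canonical pair classes.
    """
    if s.length != len(q):
        raise ValueError(f"structure length {s.length} != sequence length {len(q)}")
    out: list[Violation] = []
    for idx in s.multi_paired_indices():
        out.append(Violation(ViolationKind.MULTI_PAIRING, (idx,)))
    for i, j in sorted(s.pairs):
        if not (1 <= i < j <= s.length):  # unreachable via constructor; defensive
            out.append(Violation(ViolationKind.OUT_OF_RANGE, (i, j)))
            continue
        if j - i < MIN_PAIR_DISTANCE:
            out.append(Violation(ViolationKind.MIN_DISTANCE, (i, j)))
        if canonical_pair_type(q.base(i), q.base(j)) is None:
            out.append(Violation(ViolationKind.NON_CANONICAL, (i, j)))
    return out
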