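"""Readers and writers for FASTA, CT, BPSEQ and pseudoknot-aware dot-bracket.

All formats use 1-based indices and a partner of 0 for unpaired bases.
Dot-bracket output assigns crossing (pseudoknot) pairs to successive bracket
layers ``()``, ``[]``, ``{}``, ``<>``, then ``Aa`` .. ``Zz`` by greedy
first-fit conflict coloring in 5'->3' pair order.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .core import RnaSequence, SecondaryStructure

__all__ = [
    "StructureRecord",
    "read_fasta",
    "write_fasta",
    "read_ct",
    "write_ct",
    "read_bpseq",
    "write_bpseq",
    "to_dotbracket",
    "from_dotbracket",
]

#: Bracket alphabets for successive pseudoknot layers (28 layers available).
BRACKET_LAYERS: tuple[tuple[str, str], ...] = (
    ("(", ")"),
    ("[", "]"),
    ("{", "}"),
    ("<", ">"),
    *((c, c.lower()) for c in string.ascii_uppercase),
)


@dataclass(frozen=True)
class StructureRecord:
    """A sequence together with its reference structure and provenance."""

    sequence: RnaSequence
    structure: SecondaryStructure
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != self.structure.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != "
                f"structure length {self.structure.length}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, allow_ambiguous: bool = False) -> list[RnaSequence]:
    """Read all records of a FASTA file as normalized RNA sequences."""
    path = Path(path)
    records: list[RnaSequence] = []
    header: str | None = None
    chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise ValueError(f"{path}: record {header!r} has no sequence")
        records.append(
            RnaSequence(header, "".join(chunks), allow_ambiguous=allow_ambiguous)
        )

    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if line[1:].strip() else f"seq{lineno}"
            if header in seen:
                raise ValueError(f"{path}: duplicate id {header!r}")
            seen.add(header)
            chunks = []
        else:
            if header is None:
                raise ValueError(f"{path}:{lineno}: sequence data before any header")
            chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for q in seqs:
            fh.write(f">{q.id}\n")
            for i in range(0, len(q), width):
                fh.write(q.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CT / BPSEQ
# ---------------------------------------------------------------------------

def _pairs_from_partner_column(
    partners: dict[int, int], path: Path, lines: dict[int, int]
) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    for i, j in partners.items():
        if j == 0:
            continue
        if j not in partners:
            raise ValueError(f"{path}: base {i} (line {lines[i]}) pairs with missing index {j}")
        back = partners[j]
        if back != i:
            raise ValueError(
                f"{path}: partner columns disagree: base {i} (line {lines[i]}) says {j} "
                f"but base {j} (line {lines[j]}) says {back}"
            )
        if i < j:
            pairs.add((i, j))
    return pairs


def read_ct(path: str | Path, *, allow_ambiguous: bool = False) -> StructureRecord:
    """Read the first structure of a CT file.

    CT columns: index, base, i-1, i+1, partner-or-0, index. The free-text
    header (energy etc.) is kept as opaque provenance, never parsed. If the
    file holds several structures, only the first is read (with a warning).
    """
    path = Path(path)
    text = [l for l in path.read_text().splitlines() if l.strip()]
    if not text:
        raise ValueError(f"{path}: empty CT file")
    header = text[0]
    try:
        n = int(header.split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: malformed CT header {header!r}") from None
    if len(text) - 1 < n:
        raise ValueError(f"{path}: header declares {n} bases, found {len(text) - 1} rows")
    if len(text) - 1 > n:
        warnings.warn(f"{path}: multiple CT structures; reading only the first")
    bases: list[str] = []
    partners: dict[int, int] = {}
    lines: dict[int, int] = {}
    for row_no, row in enumerate(text[1 : n + 1], 2):
        cols = row.split()
        if len(cols) < 6:
            raise ValueError(f"{path}:{row_no}: expected 6 CT columns, got {len(cols)}")
        idx, base, partner = int(cols[0]), cols[1], int(cols[4])
        if idx != len(bases) + 1:
            raise ValueError(f"{path}:{row_no}: index {idx} out of order")
        bases.append(base)
        partners[idx] = partner
        lines[idx] = row_no
    pairs = _pairs_from_partner_column(partners, path, lines)
    name = header.split(maxsplit=1)[1].strip() if len(header.split()) > 1 else path.stem
    seq = RnaSequence(name or path.stem, "".join(bases), allow_ambiguous=allow_ambiguous)
    return StructureRecord(
        seq,
        SecondaryStructure(n, pairs, allow_conflicts=True),
        source=f"ct:{path}",
    )


def write_ct(record: StructureRecord, path: str | Path) -> None:
    q, s = record.sequence, record.structure
    partner = {i: 0 for i in range(1, s.length + 1)}
    for i, j in s.pairs:
        partner[i] = j
        partner[j] = i
    with open(path, "w") as fh:
        fh.write(f"{s.length} {q.id}\n")
        for i in range(1, s.length + 1):
            fh.write(f"{i} {q.base(i)} {i - 1} {(i + 1) % (s.length + 1)} {partner[i]} {i}\n")


def read_bpseq(path: str | Path, *, allow_ambiguous: bool = False) -> StructureRecord:
    """Read a BPSEQ file (3 columns: index, base, partner-or-0)."""
    path = Path(path)
    bases: list[str] = []
    partners: dict[int, int] = {}
    lines: dict[int, int] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 BPSEQ columns, got {len(cols)}")
        idx, base, partner = int(cols[0]), cols[1], int(cols[2])
        if idx != len(bases) + 1:
            raise ValueError(f"{path}:{lineno}: index {idx} out of order")
        bases.append(base)
        partners[idx] = partner
        lines[idx] = lineno
    if not bases:
        raise ValueError(f"{path}: empty BPSEQ file")
    pairs = _pairs_from_partner_column(partners, path, lines)
    seq = RnaSequence(path.stem, "".join(bases), allow_ambiguous=allow_ambiguous)
    return StructureRecord(
        seq,
        SecondaryStructure(len(bases), pairs, allow_conflicts=True),
        source=f"bpseq:{path}",
    )


def write_bpseq(record: StructureRecord, path: str | Path) -> None:
    q, s = record.sequence, record.structure
    partner = {i: 0 for i in range(1, s.length + 1)}
    for i, j in s.pairs:
        partner[i] = j
        partner[j] = i
    with open(path, "w") as fh:
        for i in range(1, s.length + 1):
            fh.write(f"{i} {q.base(i)} {partner[i]}\n")


# ---------------------------------------------------------------------------
# dot-bracket
# ---------------------------------------------------------------------------

def to_dotbracket(s: SecondaryStructure) -> str:
    """Render a structure in dot-bracket, using extra layers for pseudoknots.

    Pairs are colored greedily in 5'->3' order: each pair takes the first
    bracket layer in which it crosses no already-assigned pair. Nested
    structures therefore use only ``()``.
    """
    pairs = sorted(s.pairs)
    layers: list[list[tuple[int, int]]] = []
    assign: dict[tuple[int, int], int] = {}
    for i, j in pairs:
        for li, members in enumerate(layers):
            if not any(k < i < l < j or i < k < j < l for k, l in members):
                members.append((i, j))
                assign[(i, j)] = li
                break
        else:
            if len(layers) >= len(BRACKET_LAYERS):
                raise ValueError("more crossing layers than available bracket alphabets")
            layers.append([(i, j)])
            assign[(i, j)] = len(layers) - 1
    out = ["."] * s.length
    for (i, j), li in assign.items():
        op, cl = BRACKET_LAYERS[li]
        out[i - 1] = op
        out[j - 1] = cl
    return "".join(out)


def from_dotbracket(db: str) -> SecondaryStructure:
    """Parse dot-bracket (any layer emitted by :func:`to_dotbracket`)."""
    opens = {op: li for li, (op, _) in enumerate(BRACKET_LAYERS)}
    closes = {cl: li for li, (_, cl) in enumerate(BRACKET_LAYERS)}
    stacks: dict[int, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(db, 1):
        if ch in (".", "-", "_"):
            continue
        if ch in opens:
            stacks.setdefault(opens[ch], []).append(pos)
        elif ch in closes:
            st = stacks.get(closes[ch])
            if not st:
                raise ValueError(f"unbalanced {ch!r} at position {pos}")
            pairs.add((st.pop(), pos))
        else:
            raise ValueError(f"unknown dot-bracket symbol {ch!r} at position {pos}")
    for li, st in stacks.items():
        if st:
            raise ValueError(f"unclosed {BRACKET_LAYERS[li][0]!r} at position {st[-1]}")
    return SecondaryStructure(len(db), pairs)
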