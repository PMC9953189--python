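"""Sequence and structure I/O.

RNA sequences are plain strings over {A, C, G, U}; input is normalized
(uppercased, T mapped to U) and validated.  Secondary structures with one
pseudoknot are written in extended dot-bracket notation with two bracket
layers: square brackets ``[ ]`` for the 5'-opening (left) stem and its
extensions, round brackets ``( )`` for the right stem.  All positions in
the public API and in error messages are 1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO, Union

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

SQUARE = "square"
ROUND = "round"

#: (open, close) bracket characters per layer
LAYER_BRACKETS = {SQUARE: ("[", "]"), ROUND: ("(", ")")}


class SequenceError(ValueError):
    """Raised for malformed or non-RNA sequence input."""


class StructureError(ValueError):
    """Raised when a structure violates the two-layer pseudoknot invariants."""


def _normalize(raw: str, identifier: str) -> str:
    residues = raw.strip().upper().replace("T", "U")
    for pos, ch in enumerate(residues, start=1):
        if ch not in RNA_ALPHABET:
            raise SequenceError(
                f"sequence {identifier!r}: illegal character {ch!r} at position {pos}"
            )
    if not residues:
        raise SequenceError(f"sequence {identifier!r} is empty")
    return residues


@dataclass(frozen=True)
class Sequence:
    """A validated RNA sequence with 1-based position access."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalize(self.residues, self.identifier))

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    p, q = a
    r, s = b
    return p < r < q < s or r < p < s < q


@dataclass(frozen=True)
class Structure:
    """A two-layer base-pair set over a sequence of given length.

    ``pairs`` holds (p, q, layer) triples with 1 <= p < q <= length; ``gap_flags``
    marks the subset of (p, q) pairs that were formed across a bulge or internal
    loop (gap-mediated).  Construction validates: position bounds, no position in
    two pairs, nestedness within each layer, and — when both layers are occupied —
    that the layers actually cross (a pseudoknot is present).
    """

    length: int
    pairs: frozenset = frozenset()
    gap_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        object.__setattr__(self, "gap_flags", frozenset(self.gap_flags))
        if self.length < 1:
            raise StructureError("structure length must be positive")
        seen: set[int] = set()
        for p, q, layer in self.pairs:
            if layer not in LAYER_BRACKETS:
                raise StructureError(f"unknown layer {layer!r}")
            if not (1 <= p < q <= self.length):
                raise StructureError(f"pair ({p},{q}) outside 1..{self.length}")
            for pos in (p, q):
                if pos in seen:
                    raise StructureError(f"position {pos} occurs in more than one pair")
                seen.add(pos)
        by_layer = {SQUARE: [], ROUND: []}
        for p, q, layer in self.pairs:
            by_layer[layer].append((p, q))
        for layer, pl in by_layer.items():
            pl.sort()
            for a in range(len(pl)):
                for b in range(a + 1, len(pl)):
                    if _crosses(pl[a], pl[b]):
                        raise StructureError(
                            f"{layer} pairs {pl[a]} and {pl[b]} cross within one layer"
                        )
        if by_layer[SQUARE] and by_layer[ROUND]:
            if not any(
                _crosses(sq, rd) for sq in by_layer[SQUARE] for rd in by_layer[ROUND]
            ):
                raise StructureError(
                    "both layers nonempty but no square pair crosses a round pair"
                )
        bad = self.gap_flags - {(p, q) for p, q, _ in self.pairs}
        if bad:
            raise StructureError(f"gap flags {sorted(bad)} not among the pairs")

    def layer_pairs(self, layer: str) -> list:
        """Sorted (p, q) pairs of one layer."""
        return sorted((p, q) for p, q, la in self.pairs if la == layer)

    def partner_map(self) -> dict:
        """Map from each paired position to its partner."""
        out: dict[int, int] = {}
        for p, q, _ in self.pairs:
            out[p] = q
            out[q] = p
        return out

    def to_dotbracket(self) -> str:
        chars = ["."] * self.length
        for p, q, layer in self.pairs:
            op, cl = LAYER_BRACKETS[layer]
            chars[p - 1] = op
            chars[q - 1] = cl
        return "".join(chars)


def parse_dotbracket(text: str, expected_length: int | None = None) -> Structure:
    """Parse extended dot-bracket notation (two layers) into a :class:`Structure`.

    Square and round brackets are matched independently, each by its own stack.
    """
    text = text.strip()
    if expected_length is not None and len(text) != expected_length:
        raise StructureError(
            f"dot-bracket length {len(text)} != expected {expected_length}"
        )
    stacks = {SQUARE: [], ROUND: []}
    pairs = set()
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        for layer, (op, cl) in LAYER_BRACKETS.items():
            if ch == op:
                stacks[layer].append(pos)
                break
            if ch == cl:
                if not stacks[layer]:
                    raise StructureError(
                        f"unbalanced {cl!r} at position {pos}: no open bracket"
                    )
                pairs.add((stacks[layer].pop(), pos, layer))
                break
        else:
            raise StructureError(f"illegal character {ch!r} at position {pos}")
    for layer, st in stacks.items():
        if st:
            op = LAYER_BRACKETS[layer][0]
            raise StructureError(f"unbalanced {op!r} opened at position {st[-1]}")
    return Structure(length=len(text), pairs=frozenset(pairs))


def write_structure(seq: Sequence, s: Structure) -> str:
    """Render ``s`` as an extended dot-bracket string for ``seq``.

    Inverse of :func:`parse_dotbracket` on valid strings.
    """
    if s.length != seq.length:
        raise StructureError(
            f"structure length {s.length} != sequence length {seq.length}"
        )
    return s.to_dotbracket()


def read_sequences(source: Union[str, TextIO]) -> list:
    """Read RNA sequences from FASTA or one-raw-sequence-per-line text.

    ``source`` may be an open text stream or a string holding the content
    itself.  Records are normalized (uppercase, T->U) and validated; input
    order is preserved.  Plain-text records are named ``seq1``, ``seq2``, ...
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    content = source.read()
    stripped = content.lstrip()
    records: list[Sequence] = []
    if stripped.startswith(">"):
        for rec in SeqIO.parse(io.StringIO(content), "fasta"):
            if not rec.id:
                raise SequenceError("malformed FASTA header: empty identifier")
            records.append(Sequence(rec.id, str(rec.seq)))
        if not records:
            raise SequenceError("malformed FASTA: no records parsed")
    else:
        for n, line in enumerate(
            (ln for ln in content.splitlines() if ln.strip()), start=1
        ):
            records.append(Sequence(f"seq{n}", line))
    return records
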