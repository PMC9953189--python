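"""Candidate core-stem enumeration.

An H-type pseudoknot is seeded by two crossing base pairs — the *core stems*
(i, k) and (j, l) with i < j < k < l.  This module enumerates every such
quadruple for a sequence under the active complementarity rules and minimum
loop sizes.  The set is fully determined by the crossing, complementarity and
loop-minimum constraints; enumeration order is (i, j, k, l)-sorted so listings
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

from .seqio import ROUND, SQUARE, Sequence, Structure

_WC = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")})
_WOBBLE = frozenset({("G", "U"), ("U", "G")})


@dataclass(frozen=True)
class PairRules:
    """Admissible base pairs: Watson-Crick always, G-U wobble optionally."""

    allow_gu: bool = False


def is_complementary(a: str, b: str, rules: PairRules = PairRules()) -> bool:
    """True iff (a, b) may pair: A-U, C-G, and G-U when ``rules.allow_gu``."""
    if (a, b) in _WC:
        return True
    return rules.allow_gu and (a, b) in _WOBBLE


@dataclass(frozen=True, order=True)
class CoreStemQuad:
    """The two crossing core pairs (i, k) and (j, l), i < j < k < l.

    (i, k) is the left core pair (square layer), (j, l) the right core pair
    (round layer).  The left loop spans positions i+1..j-1, the right loop
    k+1..l-1.
    """

    i: int
    j: int
    k: int
    l: int

    def __post_init__(self) -> None:
        if not self.i < self.j < self.k < self.l:
            raise ValueError(
                f"core quad ({self.i},{self.j},{self.k},{self.l}) is not crossing "
                "(requires i < j < k < l)"
            )

    @property
    def left_pair(self) -> tuple:
        return (self.i, self.k)

    @property
    def right_pair(self) -> tuple:
        return (self.j, self.l)

    @property
    def left_loop(self) -> range:
        """Positions strictly between the two 5' core bases."""
        return range(self.i + 1, self.j)

    @property
    def right_loop(self) -> range:
        """Positions strictly between the two 3' core bases."""
        return range(self.k + 1, self.l)

    def as_tuple(self) -> tuple:
        return (self.i, self.j, self.k, self.l)


def enumerate_core_stems(
    seq: Sequence,
    rules: PairRules = PairRules(),
    min_left_loop: int = 1,
    min_right_loop: int = 1,
) -> list:
    """All core-stem quadruples of ``seq``, sorted by (i, j, k, l).

    A quadruple qualifies when both core pairs are complementary under
    ``rules``, the pairs cross (i < j < k < l), and the loops meet their
    minima: j - i - 1 >= min_left_loop and l - k - 1 >= min_right_loop.
    The empty list is a legal result.
    """
    if min_left_loop < 0 or min_right_loop < 0:
        raise ValueError("loop minima must be nonnegative")
    n = seq.length
    res = seq.residues
    # complementary (p, q) pairs, grouped by p for the inner scan
    comp = [
        (p, q)
        for p in range(1, n + 1)
        for q in range(p + 1, n + 1)
        if is_complementary(res[p - 1], res[q - 1], rules)
    ]
    quads = []
    for i, k in comp:
        for j, l in comp:
            if i < j < k < l and j - i - 1 >= min_left_loop and l - k - 1 >= min_right_loop:
                quads.append(CoreStemQuad(i, j, k, l))
    quads.sort()
    return quads


def core_quad_from_structure(s: Structure) -> CoreStemQuad:
    """Recover the core quadruple of a two-layer pseudoknot structure.

    The core pair of each stem is its innermost pair — the square pair with the
    largest 5' position and the round pair with the largest 5' position — which
    is where outward stem extension starts.
    """
    square = s.layer_pairs(SQUARE)
    rnd = s.layer_pairs(ROUND)
    if not square or not rnd:
        raise ValueError("structure does not contain two crossing stems")
    i, k = max(square)
    j, l = max(rnd)
    return CoreStemQuad(i, j, k, l)


def dump_candidates(quads: Iterable[CoreStemQuad], out: TextIO) -> None:
    """Debug TSV dump: one ``i<TAB>j<TAB>k<TAB>l`` line per candidate."""
    for q in quads:
        out.write(f"{q.i}\t{q.j}\t{q.k}\t{q.l}\n")
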