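"""Synthetic H-type pseudoknot instances with known ground truth.

Sequences are laid out as

    head | S1a | left loop | S2a | S1b | right loop | S2b | tail

with S1a/S1b the two arms of the left (square) stem and S2a/S2b the arms of
the right (round) stem, so the stems' base pairs cross.  Optionally one
gap-mediated continuation (bulge or internal loop) is planted on either side.
Paired positions receive random Watson-Crick pairs; unpaired positions are
filled by rejection sampling so that no accidental helix of three or more
complementary stacked pairs competes with the planted stems.  Identical seeds
give identical instances.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .corestems import CoreStemQuad, PairRules, is_complementary
from .seqio import ROUND, SQUARE, Sequence, Structure

_WC_PAIRS = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")]
_BASES = "ACGU"

#: attempts at filling unpaired positions before accepting the last draw
MAX_FILL_ATTEMPTS = 200


class InfeasibleSpecError(ValueError):
    """Raised when a plant specification cannot be realized."""


@dataclass(frozen=True)
class BulgeSpec:
    """One planted gap-mediated stem continuation.

    ``side`` is ``"left"`` (continues the round stem across the left loop and
    tail) or ``"right"`` (continues the square stem across the head and right
    loop); ``inner_gap``/``outer_gap`` are the skipped bases on the 5'/3' set
    (not both 0); ``pairs_after_gap`` is the number of planted pairs beyond
    the gap.
    """

    side: str
    inner_gap: int
    outer_gap: int
    pairs_after_gap: int = 1


@dataclass(frozen=True)
class PlantSpec:
    left_stem_len: int = 4
    right_stem_len: int = 4
    left_loop_len: int = 4
    right_loop_len: int = 5
    head_len: int = 0
    tail_len: int = 0
    bulge: Optional[BulgeSpec] = None
    seed: int = 0

    def validate(self) -> None:
        if self.left_stem_len < 2 or self.right_stem_len < 2:
            raise InfeasibleSpecError("stem lengths must be >= 2")
        if self.left_loop_len < 1 or self.right_loop_len < 1:
            raise InfeasibleSpecError("loop lengths must be >= 1")
        if self.head_len < 0 or self.tail_len < 0:
            raise InfeasibleSpecError("head/tail lengths must be >= 0")
        b = self.bulge
        if b is not None:
            if b.side not in ("left", "right"):
                raise InfeasibleSpecError(f"unknown bulge side {b.side!r}")
            if b.inner_gap < 0 or b.outer_gap < 0:
                raise InfeasibleSpecError("gap lengths must be >= 0")
            if b.inner_gap == 0 and b.outer_gap == 0:
                raise InfeasibleSpecError(
                    "bulge with both gaps 0 is a contiguous extension, not a bulge"
                )
            if b.pairs_after_gap < 1:
                raise InfeasibleSpecError("pairs_after_gap must be >= 1")

    @property
    def total_length(self) -> int:
        n = (
            self.head_len
            + 2 * self.left_stem_len
            + 2 * self.right_stem_len
            + self.left_loop_len
            + self.right_loop_len
            + self.tail_len
        )
        if self.bulge is not None:
            n += 2 * self.bulge.pairs_after_gap + self.bulge.inner_gap + self.bulge.outer_gap
        return n


def _layout(spec: PlantSpec) -> tuple:
    """Position blocks (1-based) and the planted pair lists."""
    b = spec.bulge
    m = b.pairs_after_gap if b else 0
    cursor = 1

    def block(size: int) -> list:
        nonlocal cursor
        blk = list(range(cursor, cursor + size))
        cursor += size
        return blk

    head = block(spec.head_len)
    xp_right = block(m if b and b.side == "right" else 0)
    block(b.inner_gap if b and b.side == "right" else 0)  # inner gap (unpaired)
    s1a = block(spec.left_stem_len)
    l1 = block(spec.left_loop_len)
    xp_left = block(m if b and b.side == "left" else 0)
    block(b.inner_gap if b and b.side == "left" else 0)
    s2a = block(spec.right_stem_len)
    s1b = block(spec.left_stem_len)
    block(b.outer_gap if b and b.side == "right" else 0)
    xq_right = block(m if b and b.side == "right" else 0)
    l2 = block(spec.right_loop_len)
    s2b = block(spec.right_stem_len)
    block(b.outer_gap if b and b.side == "left" else 0)
    xq_left = block(m if b and b.side == "left" else 0)
    block(spec.tail_len)

    square = list(zip(s1a, reversed(s1b)))
    rnd = list(zip(s2a, reversed(s2b)))
    gap_pairs = []
    if b:
        xp = xp_right or xp_left
        xq = xq_right or xq_left
        # continuation runs outward: descending p, ascending q
        gap_pairs = list(zip(reversed(xp), xq))
    if b and b.side == "right":
        square += gap_pairs
    elif b:
        rnd += gap_pairs
    return square, rnd, gap_pairs


def _accidental_helix(res: str, planted: set, min_run: int = 3) -> bool:
    """True if any >=min_run stacked complementary run is not fully planted."""
    n = len(res)
    rules = PairRules(allow_gu=False)
    for a in range(1, n + 1):
        for b in range(a + 2 * min_run, n + 1):
            run_planted = True
            t = 0
            while (
                a + t < b - t
                and is_complementary(res[a + t - 1], res[b - t - 1], rules)
            ):
                if (a + t, b - t) not in planted:
                    run_planted = False
                t += 1
                if t >= min_run and not run_planted:
                    return True
    return False


def generate_pseudoknot(spec: PlantSpec) -> tuple:
    """Build one planted instance: (Sequence, Structure).

    The structure's square layer holds the left stem (plus a planted
    right-side gap continuation), the round layer the right stem (plus a
    left-side continuation); gap-mediated pairs carry gap flags.  The true
    core quadruple is recoverable via
    :func:`hknot.corestems.core_quad_from_structure`.
    """
    spec.validate()
    square, rnd, gap_pairs = _layout(spec)
    n = spec.total_length
    rng = random.Random(spec.seed)

    planted = set(square) | set(rnd)
    paired_positions = {p for pr in planted for p in pr}
    # redraw stems and loops together: competing helices can be caused by the
    # stem letters themselves, which refilling loops alone cannot repair
    for _ in range(MAX_FILL_ATTEMPTS):
        chars = [""] * n
        for p, q in sorted(planted):
            x, y = rng.choice(_WC_PAIRS)
            chars[p - 1], chars[q - 1] = x, y
        for i in range(n):
            if i + 1 not in paired_positions:
                chars[i] = rng.choice(_BASES)
        if not _accidental_helix("".join(chars), planted):
            break
    seq = Sequence(f"synth-seed{spec.seed}", "".join(chars))
    pairs = {(p, q, SQUARE) for p, q in square} | {(p, q, ROUND) for p, q in rnd}
    struct = Structure(
        length=n, pairs=frozenset(pairs), gap_flags=frozenset(gap_pairs)
    )
    return seq, struct


def true_core_quad(spec: PlantSpec) -> CoreStemQuad:
    """The planted core quadruple (innermost crossing pair of each stem)."""
    square, rnd, _ = _layout(spec)
    gap = set(_layout(spec)[2])
    i, k = max(p for p in square if p not in gap)
    j, l = max(p for p in rnd if p not in gap)
    return CoreStemQuad(i, j, k, l)
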