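"""Core-stem decoration: contiguous extension and gap-mediated continuations.

Starting from a core quadruple, each stem grows outward with stacked,
complementary pairs until complementarity fails, a position is occupied, or
the sequence ends.  The right (round) stem pairs left-loop bases with tail
bases; the left (square) stem pairs head bases with right-loop bases.

After contiguous extension, each side may continue *across a gap*: skipping
``b_inner`` bases on the 5' set and ``b_outer`` on the 3' set (each between 0
and ``maximum_bulge_size``, not both 0) before the next pair.  A single
nonzero gap is a bulge; both nonzero form an internal loop.  Pairs formed
after a gap stack on contiguously until failure and carry a gap flag — they
are excluded from the maximum-base-pairing rank.  One gap event per side is
attempted.  The Cartesian product of the per-side choices (including "no
gap") yields the candidate list for the quadruple.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .corestems import CoreStemQuad, PairRules, is_complementary
from .energy import StructureCandidate
from .seqio import Sequence

LEFT_SETS = "left_pair_of_sets"
RIGHT_SETS = "right_pair_of_sets"


@dataclass(frozen=True)
class DecorationParams:
    """Decoration settings: maximum gap length tried per set, and pair rules."""

    maximum_bulge_size: int = 3
    rules: PairRules = PairRules()

    def __post_init__(self) -> None:
        if self.maximum_bulge_size < 0:
            raise ValueError("maximum_bulge_size must be >= 0")


@dataclass(frozen=True)
class GapChoice:
    """One gap-mediated continuation of a stem.

    ``b_inner`` bases are skipped on the 5' (p) set and ``b_outer`` on the 3'
    (q) set before the first new pair; ``pairs_after_gap`` is the maximal run
    of stacked pairs formed after the gap.
    """

    b_inner: int
    b_outer: int
    pairs_after_gap: tuple

    def __post_init__(self) -> None:
        if self.b_inner == 0 and self.b_outer == 0:
            raise ValueError("a gap choice needs at least one nonzero gap")
        if not self.pairs_after_gap:
            raise ValueError("pairs_after_gap must be nonempty")

    @property
    def is_internal_loop(self) -> bool:
        return self.b_inner > 0 and self.b_outer > 0


@dataclass(frozen=True)
class DecoratedCandidate:
    """A quadruple with its maximally extended contiguous stems.

    ``left_stem_pairs`` (square layer) starts at the core pair (i, k) and
    steps (-1, +1) outward; ``right_stem_pairs`` (round layer) likewise from
    (j, l).  Gap choices, when attached, are recorded per side.
    """

    quad: CoreStemQuad
    left_stem_pairs: tuple
    right_stem_pairs: tuple
    left_gap: Optional[GapChoice] = None
    right_gap: Optional[GapChoice] = None


def extend_stems(
    seq: Sequence, quad: CoreStemQuad, rules: PairRules = PairRules()
) -> DecoratedCandidate:
    """Grow both stems outward to maximality with contiguous stacked pairs.

    The right stem extends first, as (j-t, l+t) for t = 1, 2, ... while both
    positions are free, in range and complementary; then the left stem as
    (i-t, k+t).  The two stems consume disjoint position sets (left loop/tail
    versus head/right loop), so the order does not affect the result.
    """
    n = seq.length
    res = seq.residues
    occupied = {quad.i, quad.j, quad.k, quad.l}

    def grow(p0: int, q0: int) -> list:
        pairs = [(p0, q0)]
        p, q = p0 - 1, q0 + 1
        while (
            p >= 1
            and q <= n
            and p not in occupied
            and q not in occupied
            and is_complementary(res[p - 1], res[q - 1], rules)
        ):
            pairs.append((p, q))
            occupied.update((p, q))
            p, q = p - 1, q + 1
        return pairs

    right = grow(quad.j, quad.l)
    left = grow(quad.i, quad.k)
    return DecoratedCandidate(
        quad=quad, left_stem_pairs=tuple(left), right_stem_pairs=tuple(right)
    )


def _gap_sets(dc: DecoratedCandidate, side: str) -> tuple:
    """The (p_lo, q_hi) boundaries of the two unpaired sets for one side.

    Left pair of sets: remainder of the left loop (down to i+1) and the 3'
    tail; right pair of sets: the 5' head and the remainder of the right loop
    (up to l-1).  Returns (p0, q0, p_lo, q_hi) with (p0, q0) the stem's last
    contiguous pair.
    """
    quad = dc.quad
    if side == LEFT_SETS:
        p0, q0 = dc.right_stem_pairs[-1]
        return p0, q0, quad.i + 1, None  # q bounded by sequence end
    if side == RIGHT_SETS:
        p0, q0 = dc.left_stem_pairs[-1]
        return p0, q0, 1, quad.l - 1
    raise ValueError(f"unknown side {side!r}")


def enumerate_gap_extensions(
    seq: Sequence,
    dc: DecoratedCandidate,
    side: str,
    params: DecorationParams = DecorationParams(),
) -> list:
    """All gap-mediated continuations of one stem, deduplicated and sorted.

    For every (b_inner, b_outer) in [0, B]^2 except (0, 0), the pair
    (p0 - 1 - b_inner, q0 + 1 + b_outer) is attempted; if both positions lie
    inside their sets, are free, and the bases are complementary, stacking
    continues maximally inside the sets and the resulting
    :class:`GapChoice` is emitted.
    """
    n = seq.length
    res = seq.residues
    b = params.maximum_bulge_size
    p0, q0, p_lo, q_hi = _gap_sets(dc, side)
    if q_hi is None:
        q_hi = n
    used = {p for pr in dc.left_stem_pairs + dc.right_stem_pairs for p in pr}
    choices = []
    seen_pairsets = set()
    for b_inner in range(b + 1):
        for b_outer in range(b + 1):
            if b_inner == 0 and b_outer == 0:
                continue
            p, q = p0 - 1 - b_inner, q0 + 1 + b_outer
            pairs = []
            while (
                p_lo <= p
                and q <= q_hi
                and p not in used
                and q not in used
                and is_complementary(res[p - 1], res[q - 1], params.rules)
            ):
                pairs.append((p, q))
                p, q = p - 1, q + 1
            if pairs:
                key = tuple(pairs)
                if key not in seen_pairsets:
                    seen_pairsets.add(key)
                    choices.append(GapChoice(b_inner, b_outer, key))
    choices.sort(key=lambda g: (g.b_inner, g.b_outer))
    return choices


def decorate(
    seq: Sequence, quad: CoreStemQuad, params: DecorationParams = DecorationParams()
) -> list:
    """All decorated candidates of one quadruple.

    One :class:`~hknot.energy.StructureCandidate` per element of
    ({no gap} U left choices) x ({no gap} U right choices); gap-mediated
    pairs carry gap flags.
    """
    dc = extend_stems(seq, quad, params.rules)
    left_choices = [None] + enumerate_gap_extensions(seq, dc, LEFT_SETS, params)
    right_choices = [None] + enumerate_gap_extensions(seq, dc, RIGHT_SETS, params)
    out = []
    for rg in right_choices:  # continues the square (left) stem
        for lg in left_choices:  # continues the round (right) stem
            square = list(dc.left_stem_pairs)
            rnd = list(dc.right_stem_pairs)
            gaps = set()
            if rg is not None:
                square.extend(rg.pairs_after_gap)
                gaps.update(rg.pairs_after_gap)
            if lg is not None:
                rnd.extend(lg.pairs_after_gap)
                gaps.update(lg.pairs_after_gap)
            out.append(StructureCandidate(quad, square, rnd, gaps))
    return out


def trace_decoration(
    seq: Sequence, quad: CoreStemQuad, params: DecorationParams = DecorationParams()
) -> list:
    """Stage-by-stage dot-bracket rows of the decoration of one quadruple.

    Row 0 is the bare core stems; one row follows per contiguous extension
    pair (right stem first), and one per available gap choice on each side.
    Intended for debugging / the CLI trace mode.
    """
    from .seqio import ROUND, SQUARE, Structure

    def render(square, rnd) -> str:
        pairs = {(p, q, SQUARE) for p, q in square} | {(p, q, ROUND) for p, q in rnd}
        return Structure(length=seq.length, pairs=frozenset(pairs)).to_dotbracket()

    dc = extend_stems(seq, quad, params.rules)
    rows = [f"core stems\t{render([quad.left_pair], [quad.right_pair])}"]
    rnd = [quad.right_pair]
    for p, q in dc.right_stem_pairs[1:]:
        rnd.append((p, q))
        rows.append(f"extend right {p}-{q}\t{render([quad.left_pair], rnd)}")
    square = [quad.left_pair]
    for p, q in dc.left_stem_pairs[1:]:
        square.append((p, q))
        rows.append(f"extend left {p}-{q}\t{render(square, rnd)}")
    for side, label in ((LEFT_SETS, "left sets"), (RIGHT_SETS, "right sets")):
        for g in enumerate_gap_extensions(seq, dc, side, params):
            kind = "internal loop" if g.is_internal_loop else "bulge"
            sq, rn = list(square), list(rnd)
            (rn if side == LEFT_SETS else sq).extend(g.pairs_after_gap)
            first = g.pairs_after_gap[0]
            rows.append(
                f"{label} {kind} ({g.b_inner},{g.b_outer}) pair {first[0]}-{first[1]}"
                f"\t{render(sq, rn)}"
            )
    return rows
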