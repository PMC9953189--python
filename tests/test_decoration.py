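"""Stem decoration: contiguous extension and gap-mediated continuations."""

import pytest
from hypothesis import given, settings, strategies as st

from hknot import (
    CoreStemQuad,
    DecorationParams,
    PairRules,
    Sequence,
    decorate,
    enumerate_gap_extensions,
    extend_stems,
    is_complementary,
)
from hknot.decoration import LEFT_SETS, RIGHT_SETS

WORKED = Sequence("w", "ACAUCCGCCUGAUUUGAGCACA")
WORKED_QUAD = CoreStemQuad(5, 10, 11, 17)


class TestContiguousExtension:
    def test_worked_example_stems(self):
        dc = extend_stems(WORKED, WORKED_QUAD)
        # right stem stops at (9,18): the next step (8,19) is C-C
        assert dc.right_stem_pairs == ((10, 17), (9, 18))
        # left stem stops at (3,13): the next step (2,14) is C-U
        assert dc.left_stem_pairs == ((5, 11), (4, 12), (3, 13))

    def test_extension_blocked_by_occupied_position(self):
        seq = Sequence("s", "ACGUACGU")
        dc = extend_stems(seq, CoreStemQuad(1, 3, 4, 6))
        assert dc.right_stem_pairs == ((3, 6), (2, 7))  # (1,8) blocked: 1 paired
        assert dc.left_stem_pairs == ((1, 4),)

    def test_no_extension_when_flanks_cannot_pair(self):
        seq = Sequence("s", "AACAGAAGACAA")
        quad = CoreStemQuad(3, 6, 7, 10)  # C-G and G-C cores, A flanks everywhere
        dc = extend_stems(seq, quad)
        assert dc.left_stem_pairs == ((3, 7),)
        assert dc.right_stem_pairs == ((6, 10),)


class TestGapExtensions:
    def test_worked_left_pair_of_sets(self):
        dc = extend_stems(WORKED, WORKED_QUAD)
        got = {
            (g.b_inner, g.b_outer, g.pairs_after_gap)
            for g in enumerate_gap_extensions(WORKED, dc, LEFT_SETS)
        }
        assert got == {(1, 0, ((7, 19),)), (1, 2, ((7, 21),))}

    def test_worked_right_pair_of_sets(self):
        dc = extend_stems(WORKED, WORKED_QUAD)
        got = {
            (g.b_inner, g.b_outer, g.pairs_after_gap)
            for g in enumerate_gap_extensions(WORKED, dc, RIGHT_SETS)
        }
        assert got == {
            (1, 0, ((1, 14),)),
            (1, 1, ((1, 15),)),
            (0, 2, ((2, 16),)),
        }

    def test_internal_loop_flag(self):
        dc = extend_stems(WORKED, WORKED_QUAD)
        by_pair = {
            g.pairs_after_gap[0]: g
            for g in enumerate_gap_extensions(WORKED, dc, RIGHT_SETS)
        }
        assert by_pair[(1, 15)].is_internal_loop
        assert not by_pair[(1, 14)].is_internal_loop  # single-sided gap: a bulge

    def test_zero_bulge_size_yields_nothing(self):
        dc = extend_stems(WORKED, WORKED_QUAD)
        params = DecorationParams(maximum_bulge_size=0)
        assert enumerate_gap_extensions(WORKED, dc, LEFT_SETS, params) == []
        assert enumerate_gap_extensions(WORKED, dc, RIGHT_SETS, params) == []


class TestDecorate:
    def test_worked_example_candidate_count(self):
        cands = decorate(WORKED, WORKED_QUAD)
        assert len(cands) == 12  # (1 + 2 left choices) x (1 + 3 right choices)

    def test_bulge_size_zero_gives_single_candidate(self):
        cands = decorate(WORKED, WORKED_QUAD, DecorationParams(maximum_bulge_size=0))
        assert len(cands) == 1
        assert not cands[0].gap_pairs

    def test_gap_pairs_flagged_and_counted(self):
        cands = decorate(WORKED, WORKED_QUAD)
        for c in cands:
            assert c.nongap_pair_count == c.pair_count - len(c.gap_pairs)
            assert c.nongap_pair_count == 5  # 3 left + 2 right contiguous pairs

    def test_removing_gap_pairs_leaves_maximal_contiguous_decoration(self):
        dc = extend_stems(WORKED, WORKED_QUAD)
        contiguous = set(dc.left_stem_pairs) | set(dc.right_stem_pairs)
        for c in decorate(WORKED, WORKED_QUAD):
            assert set(c.all_pairs) - c.gap_pairs == contiguous


def _naive_gap_continuations(seq, dc, side, bulge):
    """Independent oracle: scan every free (p, q) inside the two sets whose
    offsets from the stem's last pair are within the bulge bound."""
    quad = dc.quad
    used = {x for pr in dc.left_stem_pairs + dc.right_stem_pairs for x in pr}
    if side == LEFT_SETS:
        p0, q0 = dc.right_stem_pairs[-1]
        p_lo, q_hi = quad.i + 1, seq.length
    else:
        p0, q0 = dc.left_stem_pairs[-1]
        p_lo, q_hi = 1, quad.l - 1
    found = set()
    for p in range(p_lo, p0):
        for q in range(q0 + 1, q_hi + 1):
            if (p0 - 1 - p) > bulge or (q - q0 - 1) > bulge:
                continue
            if (p0 - 1 - p) == 0 and (q - q0 - 1) == 0:
                continue
            if p in used or q in used:
                continue
            if not is_complementary(seq.residues[p - 1], seq.residues[q - 1]):
                continue
            run = []
            pp, qq = p, q
            while (
                p_lo <= pp <= p0 - 1
                and q0 + 1 <= qq <= q_hi
                and pp not in used
                and qq not in used
                and is_complementary(seq.residues[pp - 1], seq.residues[qq - 1])
            ):
                run.append((pp, qq))
                pp, qq = pp - 1, qq + 1
            found.add(tuple(run))
    return found


@given(st.text(alphabet="ACGU", min_size=6, max_size=14), st.integers(0, 3))
@settings(max_examples=150)
def test_gap_enumeration_matches_naive_scan(residues, bulge):
    """Grid-based gap search equals a position-scan oracle on small inputs."""
    from hknot import enumerate_core_stems

    seq = Sequence("h", residues)
    params = DecorationParams(maximum_bulge_size=bulge)
    for quad in enumerate_core_stems(seq)[:10]:
        dc = extend_stems(seq, quad)
        for side in (LEFT_SETS, RIGHT_SETS):
            got = {g.pairs_after_gap for g in enumerate_gap_extensions(seq, dc, side, params)}
            assert got == _naive_gap_continuations(seq, dc, side, bulge)


@given(st.text(alphabet="ACGU", min_size=6, max_size=16), st.booleans())
@settings(max_examples=100)
def test_every_emitted_pair_is_complementary(residues, allow_gu):
    from hknot import enumerate_core_stems

    seq = Sequence("h", residues)
    rules = PairRules(allow_gu=allow_gu)
    params = DecorationParams(maximum_bulge_size=3, rules=rules)
    for quad in enumerate_core_stems(seq, rules)[:8]:
        for c in decorate(seq, quad, params):
            for p, q in c.all_pairs:
                assert is_complementary(seq.residues[p - 1], seq.residues[q - 1], rules)
            # at most one gap event per side: the gap pairs of each layer
            # form a single stacked run ((-1,+1) steps)
            for layer_pairs in (c.square_pairs, c.round_pairs):
                run = sorted(set(layer_pairs) & c.gap_pairs, reverse=True)
                for (p1, q1), (p2, q2) in zip(run, run[1:]):
                    assert (p2, q2) == (p1 - 1, q1 + 1)
            struct = c.structure(seq.length)
            assert struct.gap_flags == c.gap_pairs
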