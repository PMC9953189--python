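"""Candidate scoring and optimal-structure selection.

Selection is two-staged: candidates are first ranked by the number of base
pairs in the two crossing stems *excluding* gap-mediated pairs (maximum base
pairing); ties are then broken by minimum free energy.  The energy model is
the pseudoknot penalty

    G_pseudo = beta1 + beta2 * Bp + beta3 * Up

(beta1 = 9.6 kcal/mol existence cost, beta2 = 0.1 per stem pair, beta3 = 0.1
per unpaired base inside the pseudoknot span) plus a within-layer helix
stacking term.  By default the stacking table is all-zero, so ranking uses
the penalty alone; a bundled Turner 2004 nearest-neighbor table
(:func:`load_stack_table`) or any mapping with the same key convention can
be swapped in via :class:`EnergyParams`.  See docs/methods.md for why the
penalty-only model is the default.
"""

from __future__ import annotations

import functools
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence as Seq

from .corestems import CoreStemQuad
from .seqio import ROUND, SQUARE, Sequence, Structure

DEFAULT_BETA1 = 9.6
DEFAULT_BETA2 = 0.1
DEFAULT_BETA3 = 0.1

_STACK_RESOURCE = "stacking_turner2004.tsv"
#: sha256 of the bundled stacking table; checked on load
STACK_TABLE_SHA256 = "0ccafa8a1a5bbda071092d3954a027fa0b6d85b1f34f2d8ce550c0fb5670d9dd"

#: tolerance below which two energies are considered equal during selection
ENERGY_TOL = 1e-9


_PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")


@functools.lru_cache(maxsize=1)
def zero_stack_table() -> Mapping:
    """An all-zero stacking table covering every ordered stack of admissible pairs."""
    return {(o, i): 0.0 for o in _PAIR_TYPES for i in _PAIR_TYPES}


@functools.lru_cache(maxsize=1)
def load_stack_table() -> Mapping:
    """Load the bundled Turner 2004 stacking table.

    Keys are (outer_pair, inner_pair) two-letter strings, where the outer pair
    reads (residue p, residue q) and the inner pair (residue p+1, residue q-1)
    of a stack; values are kcal/mol.
    """
    data = (resources.files("hknot.data") / _STACK_RESOURCE).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != STACK_TABLE_SHA256:
        raise RuntimeError(
            f"stacking table checksum mismatch: {digest} != {STACK_TABLE_SHA256}"
        )
    table = {}
    for line in data.decode().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        outer, inner, dg = line.split("\t")
        table[(outer, inner)] = float(dg)
    return table


@dataclass(frozen=True)
class EnergyParams:
    """Energy model parameters: the three betas and the stacking table.

    The default table is all-zero (penalty-only ranking); pass
    ``stack_table=load_stack_table()`` for the Turner 2004 backend.
    """

    beta1: float = DEFAULT_BETA1
    beta2: float = DEFAULT_BETA2
    beta3: float = DEFAULT_BETA3
    stack_table: Mapping = field(default_factory=zero_stack_table, compare=False)


class NoPseudoknotError(ValueError):
    """Raised when selection is attempted on an empty candidate list."""


def pseudoknot_penalty(bp: int, up: int, params: EnergyParams = EnergyParams()) -> float:
    """The pseudoknot penalty beta1 + beta2*Bp + beta3*Up (kcal/mol)."""
    if bp < 0 or up < 0:
        raise ValueError("Bp and Up must be nonnegative")
    return params.beta1 + params.beta2 * bp + params.beta3 * up


def stack_energy(seq: Sequence, s: Structure, params: EnergyParams = EnergyParams()) -> float:
    """Sum of stacking energies over within-layer adjacent pairs.

    Two pairs (p, q) and (p+1, q-1) of the same layer form one stack; isolated
    pairs and structures with no stacks score 0.
    """
    res = seq.residues
    total = 0.0
    for layer in (SQUARE, ROUND):
        pl = set(s.layer_pairs(layer))
        for p, q in pl:
            if (p + 1, q - 1) in pl:
                key = (res[p - 1] + res[q - 1], res[p] + res[q - 2])
                total += params.stack_table.get(key, 0.0)
    return total


class StructureCandidate:
    """A fully decorated candidate structure with its selection features.

    ``square_pairs``/``round_pairs`` are the pairs of the two bracket layers;
    ``gap_pairs`` the subset formed across a bulge or internal loop.  Features:

    * ``nongap_pair_count`` (== Bp): pairs in the two crossing stems excluding
      gap-mediated ones — the stage-1 ranking key;
    * ``Up``: unpaired bases strictly inside the span of the outermost pairs;
    * ``total_energy(...)``: stacking + pseudoknot penalty, the stage-2 key.
    """

    __slots__ = ("quad", "square_pairs", "round_pairs", "gap_pairs", "_structure")

    def __init__(
        self,
        quad: CoreStemQuad,
        square_pairs: Seq,
        round_pairs: Seq,
        gap_pairs: Iterable = (),
    ) -> None:
        self.quad = quad
        self.square_pairs = tuple(sorted(square_pairs))
        self.round_pairs = tuple(sorted(round_pairs))
        self.gap_pairs = frozenset(gap_pairs)
        self._structure: Optional[Structure] = None

    @property
    def all_pairs(self) -> tuple:
        return tuple(sorted(self.square_pairs + self.round_pairs))

    @property
    def pair_count(self) -> int:
        return len(self.square_pairs) + len(self.round_pairs)

    @property
    def nongap_pair_count(self) -> int:
        return self.pair_count - len(self.gap_pairs)

    # Bp of the penalty formula: base pairs of the two crossing stems,
    # gap-mediated pairs excluded.
    Bp = nongap_pair_count

    @property
    def Up(self) -> int:
        paired = {p for pr in self.all_pairs for p in pr}
        lo, hi = min(paired), max(paired)
        return sum(1 for pos in range(lo, hi + 1) if pos not in paired)

    def structure(self, length: int) -> Structure:
        """Materialize (and cache) the :class:`Structure` of this candidate."""
        if self._structure is None or self._structure.length != length:
            pairs = {(p, q, SQUARE) for p, q in self.square_pairs} | {
                (p, q, ROUND) for p, q in self.round_pairs
            }
            self._structure = Structure(
                length=length, pairs=frozenset(pairs), gap_flags=self.gap_pairs
            )
        return self._structure

    def core_pairs(self) -> tuple:
        """The two core pairs ((i,k), (j,l)) of this candidate."""
        return (self.quad.left_pair, self.quad.right_pair)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"StructureCandidate(quad={self.quad.as_tuple()}, "
            f"pairs={self.pair_count}, nongap={self.nongap_pair_count})"
        )


def total_energy(
    seq: Sequence, c: StructureCandidate, params: EnergyParams = EnergyParams()
) -> float:
    """Stacking energy plus pseudoknot penalty of a candidate (kcal/mol)."""
    return stack_energy(seq, c.structure(seq.length), params) + pseudoknot_penalty(
        c.Bp, c.Up, params
    )


def select_optimal(
    candidates: Seq, seq: Sequence, params: EnergyParams = EnergyParams()
) -> StructureCandidate:
    """Two-stage selection of the optimal candidate.

    Stage 1 keeps the candidates with the maximal non-gap pair count; stage 2
    takes the minimum total energy among them (energies closer than
    ``ENERGY_TOL`` count as equal).  Remaining ties break deterministically:
    more total pairs (gap-mediated included), then lexicographically smallest
    core quadruple, then smallest pair list.  Raises
    :class:`NoPseudoknotError` on an empty list.
    """
    candidates = list(candidates)
    if not candidates:
        raise NoPseudoknotError("no pseudoknot found: empty candidate list")
    best_count = max(c.nongap_pair_count for c in candidates)
    stage1 = [c for c in candidates if c.nongap_pair_count == best_count]
    energies = {id(c): total_energy(seq, c, params) for c in stage1}
    e_min = min(energies.values())
    stage2 = [c for c in stage1 if energies[id(c)] <= e_min + ENERGY_TOL]
    return min(
        stage2, key=lambda c: (-c.pair_count, c.quad.as_tuple(), c.all_pairs)
    )
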