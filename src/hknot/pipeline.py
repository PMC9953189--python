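"""End-to-end prediction: enumerate, decorate, select.

``predict_structure`` runs the full method on one sequence: every candidate
core-stem quadruple is decorated (contiguous extension plus bulge/internal
loop continuations) and the optimal candidate is selected by maximum non-gap
base pairing, then minimum free energy.  Sequences with no candidate
quadruple yield an all-unpaired structure with a warning rather than failing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .corestems import PairRules, enumerate_core_stems
from .decoration import DecorationParams, decorate
from .energy import EnergyParams, StructureCandidate, select_optimal
from .seqio import Sequence, Structure

logger = logging.getLogger("hknot")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration with the documented defaults."""

    allow_gu: bool = False
    maximum_bulge_size: int = 3
    beta1: float = 9.6
    beta2: float = 0.1
    beta3: float = 0.1
    min_left_loop: int = 1
    min_right_loop: int = 1
    stacking: str = "none"  # "none" (penalty-only) or "turner2004"

    def __post_init__(self) -> None:
        if self.maximum_bulge_size < 0:
            raise ValueError("maximum_bulge_size must be >= 0")
        if self.min_left_loop < 0 or self.min_right_loop < 0:
            raise ValueError("loop minima must be >= 0")
        if self.stacking not in ("none", "turner2004"):
            raise ValueError(f"unknown stacking backend {self.stacking!r}")

    @property
    def rules(self) -> PairRules:
        return PairRules(allow_gu=self.allow_gu)

    @property
    def decoration(self) -> DecorationParams:
        return DecorationParams(
            maximum_bulge_size=self.maximum_bulge_size, rules=self.rules
        )

    @property
    def energy(self) -> EnergyParams:
        from .energy import load_stack_table, zero_stack_table

        table = load_stack_table() if self.stacking == "turner2004" else zero_stack_table()
        return EnergyParams(
            beta1=self.beta1, beta2=self.beta2, beta3=self.beta3, stack_table=table
        )


@dataclass(frozen=True)
class PredictionResult:
    sequence: Sequence
    structure: Structure
    candidate: Optional[StructureCandidate]  # None when no pseudoknot was found
    n_quads: int
    n_candidates: int

    @property
    def found(self) -> bool:
        return self.candidate is not None

    def dotbracket(self) -> str:
        return self.structure.to_dotbracket()


def predict_structure(seq: Sequence, config: RunConfig = RunConfig()) -> PredictionResult:
    """Predict the H-type pseudoknot of one sequence."""
    quads = enumerate_core_stems(
        seq, config.rules, config.min_left_loop, config.min_right_loop
    )
    candidates: list[StructureCandidate] = []
    for quad in quads:
        candidates.extend(decorate(seq, quad, config.decoration))
    logger.info(
        "%s: %d core-stem quadruples, %d decorated candidates",
        seq.identifier,
        len(quads),
        len(candidates),
    )
    if not candidates:
        warnings.warn(
            f"{seq.identifier}: no pseudoknot candidate; reporting all-unpaired"
        )
        return PredictionResult(
            sequence=seq,
            structure=Structure(length=seq.length),
            candidate=None,
            n_quads=0,
            n_candidates=0,
        )
    best = select_optimal(candidates, seq, config.energy)
    return PredictionResult(
        sequence=seq,
        structure=best.structure(seq.length),
        candidate=best,
        n_quads=len(quads),
        n_candidates=len(candidates),
    )


def predict_many(seqs, config: RunConfig = RunConfig()) -> list:
    """Predict each sequence in turn (order preserved)."""
    return [predict_structure(s, config) for s in seqs]
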