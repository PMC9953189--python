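"""Prediction accuracy metrics.

Per-position confusion counts over a predicted and a reference structure,
the derived PPV / Recall / F1 / MCC metrics, and slip-tolerant matching of
the pseudoknot core stems.

Every position contributes exactly one count, so tp + tn + fp + fn equals
the sequence length: tp when paired to the same partner in both structures,
tn when unpaired in both, fn when paired only in the reference, fp otherwise
(predicted paired while the reference is unpaired, or partner mismatch).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence as Seq, Union

from .energy import StructureCandidate
from .seqio import Structure


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metrics:
    """PPV (precision), recall, their harmonic mean F1, and the MCC.

    Metrics with a zero denominator are NaN (reported with a warning,
    never silently 0).
    """

    ppv: float
    recall: float
    f1: float
    mcc: float


def confusion_counts(pred: Structure, ref: Structure) -> ConfusionCounts:
    """Per-position confusion counts of ``pred`` against ``ref``."""
    if pred.length != ref.length:
        raise ValueError(
            f"length mismatch: prediction {pred.length} vs reference {ref.length}"
        )
    pm, rm = pred.partner_map(), ref.partner_map()
    tp = tn = fp = fn = 0
    for pos in range(1, ref.length + 1):
        p, r = pm.get(pos), rm.get(pos)
        if p is None and r is None:
            tn += 1
        elif p == r:
            tp += 1
        elif p is None:
            fn += 1
        else:
            fp += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
        return math.nan
    return num / den


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """PPV, recall, F1 and MCC from confusion counts."""
    ppv = _ratio(c.tp, c.tp + c.fp, "PPV")
    recall = _ratio(c.tp, c.tp + c.fn, "Recall")
    if math.isnan(ppv) or math.isnan(recall):
        f1 = math.nan
    else:
        f1 = _ratio(2 * ppv * recall, ppv + recall, "F1")
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, mcc_den, "MCC")
    return Metrics(ppv=ppv, recall=recall, f1=f1, mcc=mcc)


def _pair_matches(pred: tuple, ref: tuple, slip: int) -> bool:
    dp = abs(pred[0] - ref[0])
    dq = abs(pred[1] - ref[1])
    # one coordinate may slip, not both simultaneously
    return (dp == 0 and dq <= slip) or (dq == 0 and dp <= slip)


def core_stem_matches(
    pred: Union[StructureCandidate, Iterable], ref_core: Seq, slip: int = 1
) -> int:
    """Number of reference core pairs (0-2) matched by predicted core pairs.

    A pair (k, l) matches (k +- slip, l) or (k, l +- slip); each predicted
    pair may satisfy at most one reference pair (best assignment is taken).
    ``pred`` is a selected candidate or an explicit iterable of (p, q) pairs.
    """
    if isinstance(pred, StructureCandidate):
        pred_pairs = list(pred.core_pairs())
    else:
        pred_pairs = list(pred)
    ref_pairs = list(ref_core)
    if len(ref_pairs) != 2:
        raise ValueError("ref_core must hold exactly two core pairs")
    best = 0
    # tiny assignment problem: try both orders of the reference pairs
    for order in (ref_pairs, ref_pairs[::-1]):
        used: set[int] = set()
        score = 0
        for r in order:
            for idx, p in enumerate(pred_pairs):
                if idx not in used and _pair_matches(p, r, slip):
                    used.add(idx)
                    score += 1
                    break
        best = max(best, score)
    return best
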