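"""Score a prediction against a reference structure.

Each position contributes one confusion count (tp / tn / fp / fn); PPV,
recall, F1 and MCC follow.  Core-stem matching tolerates a one-position slip
on a single coordinate of each pair.
"""

from hknot import (
    compute_metrics,
    confusion_counts,
    core_quad_from_structure,
    core_stem_matches,
    parse_dotbracket,
)

reference = parse_dotbracket(".[[[.((((..]]]...)))).")
predicted = parse_dotbracket(".[[[..((((.]]]...)))).")

c = confusion_counts(predicted, reference)
m = compute_metrics(c)
print(f"tp={c.tp} tn={c.tn} fp={c.fp} fn={c.fn}  (sum = {c.total} positions)")
print(f"PPV={m.ppv:.3f} Recall={m.recall:.3f} F1={m.f1:.3f} MCC={m.mcc:.3f}")

ref_quad = core_quad_from_structure(reference)
pred_quad = core_quad_from_structure(predicted)
n = core_stem_matches(
    [pred_quad.left_pair, pred_quad.right_pair],
    [ref_quad.left_pair, ref_quad.right_pair],
    slip=1,
)
print(f"core stems matched (slip 1): {n} of 2")
# PPV is the fraction of predicted paired positions that are right; recall the
# fraction of reference pairs recovered; MCC balances all four counts.
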