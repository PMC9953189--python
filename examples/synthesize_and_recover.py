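"""Plant pseudoknots with known ground truth and measure recovery.

The generator emits sequences whose only strong helices are the planted
stems (an internal loop is planted in half the instances here); the
pipeline should recover both core stems.
"""

from hknot import (
    BulgeSpec,
    PlantSpec,
    compute_metrics,
    confusion_counts,
    core_stem_matches,
    generate_pseudoknot,
    predict_structure,
    true_core_quad,
)

n_instances = 40
both = at_least_one = 0
total_counts = None
for seed in range(n_instances):
    bulge = (
        BulgeSpec(side="right", inner_gap=1, outer_gap=1, pairs_after_gap=1)
        if seed % 2
        else None
    )
    spec = PlantSpec(left_stem_len=4, right_stem_len=4, bulge=bulge, seed=seed)
    seq, truth = generate_pseudoknot(spec)
    result = predict_structure(seq)
    quad = true_core_quad(spec)
    matches = core_stem_matches(result.candidate, [quad.left_pair, quad.right_pair])
    both += matches == 2
    at_least_one += matches >= 1
    c = confusion_counts(result.structure, truth)
    total_counts = c if total_counts is None else total_counts + c

m = compute_metrics(total_counts)
print(f"{n_instances} planted instances (stems 4 bp, internal loop in half)")
print(f"both core stems recovered: {both}/{n_instances}")
print(f"at least one core stem:    {at_least_one}/{n_instances}")
print(
    f"per-position aggregate: tp={total_counts.tp} tn={total_counts.tn} "
    f"fp={total_counts.fp} fn={total_counts.fn}"
)
print(f"PPV={m.ppv:.3f} Recall={m.recall:.3f} F1={m.f1:.3f} MCC={m.mcc:.3f}")
# Recovery is near-perfect because the generator suppresses competing
# helices; real sequences contain extra motifs the model does not describe.
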