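# hknot

Prediction of H-type RNA pseudoknots — including bulges and internal loops
around the crossing stems — from sequence alone, plus the matching
evaluation metrics and a planted-pseudoknot generator for benchmarking.

An H-type pseudoknot is formed when bases of a hairpin loop pair with bases
outside the hairpin, producing two helices (stems) whose base pairs cross.
Crossing pairs cannot be written in plain dot-bracket notation, and most
nested-structure prediction tools cannot represent them; `hknot` targets the
motif directly and is aimed at people studying short pseudoknotted RNAs
(viral frameshift elements, ribozyme fragments, aptamers) or benchmarking
structure predictors.

## Method

For a sequence of length *n* (positions 1-based):

1. **Core-stem enumeration.** Every quadruple (i, j, k, l) with
   i < j < k < l, complementary pairs (i, k) and (j, l) (Watson–Crick; G–U
   wobble optional), and nonempty loops is a candidate pseudoknot core:
   pair (i, k) opens the left stem (square bracket layer), (j, l) the right
   stem (round layer), and the two cross.
2. **Decoration.** Each stem grows outward with stacked pairs,
   (i−t, k+t) and (j−t, l+t), while bases stay complementary, free and in
   range. After contiguous growth stalls, a single gap-mediated continuation
   per side is tried: skip `b_inner` ∈ [0, B] bases on the 5′ set and
   `b_outer` ∈ [0, B] on the 3′ set (not both 0; `B` = `maximum_bulge_size`,
   default 3). One nonzero gap is a **bulge**, two form an **internal
   loop**; pairs formed beyond the gap stack on maximally and are flagged.
   The Cartesian product of the per-side options yields the candidates.
3. **Selection.** Candidates are ranked by the number of base pairs in the
   two crossing stems *excluding* gap-mediated pairs; ties are broken by
   minimum free energy, modelled as the pseudoknot penalty

   G_pseudo = β₁ + β₂·Bp + β₃·Up,   β₁ = 9.6, β₂ = β₃ = 0.1 kcal/mol,

   where Bp counts the non-gap stem pairs and Up the unpaired bases inside
   the pseudoknot span. A Turner 2004 nearest-neighbor stacking term can be
   added (`RunConfig(stacking="turner2004")`); the default is the penalty
   alone (see `docs/methods.md`).

The result is written in extended dot-bracket notation, `[ ]` for the left
stem and `( )` for the right. Accuracy is measured per position
(tp/tn/fp/fn with tp + tn + fp + fn = n) via PPV, recall, F1 and the
Matthews correlation coefficient, and per core stem with a ±1 slip
tolerance on one coordinate of a pair.

## Worked example

```bash
python examples/predict_worked_example.py
```

```
sequence   ACAUCCGCCUGAUUUGAGCACA
structure  .[[[[.(.((]]]..])))...
core stems: left pair (5, 11), right pair (10, 17)
left loop 6..9, right loop 12..16
367 candidate core quadruples, 1834 decorated candidates considered
gap-mediated pairs (bulge/internal loop): [(2, 16), (7, 19)]
```

The crossing core pairs C5–G11 and U10–A17 delimit the two loops (6–9 and
12–16). Contiguous extension adds C9–G18, then U4–A12 and A3–U13; the
gap-mediated pairs C2–G16 (a two-base bulge) and G7–C19 (a one-base bulge)
complete the structure. The same script prints the stage-by-stage
decoration trace, and the other two examples demonstrate the metrics and
the synthetic generator:

```bash
python examples/evaluate_metrics.py
python examples/synthesize_and_recover.py
```

Equivalent shell interface:

```bash
hknot predict --input seqs.fasta --max-bulge-size 3
hknot evaluate --pred predicted.db --ref reference.db
hknot synth --spec plant.json --seed 7 --out-fasta s.fa --out-structure s.db
```

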