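# Methods

## Model and scope

`hknot` predicts exactly one H-type pseudoknot per sequence: two helices
whose base pairs cross, connected by two loops, optionally interrupted by
one bulge or internal loop per side. It does not model hairpins or any
other motif inside the loops, multi-pseudoknot structures, or K/L/M-type
topologies; on sequences whose real structure contains extra motifs the
prediction covers only the pseudoknot itself, which depresses per-position
recall even when the core stems are found.

The candidate space is defined set-theoretically: every quadruple
(i, j, k, l), i < j < k < l, whose pairs (i, k) and (j, l) are complementary
and whose loops meet the configured minima is a core. This is equivalent to
enumerating the parse forest of an ambiguous context-free grammar dedicated
to the crossing pattern; direct enumeration was chosen as the reference
mechanism because the candidate *set* — not the parsing strategy — is the
contract, and an exhaustive brute-force oracle can then confirm it exactly
(the test suite does so for all sequences up to 14 nt). A sliding-window
pruning pass could be layered in front as a pure performance filter; at the
problem sizes this package ships with, enumeration of complementary pair
combinations is already well under a second, so no pruning is implemented.

## Decoration

Stems grow outward from the core pair, one stacked pair at a time, under
strict complementarity; growth stops at the first non-complementary step,
occupied position, or sequence boundary. The two stems draw on disjoint
position sets (left loop + 3′ tail for the right stem; 5′ head + right loop
for the left stem), so the fixed extension order (right stem first) cannot
change the outcome.

Gap search then works per side on the two unpaired remainder sets. For gap
lengths (b_inner, b_outer) ∈ [0, B]² \ {(0, 0)}, the pair
(p₀ − 1 − b_inner, q₀ + 1 + b_outer) is attempted from the stem's last pair
(p₀, q₀); on success, stacking continues inside the sets until it fails.
Exactly one gap event per side is attempted: a second interruption of the
same helix is outside the model. Gap-mediated pairs are flagged and play no
part in the maximum-base-pairing rank — they refine the structure and the
energy only. `maximum_bulge_size` B defaults to 3; raising it quadratically
enlarges the per-side search grid but in practice adds few viable pairs.

Strict complementarity is enforced for *every* emitted pair, including
extension pairs. Admissible pairs are A–U and C–G, plus G–U when
`allow_gu` is set (off by default, since wobble pairs both enlarge the
candidate set and weaken the planted-recovery guarantees below).

## Selection and the energy model

Selection is two-staged: (1) maximal non-gap pair count; (2) minimal free
energy among the stage-1 survivors, with energies within 1e-9 kcal/mol
treated as equal, after which ties break deterministically by total pair
count (gap pairs included), then lexicographically smallest core quadruple,
then smallest pair list. The tie-break chain makes the selection invariant
under permutation of the candidate list and reproducible across platforms.

The energy of a candidate is

    E = E_stack + β₁ + β₂·Bp + β₃·Up

with defaults β₁ = 9.6, β₂ = β₃ = 0.1 kcal/mol; Bp is the number of pairs
in the two crossing stems excluding gap-mediated pairs, and Up the number
of unpaired bases strictly inside the span of the outermost pairs. Bp is
read as a *pair count* rather than a stem count (a stem count would be the
constant 2 for every H-type candidate and discriminate nothing).

`E_stack` sums nearest-neighbor stacking terms over adjacent pairs
(p, q), (p+1, q−1) within each bracket layer. **By default the stacking
table is all-zero**, i.e. ranking uses the penalty alone. The package
bundles the Turner 2004 stacking constants (37 °C, kcal/mol, checksummed
text file `src/hknot/data/stacking_turner2004.tsv`) and any mapping with
the same key convention can be swapped in (`EnergyParams(stack_table=...)`,
CLI `--stacking turner2004`). The penalty-only default is a deliberate
validation-driven choice: on the one sequence for which the full method's
selected structure is known end to end (the 22-nt worked example), the
penalty-only model selects the correct core quadruple (5, 10, 11, 17) at
10.5 vs 10.7 kcal/mol for its closest rival, whereas adding the Turner
term lets a rival quadruple with one strong G·C/C·G stack win. Mixing
stacking constants calibrated within a complete thermodynamic model into a
standalone penalty double-counts helix stability; the penalty's βs were
tuned without such a term. A full loop-entropy/dangling-end engine is out
of scope, so within the winning quadruple the choice among equal-count
bulge variants falls to Up alone — a coarser criterion than a complete
nearest-neighbor model would apply.

## Evaluation

Confusion counts are per position, so tp + tn + fp + fn equals the sequence
length for every comparison. A position paired to the same partner in
prediction and reference is tp; unpaired in both, tn; paired only in the
reference, fn; anything else — paired only in the prediction, or paired to
the wrong partner — is fp. Counting a partner mismatch as a single fp (not
fp + fn) preserves the one-count-per-position invariant. PPV, recall, F1
and MCC follow the standard closed forms; any metric with a zero
denominator is reported as NaN with a warning, never silently as 0. The
MCC implementation is cross-checked in the tests against the Pearson
correlation of the per-position binary indicators. Displayed values are
rounded to 3 decimals (round-half-even); internal values keep full
precision.

Core-stem matching compares the predicted core pairs against the reference
core pairs with a slip tolerance: (k, l) matches (k ± 1, l) or (k, l ± 1)
— one coordinate may move by one position, not both. Each predicted pair
may satisfy at most one reference pair. The core of a stem is its
*innermost* crossing pair (largest 5′ position in each layer), the pair
from which outward extension starts; the same convention is applied to
reference structures and to the synthetic generator's ground truth, so
predicted and true cores are directly comparable.

## Synthetic generator

`generate_pseudoknot` plants a pseudoknot with configurable stem, loop,
head and tail lengths, and optionally one bulge or internal loop
continuation on either side; the default geometry (4 bp stems, loops of 4
and 5, no head/tail — a 25-nt instance) mirrors the compact pseudoknots the
method targets. Planted pairs are drawn uniformly from the Watson–Crick
pair types; all positions are then (re)drawn under rejection sampling until
no run of ≥ 3 stacked complementary pairs exists outside the planted
helices (up to 200 attempts — the stems are redrawn too, because a
competing helix can be created by the stem letters themselves, e.g. the
off-diagonal pairings of a poly-G/poly-C stem). Identical seeds give
identical instances.

What passing the recovery suite shows, and what it does not: on instances
whose only strong helices are the planted stems, the pipeline recovers both
core stems in ≥ 95% of cases (200 seeded instances in the acceptance
suite; observed 200/200). Real sequences have biased composition, competing
near-isoenergetic helices and additional motifs, none of which the
generator emulates, so planted-recovery rates are an upper bound on
real-data core-stem accuracy.

## Numerical and degenerate-input choices

* Positions are 1-based inclusive at every interface; internal 0-based
  indexing never leaks.
* Sequences shorter than 6 nt, or without any complementary crossing
  quadruple, yield an all-unpaired prediction plus a warning rather than an
  error.
* Structure objects validate on construction (bounds, single partner per
  position, within-layer nestedness, cross-layer crossing) and reject
  violations loudly.
* Energies are compared with absolute tolerance 1e-9 before tie-breaks.
* Problem sizes in the shipped tests (sequences ≤ 25 nt, 200 synthetic
  instances, 1000 brute-force enumeration cases ≤ 14 nt) keep the full
  suite around five seconds while exercising every code path; the method
  itself handles a few hundred nucleotides in seconds.

## Known limitations

* One pseudoknot per sequence; no nested helices inside loops.
* The energy model ranks candidates; its absolute values are not folding
  free energies and should not be compared with thermodynamic predictions.
* With `allow_gu`, wobble pairs participate in cores, extensions and gap
  pairs alike; no special terminal-G·U handling exists.
* The evaluation's per-position scheme scores a shifted-by-one helix
  harshly (every position is a partner mismatch) even though core-stem slip
  matching still accepts it; both views are reported so the difference is
  visible.
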