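"""Predict the H-type pseudoknot of a 22-nt sequence and trace the decoration.

The two crossing core pairs seed the structure; each stem then grows with
stacked pairs, and bulge/internal-loop continuations are tried before the
best candidate is chosen by maximum non-gap base pairing, then minimum
penalty energy.
"""

from hknot import CoreStemQuad, RunConfig, Sequence, predict_structure
from hknot.decoration import trace_decoration

seq = Sequence("example", "ACAUCCGCCUGAUUUGAGCACA")
result = predict_structure(seq, RunConfig(maximum_bulge_size=3))

print(f"sequence   {seq.residues}")
print(f"structure  {result.dotbracket()}")
quad = result.candidate.quad
print(f"core stems: left pair {quad.left_pair}, right pair {quad.right_pair}")
print(f"left loop {list(quad.left_loop)[0]}..{list(quad.left_loop)[-1]}, "
      f"right loop {list(quad.right_loop)[0]}..{list(quad.right_loop)[-1]}")
print(f"{result.n_quads} candidate core quadruples, "
      f"{result.n_candidates} decorated candidates considered")
print(f"gap-mediated pairs (bulge/internal loop): {sorted(result.candidate.gap_pairs)}")
print()
print("decoration stages for the selected quadruple:")
for row in trace_decoration(seq, quad, RunConfig().decoration):
    print("  " + row)
# Square brackets mark the left stem, round brackets the right stem; the two
# layers cross, which is what makes the motif a pseudoknot.
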