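# Nearest-neighbor helix stacking free energies, RNA, 37 C (Turner 2004 set).
# Columns: outer pair (5' base, 3' base) <TAB> inner pair (5' base, 3' base) <TAB> dG (kcal/mol)
# A stack is two adjacent base pairs (p,q) and (p+1,q-1); the outer pair reads
# (residue p, residue q), the inner pair (residue p+1, residue q-1).
# Covers all ordered combinations of the six admissible pairs (Watson-Crick + G-U wobble).
CG	GC	-2.40
CG	CG	-3.30
CG	UG	-2.10
CG	GU	-1.40
CG	UA	-2.10
CG	AU	-2.10
GC	GC	-3.30
GC	CG	-3.40
GC	UG	-2.50
GC	GU	-1.50
GC	UA	-2.20
GC	AU	-2.40
GU	GC	-2.10
GU	CG	-2.50
GU	UG	1.30
GU	GU	-0.50
GU	UA	-1.40
GU	AU	-1.30
UG	GC	-1.40
UG	CG	-1.50
UG	UG	-0.50
UG	GU	0.30
UG	UA	-0.60
UG	AU	-1.00
AU	GC	-2.10
AU	CG	-2.20
AU	UG	-1.40
AU	GU	-0.60
AU	UA	-1.10
AU	AU	-0.90
UA	GC	-2.10
UA	CG	-2.40
UA	UG	-1.30
UA	GU	-1.00
UA	UA	-0.90
UA	AU	-1.30
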