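# RNA/RNA nearest-neighbor stacking free energies, dG37 kcal/mol
# top: 5'->3' dinucleotide step on the mRNA strand;
# bottom: paired dinucleotide on the ASD strand, 3'->5', aligned under top
#! init_dg	4.09
#! terminal_au_dg	0.45
#! allow_gu	true
top	bottom	dg37
AA	UU	-0.93
AC	UG	-2.24
AG	UC	-2.08
AG	UU	-0.60
AU	UA	-1.10
AU	UG	-1.40
CA	GU	-2.11
CC	GG	-3.26
CG	GC	-2.36
CG	GU	-1.40
CU	GA	-2.08
CU	GG	-2.10
GA	CU	-2.35
GA	UU	-1.30
GC	CG	-3.42
GC	UG	-2.50
GG	CC	-3.26
GG	CU	-1.50
GG	UC	-2.10
GG	UU	-0.50
GU	CA	-2.24
GU	CG	-2.50
GU	UA	-1.40
GU	UG	1.30
UA	AU	-1.33
UA	GU	-1.00
UC	AG	-2.35
UC	GG	-1.50
UG	AC	-2.11
UG	AU	-1.00
UG	GC	-1.40
UG	GU	0.30
UU	AA	-0.93
UU	AG	-1.30
UU	GA	-0.60
UU	GG	-0.50
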