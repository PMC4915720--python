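# ar/R selectivity filter and Froger-position grouping rules per subfamily.
# columns: kind (arR|fp)  subfamily  label  pattern  [provisional]
# Rule order defines precedence: the first matching rule wins.
#
# ar/R rules -----------------------------------------------------------------
# PIPs carry one invariant filter (F, H, T, R); no groups are defined.
arR	PIP	conserved	FHTR
# TIP group I is H-I-A-V (TIP1s); Y may substitute the H2 histidine.
arR	TIP	I	(H/Y)IAV
arR	TIP	IIA	HIGR
arR	TIP	IIB	H(V/I/M)AR
arR	TIP	IIC	(Q/H/N)(S/V/T)AR
arR	NIP	I	W(V/A)AR
arR	NIP	II	A(A/I)(A/P/G)R
arR	NIP	III	GSGR
arR	NIP	IV	(C/V)GGR
arR	SIP	I	(L/V)(V/I)PN
arR	SIP	II	SHGS
#
# FP rules -------------------------------------------------------------------
# PIP P2-P5 are invariant S,A,F,W; group I keeps Gln at P1, group II
# substitutes it.  (Fig 3 also marks IA/IB subgroups, undefined by residue.)
fp	PIP	I	QSAFW	provisional
fp	PIP	II	(H/V/T/M/N/E)SAFW	provisional
fp	TIP	I	T(S/V/A)AYW
fp	TIP	II	S(S/A)AYW
# NIP FP groups track the NIP1/NIP2/NIP3 subgroups; P3-P4 are always A,Y.
fp	NIP	I	FSAY(L/I)	provisional
fp	NIP	II	(L/I)TAYF	provisional
fp	NIP	III	(F/I/L/M/V)TAY(F/L)	provisional
# (no residue definition exists for the NIP group IV FPs; such FPs are
# reported "unassigned")
fp	SIP	I	MAAYW
fp	SIP	II	(F/L)AAYW
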