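# Substrate-specific signature sequences / specificity-determining positions
# for MIPs transporting non-aqua substrates, one row per (substrate, subfamily).
# columns: substrate  subfamily  diameter_A  mode  arR  npa_lb  npa_le  fp
# mode "fp_derived" marks the SIP rows, which were inferred from Froger
# positions only (no experimentally characterized SIP transporter exists).
# Transcription notes:
#   - stray whitespace and trailing empty alternatives in the printed loop-B
#     patterns were stripped;
#   - the urea/SIP ar/R "(NF/I)" is normalized to "(N/F/I)" (typographic slash
#     omission);
#   - the urea/SIP loop-E pattern is printed one element short (10 of 11); a
#     trailing wildcard is appended, keeping the N-P-x core at window
#     position 5 like every other loop-E row.
ammonia	TIP	3.26	standard	HI(G/A)R	SGGH(V/L)NPAVT	G(G/A)SMNPARSFG	TSAYW
ammonia	NIP	3.26	standard	WVAR	SGGH(L/F)NPAVT	G(G/A)SMNPARSLG	FSAYL
antimonite	NIP	3.70	standard	(G/A/T)(S/I/V/A)(G/A)R	SG(A/C)H(L/M)NP(S/A)(V/I/T)(T/S)	(G/S)(G/A)SMNP(V/A)R(T/S)L(G/A)	(L/F/Y/I)(T/S)AY(L/M/F)
arsenic	NIP	4.00	standard	(G/W/A)(V/S/I)(G/A)(R/V)	SGAH(L/M/I/V)NP(A/S)(V/I)T	(G/S)(A/G)SMNP(A/V)R(T/S)(L/I)G	(L/F/Y)(T/S)AY(F/L/M)
arsenic	SIP	4.00	fp_derived	SHGS	GGASYNPLT(I/V)	GG(I/V)MNPASAFA	(F/L)AAYW
boron	NIP	2.57	standard	(A/G)(I/S)GR	SGAH(M/L/I)NP(A/S)(V/L)T	(G/S)(G/A)SMNP(A/V)R(S/T)LG	(F/I)TAY(F/L)
co2	PIP	3.00	standard	FHTR	SGGHINPAVT	GTGINPARSLG	(Q/M)SAFW
h2o2	PIP	3.20	standard	FHTR	SGGH(I/L/V)NPAVT	GT(G/S)INPARS(L/F)G	(Q/F)SAFW
h2o2	TIP	3.20	standard	HI(A/G)(R/V)	SGGH(V/L/I)NPAVT	G(A/G)SMNPA(R/V)SFG	TSAYW
h2o2	NIP	3.20	standard	WVAR	SGAH(F/L/I/V)NPAVT	G(A/G)SMNPARSLG	FSAY(I/L)
h2o2	SIP	3.20	fp_derived	SHGS	GGASYNPLT(I/V)	GG(I/V)MNPASAFA	(F/L)AAYW
silicon	NIP	4.38	standard	GSGR	SGAHMNPA(V/L)T	GGSMNPARTL(G/A)	(L/I)TAYF
urea	TIP	2.62	standard	(H/G/N)(I/V)(A/G)(R/V/C)	SGGH(V/I/L/M)NPAVT	G(A/G)SMNPA(R/V/C)SFG	T(S/A)AYW
urea	NIP	2.62	standard	(G/A)(S/I)AR	SGAH(M/V/I/L)NPAVT	(G/S)(A/G)SMNP(A/V)R(T/S)LG	(L/F/M/V/I)TAY(F/L)
urea	SIP	2.62	fp_derived	(L/V/I/A)(V/I/F/M/T)P(N/F/I)	G(G/S)(V/A)(S/T)(F/W)NP(S/C/T/A)(T/A/G/D)(S/T/N/L/V/I/F)	(G/R)P(S/A)MNPA(N/F/I)A(F/Y)X	(M/I)AAYW
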