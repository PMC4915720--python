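# synthetic reference template: a constructed scaffold standing in for the
# structure-derived reference (no published coordinate map exists); the
# planted constriction elements are the authentic subfamily-canonical ones.
# All positions are 1-based inclusive.
id: NIP2
subfamily: NIP
subgroup: NIP2
h2: 58
lb_start: 67
h5: 162
le_start: 168
le1: 169
le2: 175
p1: 181
p2: 209
p3: 212
p4: 215
p5: 218
sequence: SQFDIRRKPSAMRSFMLILLIFFVVAVMILFIAMLEKRSTSIGQMALLVAMVAVALIGLIILMKHISGAHMNPAVTAQYFIILIIMFLMFIVLIFLMLSRGGIRMKKPQNYVLGKAMFVMAIMVLFILLFIMAAVKGHGTHHGSPLFIIVILILMIAVMLLSVMSLCGGSMNPARTLGGTLNNSLAMAFAFAAIVIIILFLIMILYYQTDEAKKYTDFSVQISSAETGLDAAGSP
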