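# NIPs and SIPs with unusual NPA motifs and their characteristic C-termini,
# transcribed from the published survey (leading dashes on termini stripped).
# columns: mip  subfamily  lb_triplet  le_triplet  c_terminus  npa_class  arg_rich  lys_rich
PvNIP3;9	NIP	NPS	NPV	GETPRTQRSFRR	both	true	false
PvNIP3;10	NIP	NPS	NPV	GETPRAQRSFRR	both	true	false
PvNIP4;1	NIP	NPA	NPI	PHAIGAVASQQF	LE-variant	false	false
SiNIP3;5	NIP	NPS	NPV	GETPRTQRSFRR	both	true	false
SbNIP3;4	NIP	NPS	NPV	GEAPRPQRSFRR	both	true	false
SbNIP4;1	NIP	NPA	NPI	RAVGSLASSPHY	LE-variant	false	false
BdNIP3;1	NIP	NPS	NPV	GEAPRPQRSFRR	both	true	false
BdNIP4;1	NIP	NPA	NPV	GRGGAAARSGSN	LE-variant	false	false
OsNIP3;1	NIP	NPS	NPV	GETPRPQRSFRR	both	true	false
AtNIP5;1	NIP	NPS	NPV	TDPPRPVRSFRR	both	true	false
AtNIP7;1	NIP	NPL	NPA	SPVSPSVSSLLR	LB-variant	false	false
PvSIP1;1	SIP	NPT	NPA	LAPPPKPKAKKA	LB-variant	false	true
PvSIP2;1	SIP	NPL	NPA	TFLTKPKKIKEQ	LB-variant	false	true
SiSIP2;1	SIP	NPL	NPA	EQEADENKTKKE	LB-variant	false	true
BdSIP1;1	SIP	NPT	NPA	PPPAPKPKAKKA	LB-variant	false	true
GmSIP1;5	SIP	NPS	NPA	SMFMPPIKQKKA	LB-variant	false	true
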