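# Methods

## The prediction model

`mipscan` treats substrate selectivity of a plant MIP as a deterministic
function of three sequence constrictions: the loop-B NPA region (a 10-residue
window, consensus `SGXHXNPAVT`), the loop-E NPA region (11 residues,
consensus `GXXXNPAR(S/D)XG`), the ar/R selectivity filter (residues from H2,
H5, LE1, LE2) and the five Froger positions P1–P5.  The bundled signature
table lists, per (substrate, subfamily) pair, one PROSITE-like pattern for
each constriction plus the substrate's molecular diameter.  The decision rule
is **conjunctive**: a substrate is predicted only when the ar/R, loop-B,
loop-E and FP patterns of a row for the gene's own subfamily all match
anchored; a missing profile field makes the row not evaluable and the
prediction fails closed.  Channels are categorized by predicted-substrate
count: 0 none, 1 single, 2 dual, ≥ 3 multichannel.

Within the loop-E window the tetrad's LE1 and LE2 residues sit at window
positions 2 and 8; the N-P-x core sits at window position 6 in loop B and 5
in loop E.  These offsets are fixed by the consensus patterns and are
asserted throughout (signature rows, templates, generator).

### Pattern semantics

Two notations are parsed with one semantics: compact
(`SG(A/C)H(L/M)NP(S/A)(V/I/T)(T/S)`) and dashed (`R-x-x-R-S-F-R-R`,
slashes binding tighter than dashes).  Elements are fixed residues,
alternative sets, or wildcards (`x`, `X`; in dashed motifs the lowercase
placeholders `y`, `z` are read as further wildcards — in `G-L-x-y-G-G` the
`y` is a position placeholder, not tyrosine).  Matching is anchored and
case-insensitive.  The unknown residue `X` in a sequence is admitted only by
wildcards, so unresolved positions can never satisfy a fixed constraint
(fail-closed again).  Repetition counts and terminal anchors of the full
PROSITE grammar are deliberately unsupported; no signature uses them.

Two transcription normalizations in the bundled table are flagged in the
file itself: the urea/SIP ar/R `(NF/I)` is read as `(N/F/I)`, and the
urea/SIP loop-E pattern, printed one element short, carries a trailing
wildcard so that every loop-E row has 11 elements with the core at
position 5.

### Constriction extraction

The query is aligned globally (Needleman–Wunsch with BLOSUM62, gap open 10,
extend 1, via Biopython's `PairwiseAligner`) against each bundled reference
template; the best score wins, ties breaking on identity and then declared
template order.  Annotated template positions are mapped through the
alignment.  A window whose mapped core is not N-P-x is rescued by the nearest
N-P-x seed within 15 residues ("motif-seeded" provenance); otherwise it is
missing.  The ar/R tetrad and FPs come purely from the alignment mapping — if
any of their positions maps to a gap the whole field is missing.  The
C-terminus is simply the last 12 residues.  The original analysis used
structure-guided alignment against the spinach PIP SoPIP2;1 crystal
structure; sequence-only global alignment is this package's surrogate, and
the template coordinate map is rebuilt once (see below) rather than taken
from a published table, which does not exist.

Full-length validation: sequence length within 200–420 residues, both NPA
windows present, and template coverage ≥ 0.7.  All three bounds are
configurable; failures are enumerated per gene, emulating the manual
pseudo-gene triage of genome surveys.

### Reference templates (synthetic scaffolds)

Six templates are bundled (PIP, TIP, NIP1-like, NIP2-like, SIP1, SIP2).  No
coordinate map for the original structure-based references is published, so
each template is a **synthetic scaffold** — clearly labelled as such in its
file header — built from the canonical MIP architecture: six hydrophobic TM
helices of 19 residues (A/I/L/V/F/M) joined by loops, 235 residues total,
with the authentic subfamily-canonical constriction elements planted at fixed
annotated positions (ar/R `FHTR`+FP `QSAFW` for PIP, `HIGR`/`TSAYW` for TIP,
`WVAR`/`FSAYL` and `GSGR`/`LTAYF` for the two NIP subgroups, `LVPN`/`MAAYW`
and `SHGS`/`FAAYW` for the SIPs, with their NPT/NPL loop-B variants and
Lys-rich termini).  Templates double as the labeled panel for subfamily
assignment (highest global-alignment identity; identities below 0.4 are
flagged low-confidence) — the cheap surrogate for tree-based placement, which
remains available through the phylogeny module.

### Grouping rules

ar/R and FP group labels are data, not code: an ordered rules file maps
(subfamily, tetrad/FP pattern) to a label, first match winning.  The PIP FP
groups I/II (Gln vs H/V/T/M/N/E at P1), the TIP ar/R groups I/IIA/IIB/IIC and
FP groups I/II, the NIP ar/R groups I–IV and the SIP groups I/II follow the
published scheme.  Entries whose residue sets are not fully printed anywhere
(PIP FP subgroups IA/IB, the NIP FP group rules, NIP group IV FPs) are marked
`provisional` in the file; unmatched strings report `unassigned` rather than
guessing.

### SIP rows and optional gates

No SIP has been experimentally shown to transport a non-aqua substrate; the
SIP rows of the signature table were derived from Froger positions of
experimentally characterized PIPs/TIPs/NIPs.  `sip_mode="table"` (default,
conservative) applies them as ordinary conjunctive rows; `sip_mode="fp_only"`
additionally calls urea/arsenic/H₂O₂ for a SIP whose FP string alone matches,
reproducing the FP-only reading under which nearly all SIP1s are urea
transporters.  `strict_co2` optionally requires PIP FP group I membership for
a CO₂ call; it is off by default because the CO₂ FP pattern already
constrains P1 to Q/M.  Arsenic rows exist only for NIPs (and SIPs), never
PIPs.

### Ancillary motif flags

Unusual NPA triplets (≠ NPA), the Arg-rich C-terminus (`R-x-x-R-S-F-R-R`
within the 12-mer), a Lys-rich C-terminus (≥ 3 K in the 12-mer — a heuristic;
no published threshold exists), the ammonia-associated loop motifs
(`G-L-x-y-G-G` and `P-x-H`), the metalloid loop-B motif (`F/L-x-H-F-P`) and
the boron loop-C motif (`SGGVTVP`) are reported as boolean annotations only;
they never gate predictions.  Loop-region motifs are searched within the
template-mapped interval from the loop-B window to the H5 residue (an
approximation of loops B–C; the exact loop boundaries are not printed
anywhere), falling back to the whole sequence when the interval is
unavailable.

## Phylogeny

p-distances are computed from pairwise global alignments with pairwise
deletion (gap columns excluded per pair; whether the original analysis used
complete or pairwise deletion is unstated — pairwise was chosen and is noted
here).  Trees are built with the Saitou–Nei Neighbor-Joining agglomeration,
re-implemented: ties on the Q criterion break on the lexicographically
smallest taxon pair, and negative branch lengths are clamped to zero with the
remainder shifted to the sister edge (the common MEGA-compatible convention).
Column-resampling bootstrap support is available when an alignment is
supplied; it is never run by default.  Tests cross-check topologies against
scikit-bio's independent NJ implementation and against 100 random additive
matrices, which NJ must recover exactly.

## Pore profiles and the size heuristic

Sparse (position, diameter) tables are completed on the integer grid spanning
their range by linear interpolation; observed points pass through
bit-for-bit, and no extrapolation occurs.  Linear interpolation was chosen
because the original R-script's method is unspecified; it is exact on affine
data, monotone between knots and parameter-free.  The feasibility check at
the ar/R filter (pore diameter ≥ substrate diameter, boundary feasible) is
labelled a *necessary-size heuristic* and is never merged into the
signature-based predictions — pore diameter alone does not determine
selectivity.

## Expression

FPKM < 1 is treated as no expression; exactly 1 is expressed.  A gene counts
as expressed in an organ if any condition column of that organ reaches the
threshold (the aggregation rule over "diverse conditions" is not stated in
the source data description; *any* was adopted and documented).  Per-plant
summaries report the percentage of genes expressed in ≥ 1 organ and in all
organs (always ≥-ordered), rounded to integers by default to match the
reporting style of genome surveys, with a raw mode available.

## Synthetic data: what it does and does not show

The generator plants exact constriction elements on subfamily scaffolds and
then mutates only the unprotected background (default 5 % substitutions, no
indels, optional N-terminal length jitter; a `corrupt_constrictions` flag
lifts the protection for fail-closed tests).  Decoys emulate pseudo genes by
ablating one NPA window (with nearby Asn removed so motif rescue cannot
re-find it) or truncating the sequence.  Ground truth includes the substrate
set obtained by applying the signature table directly to the planted profile,
so generator and classifier cannot drift apart.

Passing the closed-loop tests therefore shows that extraction, grouping and
classification are internally correct and robust to background divergence and
window drift.  It does **not** show that the signature table generalizes to
real proteomes: real MIPs diverge inside the constrictions, have variable
loop lengths and helix boundaries, and include lineage-specific subfamilies
(XIP/HIP/GIP) with no templates here.  Reproducing the published census
(68/42/38/28 full-length MIPs) requires the original accession sequences,
which must be fetched (`scripts/fetch_accessions.py`); likewise the published
expression percentages depend on the original FPKM extracts and are validated
only when those are supplied.

## Problem sizes and defaults

| parameter | default | why |
| --- | --- | --- |
| gap open / extend | 10 / 1 (BLOSUM62) | standard protein global-alignment scoring |
| window rescue radius | 15 residues | covers loop-length drift without jumping loops |
| full-length bounds | 200–420 aa, coverage ≥ 0.7 | brackets known plant MIPs (≈ 230–380 aa) with margin |
| subfamily confidence | identity ≥ 0.4 | below this, panel assignment is reported but flagged |
| Lys-rich threshold | ≥ 3 K / 12 aa | heuristic, documented above |
| generator corpus | 40 seqs (12/12/10/6 per subfamily), 5 % subs | small enough for seconds-scale tests, large enough to hit every profile class |
| acceptance corpus | 150 seqs, 20 % decoys; 100 NJ matrices | keeps the full from-scratch recomputation in the minutes range |

## Known limitations

* Sequence-only alignment replaces structure-guided alignment; on real,
  deeply diverged MIPs the template mapping (especially the FPs, which have
  no motif rescue) is the accuracy bottleneck.
* Group rules marked provisional encode the printed text only; figure-level
  subgroupings (PIP FP IA/IB, NIP FP IV) cannot be reproduced from it.
* The necessary-size pore check is deliberately decoupled from prediction.
* No XIP/HIP/GIP support; unknown subfamilies are assigned to the nearest of
  PIP/TIP/NIP/SIP with a low-confidence flag.
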