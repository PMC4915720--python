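# mipscan

Rule-based prediction of **non-aqua substrate transport** for plant major
intrinsic proteins (MIPs, the aquaporin superfamily), from protein sequence
alone.

Plant MIPs — the PIP, TIP, NIP and SIP subfamilies — conduct not only water
but also ammonia, boron, CO₂, H₂O₂, silicon, urea and the toxic metalloids
arsenite and antimonite.  Which solutes a given channel admits is encoded in
three sequence constrictions:

* the two **NPA regions** — a 10-residue loop-B window with consensus
  `SGXHXNPAVT` and an 11-residue loop-E window with consensus
  `GXXXNPAR(S/D)XG`, each carrying an Asn-Pro-Ala core (variants NPS, NPT,
  NPV, ... are "unusual NPA motifs");
* the **ar/R selectivity filter** — four residues, one each from helices H2
  and H5 and two from loop E (LE1, LE2), at the extracellular pore mouth;
* the five **Froger positions** (P1–P5).

`mipscan` extracts these constrictions from a raw sequence by global
alignment (Needleman–Wunsch, BLOSUM62, affine gaps) against annotated
reference templates, with an N-P-x motif-seeded rescue for drifted windows.
It then matches them against a bundled table of substrate-specific signature
patterns (PROSITE-like notation, e.g. ar/R `(A/G)(I/S)GR` for boron/NIP) and
predicts a substrate **only when all four constriction patterns of a
subfamily-matched row agree** (missing fields fail closed).  A channel is
reported as *single*, *dual* or *multichannel* (≥ 3 substrates).  The package
also assigns subfamily and ar/R / FP group labels, flags unusual NPA motifs
and the Arg-rich (`R-x-x-R-S-F-R-R`) and Lys-rich C-termini, builds
Neighbor-Joining trees from p-distances, interpolates sparse pore-diameter
profiles, and applies the FPKM ≥ 1 expression threshold to transcript tables.

A fully specified synthetic-data generator produces MIP-like sequences
(six hydrophobic TM segments, planted constrictions, pseudo-gene decoys) with
known ground truth, so the entire pipeline is testable offline.

## Worked example

Classify a silicon-transporter-like NIP profile directly from the library:

```python
from mipscan import predict_substrates, load_bundled_signature_table
from mipscan.extract import ConstrictionProfile

table = load_bundled_signature_table()
profile = ConstrictionProfile(
    "OsNIP2;1-like",
    arR="GSGR", fps="LTAYF",
    npa_lb_window="SGAHMNPAVT", npa_le_window="GGSMNPARTLG",
)
pred = predict_substrates(profile, "NIP", table)
print(sorted(pred.substrates), pred.category)
```

prints

```
['antimonite', 'arsenic', 'silicon'] multichannel
```

— the `GSGR` filter plus `LTAYF` Froger string satisfies the silicon, arsenic
and antimonite NIP rows conjunctively, so this channel is called a
multichannel metalloid transporter.

Or from the shell, on a generated corpus:

```sh
mipscan simulate --seed 11 --out demo --decoy-fraction 0.2
mipscan scan demo/synthetic.fasta --out demo_out
```

```json
{
  "by_category": {"dual": 10, "multichannel": 10, "none": 6, "single": 6},
  "by_subfamily": {"NIP": 8, "PIP": 10, "SIP": 5, "TIP": 9},
  "by_substrate": {"ammonia": 6, "antimonite": 6, "arsenic": 7, "boron": 3,
                   "co2": 4, "h2o2": 14, "silicon": 3, "urea": 13},
  "n_full_length": 32, "n_input": 40, "n_pseudo_or_fragment": 8
}
```

Eight of the forty inputs are decoys (an NPA window ablated or the sequence
truncated) and are correctly set aside as pseudo/fragment; the remaining 32
are classified.  `demo_out/results.tsv` holds one row per gene
(constrictions, groups, substrates, motif flags) and `demo_out/traces.json`
records, per gene and substrate, which constriction matched or failed:

```
gene_id        subfamily  verdict          arR   fps    substrates                  channel_category
SYN_NIP_0001   NIP        pseudo/fragment  WVAR  FSAYL  -                           NA
SYN_NIP_0002   NIP        full-length      GSGR  LTAYF  antimonite,arsenic,silicon  multichannel
```

Other subcommands: `mipscan tree` (NJ/p-distance, Newick out), `mipscan pore`
(pore-diameter interpolation and the necessary-size check), `mipscan
expression` (FPKM thresholding and per-plant summaries), `mipscan validate`
(full-length verdicts only).

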