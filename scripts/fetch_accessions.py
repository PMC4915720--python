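#!/usr/bin/env python
"""Fetch the published benchmark protein sequences by NCBI accession.

The census benchmark (68 + 42 + 38 + 28 full-length MIPs in switchgrass,
foxtail millet, sorghum and Brachypodium) refers to sequences identified by
Phytozome/NCBI accessions.  This helper retrieves the NCBI protein accessions
(XP_*/NP_* style) via Entrez efetch and writes them to
``data/fetched/grass_mips.fasta`` with two-letter species-prefixed gene names
(Pv/Si/Sb/Bd) as record ids, the layout the census acceptance check expects.

Network access is required; the core library never downloads anything.

Usage:
    python scripts/fetch_accessions.py --accessions accessions.tsv

where accessions.tsv has two tab-separated columns: gene name (e.g.
``SbPIP1;1``) and NCBI protein accession (e.g. ``XP_002446929``).  Phytozome
accessions (e.g. ``Pavir.Gb01084.2``) must be exported manually from a
Phytozome session, as Phytozome offers no unauthenticated API.
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
OUT = Path(__file__).resolve().parent.parent / "data" / "fetched" / "grass_mips.fasta"


def fetch_protein(accession: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "protein", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as fh:
        return fh.read().decode()


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--accessions", type=Path, required=True,
                        help="TSV: gene name <tab> NCBI protein accession")
    parser.add_argument("--out", type=Path, default=OUT)
    args = parser.parse_args()

    pairs = []
    for line in args.accessions.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        name, accession = line.split("\t")[:2]
        pairs.append((name.strip(), accession.strip()))

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as out:
        for name, accession in pairs:
            try:
                fasta = fetch_protein(accession)
            except OSError as exc:
                print(f"FAILED {name} ({accession}): {exc}", file=sys.stderr)
                continue
            body = "".join(fasta.splitlines(keepends=True)[1:])
            out.write(f">{name} {accession}\n{body}")
            time.sleep(0.4)  # NCBI rate limit
            print(f"fetched {name}", file=sys.stderr)
    print(f"wrote {args.out}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
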