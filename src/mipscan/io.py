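"""Readers and writers for every external representation the pipeline touches.

FASTA in, TSV/JSON results out, Newick trees, plus the two bundled plain-text
data formats: the substrate signature table and the annotated reference
templates.  All annotation coordinates are 1-based inclusive on disk and are
converted to 0-based offsets exactly once, here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .patterns import AMINO_ACIDS, SEQUENCE_ALPHABET, SignaturePattern, parse_pattern
from .phylo import Clade, tree_to_newick

SUBSTRATES = (
    "ammonia",
    "antimonite",
    "arsenic",
    "boron",
    "co2",
    "h2o2",
    "silicon",
    "urea",
)
SUBFAMILIES = ("PIP", "TIP", "NIP", "SIP")

#: element counts per constriction: loop-B window, loop-E window, ar/R, FPs
CONSTRICTION_LENGTHS = {"npa_lb": 10, "npa_le": 11, "arR": 4, "fp": 5}


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: accession/gene id, free-text description, residues."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - set(SEQUENCE_ALPHABET)
        if bad:
            raise ValueError(f"{self.id}: illegal residue letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path, *, strict: bool = False) -> list[SequenceRecord]:
    """Read a protein FASTA file.

    Residues are uppercased.  Non-standard letters are mapped to ``X`` in the
    default lenient mode and rejected in strict mode.  Duplicate ids and empty
    files are always errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if strict:
            bad = set(residues) - set(SEQUENCE_ALPHABET)
            if bad:
                raise ValueError(f"{rec.id}: illegal residue letters {sorted(bad)}")
        else:
            residues = "".join(
                ch if ch in SEQUENCE_ALPHABET else "X" for ch in residues
            )
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        description = rec.description[len(rec.id) :].strip()
        records.append(SequenceRecord(rec.id, description, residues))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# substrate signature table


@dataclass(frozen=True)
class SignatureRow:
    """One (substrate, subfamily) row: four constriction patterns + diameter."""

    substrate: str
    subfamily: str
    diameter: float  # substrate diameter, angstrom
    mode: str  # "standard" | "fp_derived" (the starred SIP rows)
    arR: SignaturePattern
    npa_lb: SignaturePattern
    npa_le: SignaturePattern
    fp: SignaturePattern

    def patterns(self) -> dict[str, SignaturePattern]:
        return {
            "arR": self.arR,
            "npa_lb": self.npa_lb,
            "npa_le": self.npa_le,
            "fp": self.fp,
        }


class SubstrateSignatureTable:
    """The substrate-specificity rule table in machine-readable form."""

    def __init__(self, rows: list[SignatureRow]):
        if not rows:
            raise ValueError("empty signature table")
        self.rows = rows

    @property
    def substrates(self) -> set[str]:
        return {r.substrate for r in self.rows}

    def rows_for(self, subfamily: str) -> list[SignatureRow]:
        return [r for r in self.rows if r.subfamily == subfamily]

    def diameter_of(self, substrate: str) -> float:
        for r in self.rows:
            if r.substrate == substrate:
                return r.diameter
        raise KeyError(f"unknown substrate {substrate!r}")


def read_signature_table(path) -> SubstrateSignatureTable:
    """Parse a tab-separated signature table.

    Columns: substrate, subfamily, diameter_A, mode, arR, npa_lb, npa_le, fp.
    ``#`` starts a comment.  Pattern element counts are enforced per
    constriction (ar/R 4, loop-B 10, loop-E 11, FPs 5).
    """
    rows: list[SignatureRow] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
        substrate, subfamily, diameter_s, mode, arr_s, lb_s, le_s, fp_s = fields
        if substrate not in SUBSTRATES:
            raise ValueError(f"{path}:{lineno}: unknown substrate {substrate!r}")
        if subfamily not in SUBFAMILIES:
            raise ValueError(f"{path}:{lineno}: unknown subfamily {subfamily!r}")
        if mode not in ("standard", "fp_derived"):
            raise ValueError(f"{path}:{lineno}: unknown mode {mode!r}")
        diameter = float(diameter_s)
        if diameter <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive diameter")
        patterns = {}
        for key, text in (("arR", arr_s), ("npa_lb", lb_s), ("npa_le", le_s), ("fp", fp_s)):
            pat = parse_pattern(text)
            want = CONSTRICTION_LENGTHS[key]
            if len(pat) != want:
                raise ValueError(
                    f"{path}:{lineno}: {key} pattern has {len(pat)} elements, expected {want}"
                )
            patterns[key] = pat
        rows.append(SignatureRow(substrate, subfamily, diameter, mode, **patterns))
    return SubstrateSignatureTable(rows)


# ---------------------------------------------------------------------------
# reference templates

_TEMPLATE_POSITION_KEYS = (
    "lb_start",
    "le_start",
    "h2",
    "h5",
    "le1",
    "le2",
    "p1",
    "p2",
    "p3",
    "p4",
    "p5",
)


@dataclass(frozen=True)
class ReferenceTemplate:
    """An annotated reference sequence carrying 1-based constriction positions."""

    id: str
    subfamily: str
    subgroup: str
    sequence: str
    positions: dict[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for key in _TEMPLATE_POSITION_KEYS:
            if key not in self.positions:
                raise ValueError(f"template {self.id}: missing position {key!r}")
            pos = self.positions[key]
            if not 1 <= pos <= n:
                raise ValueError(f"template {self.id}: {key}={pos} out of bounds (1..{n})")
        if self.positions["lb_start"] + 9 > n:
            raise ValueError(f"template {self.id}: loop-B window exceeds sequence")
        if self.positions["le_start"] + 10 > n:
            raise ValueError(f"template {self.id}: loop-E window exceeds sequence")
        order = [self.positions[k] for k in ("h2", "h5", "le1", "le2")]
        if not (order[0] < order[1] < order[2] < order[3]):
            raise ValueError(f"template {self.id}: require h2 < h5 < le1 < le2")

    # --- convenience views over the annotated elements --------------------
    def lb_window(self) -> str:
        s = self.positions["lb_start"] - 1
        return self.sequence[s : s + 10]

    def le_window(self) -> str:
        s = self.positions["le_start"] - 1
        return self.sequence[s : s + 11]

    def arR(self) -> str:
        return "".join(
            self.sequence[self.positions[k] - 1] for k in ("h2", "h5", "le1", "le2")
        )

    def fps(self) -> str:
        return "".join(
            self.sequence[self.positions[k] - 1] for k in ("p1", "p2", "p3", "p4", "p5")
        )


def read_template_annotations(path) -> ReferenceTemplate:
    """Parse a key/value template annotation file (1-based positions)."""
    meta: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value'")
        key, value = line.split(":", 1)
        meta[key.strip()] = value.strip()
    try:
        positions = {k: int(meta[k]) for k in _TEMPLATE_POSITION_KEYS}
        return ReferenceTemplate(
            id=meta["id"],
            subfamily=meta["subfamily"],
            subgroup=meta.get("subgroup", meta["subfamily"]),
            sequence=meta["sequence"].upper(),
            positions=positions,
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing annotation key {exc}") from exc


# ---------------------------------------------------------------------------
# bundled package data

_DATA = resources.files(__package__) / "data"

TEMPLATE_IDS = ("PIP", "TIP", "NIP1", "NIP2", "SIP1", "SIP2")


def load_bundled_signature_table() -> SubstrateSignatureTable:
    with resources.as_file(_DATA / "signature_table.tsv") as p:
        return read_signature_table(p)


def load_bundled_templates() -> list[ReferenceTemplate]:
    templates = []
    for tid in TEMPLATE_IDS:
        with resources.as_file(_DATA / "templates" / f"{tid}.txt") as p:
            templates.append(read_template_annotations(p))
    return templates


def bundled_rules_path() -> Path:
    with resources.as_file(_DATA / "group_rules.tsv") as p:
        return Path(p)


# ---------------------------------------------------------------------------
# results table


@dataclass
class ResultsRow:
    """One annotated gene for the report; missing values are None."""

    gene_id: str
    subfamily: str | None = None
    subfamily_identity: float | None = None
    verdict: str | None = None  # "full-length" | "pseudo/fragment"
    arR: str | None = None
    fps: str | None = None
    npa_lb_window: str | None = None
    npa_le_window: str | None = None
    npa_lb_triplet: str | None = None
    npa_le_triplet: str | None = None
    c_terminus: str | None = None
    arR_group: str | None = None
    fp_group: str | None = None
    npa_class: str | None = None
    substrates: tuple = ()
    channel_category: str | None = None
    flags: tuple = ()  # names of raised ancillary motif flags
    reasons: tuple = ()  # full-length validation failures

    def __post_init__(self) -> None:
        bad = set(self.substrates) - set(SUBSTRATES)
        if bad:
            raise ValueError(f"{self.gene_id}: unknown substrates {sorted(bad)}")


RESULTS_COLUMNS = [
    "gene_id",
    "subfamily",
    "subfamily_identity",
    "verdict",
    "arR",
    "fps",
    "npa_lb_window",
    "npa_le_window",
    "npa_lb_triplet",
    "npa_le_triplet",
    "c_terminus",
    "arR_group",
    "fp_group",
    "npa_class",
    "substrates",
    "channel_category",
    "flags",
    "reasons",
]


def _cell(row: ResultsRow, col: str) -> str:
    value = getattr(row, col)
    if col == "substrates":
        return ",".join(sorted(value)) if value else "-"
    if col in ("flags", "reasons"):
        return ";".join(value) if value else "-"
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def write_results_table(rows, path) -> None:
    """Tab-separated report: fixed column order, NA for missing values."""
    lines = ["\t".join(RESULTS_COLUMNS)]
    for row in rows:
        lines.append("\t".join(_cell(row, c) for c in RESULTS_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results_table(path) -> list[ResultsRow]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header != RESULTS_COLUMNS:
        raise ValueError(f"{path}: unexpected results header")
    rows = []
    for line in lines[1:]:
        cells = dict(zip(RESULTS_COLUMNS, line.split("\t")))
        kwargs = {}
        for col, raw in cells.items():
            if col == "substrates":
                kwargs[col] = tuple(sorted(raw.split(","))) if raw != "-" else ()
            elif col in ("flags", "reasons"):
                kwargs[col] = tuple(raw.split(";")) if raw != "-" else ()
            elif raw == "NA":
                kwargs[col] = None
            elif col == "subfamily_identity":
                kwargs[col] = float(raw)
            else:
                kwargs[col] = raw
        rows.append(ResultsRow(**kwargs))
    return rows


def write_results_json(rows, path) -> None:
    payload = []
    for row in rows:
        d = asdict(row)
        d["substrates"] = sorted(row.substrates)
        d["flags"] = list(row.flags)
        d["reasons"] = list(row.reasons)
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_newick(tree: Clade, path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")
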