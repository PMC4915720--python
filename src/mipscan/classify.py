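"""Conjunctive substrate prediction from constriction profiles.

A substrate is predicted for a gene only when *all four* constriction patterns
of an applicable (substrate, subfamily) signature row match the extracted
profile: the ar/R tetrad, the loop-B 10-mer, the loop-E 11-mer and the five
Froger positions.  A missing profile field makes the row "not evaluable" and
the prediction fails closed.  Rows are applied subfamily-restricted: a NIP row
is never tested against a PIP, so e.g. silicon can only ever be predicted for
NIPs and CO2 only for PIPs.

The SIP rows of the signature table were derived from Froger positions alone
(no experimentally characterized SIP transporter exists); ``sip_mode``
controls whether they are applied as ordinary conjunctive rows ("table",
default) or whether, additionally, a SIP is predicted from its FP pattern
alone ("fp_only").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .extract import ConstrictionProfile
from .io import SUBFAMILIES, SignatureRow, SubstrateSignatureTable
from .patterns import match_anchored, parse_pattern

CATEGORIES = ("none", "single", "dual", "multichannel")

_CONSTRICTION_FIELDS = {
    "arR": "arR",
    "npa_lb": "npa_lb_window",
    "npa_le": "npa_le_window",
    "fp": "fps",
}


@dataclass
class RowOutcome:
    """Per-constriction outcomes for one signature row vs one profile."""

    substrate: str
    subfamily: str
    outcomes: dict  # constriction -> "match" | "mismatch" | "not evaluable"
    overall: bool
    via: str = "table"  # "table" | "fp_only"


def evaluate_signature_row(row: SignatureRow, profile: ConstrictionProfile) -> RowOutcome:
    """Conjunctive evaluation; any missing field fails closed."""
    outcomes = {}
    for key, attr in _CONSTRICTION_FIELDS.items():
        value = getattr(profile, attr)
        if value is None:
            outcomes[key] = "not evaluable"
        elif match_anchored(row.patterns()[key], value):
            outcomes[key] = "match"
        else:
            outcomes[key] = "mismatch"
    overall = all(v == "match" for v in outcomes.values())
    return RowOutcome(row.substrate, row.subfamily, outcomes, overall)


@dataclass
class SubstratePrediction:
    substrates: set
    trace: list = field(default_factory=list)  # RowOutcome per evaluated row

    @property
    def category(self) -> str:
        return channel_category(self)


def predict_substrates(
    profile: ConstrictionProfile,
    subfamily: str,
    table: SubstrateSignatureTable,
    *,
    sip_mode: str = "table",
    strict_co2: bool = False,
    fp_group: str | None = None,
) -> SubstratePrediction:
    """Union of substrates whose row for ``subfamily`` evaluates true.

    ``strict_co2`` additionally requires PIP FP Group I membership for a CO2
    call (pass the gene's FP group via ``fp_group``); off by default because
    the CO2 FP pattern already constrains P1.
    """
    if subfamily not in SUBFAMILIES:
        raise ValueError(f"unknown subfamily {subfamily!r}")
    if sip_mode not in ("table", "fp_only"):
        raise ValueError(f"unknown sip_mode {sip_mode!r}")
    prediction = SubstratePrediction(set())
    for row in table.rows_for(subfamily):
        outcome = evaluate_signature_row(row, profile)
        prediction.trace.append(outcome)
        if outcome.overall:
            prediction.substrates.add(row.substrate)
        if (
            sip_mode == "fp_only"
            and subfamily == "SIP"
            and row.mode == "fp_derived"
            and profile.fps is not None
            and match_anchored(row.fp, profile.fps)
        ):
            if row.substrate not in prediction.substrates:
                prediction.trace.append(
                    RowOutcome(
                        row.substrate,
                        row.subfamily,
                        {"fp": "match"},
                        True,
                        via="fp_only",
                    )
                )
                prediction.substrates.add(row.substrate)
    if strict_co2 and "co2" in prediction.substrates and fp_group != "I":
        prediction.substrates.discard("co2")
    return prediction


def channel_category(prediction) -> str:
    """none / single / dual / multichannel by predicted-substrate count.

    A multichannel MIP transports three or more non-aqua substrates.
    """
    n = len(prediction.substrates if hasattr(prediction, "substrates") else prediction)
    if n == 0:
        return "none"
    if n == 1:
        return "single"
    if n == 2:
        return "dual"
    return "multichannel"


# ancillary motifs discussed as selectivity hypotheses; annotations only,
# never used to gate substrate predictions
ARG_RICH_CTERM = parse_pattern("R-x-x-R-S-F-R-R")
AMMONIA_LOOP_B = parse_pattern("G-L-x-y-G-G")
AMMONIA_LOOP_C = parse_pattern("P-x-H")
METALLOID_LOOP_B = parse_pattern("F/L-x-H-F-P")
BORON_LOOP_C = parse_pattern("SGGVTVP")

#: lysines in the 12-residue terminus needed to call it Lys-rich (heuristic)
LYS_RICH_MIN_K = 3


def _search_span(pattern, query: str, span) -> bool:
    from .patterns import search_all

    if span is not None:
        lo, hi = span
        region = query[lo - 1 : hi]
    else:
        region = query
    return bool(search_all(pattern, region))


def annotate_ancillary_motifs(
    profile: ConstrictionProfile, query, subfamily: str | None = None
) -> dict:
    """Boolean annotation flags for one gene.

    Loop-region motifs are searched within the template-mapped loop B..C span
    when available, else over the whole sequence.
    """
    residues = query.residues if hasattr(query, "residues") else str(query)
    span = profile.loop_bc_span
    lb = profile.npa_lb_triplet
    le = profile.npa_le_triplet
    return {
        "lb_unusual": lb is not None and lb != "NPA",
        "le_unusual": le is not None and le != "NPA",
        "arg_rich_cterm": bool(
            profile.c_terminus
            and _search_span(ARG_RICH_CTERM, profile.c_terminus, None)
        ),
        "lys_rich_cterm": profile.c_terminus.count("K") >= LYS_RICH_MIN_K,
        "ammonia_loop_motifs": _search_span(AMMONIA_LOOP_B, residues, span)
        and _search_span(AMMONIA_LOOP_C, residues, span),
        "metalloid_lb_motif": _search_span(METALLOID_LOOP_B, residues, span),
        "boron_lc_motif": _search_span(BORON_LOOP_C, residues, span),
    }
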