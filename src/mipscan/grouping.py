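"""Subfamily assignment and ar/R / Froger-position group labels.

Subfamily assignment is by highest global-alignment identity against a labeled
reference panel (the bundled templates by default).  Group labels are pure
functions of (subfamily, tetrad) or (subfamily, FP string), driven by an
ordered rules file so the grouping scheme is data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .extract import ConstrictionProfile, make_aligner
from .io import bundled_rules_path
from .patterns import AMINO_ACIDS, SignaturePattern, match_anchored, parse_pattern

UNASSIGNED = "unassigned"

#: identity below this is reported but flagged low-confidence
DEFAULT_CONFIDENCE = 0.4


@dataclass(frozen=True)
class GroupRule:
    kind: str  # "arR" | "fp"
    subfamily: str
    label: str
    pattern: SignaturePattern
    provisional: bool = False


class GroupRuleSet:
    """Ordered grouping rules; order defines precedence (first match wins)."""

    def __init__(self, rules: list[GroupRule]):
        self.rules = rules
        for kind in ("arR", "fp"):
            for subfamily in {r.subfamily for r in rules}:
                labels = [
                    r.label for r in rules if r.kind == kind and r.subfamily == subfamily
                ]
                if len(labels) != len(set(labels)):
                    raise ValueError(f"duplicate {kind} labels for {subfamily}")

    def match(self, kind: str, subfamily: str, value: str) -> str:
        for rule in self.rules:
            if rule.kind == kind and rule.subfamily == subfamily:
                if match_anchored(rule.pattern, value):
                    return rule.label
        return UNASSIGNED


def read_group_rules(path) -> GroupRuleSet:
    """Parse the rules file: kind, subfamily, label, pattern[, provisional]."""
    rules = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) not in (4, 5):
            raise ValueError(f"{path}:{lineno}: expected 4-5 columns")
        kind, subfamily, label, pattern_s = fields[:4]
        if kind not in ("arR", "fp"):
            raise ValueError(f"{path}:{lineno}: unknown rule kind {kind!r}")
        provisional = len(fields) == 5 and fields[4].strip().lower() == "provisional"
        pat = parse_pattern(pattern_s)
        want = 4 if kind == "arR" else 5
        if len(pat) != want:
            raise ValueError(f"{path}:{lineno}: {kind} pattern needs {want} elements")
        rules.append(GroupRule(kind, subfamily, label, pat, provisional))
    return GroupRuleSet(rules)


def load_bundled_rules() -> GroupRuleSet:
    return read_group_rules(bundled_rules_path())


def _validate_residue_string(value: str, length: int, what: str) -> str:
    value = value.upper()
    if len(value) != length:
        raise ValueError(f"{what} must have length {length}, got {len(value)}")
    bad = set(value) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"{what} contains illegal residues {sorted(bad)}")
    return value


def assign_arR_group(subfamily: str, tetrad: str, rules: GroupRuleSet | None = None) -> str:
    """ar/R group label for a 4-residue tetrad, or "unassigned"."""
    tetrad = _validate_residue_string(tetrad, 4, "ar/R tetrad")
    rules = rules or load_bundled_rules()
    return rules.match("arR", subfamily, tetrad)


def assign_fp_group(subfamily: str, fps: str, rules: GroupRuleSet | None = None) -> str:
    """Froger-position group label for a 5-residue string, or "unassigned"."""
    fps = _validate_residue_string(fps, 5, "FP string")
    rules = rules or load_bundled_rules()
    return rules.match("fp", subfamily, fps)


@dataclass(frozen=True)
class SubfamilyCall:
    subfamily: str
    subgroup: str
    identity: float
    low_confidence: bool


def assign_subfamily(
    query,
    reference_panel,
    aligner=None,
    *,
    min_identity: float = DEFAULT_CONFIDENCE,
) -> SubfamilyCall:
    """Label of the highest-identity panel reference under global alignment.

    The panel is a list of objects carrying ``subfamily``, ``subgroup`` (or
    ``id``) and ``sequence``/``residues``.  Ties break by panel order.
    """
    if not reference_panel:
        raise ValueError("empty reference panel")
    if aligner is None:
        aligner = make_aligner()
    residues = query.residues if hasattr(query, "residues") else str(query)
    best = None
    for order, ref in enumerate(reference_panel):
        ref_seq = getattr(ref, "sequence", None) or getattr(ref, "residues")
        aln = aligner.align(ref_seq, residues)[0]
        matches = aligned = 0
        for (t0, t1), (q0, q1) in zip(*aln.aligned):
            for k in range(t1 - t0):
                aligned += 1
                if ref_seq[t0 + k] == residues[q0 + k]:
                    matches += 1
        identity = matches / aligned if aligned else 0.0
        key = (identity, -order)
        if best is None or key > best[0]:
            best = (key, ref, identity)
    _, ref, identity = best
    subfamily = getattr(ref, "subfamily", None) or getattr(ref, "id")
    subgroup = getattr(ref, "subgroup", subfamily)
    return SubfamilyCall(subfamily, subgroup, identity, identity < min_identity)


def detect_unusual_npa(profile: ConstrictionProfile) -> tuple[str, tuple]:
    """Classify the NPA triplets as canonical / LB-variant / LE-variant / both.

    Returns (classification, (lb_triplet, le_triplet)); a missing triplet is
    "indeterminate".
    """
    lb, le = profile.npa_lb_triplet, profile.npa_le_triplet
    if lb is None or le is None:
        return "indeterminate", (lb, le)
    lb_var, le_var = lb != "NPA", le != "NPA"
    if lb_var and le_var:
        return "both", (lb, le)
    if lb_var:
        return "LB-variant", (lb, le)
    if le_var:
        return "LE-variant", (lb, le)
    return "canonical", (lb, le)
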