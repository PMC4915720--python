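"""PROSITE-like signature patterns for aquaporin constriction motifs.

Two notations occur in the aquaporin selectivity literature and both are
supported here:

* a *compact* dialect where each character is one position and parenthesized
  slash-separated groups list alternatives, e.g. ``SG(A/C)H(L/M)NP(S/A)(V/I/T)(T/S)``;
* a *dashed* dialect where positions are joined by dashes and ``x`` is a
  wildcard, e.g. ``R-x-x-R-S-F-R-R`` or ``F/L-x-H-F-P`` (slashes bind tighter
  than dashes).

Matching is anchored and position-wise: a window matches iff every residue is
admitted by the corresponding element.  The unknown residue ``X`` is admitted
only by wildcards, never by a fixed residue or an alternative set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: letters accepted in sequences (standard residues plus the unknown marker)
SEQUENCE_ALPHABET = AMINO_ACIDS + "X"

#: sentinel used for wildcard elements
WILDCARD = None

# lowercase placeholder letters used for wildcards in the dashed dialect
# ("y" occurs in the loop-B motif G-L-x-y-G-G as a second placeholder)
_PLACEHOLDERS = {"x", "y", "z"}


class PatternError(ValueError):
    """Raised when a pattern string cannot be parsed."""


@dataclass(frozen=True)
class SignaturePattern:
    """An ordered sequence of allowed-residue sets with wildcards.

    ``elements`` holds, per position, either ``None`` (wildcard) or a frozenset
    of allowed residues (a singleton set for a fixed residue).
    """

    elements: tuple[frozenset | None, ...]
    source_text: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not self.elements:
            raise PatternError("pattern has no elements")
        for el in self.elements:
            if el is None:
                continue
            if not el:
                raise PatternError("empty alternative set")
            bad = set(el) - set(AMINO_ACIDS)
            if bad:
                raise PatternError(f"illegal residue letter(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.elements)

    def admits(self, index: int, residue: str) -> bool:
        el = self.elements[index]
        if el is None:
            return residue in SEQUENCE_ALPHABET
        return residue in el

    def render(self) -> str:
        """Canonical compact rendering (sorted alternatives, ``X`` wildcard)."""
        parts = []
        for el in self.elements:
            if el is None:
                parts.append("X")
            elif len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("(" + "/".join(sorted(el)) + ")")
        return "".join(parts)


def _parse_group(body: str, text: str) -> frozenset:
    alts = body.split("/")
    if any(a == "" for a in alts):
        raise PatternError(f"empty alternative in {text!r}")
    residues = set()
    for a in alts:
        a = a.strip().upper()
        if len(a) != 1:
            raise PatternError(f"multi-letter alternative {a!r} in {text!r}")
        residues.add(a)
    return frozenset(residues)


def _tokenize_compact(text: str) -> list:
    elements: list = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            j = text.find(")", i)
            if j < 0:
                raise PatternError(f"unbalanced parentheses in {text!r}")
            elements.append(_parse_group(text[i + 1 : j], text))
            i = j + 1
        elif ch == ")":
            raise PatternError(f"unbalanced parentheses in {text!r}")
        elif ch in _PLACEHOLDERS or ch == "X":
            elements.append(WILDCARD)
            i += 1
        else:
            up = ch.upper()
            if up not in AMINO_ACIDS:
                raise PatternError(f"illegal residue letter {ch!r} in {text!r}")
            elements.append(frozenset(up))
            i += 1
    return elements


def _tokenize_dashed(text: str) -> list:
    elements: list = []
    for tok in text.split("-"):
        tok = tok.strip()
        if not tok:
            raise PatternError(f"empty dash token in {text!r}")
        if tok.startswith("(") and tok.endswith(")"):
            tok = tok[1:-1]
        if "/" in tok:
            elements.append(_parse_group(tok, text))
        elif tok in _PLACEHOLDERS or tok == "X":
            elements.append(WILDCARD)
        else:
            up = tok.upper()
            if len(up) != 1 or up not in AMINO_ACIDS:
                raise PatternError(f"illegal token {tok!r} in {text!r}")
            elements.append(frozenset(up))
    return elements


def _has_top_level_dash(text: str) -> bool:
    depth = 0
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        elif ch == "-" and depth == 0:
            return True
    return False


def parse_pattern(text: str) -> SignaturePattern:
    """Parse either dialect into a :class:`SignaturePattern`.

    The dialect is auto-detected by the presence of a dash outside
    parentheses.  Case-insensitive except that lowercase ``x``/``y``/``z``
    (and uppercase ``X``) are wildcards.
    """
    stripped = text.strip()
    if not stripped:
        raise PatternError("empty pattern")
    if _has_top_level_dash(stripped):
        elements = _tokenize_dashed(stripped)
    else:
        elements = _tokenize_compact(stripped)
    return SignaturePattern(tuple(elements), source_text=text)


def match_anchored(pattern: SignaturePattern, window: str, *, strict: bool = False) -> bool:
    """True iff ``window`` matches ``pattern`` position by position.

    A length mismatch is ``False`` in lenient mode and a ``ValueError`` in
    strict mode.
    """
    window = window.upper()
    if len(window) != len(pattern):
        if strict:
            raise ValueError(
                f"window length {len(window)} != pattern length {len(pattern)}"
            )
        return False
    return all(pattern.admits(i, res) for i, res in enumerate(window))


def search_all(pattern: SignaturePattern, sequence: str) -> list[int]:
    """All 1-based start positions of (possibly overlapping) anchored matches."""
    sequence = sequence.upper()
    n, m = len(sequence), len(pattern)
    return [
        s + 1
        for s in range(n - m + 1)
        if all(pattern.admits(i, sequence[s + i]) for i in range(m))
    ]
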