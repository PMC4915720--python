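import itertools

import pytest
from hypothesis import given, settings, strategies as st

from mipscan.patterns import (
    PatternError,
    SignaturePattern,
    match_anchored,
    parse_pattern,
    search_all,
)

from oracles import regex_matches, regex_search_starts


@pytest.mark.parametrize(
    "text, n_elements, checks",
    [
        # boron ar/R: four elements, alternatives preserved as sets
        ("(A/G)(I/S)GR", 4, {0: {"A", "G"}, 1: {"I", "S"}, 2: {"G"}, 3: {"R"}}),
        # Arg-rich C-terminal motif: wildcards at positions 2 and 3
        ("R-x-x-R-S-F-R-R", 8, {1: None, 2: None, 0: {"R"}}),
        ("A", 1, {0: {"A"}}),
        # loop-B NPA consensus: uppercase X is a wildcard in the compact dialect
        ("SGXHXNPAVT", 10, {2: None, 4: None, 5: {"N"}}),
        # slashes bind tighter than dashes
        ("F/L-x-H-F-P", 5, {0: {"F", "L"}, 1: None}),
        # "y" is a second wildcard placeholder, not tyrosine
        ("G-L-x-y-G-G", 6, {2: None, 3: None, 1: {"L"}}),
        # antimonite loop-B row
        ("SG(A/C)H(L/M)NP(S/A)(V/I/T)(T/S)", 10, {8: {"V", "I", "T"}}),
    ],
)
def test_parse_both_dialects(text, n_elements, checks):
    pat = parse_pattern(text)
    assert len(pat) == n_elements
    for idx, want in checks.items():
        el = pat.elements[idx]
        assert (el is None) if want is None else (el == frozenset(want))


@pytest.mark.parametrize(
    "text",
    ["", "(A/G", "A)G", "(A//G)", "()", "(A/)", "B1Z", "R--R", "(AB/C)"],
)
def test_parse_errors(text):
    with pytest.raises((PatternError, ValueError)):
        parse_pattern(text)


def test_match_anchored_examples():
    assert match_anchored(parse_pattern("(Q/M)SAFW"), "QSAFW")
    assert not match_anchored(parse_pattern("FHTR"), "HIAV")
    # lenient length mismatch is False; strict raises
    pat = parse_pattern("FHTR")
    assert not match_anchored(pat, "FHT")
    with pytest.raises(ValueError):
        match_anchored(pat, "FHT", strict=True)
    # X is admitted only by wildcards
    assert not match_anchored(pat, "XHTR")
    assert match_anchored(parse_pattern("xHTR"), "XHTR")
    # case-insensitive input
    assert match_anchored(parse_pattern("(Q/M)SAFW"), "qsafw")


def test_search_all_cterminal_motifs():
    arg_rich = parse_pattern("R-x-x-R-S-F-R-R")
    assert search_all(arg_rich, "GETPRTQRSFRR") == [5]
    assert search_all(arg_rich, "GRGGAAARSGSN") == []
    assert search_all(arg_rich, "") == []
    # overlapping matches are all reported
    assert search_all(parse_pattern("AA"), "AAAA") == [1, 2, 3]


# --- oracle equivalence ----------------------------------------------------

_ALPHA3 = "ACG"


def _random_pattern_text(rng, length):
    parts = []
    for _ in range(length):
        kind = rng.choice(["fixed", "set", "wild"], p=[0.5, 0.35, 0.15])
        if kind == "fixed":
            parts.append(rng.choice(list(_ALPHA3)))
        elif kind == "wild":
            parts.append("X")
        else:
            k = int(rng.integers(2, 4))
            letters = rng.choice(list(_ALPHA3), size=k, replace=False)
            parts.append("(" + "/".join(letters) + ")")
    return "".join(parts)


def test_regex_oracle_equivalence_exhaustive_small_alphabet():
    """Anchored matching agrees with an independent regex oracle on every
    window up to length 6 over a 3-letter alphabet."""
    import numpy as np

    rng = np.random.default_rng(2024)
    for length in range(1, 7):
        windows = ["".join(w) for w in itertools.product(_ALPHA3, repeat=length)]
        for _ in range(8):
            text = _random_pattern_text(rng, length)
            pat = parse_pattern(text)
            for w in windows:
                assert match_anchored(pat, w) == regex_matches(text, w), (text, w)


def test_regex_oracle_equivalence_search(rng_seed=5):
    import numpy as np

    rng = np.random.default_rng(rng_seed)
    for _ in range(200):
        seq = "".join(rng.choice(list(_ALPHA3), size=int(rng.integers(0, 30))))
        text = _random_pattern_text(rng, int(rng.integers(1, 5)))
        assert search_all(parse_pattern(text), seq) == regex_search_starts(text, seq)


# --- properties ------------------------------------------------------------

_element = st.one_of(
    st.none(),
    st.frozensets(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=1, max_size=4),
)


@settings(max_examples=150, derandomize=True)
@given(
    st.lists(_element, min_size=1, max_size=8).map(tuple),
    st.data(),
)
def test_monotonicity_enlarging_sets_never_removes_matches(elements, data):
    pat = SignaturePattern(elements)
    window = "".join(
        data.draw(st.sampled_from("ACDEFGHIKLMNPQRSTVWY")) for _ in elements
    )
    widened = tuple(
        None if el is None else el | {window[i].upper()}
        for i, el in enumerate(elements)
    )
    wide = SignaturePattern(widened)
    if match_anchored(pat, window):
        assert match_anchored(wide, window)
    assert match_anchored(wide, window)  # widened to include the window itself


@settings(max_examples=150, derandomize=True)
@given(st.lists(_element, min_size=1, max_size=8).map(tuple))
def test_render_parse_roundtrip_is_stable(elements):
    pat = SignaturePattern(elements)
    once = parse_pattern(pat.render())
    twice = parse_pattern(once.render())
    assert once.elements == pat.elements
    assert twice.elements == once.elements
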