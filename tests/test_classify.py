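from pathlib import Path

import pytest

from mipscan.classify import (
    annotate_ancillary_motifs,
    channel_category,
    evaluate_signature_row,
    predict_substrates,
)
from mipscan.extract import ConstrictionProfile
from mipscan.io import SignatureRow, SubstrateSignatureTable
from mipscan.patterns import parse_pattern
from mipscan.simulate import PROFILE_LIBRARY

DATA = Path(__file__).parent / "data"


def _profile(arR=None, lb=None, le=None, fps=None, cterm="", gene="g") -> ConstrictionProfile:
    return ConstrictionProfile(
        gene_id=gene,
        npa_lb_window=lb,
        npa_le_window=le,
        arR=arR,
        fps=fps,
        c_terminus=cterm,
    )


PIP_CO2_PROFILE = _profile("FHTR", "SGGHINPAVT", "GTGINPARSLG", "QSAFW")
NIP_SILICON_PROFILE = _profile("GSGR", "SGAHMNPAVT", "GGSMNPARTLG", "LTAYF")


def _row(table, substrate, subfamily):
    return next(
        r for r in table.rows if r.substrate == substrate and r.subfamily == subfamily
    )


def test_co2_pip_row_matches_canonical_pip_profile(signature_table):
    outcome = evaluate_signature_row(_row(signature_table, "co2", "PIP"), PIP_CO2_PROFILE)
    assert outcome.overall
    assert set(outcome.outcomes.values()) == {"match"}


def test_urea_nip_row_rejects_silicon_tetrad(signature_table):
    # urea/NIP ar/R requires A at the third position; GSGR carries G
    outcome = evaluate_signature_row(_row(signature_table, "urea", "NIP"), NIP_SILICON_PROFILE)
    assert not outcome.overall
    assert outcome.outcomes["arR"] == "mismatch"


def test_missing_field_fails_closed(signature_table):
    profile = _profile("FHTR", "SGGHINPAVT", "GTGINPARSLG", fps=None)
    outcome = evaluate_signature_row(_row(signature_table, "co2", "PIP"), profile)
    assert not outcome.overall
    assert outcome.outcomes["fp"] == "not evaluable"


def test_predict_pip_dual_co2_h2o2(signature_table):
    pred = predict_substrates(PIP_CO2_PROFILE, "PIP", signature_table)
    assert pred.substrates == {"co2", "h2o2"}
    assert channel_category(pred) == "dual"


def test_predict_nip_silicon_multichannel(signature_table):
    pred = predict_substrates(NIP_SILICON_PROFILE, "NIP", signature_table)
    assert pred.substrates == {"silicon", "arsenic", "antimonite"}
    assert channel_category(pred) == "multichannel"


def test_empty_profile_predicts_nothing(signature_table):
    pred = predict_substrates(_profile(), "NIP", signature_table)
    assert pred.substrates == set()
    assert channel_category(pred) == "none"


def test_unknown_subfamily_rejected(signature_table):
    with pytest.raises(ValueError):
        predict_substrates(_profile(), "XIP", signature_table)


@pytest.mark.parametrize(
    "n, category",
    [(0, "none"), (1, "single"), (2, "dual"), (3, "multichannel"), (5, "multichannel")],
)
def test_channel_category_thresholds(n, category):
    assert channel_category(set(list("abcde")[:n])) == category


def test_sip_modes(signature_table):
    # a SIP profile whose FPs match the urea row but whose other
    # constrictions do not
    profile = _profile("SHGS", "GGASYNPLTI", "GGIMNPASAFA", "MAAYW")
    table_pred = predict_substrates(profile, "SIP", signature_table, sip_mode="table")
    fp_pred = predict_substrates(profile, "SIP", signature_table, sip_mode="fp_only")
    assert "urea" not in table_pred.substrates  # conjunctive rule fails
    assert "urea" in fp_pred.substrates  # FP-only route adds it
    assert table_pred.substrates <= fp_pred.substrates


def test_strict_co2_requires_fp_group_one(signature_table):
    relaxed = predict_substrates(PIP_CO2_PROFILE, "PIP", signature_table)
    gated = predict_substrates(
        PIP_CO2_PROFILE, "PIP", signature_table, strict_co2=True, fp_group="II"
    )
    assert "co2" in relaxed.substrates
    assert "co2" not in gated.substrates
    assert gated.substrates | {"co2"} == relaxed.substrates


# --- corpus-level properties -------------------------------------------------


def test_conjunction_ablating_any_constriction_removes_substrate(
    signature_table, corpus_clean
):
    """Flipping any single matched constriction to non-matching removes the
    substrate (conjunctive rule)."""
    _, truths, _ = corpus_clean
    seen = 0
    for truth in truths:
        planted = truth.planted
        base = planted.as_constriction_profile()
        pred = predict_substrates(base, truth.subfamily, signature_table)
        for substrate in pred.substrates:
            seen += 1
            for fld, broken in (
                ("arR", "WWWW"),
                ("fps", "WWWWW"),
                ("npa_lb_window", "WWWWWNPAWW"),
                ("npa_le_window", "WWWWNPAWWWW"),
            ):
                kwargs = {
                    "arR": base.arR,
                    "lb": base.npa_lb_window,
                    "le": base.npa_le_window,
                    "fps": base.fps,
                }
                key = {"arR": "arR", "fps": "fps",
                       "npa_lb_window": "lb", "npa_le_window": "le"}[fld]
                kwargs[key] = broken
                ablated = _profile(**kwargs)
                after = predict_substrates(ablated, truth.subfamily, signature_table)
                assert substrate not in after.substrates
    assert seen > 20  # the corpus does exercise the rule


def test_fail_closed_never_predicts_from_missing_fields(signature_table, corpus_decoys):
    _, truths, profiles = corpus_decoys
    for truth, profile in zip(truths, profiles):
        if any(
            getattr(profile, f) is None
            for f in ("arR", "fps", "npa_lb_window", "npa_le_window")
        ):
            pred = predict_substrates(profile, truth.subfamily, signature_table)
            missing = {
                f for f in ("arR", "fps", "npa_lb_window", "npa_le_window")
                if getattr(profile, f) is None
            }
            # any substrate whose row touches a missing field must be absent;
            # with the full conjunctive rule that means nothing is predicted
            assert pred.substrates == set(), (truth.gene_id, missing)


def test_monotonicity_widening_patterns_never_shrinks_prediction(signature_table):
    """Replacing every pattern element with a wider set can only add substrates."""
    widened_rows = []
    for row in signature_table.rows:
        def widen(pat):
            return parse_pattern("X" * len(pat))

        widened_rows.append(
            SignatureRow(
                row.substrate,
                row.subfamily,
                row.diameter,
                row.mode,
                widen(row.arR),
                widen(row.npa_lb),
                widen(row.npa_le),
                widen(row.fp),
            )
        )
    wide_table = SubstrateSignatureTable(widened_rows)
    for profile, subfamily in (
        (PIP_CO2_PROFILE, "PIP"),
        (NIP_SILICON_PROFILE, "NIP"),
        (_profile("WVAR", "SGGHLNPAVT", "GASMNPARSLG", "FSAYL"), "NIP"),
    ):
        narrow = predict_substrates(profile, subfamily, signature_table).substrates
        wide = predict_substrates(profile, subfamily, wide_table).substrates
        assert narrow <= wide


def test_subfamily_restriction_on_corpus(signature_table, corpus_clean):
    """Silicon only for NIPs, CO2 only for PIPs: rows never cross subfamilies."""
    _, truths, profiles = corpus_clean
    for truth, profile in zip(truths, profiles):
        pred = predict_substrates(profile, truth.subfamily, signature_table)
        if "silicon" in pred.substrates:
            assert truth.subfamily == "NIP"
        if "co2" in pred.substrates:
            assert truth.subfamily == "PIP"
        if "arsenic" in pred.substrates:
            assert truth.subfamily in ("NIP", "SIP")


# --- ancillary motif annotations ---------------------------------------------


def _profile_from_triplets(lb_triplet, le_triplet, cterm):
    lb = "SGGHA" + lb_triplet + "VT"
    le = "GGSM" + le_triplet + "RSLG"
    return _profile("GSGR", lb, le, "LTAYF", cterm=cterm)


def test_ancillary_flags_on_published_termini():
    profile = _profile_from_triplets("NPS", "NPV", "GETPRTQRSFRR")
    flags = annotate_ancillary_motifs(profile, "X" * 30, "NIP")
    assert flags["arg_rich_cterm"]
    assert flags["lb_unusual"] and flags["le_unusual"]
    assert not flags["lys_rich_cterm"]

    profile = _profile_from_triplets("NPT", "NPA", "LAPPPKPKAKKA")
    flags = annotate_ancillary_motifs(profile, "X" * 30, "SIP")
    assert flags["lb_unusual"] and not flags["le_unusual"]
    assert flags["lys_rich_cterm"] and not flags["arg_rich_cterm"]

    profile = _profile_from_triplets("NPA", "NPA", "GDSTAGAGLDSA")
    flags = annotate_ancillary_motifs(profile, "X" * 30, "PIP")
    assert not any(
        flags[k] for k in ("lb_unusual", "le_unusual", "arg_rich_cterm", "lys_rich_cterm")
    )


def test_ancillary_flags_against_published_table():
    """The transcribed unusual-NPA table reproduces every documented call."""
    rows = [
        line.split("\t")
        for line in (DATA / "table5_motifs.tsv").read_text().splitlines()
        if line and not line.startswith("#")
    ]
    assert len(rows) >= 15
    for mip, subfamily, lb, le, cterm, npa_class, arg_rich, lys_rich in rows:
        profile = _profile_from_triplets(lb, le, cterm)
        flags = annotate_ancillary_motifs(profile, "X" * 30, subfamily)
        assert flags["arg_rich_cterm"] == (arg_rich == "true"), mip
        assert flags["lys_rich_cterm"] == (lys_rich == "true"), mip


def test_loop_motifs_searched_within_span():
    # plant P-x-H and G-L-x-y-G-G inside the loop B..C span only
    seq = "A" * 10 + "GLKTGG" + "A" * 4 + "PTH" + "A" * 40
    profile = _profile("HIGR", "SGGHVNPAVT", "GGSMNPARSFG", "TSAYW", cterm="A" * 12)
    profile.loop_bc_span = (11, 24)
    flags = annotate_ancillary_motifs(profile, seq, "TIP")
    assert flags["ammonia_loop_motifs"]
    profile.loop_bc_span = (30, 50)  # span excludes the planted motifs
    flags = annotate_ancillary_motifs(profile, seq, "TIP")
    assert not flags["ammonia_loop_motifs"]
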