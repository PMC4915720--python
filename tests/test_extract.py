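import re

import numpy as np
import pytest

from mipscan.extract import (
    align_to_template,
    extract_profile,
    find_npa_seeds,
    make_aligner,
    validate_full_length,
)
from mipscan.io import SequenceRecord

from oracles import gotoh_global_score


def test_template_self_alignment_is_identity(templates, aligner):
    pip = templates[0]
    query = SequenceRecord(pip.id, "", pip.sequence)
    aln = align_to_template(query, pip, aligner)
    assert aln.identity == 1.0
    assert aln.coverage == 1.0
    assert aln.mapping == list(range(len(pip.sequence)))


def test_alignment_mapping_shifts_after_deletion(templates, aligner):
    pip = templates[0]
    k = 120  # delete one residue in the middle
    mutated = pip.sequence[:k] + pip.sequence[k + 1 :]
    aln = align_to_template(SequenceRecord("del", "", mutated), pip, aligner)
    assert aln.mapping[50] == 50
    assert aln.mapping[k] is None  # the deleted column is a gap
    assert aln.mapping[200] == 199  # downstream positions shift by one


def test_alignment_scores_match_textbook_dp_oracle(aligner, templates):
    """Scores agree with an independent affine-gap Gotoh DP on random 40-mers."""
    rng = np.random.default_rng(42)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    template = templates[0]
    for _ in range(50):
        a = "".join(rng.choice(aa, size=40))
        b = "".join(rng.choice(aa, size=40))
        got = aligner.align(a, b)[0].score
        assert got == pytest.approx(gotoh_global_score(a, b))


def test_find_npa_seeds():
    seq = "MKSGGHINPAVTGGGTGINPARSLGMM"
    seeds = find_npa_seeds(seq)
    assert [s[0] for s in seeds] == [8, 19]
    assert [s[1] for s in seeds] == ["NPA", "NPA"]
    assert find_npa_seeds("MKNPAK") == [(3, "NPA")]
    assert find_npa_seeds("MKNP") == []  # needs a third residue


def test_find_npa_seeds_matches_regex_oracle():
    rng = np.random.default_rng(9)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(200):
        seq = "".join(rng.choice(aa, size=int(rng.integers(3, 80))))
        want = [m.start() + 1 for m in re.finditer(r"(?=NP[A-WY])", seq)]
        assert [s[0] for s in find_npa_seeds(seq)] == want


def test_extract_bundled_pip_template_as_query(templates, aligner):
    pip = next(t for t in templates if t.id == "PIP")
    profile = extract_profile(SequenceRecord("q", "", pip.sequence), templates, aligner)
    assert profile.arR == "FHTR"
    assert profile.fps == "QSAFW"
    assert profile.template_id == "PIP"
    assert all(v == "aligned" for v in profile.provenance.values())


def test_extract_roundtrip_zero_mutation(corpus_clean):
    """Every planted field is recovered exactly on unmutated sequences."""
    records, truths, profiles = corpus_clean
    for truth, profile in zip(truths, profiles):
        planted = truth.planted
        assert profile.npa_lb_window == planted.npa_lb_window
        assert profile.npa_le_window == planted.npa_le_window
        assert profile.arR == planted.arR
        assert profile.fps == planted.fps
        assert profile.c_terminus == planted.c_terminus
        assert profile.template_id == truth.subgroup


def test_extract_recovery_under_substitution(corpus_mutated):
    """At 5% substitution (no indels) ar/R and FP recovery stay >= 95%."""
    records, truths, profiles = corpus_mutated
    n = len(records)
    arr = sum(p.arR == t.planted.arR for p, t in zip(profiles, truths))
    fps = sum(p.fps == t.planted.fps for p, t in zip(profiles, truths))
    assert n == 200
    assert arr / n >= 0.95
    assert fps / n >= 0.95


def test_extraction_deterministic_and_order_independent(corpus_clean, templates, aligner):
    records, _, profiles = corpus_clean
    again = [extract_profile(r, templates, aligner) for r in reversed(records)]
    for profile, redo in zip(profiles, reversed(again)):
        assert (profile.arR, profile.fps, profile.npa_lb_window) == (
            redo.arR,
            redo.fps,
            redo.npa_lb_window,
        )


def test_c_terminus_is_a_12_residue_suffix(corpus_clean):
    records, _, profiles = corpus_clean
    for record, profile in zip(records, profiles):
        assert len(profile.c_terminus) == 12
        assert record.residues.endswith(profile.c_terminus)


def test_truncated_fragment_loses_loop_e(templates, aligner):
    pip = next(t for t in templates if t.id == "PIP")
    fragment = SequenceRecord("frag", "", pip.sequence[:100])
    profile = extract_profile(fragment, templates, aligner)
    assert profile.npa_le_window is None
    assert profile.arR is None  # H5/LE1/LE2 unmappable
    verdict = validate_full_length(profile, fragment)
    assert not verdict.is_full_length
    assert any("length" in r for r in verdict.reasons)
    assert any("loop-E" in r for r in verdict.reasons)


def test_validate_full_length_on_generator_corpora(corpus_clean, corpus_decoys):
    for records, truths, profiles in (corpus_clean, corpus_decoys):
        for record, truth, profile in zip(records, truths, profiles):
            verdict = validate_full_length(profile, record)
            assert verdict.label == truth.expected_verdict, (
                record.id,
                truth.decoy_kind,
                verdict.reasons,
            )
            if truth.is_decoy:
                assert verdict.reasons


def test_motif_seeded_rescue_of_shifted_window(templates, aligner):
    """An insertion right before loop B still yields the correct window,
    recovered via the N-P-x seed when the aligned core drifts."""
    pip = next(t for t in templates if t.id == "PIP")
    lb0 = pip.positions["lb_start"] - 1
    shifted = pip.sequence[: lb0 - 2] + "GSTG" + pip.sequence[lb0 - 2 :]
    profile = extract_profile(SequenceRecord("ins", "", shifted), templates, aligner)
    assert profile.npa_lb_window == pip.lb_window()
    assert profile.provenance["npa_lb_window"] in ("aligned", "motif-seeded")
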