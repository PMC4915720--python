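import pytest

from mipscan.extract import extract_profile, make_aligner
from mipscan.grouping import load_bundled_rules
from mipscan.io import load_bundled_signature_table, load_bundled_templates
from mipscan.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def signature_table():
    return load_bundled_signature_table()


@pytest.fixture(scope="session")
def templates():
    return load_bundled_templates()


@pytest.fixture(scope="session")
def rules():
    return load_bundled_rules()


@pytest.fixture(scope="session")
def aligner():
    return make_aligner()


def _extract_all(records, templates, aligner):
    return [extract_profile(rec, templates, aligner) for rec in records]


@pytest.fixture(scope="session")
def corpus_clean(templates, aligner):
    """40 intact sequences, zero mutation: (records, truths, profiles)."""
    records, truths = generate_dataset(GeneratorConfig(seed=7, substitution_rate=0.0))
    return records, truths, _extract_all(records, templates, aligner)


@pytest.fixture(scope="session")
def corpus_mutated(templates, aligner):
    """200 intact sequences at 5% substitution, no indels."""
    config = GeneratorConfig(
        seed=11,
        counts={"PIP": 60, "TIP": 60, "NIP": 50, "SIP": 30},
        substitution_rate=0.05,
    )
    records, truths = generate_dataset(config)
    return records, truths, _extract_all(records, templates, aligner)


@pytest.fixture(scope="session")
def corpus_decoys(templates, aligner):
    """40 sequences, 25% converted to pseudo-gene decoys."""
    records, truths = generate_dataset(GeneratorConfig(seed=13, decoy_fraction=0.25))
    return records, truths, _extract_all(records, templates, aligner)
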