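"""Synthetic MIP-like sequences with fully known ground truth.

Sequences follow the canonical MIP architecture — six hydrophobic
transmembrane segments (fixed length 19, drawn from A/I/L/V/F/M) joined by
loops drawn from the full alphabet — with the two NPA windows, the ar/R
residues, the Froger positions and a characteristic 12-residue C-terminus
planted at fixed, template-consistent offsets.  Every planted field and the
substrate set it implies (computed by applying the signature table directly to
the planted profile) are recorded as ground truth, so the extractor and the
classifier can be tested in a closed loop with no downloads.

Decoys emulate pseudo genes: one NPA window ablated, or the sequence
truncated.  Mutations never touch planted constriction windows unless
``corrupt_constrictions`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .extract import ConstrictionProfile, LB_CORE_OFFSET, LE_CORE_OFFSET, RESCUE_RADIUS
from .io import (
    ReferenceTemplate,
    SequenceRecord,
    SubstrateSignatureTable,
    load_bundled_signature_table,
)
from .patterns import AMINO_ACIDS

TM_ALPHABET = "AILVFM"
TM_LENGTH = 19

# scaffold segments: (name, length); six TM helices, five loops, termini
SEGMENTS = (
    ("n_term", 15),
    ("H1", TM_LENGTH),
    ("loopA", 10),
    ("H2", TM_LENGTH),
    ("loopB", 16),
    ("H3", TM_LENGTH),
    ("loopC", 18),
    ("H4", TM_LENGTH),
    ("loopD", 10),
    ("H5", TM_LENGTH),
    ("loopE", 22),
    ("H6", TM_LENGTH),
    ("post", 18),
    ("c_term", 12),
)
SCAFFOLD_LENGTH = sum(length for _, length in SEGMENTS)  # 235

#: planted element positions, 1-based (shared by all templates)
PLANT_POSITIONS = {
    "h2": 58,
    "lb_start": 67,
    "h5": 162,
    "le_start": 168,
    "le1": 169,  # loop-E window position 2
    "le2": 175,  # loop-E window position 8
    "p1": 181,
    "p2": 209,
    "p3": 212,
    "p4": 215,
    "p5": 218,
}
C_TERM_START = SCAFFOLD_LENGTH - 12 + 1  # 1-based


@dataclass(frozen=True)
class PlantedProfile:
    """The constriction elements planted into one synthetic sequence."""

    name: str
    subfamily: str  # PIP | TIP | NIP | SIP
    subgroup: str  # template scaffold to build on (PIP, TIP, NIP1, ...)
    arR: str
    npa_lb_window: str
    npa_le_window: str
    fps: str
    c_terminus: str

    def __post_init__(self) -> None:
        if len(self.arR) != 4 or len(self.fps) != 5:
            raise ValueError(f"{self.name}: ar/R must be 4 residues, FPs 5")
        if len(self.npa_lb_window) != 10 or len(self.npa_le_window) != 11:
            raise ValueError(f"{self.name}: windows must be 10/11 residues")
        if self.npa_lb_window[LB_CORE_OFFSET : LB_CORE_OFFSET + 2] != "NP":
            raise ValueError(f"{self.name}: loop-B window lacks its N-P core")
        if self.npa_le_window[LE_CORE_OFFSET : LE_CORE_OFFSET + 2] != "NP":
            raise ValueError(f"{self.name}: loop-E window lacks its N-P core")
        # LE1/LE2 of the tetrad live at loop-E window positions 2 and 8
        if self.arR[2] != self.npa_le_window[1] or self.arR[3] != self.npa_le_window[7]:
            raise ValueError(f"{self.name}: ar/R LE1/LE2 inconsistent with loop-E window")
        if len(self.c_terminus) != 12:
            raise ValueError(f"{self.name}: C-terminus must be 12 residues")

    def as_constriction_profile(self, gene_id: str = "planted") -> ConstrictionProfile:
        return ConstrictionProfile(
            gene_id=gene_id,
            npa_lb_window=self.npa_lb_window,
            npa_le_window=self.npa_le_window,
            arR=self.arR,
            fps=self.fps,
            c_terminus=self.c_terminus,
            provenance={k: "planted" for k in
                        ("npa_lb_window", "npa_le_window", "arR", "fps", "c_terminus")},
        )


#: the planted-profile library: one entry per emulated selectivity class
PROFILE_LIBRARY = {
    p.name: p
    for p in (
        # group I PIP: CO2 + H2O2 (Gln at P1)
        PlantedProfile("PIP_groupI", "PIP", "PIP", "FHTR",
                       "SGGHINPAVT", "GTGINPARSLG", "QSAFW", "GDSTAGAGLDSA"),
        # group II PIP: P1 substituted -> no non-aqua substrate
        PlantedProfile("PIP_groupII", "PIP", "PIP", "FHTR",
                       "SGGHINPAVT", "GTGINPARSLG", "HSAFW", "GDSTAGAGLDSA"),
        # TIP2-like (ar/R group IIA): ammonia + H2O2 + urea, a multichannel TIP
        PlantedProfile("TIP_ammonia", "TIP", "TIP", "HIGR",
                       "SGGHVNPAVT", "GGSMNPARSFG", "TSAYW", "AVDSAGTELGSA"),
        # TIP1-like (ar/R group I, Val at LE2): urea + H2O2
        PlantedProfile("TIP_groupI", "TIP", "TIP", "HIAV",
                       "SGGHVNPAVT", "GASMNPAVSFG", "TSAYW", "AVDSAGTELGSA"),
        # NIP1-like (WVAR): ammonia
        PlantedProfile("NIP1_ammonia", "NIP", "NIP1", "WVAR",
                       "SGGHLNPAVT", "GASMNPARSLG", "FSAYL", "SGDAATELGAPA"),
        # NIP2-like silicon transporter (GSGR): silicon + arsenic + antimonite
        PlantedProfile("NIP2_silicon", "NIP", "NIP2", "GSGR",
                       "SGAHMNPAVT", "GGSMNPARTLG", "LTAYF", "SAETGLDAAGSP"),
        # NIP3-like boron transporter: unusual NPS/NPV motifs, Arg-rich terminus
        PlantedProfile("NIP3_boron", "NIP", "NIP1", "AIGR",
                       "SGAHMNPSVT", "GGSMNPVRSLG", "FTAYF", "GETPRTQRSFRR"),
        # SIP1: NPT in loop B, Lys-rich terminus; urea by the FP-derived row
        PlantedProfile("SIP1_urea", "SIP", "SIP1", "LVPN",
                       "GGVSFNPTTS", "GPSMNPANAFA", "MAAYW", "LAPPPKPKAKKA"),
        # SIP2: NPL in loop B, Lys-rich terminus; arsenic + H2O2 rows
        PlantedProfile("SIP2_arsenic", "SIP", "SIP2", "SHGS",
                       "GGASYNPLTI", "GGIMNPASAFA", "FAAYW", "TFLTKPKKIKEQ"),
    )
}

#: canonical profile used for each bundled template scaffold
TEMPLATE_PROFILES = {
    "PIP": "PIP_groupI",
    "TIP": "TIP_ammonia",
    "NIP1": "NIP1_ammonia",
    "NIP2": "NIP2_silicon",
    "SIP1": "SIP1_urea",
    "SIP2": "SIP2_arsenic",
}
_TEMPLATE_SEEDS = {"PIP": 101, "TIP": 102, "NIP1": 103, "NIP2": 104, "SIP1": 105, "SIP2": 106}

# loop residues, mildly biased toward small/polar residues as in real loops
_LOOP_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_LOOP_WEIGHTS = np.array(
    [8, 1, 5, 6, 3, 9, 2, 4, 6, 7, 2, 4, 6, 4, 5, 8, 6, 5, 1, 3], dtype=float
)
_LOOP_WEIGHTS /= _LOOP_WEIGHTS.sum()


def _scaffold(rng: np.random.Generator) -> list[str]:
    chars: list[str] = []
    for name, length in SEGMENTS:
        if name.startswith("H"):
            chars.extend(rng.choice(list(TM_ALPHABET), size=length))
        else:
            chars.extend(rng.choice(list(_LOOP_ALPHABET), size=length, p=_LOOP_WEIGHTS))
    return chars


def _plant(chars: list[str], profile: PlantedProfile) -> list[str]:
    chars = list(chars)
    pos = PLANT_POSITIONS
    chars[pos["h2"] - 1] = profile.arR[0]
    chars[pos["h5"] - 1] = profile.arR[1]
    lb0 = pos["lb_start"] - 1
    chars[lb0 : lb0 + 10] = list(profile.npa_lb_window)
    le0 = pos["le_start"] - 1
    chars[le0 : le0 + 11] = list(profile.npa_le_window)
    for i, key in enumerate(("p1", "p2", "p3", "p4", "p5")):
        chars[pos[key] - 1] = profile.fps[i]
    chars[C_TERM_START - 1 :] = list(profile.c_terminus)
    return chars


def protected_positions() -> set[int]:
    """0-based scaffold positions carrying planted constriction elements."""
    pos = PLANT_POSITIONS
    protected = {pos["h2"] - 1, pos["h5"] - 1}
    protected |= set(range(pos["lb_start"] - 1, pos["lb_start"] + 9))
    protected |= set(range(pos["le_start"] - 1, pos["le_start"] + 10))
    protected |= {pos[k] - 1 for k in ("p1", "p2", "p3", "p4", "p5")}
    protected |= set(range(C_TERM_START - 1, SCAFFOLD_LENGTH))
    return protected


def build_template(subgroup: str) -> ReferenceTemplate:
    """Deterministically rebuild a bundled synthetic reference template.

    The scaffold is a synthetic stand-in for the structure-derived reference
    (no published coordinate map exists); the planted constriction elements
    are the authentic subfamily-canonical ones.
    """
    profile = PROFILE_LIBRARY[TEMPLATE_PROFILES[subgroup]]
    rng = np.random.default_rng(_TEMPLATE_SEEDS[subgroup])
    chars = _plant(_scaffold(rng), profile)
    return ReferenceTemplate(
        id=subgroup,
        subfamily=profile.subfamily,
        subgroup=subgroup,
        sequence="".join(chars),
        positions=dict(PLANT_POSITIONS),
    )


# ---------------------------------------------------------------------------
# dataset generation


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    seed: int
    counts: dict = field(
        default_factory=lambda: {"PIP": 12, "TIP": 12, "NIP": 10, "SIP": 6}
    )
    mixture: dict = field(
        default_factory=lambda: {
            "PIP": (("PIP_groupI", 0.75), ("PIP_groupII", 0.25)),
            "TIP": (("TIP_ammonia", 0.5), ("TIP_groupI", 0.5)),
            "NIP": (("NIP1_ammonia", 0.4), ("NIP2_silicon", 0.3), ("NIP3_boron", 0.3)),
            "SIP": (("SIP1_urea", 0.5), ("SIP2_arsenic", 0.5)),
        }
    )
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    length_jitter: int = 0
    decoy_fraction: float = 0.0
    corrupt_constrictions: bool = False

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate, self.decoy_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class GroundTruth:
    """Everything known by construction about one generated sequence."""

    gene_id: str
    profile_name: str
    subfamily: str
    subgroup: str
    planted: PlantedProfile
    expected_substrates: frozenset
    expected_category: str
    is_decoy: bool
    decoy_kind: str | None
    expected_verdict: str


def expected_substrates_for(
    profile: PlantedProfile, table: SubstrateSignatureTable | None = None, sip_mode: str = "table"
) -> frozenset:
    """Classifier applied directly to the planted profile (bypassing extraction)."""
    from .classify import predict_substrates

    table = table or load_bundled_signature_table()
    pred = predict_substrates(
        profile.as_constriction_profile(), profile.subfamily, table, sip_mode=sip_mode
    )
    return frozenset(pred.substrates)


def _mutate(chars: list[str], protected: set[int], config: GeneratorConfig, rng) -> list[str]:
    tagged = [(c, i in protected and not config.corrupt_constrictions)
              for i, c in enumerate(chars)]
    # substitutions
    out = []
    for c, prot in tagged:
        if not prot and rng.random() < config.substitution_rate:
            choices = [a for a in AMINO_ACIDS if a != c]
            c = choices[int(rng.integers(len(choices)))]
        out.append((c, prot))
    tagged = out
    # indels (never inside a planted span)
    n_events = rng.binomial(len(tagged), config.indel_rate)
    for _ in range(n_events):
        unprot = [i for i, (_, prot) in enumerate(tagged) if not prot]
        if not unprot:
            break
        i = unprot[int(rng.integers(len(unprot)))]
        if rng.random() < 0.5:
            del tagged[i]
        else:
            res = _LOOP_ALPHABET[int(rng.integers(len(_LOOP_ALPHABET)))]
            tagged.insert(i, (res, False))
    # N-terminal length jitter
    if config.length_jitter:
        extra = int(rng.integers(0, config.length_jitter + 1))
        for _ in range(extra):
            res = _LOOP_ALPHABET[int(rng.integers(len(_LOOP_ALPHABET)))]
            tagged.insert(0, (res, False))
    return [c for c, _ in tagged]


def generate_mip_sequence(
    gene_id: str,
    planted: PlantedProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
    templates: dict | None = None,
) -> tuple[SequenceRecord, GroundTruth]:
    """One synthetic MIP built on its subgroup scaffold, plus its ground truth."""
    template = (templates or {}).get(planted.subgroup) or build_template(planted.subgroup)
    chars = _plant(list(template.sequence), planted)
    chars = _mutate(chars, protected_positions(), config, rng)
    record = SequenceRecord(gene_id, f"synthetic {planted.name}", "".join(chars))
    substrates = expected_substrates_for(planted)
    from .classify import channel_category

    truth = GroundTruth(
        gene_id=gene_id,
        profile_name=planted.name,
        subfamily=planted.subfamily,
        subgroup=planted.subgroup,
        planted=planted,
        expected_substrates=substrates,
        expected_category=channel_category(substrates),
        is_decoy=False,
        decoy_kind=None,
        expected_verdict="full-length",
    )
    return record, truth


def _ablate_window(residues: str, start0: int, length: int) -> str:
    """Remove one NPA window: replace it (and nearby Asn) with inert residues."""
    chars = list(residues)
    filler = "GSTAGSTAGST"
    for k in range(length):
        chars[start0 + k] = filler[k % len(filler)]
    core = start0 + LB_CORE_OFFSET
    lo = max(0, core - RESCUE_RADIUS - 3)
    hi = min(len(chars), core + RESCUE_RADIUS + 3)
    for i in range(lo, hi):
        if chars[i] == "N":
            chars[i] = "Q"
    return "".join(chars)


def _make_decoy(record: SequenceRecord, truth: GroundTruth, kind: str, rng) -> tuple:
    residues = record.residues
    if kind == "truncate":
        cut = int(rng.integers(100, 160))
        residues = residues[:cut]
    elif kind == "ablate_lb":
        residues = _ablate_window(residues, PLANT_POSITIONS["lb_start"] - 1, 10)
    elif kind == "ablate_le":
        residues = _ablate_window(residues, PLANT_POSITIONS["le_start"] - 1, 11)
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    record = SequenceRecord(record.id, record.description + f" decoy:{kind}", residues)
    truth = replace(
        truth,
        expected_substrates=frozenset(),
        expected_category="none",
        is_decoy=True,
        decoy_kind=kind,
        expected_verdict="pseudo/fragment",
    )
    return record, truth


def generate_dataset(config: GeneratorConfig) -> tuple[list, list]:
    """Deterministic synthetic corpus: (records, ground truths).

    ``decoy_fraction`` of the sequences (rounded) are converted to pseudo-gene
    decoys with one NPA window ablated or the sequence truncated.
    """
    rng = np.random.default_rng(config.seed)
    templates = {sub: build_template(sub) for sub in TEMPLATE_PROFILES}
    records, truths = [], []
    idx = 0
    for subfamily in sorted(config.counts):
        names, weights = zip(*config.mixture[subfamily])
        weights = np.array(weights, dtype=float)
        weights /= weights.sum()
        for _ in range(config.counts[subfamily]):
            idx += 1
            name = names[int(rng.choice(len(names), p=weights))]
            planted = PROFILE_LIBRARY[name]
            rec, truth = generate_mip_sequence(
                f"SYN_{subfamily}_{idx:04d}", planted, config, rng, templates
            )
            records.append(rec)
            truths.append(truth)
    n_decoys = int(round(config.total * config.decoy_fraction))
    if n_decoys:
        decoy_idx = rng.choice(len(records), size=n_decoys, replace=False)
        kinds = ("ablate_lb", "ablate_le", "truncate")
        for j, i in enumerate(sorted(decoy_idx)):
            records[i], truths[i] = _make_decoy(
                records[i], truths[i], kinds[j % 3], rng
            )
    return records, truths


def write_ground_truth(truths, path) -> None:
    """Ground-truth table as TSV alongside the generated FASTA."""
    cols = [
        "gene_id", "profile_name", "subfamily", "subgroup", "arR", "fps",
        "npa_lb_window", "npa_le_window", "c_terminus",
        "expected_substrates", "expected_category",
        "is_decoy", "decoy_kind", "expected_verdict",
    ]
    lines = ["\t".join(cols)]
    for t in truths:
        lines.append("\t".join([
            t.gene_id, t.profile_name, t.subfamily, t.subgroup,
            t.planted.arR, t.planted.fps,
            t.planted.npa_lb_window, t.planted.npa_le_window,
            t.planted.c_terminus,
            ",".join(sorted(t.expected_substrates)) or "-",
            t.expected_category,
            str(t.is_decoy), t.decoy_kind or "-", t.expected_verdict,
        ]))
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# auxiliary fixtures


def generate_pore_fixture(seed: int, n_points: int = 40, gap_fraction: float = 0.4):
    """Sparse pore table punched out of a known piecewise-linear curve.

    Returns (sparse profile, ground-truth callable).  Knots sit on the integer
    grid so the punched values are exactly recoverable by linear interpolation.
    """
    from .pore import PoreDiameterProfile

    rng = np.random.default_rng(seed)
    positions = np.arange(1, n_points + 1)
    knot_step = 5
    knots = positions[:: knot_step]
    if knots[-1] != positions[-1]:
        knots = np.append(knots, positions[-1])
    knot_vals = rng.uniform(1.5, 6.0, size=len(knots))
    truth = lambda p: float(np.interp(p, knots, knot_vals))  # noqa: E731
    diameters = [truth(p) for p in positions]
    interior = [p for p in positions if p not in set(knots)]
    n_gaps = int(len(interior) * gap_fraction)
    punched = set(rng.choice(interior, size=n_gaps, replace=False).tolist())
    kept = [(int(p), d) for p, d in zip(positions, diameters) if int(p) not in punched]
    profile = PoreDiameterProfile(
        tuple(p for p, _ in kept), tuple(d for _, d in kept)
    )
    return profile, truth, sorted(punched)


def generate_fpkm_fixture(seed: int, n_genes: int = 24):
    """FPKM matrix with a planted expressed/unexpressed pattern around 1.0."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    organs = ["root", "shoot", "leaf"]
    genes = [f"SYNG{i:03d}" for i in range(1, n_genes + 1)]
    values = np.zeros((n_genes, len(organs)))
    expected = np.zeros_like(values, dtype=bool)
    for i in range(n_genes):
        for j in range(len(organs)):
            if rng.random() < 0.6:
                values[i, j] = float(rng.uniform(1.0, 900.0))
                expected[i, j] = True
            else:
                values[i, j] = float(rng.uniform(0.0, 0.999))
    # pin boundary cases
    values[0, 0], expected[0, 0] = 1.0, True
    values[1, 0], expected[1, 0] = 0.999, False
    matrix = pd.DataFrame(values, index=genes, columns=organs)
    flags = pd.DataFrame(expected, index=genes, columns=organs)
    return matrix, flags
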