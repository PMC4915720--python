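"""Template-anchored extraction of the selectivity constrictions.

A query MIP is aligned globally (Needleman-Wunsch, BLOSUM62, gap open 10 /
extend 1) against each bundled reference template; the best-scoring template's
annotated positions are mapped through the alignment to pull out the loop-B
NPA 10-mer, the loop-E NPA 11-mer, the ar/R tetrad (H2, H5, LE1, LE2), the
five Froger positions and the C-terminal 12-mer.  Windows whose mapped core is
not N-P-x are rescued by the nearest N-P-x seed ("motif-seeded" provenance);
positions that map to gaps yield missing fields.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .io import ReferenceTemplate, SequenceRecord

# offsets of the NPA asparagine inside the windows (0-based):
# loop-B consensus S-G-X-H-X-N-P-A-V-T has N at index 5,
# loop-E consensus G-X-X-X-N-P-A-R-(S/D)-X-G has N at index 4.
LB_CORE_OFFSET = 5
LE_CORE_OFFSET = 4
LB_LEN, LE_LEN = 10, 11
C_TERM_LEN = 12

#: residues within this distance of the expected core may rescue a window
RESCUE_RADIUS = 15

_NPA_SEED = re.compile(r"(?=NP[ACDEFGHIKLMNPQRSTVWY])")


def make_aligner() -> Align.PairwiseAligner:
    """The package's standard global protein aligner."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass
class TemplateAlignment:
    """A total mapping from template positions to query positions (or None)."""

    template_id: str
    score: float
    identity: float
    coverage: float  # fraction of template residues aligned to query residues
    mapping: list  # index: 0-based template pos -> 0-based query pos | None


def align_to_template(query: SequenceRecord, template: ReferenceTemplate, aligner=None) -> TemplateAlignment:
    """Global alignment of ``query`` against ``template`` (deterministic)."""
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(template.sequence, query.residues)[0]
    t_len = len(template.sequence)
    mapping: list = [None] * t_len
    matches = aligned_pairs = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            ti, qi = t0 + k, q0 + k
            mapping[ti] = qi
            aligned_pairs += 1
            if template.sequence[ti] == query.residues[qi]:
                matches += 1
    identity = matches / aligned_pairs if aligned_pairs else 0.0
    coverage = aligned_pairs / t_len
    return TemplateAlignment(template.id, float(aln.score), identity, coverage, mapping)


@dataclass
class ConstrictionProfile:
    """The extracted selectivity-relevant residues of one MIP."""

    gene_id: str
    npa_lb_window: str | None = None
    npa_le_window: str | None = None
    arR: str | None = None
    fps: str | None = None
    c_terminus: str = ""
    provenance: dict = field(default_factory=dict)
    # extraction metadata
    template_id: str | None = None
    alignment_score: float | None = None
    identity: float | None = None
    coverage: float | None = None
    loop_bc_span: tuple | None = None  # 1-based (start, end) query interval

    @property
    def npa_lb_triplet(self) -> str | None:
        if self.npa_lb_window is None:
            return None
        return self.npa_lb_window[LB_CORE_OFFSET : LB_CORE_OFFSET + 3]

    @property
    def npa_le_triplet(self) -> str | None:
        if self.npa_le_window is None:
            return None
        return self.npa_le_window[LE_CORE_OFFSET : LE_CORE_OFFSET + 3]

    def window(self, which: str) -> str | None:
        return self.npa_lb_window if which == "lb" else self.npa_le_window


def find_npa_seeds(sequence: str) -> list[tuple[int, str]]:
    """All N-P-? occurrences, 1-based position of the N, with the triplet.

    Overlapping occurrences are all reported, in sequence order.
    """
    sequence = sequence.upper()
    seeds = []
    for m in _NPA_SEED.finditer(sequence):
        pos = m.start()
        seeds.append((pos + 1, sequence[pos : pos + 3]))
    return seeds


def _map_pos(mapping, t_pos0: int):
    """Query 0-based position for a template 0-based position, or None."""
    if 0 <= t_pos0 < len(mapping):
        return mapping[t_pos0]
    return None


def _nearest_mapped(mapping, t_pos0: int):
    """Query position of the nearest mapped template position (gap fallback)."""
    for delta in range(len(mapping)):
        for cand in (t_pos0 - delta, t_pos0 + delta):
            if 0 <= cand < len(mapping) and mapping[cand] is not None:
                return mapping[cand] + (t_pos0 - cand)
    return None


def _extract_window(query: str, mapping, t_start0: int, length: int, core_offset: int):
    """Window string, its 0-based query start and a provenance flag."""
    t_core = t_start0 + core_offset
    q_core = _map_pos(mapping, t_core)
    aligned = q_core is not None
    if q_core is None:
        q_core = _nearest_mapped(mapping, t_core)
    if q_core is None:
        return None, None, "missing"
    q_start = q_core - core_offset
    if aligned and 0 <= q_start and q_start + length <= len(query):
        window = query[q_start : q_start + length]
        if window[core_offset : core_offset + 2] == "NP":
            return window, q_start, "aligned"
    # rescue: nearest N-P-? seed to the expected core position
    best = None
    for seed_pos1, _ in find_npa_seeds(query):
        seed0 = seed_pos1 - 1
        dist = abs(seed0 - q_core)
        if dist <= RESCUE_RADIUS and (best is None or dist < best[0]):
            start = seed0 - core_offset
            if 0 <= start and start + length <= len(query):
                best = (dist, start)
    if best is not None:
        start = best[1]
        return query[start : start + length], start, "motif-seeded"
    return None, None, "missing"


def extract_profile(
    query: SequenceRecord,
    templates: list[ReferenceTemplate],
    aligner=None,
) -> ConstrictionProfile:
    """Extract a :class:`ConstrictionProfile` using the best-scoring template.

    Template ties break on higher identity, then declared template order.
    Froger positions come purely from the template mapping; if any single FP
    maps to a gap the whole ``fps`` field is missing (classification then
    fails closed).
    """
    if not templates:
        raise ValueError("at least one template required")
    if aligner is None:
        aligner = make_aligner()
    alignments = [align_to_template(query, t, aligner) for t in templates]
    order = range(len(templates))
    best_i = max(order, key=lambda i: (alignments[i].score, alignments[i].identity, -i))
    template, aln = templates[best_i], alignments[best_i]

    q = query.residues
    profile = ConstrictionProfile(
        gene_id=query.id,
        template_id=template.id,
        alignment_score=aln.score,
        identity=aln.identity,
        coverage=aln.coverage,
    )

    lb_window, lb_start0, lb_prov = _extract_window(
        q, aln.mapping, template.positions["lb_start"] - 1, LB_LEN, LB_CORE_OFFSET
    )
    le_window, _, le_prov = _extract_window(
        q, aln.mapping, template.positions["le_start"] - 1, LE_LEN, LE_CORE_OFFSET
    )
    profile.npa_lb_window, profile.npa_le_window = lb_window, le_window
    profile.provenance["npa_lb_window"] = lb_prov
    profile.provenance["npa_le_window"] = le_prov

    arr = []
    for key in ("h2", "h5", "le1", "le2"):
        qpos = _map_pos(aln.mapping, template.positions[key] - 1)
        if qpos is None:
            arr = None
            break
        arr.append(q[qpos])
    profile.arR = "".join(arr) if arr else None
    profile.provenance["arR"] = "aligned" if arr else "missing"

    fps = []
    for key in ("p1", "p2", "p3", "p4", "p5"):
        qpos = _map_pos(aln.mapping, template.positions[key] - 1)
        if qpos is None:
            fps = None
            break
        fps.append(q[qpos])
    profile.fps = "".join(fps) if fps else None
    profile.provenance["fps"] = "aligned" if fps else "missing"

    profile.c_terminus = q[-C_TERM_LEN:]
    profile.provenance["c_terminus"] = "aligned"

    # loop B..C region approximation: loop-B window end through the H5 residue
    h5_q = _map_pos(aln.mapping, template.positions["h5"] - 1)
    if lb_start0 is not None and h5_q is not None and lb_start0 + LB_LEN < h5_q:
        profile.loop_bc_span = (lb_start0 + 1, h5_q + 1)
    return profile


@dataclass
class FullLengthVerdict:
    is_full_length: bool
    reasons: tuple

    @property
    def label(self) -> str:
        return "full-length" if self.is_full_length else "pseudo/fragment"


def validate_full_length(
    profile: ConstrictionProfile,
    query: SequenceRecord,
    *,
    min_length: int = 200,
    max_length: int = 420,
    min_coverage: float = 0.7,
) -> FullLengthVerdict:
    """Full-length iff length in bounds, both NPA windows present, coverage OK.

    ``reasons`` enumerates every failed criterion.
    """
    reasons = []
    if not min_length <= len(query) <= max_length:
        reasons.append(f"length {len(query)} outside [{min_length}, {max_length}]")
    if profile.npa_lb_window is None:
        reasons.append("loop-B NPA window missing")
    if profile.npa_le_window is None:
        reasons.append("loop-E NPA window missing")
    if profile.coverage is not None and profile.coverage < min_coverage:
        reasons.append(f"template coverage {profile.coverage:.2f} < {min_coverage}")
    return FullLengthVerdict(not reasons, tuple(reasons))
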