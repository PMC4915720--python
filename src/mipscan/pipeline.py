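"""The end-to-end annotation pipeline: validate, extract, group, classify, report."""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from . import io
from .classify import annotate_ancillary_motifs, channel_category, predict_substrates
from .extract import extract_profile, make_aligner, validate_full_length
from .grouping import (
    assign_arR_group,
    assign_fp_group,
    assign_subfamily,
    detect_unusual_npa,
    load_bundled_rules,
    read_group_rules,
)

logger = logging.getLogger("mipscan")


@dataclass
class PipelineConfig:
    input_fasta: str | None = None
    signature_table: str | None = None  # None -> bundled
    rules_file: str | None = None  # None -> bundled
    template_files: tuple = ()  # empty -> bundled
    sip_mode: str = "table"
    strict_co2: bool = False
    strict_residues: bool = False
    min_length: int = 200
    max_length: int = 420
    min_coverage: float = 0.7
    output_dir: str | None = None
    write_json: bool = False

    def __post_init__(self) -> None:
        if self.sip_mode not in ("table", "fp_only"):
            raise ValueError(f"invalid sip_mode {self.sip_mode!r}")


@dataclass
class PipelineResult:
    rows: list
    traces: dict  # gene id -> per-substrate evaluation trace
    summary: dict

    def to_json(self) -> str:
        return json.dumps(
            {"summary": self.summary, "traces": self.traces}, indent=2, sort_keys=True
        )


def _load_resources(config: PipelineConfig):
    table = (
        io.read_signature_table(config.signature_table)
        if config.signature_table
        else io.load_bundled_signature_table()
    )
    if config.template_files:
        templates = [io.read_template_annotations(p) for p in config.template_files]
    else:
        templates = io.load_bundled_templates()
    rules = (
        load_bundled_rules()
        if config.rules_file is None
        else read_group_rules(config.rules_file)
    )
    return table, templates, rules


def annotate_records(records, config: PipelineConfig | None = None) -> PipelineResult:
    """Annotate a collection of :class:`~mipscan.io.SequenceRecord`."""
    config = config or PipelineConfig()
    table, templates, rules = _load_resources(config)
    aligner = make_aligner()
    rows, traces = [], {}
    for record in records:
        profile = extract_profile(record, templates, aligner)
        call = assign_subfamily(record, templates, aligner)
        verdict = validate_full_length(
            profile,
            record,
            min_length=config.min_length,
            max_length=config.max_length,
            min_coverage=config.min_coverage,
        )
        row = io.ResultsRow(
            gene_id=record.id,
            subfamily=call.subfamily,
            subfamily_identity=call.identity,
            verdict=verdict.label,
            arR=profile.arR,
            fps=profile.fps,
            npa_lb_window=profile.npa_lb_window,
            npa_le_window=profile.npa_le_window,
            npa_lb_triplet=profile.npa_lb_triplet,
            npa_le_triplet=profile.npa_le_triplet,
            c_terminus=profile.c_terminus,
            reasons=verdict.reasons,
        )
        if not verdict.is_full_length:
            logger.info("dropped %s: %s", record.id, "; ".join(verdict.reasons))
        npa_class, _ = detect_unusual_npa(profile)
        row.npa_class = npa_class
        if profile.arR is not None:
            row.arR_group = assign_arR_group(call.subfamily, profile.arR, rules)
        if profile.fps is not None:
            row.fp_group = assign_fp_group(call.subfamily, profile.fps, rules)
        if verdict.is_full_length:
            prediction = predict_substrates(
                profile,
                call.subfamily,
                table,
                sip_mode=config.sip_mode,
                strict_co2=config.strict_co2,
                fp_group=row.fp_group,
            )
            row.substrates = tuple(sorted(prediction.substrates))
            row.channel_category = channel_category(prediction)
            flags = annotate_ancillary_motifs(profile, record, call.subfamily)
            row.flags = tuple(sorted(name for name, on in flags.items() if on))
            traces[record.id] = [
                {
                    "substrate": o.substrate,
                    "subfamily": o.subfamily,
                    "via": o.via,
                    "overall": o.overall,
                    "outcomes": o.outcomes,
                }
                for o in prediction.trace
            ]
        rows.append(row)
    return PipelineResult(rows, traces, summarize(rows))


def summarize(rows) -> dict:
    """Per-subfamily, per-substrate and channel-category counts."""
    full = [r for r in rows if r.verdict == "full-length"]
    substrate_counts = Counter()
    for r in full:
        substrate_counts.update(r.substrates)
    return {
        "n_input": len(rows),
        "n_full_length": len(full),
        "n_pseudo_or_fragment": len(rows) - len(full),
        "by_subfamily": dict(Counter(r.subfamily for r in full)),
        "by_substrate": dict(substrate_counts),
        "by_category": dict(
            Counter(r.channel_category for r in full if r.channel_category)
        ),
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read the input FASTA, annotate, and write the report files."""
    if not config.input_fasta:
        raise ValueError("input_fasta is required")
    records = io.read_fasta(config.input_fasta, strict=config.strict_residues)
    result = annotate_records(records, config)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_results_table(result.rows, out / "results.tsv")
        (out / "summary.json").write_text(
            json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
        )
        (out / "traces.json").write_text(
            json.dumps(result.traces, indent=2, sort_keys=True) + "\n"
        )
        if config.write_json:
            io.write_results_json(result.rows, out / "results.json")
    return result
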