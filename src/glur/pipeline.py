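"""End-to-end annotation runs: screen → QC → mapping → rules → tree classes.

`run_pipeline` consumes a validated :class:`RunConfig`, runs the stages in
order with per-stage logging, and emits one :class:`AnnotationRecord` per
input sequence (kept or discarded, with the discarding rule named) plus a
summary of all rule-engine counts and per-lineage class tallies. Outputs are
deterministic: re-running the persisted config reproduces the report TSVs
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import qc_filters
from .errors import ConfigurationError, JoinError, NamingError, PipelineStageError
from .io_formats import (
    MultipleAlignment,
    ReferenceTableRow,
    SequenceRecord,
    join_records_to_table,
    read_alignment,
    read_fasta,
    read_reference_table,
    write_newick,
)
from .ligand_rules import (
    ChannelCall,
    LigandCall,
    ResidueProfile,
    call_channel,
    call_mglur_binding,
    call_selectivity,
    summarize_calls,
)
from .reference_map import load_scheme, map_reference_sites
from .tree_surrogate import (
    CladeAssignment,
    assign_classes,
    corrected_distances,
    neighbor_joining,
    p_distance,
)

logger = logging.getLogger(__name__)

IGLUR_FAMILY_CODES = {"A", "K", "F", "D", "Akdf", "E", "N", "L"}

GREEK_LETTERS = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ", "epsilon": "ε",
    "zeta": "ζ", "eta": "η", "theta": "θ",
}


@dataclass
class RunConfig:
    """All knobs of one annotation run, validated before any computation."""

    family: str = "iglur"  # iglur | mglur
    fasta: str | None = None
    reference_table: str | None = None
    alignment: str | None = None
    out_dir: str = "glur_out"
    seed: int = 0
    # reference mapping
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    coverage_floor: float = 0.30
    scheme_yaml: str | None = None
    sites_tsv: str | None = None
    # QC (config keys qc.*)
    qc_motif: str = "SYTANLAAF"
    qc_min_conserved: int = 4
    qc_similarity: bool = False
    qc_tm_window: int = 19
    qc_tm_threshold: float = 1.6
    qc_tm_min_gap: int = 5
    qc_tm_required_min: int = 6
    # rules
    non_polar_site: str = "655"
    # screen
    e_threshold: float = 0.05
    # tree
    outgroup: list[str] = field(default_factory=list)
    saturation_cap: float = 5.0

    def __post_init__(self):
        if self.family not in {"iglur", "mglur"}:
            raise ConfigurationError(f"family must be iglur or mglur, got {self.family!r}")
        if not 0 <= self.coverage_floor <= 1:
            raise ConfigurationError("coverage_floor must be in [0, 1]")
        if self.qc_min_conserved < 0 or self.qc_tm_required_min < 0:
            raise ConfigurationError("QC thresholds must be non-negative")
        if self.e_threshold <= 0:
            raise ConfigurationError("e_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        params = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class AnnotationRecord:
    """Per-query verdicts across every stage it reached."""

    query_id: str
    group_label: str = ""
    phylum: str = ""
    kept: bool = True
    discard_rule: str = ""
    coverage: float | None = None
    low_homology: bool = False
    motif_count: int | None = None
    tm_count: int | None = None
    residues: dict[str, str] = field(default_factory=dict)
    ligand_category: str = ""
    ligand_confidence: str = ""
    rule_trace: str = ""
    qr_site: str = ""
    acidic_590: bool | None = None
    rectification_flag: bool | None = None
    mglur_binding: str = ""
    class_assignment: str = ""
    warnings: list[str] = field(default_factory=list)


def compose_protein_name(
    family_code: str,
    ortholog_numbers: str = "",
    paralog_letter: str = "",
    species_code: str = "",
) -> str:
    """Compose a receptor name from its four parts.

    iGluR names read ``Glu`` + subfamily/class code + ortholog number(s) +
    optional Greek paralog letter + ``_`` + three-letter species code, e.g.
    ``GluL5_Oca`` or ``GluN2/3_Nve``; mGluRs use the ``mGluR`` prefix with
    the class number in place of the letter code. Greek letters are emitted
    as Latin transliterations (file-safe); :data:`GREEK_LETTERS` maps them to
    the display form.
    """
    if len(species_code) != 3:
        raise NamingError(f"species code must have 3 letters, got {species_code!r}")
    if paralog_letter and paralog_letter not in GREEK_LETTERS:
        raise NamingError(f"unknown Greek letter name {paralog_letter!r}")
    if family_code == "mGluR":
        return f"mGluR{ortholog_numbers}{paralog_letter}_{species_code}"
    if family_code not in IGLUR_FAMILY_CODES:
        raise NamingError(f"unknown iGluR family code {family_code!r}")
    return f"Glu{family_code}{ortholog_numbers}{paralog_letter}_{species_code}"


def lineage_class_counts(
    assignment: CladeAssignment,
    table: list[ReferenceTableRow],
    lineage_map: dict[str, str],
) -> dict:
    """Contingency counts of assigned classes per lineage.

    ``lineage_map`` maps phylum -> lineage (e.g. Mollusca -> Lophotrochozoa).
    Unassigned queries are tallied separately. Queries absent from the
    reference table raise a :class:`JoinError` listing the offending ids.
    """
    phylum_of = {row.protein_name: row.phylum for row in table}
    missing = sorted(q for q in assignment.assignments if q not in phylum_of)
    if missing:
        raise JoinError(missing)
    counts: dict[tuple[str, str], int] = {}
    unassigned: dict[str, int] = {}
    for query, cls in assignment.assignments.items():
        lineage = lineage_map.get(phylum_of[query], phylum_of[query])
        if cls == "unassigned":
            unassigned[lineage] = unassigned.get(lineage, 0) + 1
            continue
        key = (lineage, cls)
        counts[key] = counts.get(key, 0) + 1
    ratios = {}
    for lineage in {k[0] for k in counts}:
        by_class = {c: n for (l, c), n in counts.items() if l == lineage}
        ratios[lineage] = by_class
    return {"counts": counts, "per_lineage": ratios, "unassigned": unassigned}


def _annotate_iglur(rec: SequenceRecord, scheme, config: RunConfig) -> AnnotationRecord:
    asg = map_reference_sites(
        rec, scheme, config.matrix, config.gap_open, config.gap_extend,
        config.coverage_floor,
    )
    ann = AnnotationRecord(
        query_id=rec.id, group_label=rec.group_label, phylum=rec.phylum,
        coverage=round(asg.coverage, 4), low_homology=asg.low_homology,
        residues=dict(asg.residues),
    )
    if asg.low_homology:
        ann.warnings.append("low_coverage")
    report = qc_filters.motif_conservation(
        asg, rec, config.qc_motif, config.qc_similarity
    )
    ann.motif_count = report.conserved_count
    if qc_filters.iglur_qc(report, config.qc_min_conserved) == "discard":
        ann.kept = False
        ann.discard_rule = "motif_lt_min_conserved"
        return ann
    profile = ResidueProfile.from_assignment(asg)
    lig = call_selectivity(profile, non_polar_site=config.non_polar_site)
    chan = call_channel(profile)
    ann.ligand_category = lig.category
    ann.ligand_confidence = lig.confidence
    ann.rule_trace = ">".join(lig.rule_trace)
    ann.qr_site = chan.qr_site
    ann.acidic_590 = chan.acidic_590
    ann.rectification_flag = chan.rectification_flag
    return ann


def _annotate_mglur(rec: SequenceRecord, scheme, config: RunConfig) -> AnnotationRecord:
    ann = AnnotationRecord(query_id=rec.id, group_label=rec.group_label, phylum=rec.phylum)
    report = qc_filters.count_tm_segments(
        rec.ungapped, config.qc_tm_window, config.qc_tm_threshold,
        config.qc_tm_min_gap, rec.id,
    )
    ann.tm_count = report.n_segments
    if qc_filters.mglur_qc(report, config.qc_tm_required_min) == "discard":
        ann.kept = False
        ann.discard_rule = "tm_lacking_two_or_more"
        return ann
    asg = map_reference_sites(
        rec, scheme, config.matrix, config.gap_open, config.gap_extend,
        config.coverage_floor,
    )
    ann.coverage = round(asg.coverage, 4)
    ann.low_homology = asg.low_homology
    ann.residues = dict(asg.residues)
    if asg.low_homology:
        ann.warnings.append("low_coverage")
    ann.mglur_binding = call_mglur_binding(ResidueProfile.from_assignment(asg))
    return ann


def run_pipeline(
    config: RunConfig,
    records: list[SequenceRecord] | None = None,
    table: list[ReferenceTableRow] | None = None,
    alignment: MultipleAlignment | None = None,
    reference_classes: dict[str, str] | None = None,
    lineage_map: dict[str, str] | None = None,
) -> tuple[list[AnnotationRecord], dict]:
    """Run QC → mapping → rules (→ tree classes) over the input sequences.

    Inputs may be passed in memory or loaded from the paths in ``config``.
    When an alignment plus ``reference_classes`` (leaf -> class for labelled
    reference leaves) and ``config.outgroup`` are available, the NJ surrogate
    assigns classes and, with a reference table + ``lineage_map``, tallies
    per-lineage class counts.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "run_config.yaml")
    logger.info("run %s: family=%s", config.digest(), config.family)

    stage = "load_inputs"
    try:
        if records is None:
            if config.fasta is None:
                raise ConfigurationError("no input sequences: set fasta or pass records")
            records = read_fasta(config.fasta)
        if table is None and config.reference_table:
            table = read_reference_table(config.reference_table)
        if table:
            matched, unmatched = join_records_to_table(records, table)
            for rid in unmatched:
                logger.warning("record %s missing from reference table", rid)
        if alignment is None and config.alignment:
            alignment = read_alignment(config.alignment)

        stage = "reference_mapping"
        scheme = load_scheme(config.family, config.scheme_yaml, config.sites_tsv)
        annotate = _annotate_iglur if config.family == "iglur" else _annotate_mglur
        annotations = []
        for rec in records:
            ann = annotate(rec, scheme, config)
            if not ann.kept:
                logger.info("discarded %s by rule %s", ann.query_id, ann.discard_rule)
            annotations.append(ann)

        stage = "tree_assignment"
        clade_summary = None
        if alignment is not None and reference_classes and config.outgroup:
            dm = corrected_distances(p_distance(alignment), config.saturation_cap)
            tree = neighbor_joining(dm)
            write_newick(tree, out_dir / "nj_tree.nwk")
            clade = assign_classes(tree, reference_classes, set(config.outgroup))
            for ann in annotations:
                if ann.query_id in clade.assignments:
                    ann.class_assignment = clade.assignments[ann.query_id]
            clade_summary = {
                "assignments": clade.assignments,
                "monophyletic": clade.monophyletic,
            }
            if table and lineage_map:
                clade_summary["lineage_counts"] = {
                    f"{l}|{c}": n
                    for (l, c), n in lineage_class_counts(
                        clade, table, lineage_map
                    )["counts"].items()
                }

        stage = "summary"
        kept = [a for a in annotations if a.kept]
        summary = {
            "run_id": config.digest(),
            "family": config.family,
            "n_input": len(records),
            "n_kept": len(kept),
            "n_discarded": len(annotations) - len(kept),
        }
        if config.family == "iglur":
            calls = [
                (a.query_id,
                 LigandCall(a.ligand_category, a.ligand_confidence,
                            a.rule_trace.split(">")),
                 ChannelCall(a.qr_site, bool(a.acidic_590), bool(a.rectification_flag)))
                for a in kept
            ]
            summary["rule_counts"] = summarize_calls(calls)
        else:
            summary["mglur_binding"] = {
                k: sum(1 for a in kept if a.mglur_binding == k)
                for k in ("glutamate_competent", "glutamate_incompetent", "unknown")
            }
        if clade_summary:
            summary["clades"] = clade_summary
    except ConfigurationError:
        raise
    except Exception as exc:  # surface the failing stage; keep partial outputs
        (out_dir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise PipelineStageError(stage, exc) from exc

    _write_outputs(annotations, summary, out_dir)
    return annotations, summary


def _write_outputs(annotations: list[AnnotationRecord], summary: dict, out_dir: Path) -> None:
    rows = []
    for a in annotations:
        row = {k: v for k, v in asdict(a).items() if k not in ("residues", "warnings")}
        for site, res in sorted(a.residues.items(), key=lambda kv: int(kv[0])):
            row[f"site_{site}"] = res
        row["warnings"] = ";".join(a.warnings)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "annotations.tsv", sep="\t", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
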