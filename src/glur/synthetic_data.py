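"""Synthetic GluR-like protein families with known ground truth.

Every pipeline stage (mapping, QC, rules, screen, tree) is tested against
families generated here: a template sequence (by default the packaged
reference scheme) with rule-satisfying residues planted at diagnostic sites,
a gating motif set to an exact conservation count, an optional number of
transmembrane helices, and seeded point mutations / single-residue indels
applied outside the protected positions.

Mutations draw replacement residues from BLOSUM62-conditional weights
(``P(b|a) ∝ exp(λ·S(a,b))``, λ = 0.267) so that pairwise distances behave
like protein evolution rather than uniform noise; ``uniform=True`` switches
to uniform replacement. All randomness flows from a single
``numpy.random.default_rng(seed)`` per call — no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, RangeError
from .io_formats import AMINO_ACIDS, SequenceRecord, write_fasta
from .ligand_rules import ResidueProfile, call_channel, call_mglur_binding, call_selectivity
from .qc_filters import GATING_MOTIF
from .reference_map import ReferenceScheme, load_scheme

#: residues used when a motif position must mismatch its motif letter
_MISMATCH_POOL = "DEKR"
_POLAR_POOL = "DEKRNQSTGP"

#: layout of the planted 7TM region on the synthetic mGluR scheme
TM_START, TM_LEN, LOOP_LEN = 580, 21, 15


def _blosum_conditional() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    idx = [str(mat.alphabet).index(a) for a in AMINO_ACIDS]
    S = np.asarray(mat)[np.ix_(idx, idx)]
    W = np.exp(0.267 * S)
    np.fill_diagonal(W, 0.0)
    return W / W.sum(axis=1, keepdims=True)

_COND = _blosum_conditional()
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class FamilySpec:
    """Recipe for one synthetic receptor family."""

    class_label: str
    family: str = "iglur"  # iglur | mglur
    template: str | None = None
    scheme: ReferenceScheme | None = None
    planted_sites: dict[str, str] = field(default_factory=dict)
    motif_conserved_count: int | None = None
    n_tm_segments: int | None = None
    n_sequences: int = 10
    mutation_rate: float = 0.02
    indel_rate: float = 0.0
    seed: int = 0
    uniform: bool = False

    def __post_init__(self):
        if not 0 <= self.mutation_rate < 1 or not 0 <= self.indel_rate < 1:
            raise ConfigurationError("rates must lie in [0, 1)")
        if self.n_sequences < 1:
            raise ConfigurationError("n_sequences must be >= 1")
        if self.motif_conserved_count is not None and not 0 <= self.motif_conserved_count <= 9:
            raise ConfigurationError("motif_conserved_count must be in 0..9")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "list[FamilySpec]":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries = raw if isinstance(raw, list) else raw.get("families", [raw])
        return [cls(**e) for e in entries]


@dataclass
class TruthRecord:
    """Intended (pre-noise) properties of one generated sequence."""

    seq_id: str
    class_label: str
    ligand_category: str
    motif_count: int | None
    tm_count: int | None


@dataclass
class SyntheticTruth:
    records: dict[str, TruthRecord]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([r.__dict__ for r in self.records.values()]).to_csv(
            path, sep="\t", index=False
        )


def _build_base(spec: FamilySpec) -> tuple[list[str], set[int], ReferenceScheme]:
    """Plant sites/motif/TM layout on the template; return (base, protected, scheme)."""
    scheme = spec.scheme or load_scheme(spec.family)
    base = list(spec.template or scheme.sequence)
    protected: set[int] = set()  # 0-based indices
    for label, res in spec.planted_sites.items():
        if label not in scheme.sites:
            raise RangeError(f"planted site {label!r} not in scheme {scheme.name!r}")
        pos = scheme.sites[label]
        if pos > len(base):
            raise RangeError(f"site {label} position {pos} outside template")
        base[pos - 1] = res
    # every scheme site is part of the ground truth: protect all of them
    for pos in scheme.sites.values():
        if pos <= len(base):
            protected.add(pos - 1)
    rng = np.random.default_rng(spec.seed)
    if spec.motif_conserved_count is not None:
        if scheme.motif_anchor is None:
            raise ConfigurationError("motif_conserved_count set but scheme has no motif")
        _, start = scheme.motif_anchor
        motif = GATING_MOTIF
        if start - 1 + len(motif) > len(base):
            raise RangeError("motif window outside template")
        positions = list(range(start - 1, start - 1 + len(motif)))
        base[start - 1 : start - 1 + len(motif)] = motif
        k_break = len(motif) - spec.motif_conserved_count
        for off in rng.choice(len(motif), size=k_break, replace=False):
            pool = [c for c in _MISMATCH_POOL if c != motif[off]]
            base[positions[off]] = pool[int(rng.integers(len(pool)))]
        protected.update(positions)
    if spec.n_tm_segments is not None:
        if not 0 <= spec.n_tm_segments <= 7:
            raise ConfigurationError("n_tm_segments must be in 0..7")
        for k in range(7):
            seg0 = TM_START - 1 + k * (TM_LEN + LOOP_LEN)
            if seg0 + TM_LEN > len(base):
                raise RangeError("TM layout outside template")
            if k >= spec.n_tm_segments:  # strip this helix: polarise it
                for p in range(seg0, seg0 + TM_LEN):
                    base[p] = _POLAR_POOL[int(rng.integers(len(_POLAR_POOL)))]
            protected.update(range(seg0, seg0 + TM_LEN))
    return base, protected, scheme


def _intended_category(base: list[str], scheme: ReferenceScheme, family: str) -> str:
    residues = {lbl: base[pos - 1] for lbl, pos in scheme.sites.items() if pos <= len(base)}
    profile = ResidueProfile("template", residues, scheme.name)
    if family == "mglur":
        return call_mglur_binding(profile)
    return call_selectivity(profile).category


def _mutate(seq: list[str], protected: set[int], rate: float, rng, uniform: bool) -> list[str]:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for p in hits:
        if p in protected or out[p] not in _AA_INDEX:
            continue
        if uniform:
            choices = [a for a in AMINO_ACIDS if a != out[p]]
            out[p] = choices[int(rng.integers(len(choices)))]
        else:
            out[p] = AMINO_ACIDS[int(rng.choice(20, p=_COND[_AA_INDEX[out[p]]]))]
    return out


def _indels(seq: list[str], protected: set[int], rate: float, rng) -> list[str]:
    if rate == 0:
        return seq
    out: list[str] = []
    for p, ch in enumerate(seq):
        u = rng.random()
        if p not in protected and u < rate / 2:
            continue  # deletion
        out.append(ch)
        if p not in protected and rate / 2 <= u < rate:
            out.append(AMINO_ACIDS[int(rng.integers(20))])  # insertion after p
    return out


def generate_family(spec: FamilySpec) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Generate one family plus its ground truth; deterministic per seed."""
    base, protected, scheme = _build_base(spec)
    category = _intended_category(base, scheme, spec.family)
    motif_count = spec.motif_conserved_count
    if motif_count is None and scheme.motif_anchor is not None:
        _, start = scheme.motif_anchor
        window = "".join(base[start - 1 : start - 1 + len(GATING_MOTIF)])
        motif_count = sum(1 for q, m in zip(window, GATING_MOTIF) if q == m)
    tm_count = spec.n_tm_segments
    if tm_count is None and spec.family == "mglur":
        tm_count = 7
    rng = np.random.default_rng(spec.seed + 1)
    records, truth = [], {}
    for i in range(spec.n_sequences):
        seq = _mutate(base, protected, spec.mutation_rate, rng, spec.uniform)
        seq = _indels(seq, protected, spec.indel_rate, rng)
        sid = f"{spec.class_label}_{i + 1:03d}"
        records.append(
            SequenceRecord(
                id=sid,
                sequence="".join(seq),
                species_code="Syn",
                phylum="Synthetica",
                group_label=spec.class_label,
            )
        )
        truth[sid] = TruthRecord(sid, spec.class_label, category, motif_count, tm_count)
    return records, SyntheticTruth(truth)


def generate_decoys(
    n: int,
    length_range: tuple[int, int] = (300, 500),
    seed: int = 0,
) -> list[SequenceRecord]:
    """Composition-shuffled non-homologous decoys for screen specificity tests.

    Residues are drawn iid from the packaged iGluR reference's composition,
    so decoys match GluR amino-acid usage without any positional homology.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    template = load_scheme("iglur").sequence
    counts = np.array([template.count(a) for a in AMINO_ACIDS], dtype=float)
    freqs = counts / counts.sum()
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    out = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(AMINO_ACIDS[k] for k in rng.choice(20, size=L, p=freqs))
        out.append(SequenceRecord(id=f"decoy_{i + 1:03d}", sequence=seq,
                                  group_label="decoy"))
    return out


def make_screen_benchmark(
    seed: int = 0,
    n_planted: int = 20,
    n_decoys: int = 20,
    n_queries: int = 3,
    n_db_others: int = 40,
) -> dict:
    """Seeded benchmark for the reciprocal screen.

    Candidates are ``n_planted`` heavily diverged GluR-derived sequences
    (mutation 0.30, indel 0.02) plus ``n_decoys`` composition-shuffled
    decoys of 150–400 residues. The reciprocal database holds the GluR
    query set plus ``n_db_others`` unrelated proteins of 300–800 residues,
    so that glutamate receptors are a small minority of the database length
    — the property of the real non-redundant database that makes the
    reciprocal top-hit rule discriminative. A decoy passes the forward
    E-gate with probability ≈ the threshold (calibrated E-values), so
    rejection rests on the reciprocal step, exactly as in the two-tier
    procedure this emulates.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    queries, _ = generate_family(
        FamilySpec(class_label="Query", n_sequences=n_queries,
                   mutation_rate=0.15, seed=sub())
    )
    for q in queries:
        q.group_label = "GluR"
    planted, _ = generate_family(
        FamilySpec(class_label="Planted", n_sequences=n_planted,
                   mutation_rate=0.30, indel_rate=0.02, seed=sub())
    )
    decoys = generate_decoys(n_decoys, length_range=(150, 400), seed=sub())
    others = generate_decoys(n_db_others, length_range=(300, 800), seed=sub())
    for o in others:
        o.id = "db_" + o.id
        o.group_label = "Other"
    return {
        "candidates": planted + decoys,
        "queries": queries,
        "reciprocal_db": queries + others,
        "planted_ids": {r.id for r in planted},
        "decoy_ids": {r.id for r in decoys},
    }


#: per-lineage AMPA/Kainate query counts emulating the opposite expansions of
#: the two protostome lineages (≈4:1 in lophotrochozoans, ≈1:4 in ecdysozoans)
PROTOSTOME_COUNTS = {
    "Lophotrochozoa": {"AMPA": 40, "Kainate": 15},
    "Ecdysozoa": {"AMPA": 10, "Kainate": 40},
}

_LINEAGE_PHYLA = {
    "Lophotrochozoa": ["Mollusca", "Annelida"],
    "Ecdysozoa": ["Arthropoda", "Priapulida"],
}


def make_protostome_benchmark(
    seed: int = 0,
    counts: dict[str, dict[str, int]] | None = None,
    n_refs_per_class: int = 3,
    class_divergence: float = 0.12,
    within_class_rate: float = 0.03,
    outgroup_divergence: float = 0.25,
) -> dict:
    """Two-class (AMPA/Kainate) dataset with known classes for the NJ surrogate.

    Each class descends from its own template (``class_divergence`` mutations
    from the packaged reference); members diverge ``within_class_rate``
    further, so between-class distances cleanly exceed within-class ones.
    Two GluN1-like leaves (``outgroup_divergence`` from the base) provide the
    outgroup, as chordate NMDA1 subunits do for the protostome AMPA/Kainate
    tree. No indels are applied, so the records align column-for-column.
    """
    from .io_formats import ReferenceTableRow

    if counts is None:
        counts = PROTOSTOME_COUNTS
    rng = np.random.default_rng(seed)
    base = list(load_scheme("iglur").sequence)
    templates = {
        cls: _mutate(base, set(), class_divergence, rng, uniform=False)
        for cls in ("AMPA", "Kainate")
    }
    records, table_rows, truth = [], [], {}

    def derive(template, rate):
        return "".join(_mutate(template, set(), rate, rng, uniform=False))

    reference_classes = {}
    for cls in ("AMPA", "Kainate"):
        for i in range(n_refs_per_class):
            rid = f"ref_{cls}_{i + 1}"
            records.append(SequenceRecord(rid, derive(templates[cls], within_class_rate),
                                          group_label=cls, phylum="Chordata"))
            reference_classes[rid] = cls
            table_rows.append(ReferenceTableRow(rid, species_code="Ref",
                                                phylum="Chordata", group_label=cls))
    outgroup = set()
    for i in range(2):
        oid = f"GluN1_out{i + 1}"
        records.append(SequenceRecord(oid, derive(base, outgroup_divergence),
                                      group_label="NMDA", phylum="Chordata"))
        outgroup.add(oid)
        table_rows.append(ReferenceTableRow(oid, species_code="Out",
                                            phylum="Chordata", group_label="NMDA"))
    lineage_map = {}
    for lineage, per_class in counts.items():
        phyla = _LINEAGE_PHYLA.get(lineage, [lineage])
        for ph in phyla:
            lineage_map[ph] = lineage
        k = 0
        for cls, n in per_class.items():
            for i in range(n):
                qid = f"q_{lineage[:5]}_{cls}_{i + 1:03d}"
                phylum = phyla[k % len(phyla)]
                k += 1
                records.append(SequenceRecord(qid, derive(templates[cls], within_class_rate),
                                              phylum=phylum))
                truth[qid] = cls
                table_rows.append(ReferenceTableRow(qid, species_code="Syn",
                                                    phylum=phylum, group_label=""))
    return {
        "records": records,
        "reference_classes": reference_classes,
        "outgroup": outgroup,
        "truth": truth,
        "table": table_rows,
        "lineage_map": lineage_map,
    }


def write_family(records: list[SequenceRecord], truth: SyntheticTruth,
                 fasta_path: str | Path, truth_path: str | Path) -> None:
    write_fasta(records, fasta_path)
    truth.to_tsv(truth_path)
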