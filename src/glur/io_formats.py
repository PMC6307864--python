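"""Readers and writers for the formats the pipeline touches.

FASTA and aligned FASTA are parsed through Biopython's SeqIO/AlignIO and then
validated against the pipeline's stricter contracts (unique ids, amino-acid
alphabet, rectangular alignments); the reference table is a TSV read through
pandas. Newick output is produced directly from the tree surrogate's node
structure.

Conventions
-----------
* Output FASTA wraps at 60 columns; unwrapped input is accepted.
* ``'*'`` stop characters are stripped with a logged warning (deposited
  alignments of translated gene models may include them).
* ``'/'`` is a legal id character (names such as ``GluN2/3_Nve``); the id is
  the full first whitespace-delimited header token.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    DuplicateIdError,
    FastaFormatError,
    SchemaError,
    SequenceCharacterError,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: letters legal in a (possibly gapped) pipeline sequence
ALLOWED_LETTERS = frozenset(AMINO_ACIDS + "X-")


@dataclass
class SequenceRecord:
    """One protein sequence plus the metadata the pipeline tracks.

    ``sequence`` may be gapped (alignment member) or ungapped; the ungapped
    content is restricted to the 20 amino-acid letters plus ``X``.
    """

    id: str
    sequence: str
    species_code: str = ""
    phylum: str = ""
    group_label: str = ""
    description: str = ""

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MultipleAlignment:
    """A rectangular protein alignment (gapped records of equal length)."""

    records: list[SequenceRecord]
    n_columns: int = field(init=False)

    def __post_init__(self):
        if len(self.records) < 2:
            raise AlignmentShapeError(
                self.records[0].id if self.records else "<empty>", 0, 0
            )
        width = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != width:
                raise AlignmentShapeError(rec.id, width, len(rec.sequence))
        self.n_columns = width

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)


@dataclass
class ReferenceTableRow:
    """One row of the project metadata table (protein -> species/phylum/group)."""

    protein_name: str
    species: str = ""
    species_code: str = ""
    phylum: str = ""
    group_label: str = ""
    accession: str = ""


def _validate_letters(record_id: str, seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in ALLOWED_LETTERS:
            raise SequenceCharacterError(record_id, ch, i + 1)


def _records_from_seqio(path: Path) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning("stripping %d '*' character(s) from %s", seq.count("*"), rec.id)
            seq = seq.replace("*", "")
        if rec.id in seen:
            raise DuplicateIdError(rec.id)
        seen.add(rec.id)
        _validate_letters(rec.id, seq)
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        records.append(
            SequenceRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into validated :class:`SequenceRecord` objects.

    The id is the header token up to the first whitespace; the full header is
    preserved in ``description``. Raises :class:`FastaFormatError` on an empty
    file, :class:`DuplicateIdError` on repeated ids and
    :class:`SequenceCharacterError` on letters outside the alphabet.
    """
    path = Path(path)
    records = _records_from_seqio(path)
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    # The header syntax of deposited files varies; log what we actually saw.
    logger.debug("read %d records from %s; first header: %r",
                 len(records), path, records[0].description)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file; all records must have equal gapped length."""
    records = read_fasta(path)
    return MultipleAlignment(records)


def write_alignment(alignment: MultipleAlignment, path: str | Path, wrap: int = 60) -> None:
    write_fasta(alignment.records, path, wrap=wrap)


def write_phylip(alignment: MultipleAlignment, path: str | Path) -> None:
    """Relaxed PHYLIP export for external ML/Bayesian tools."""
    with open(path, "w") as fh:
        fh.write(f" {len(alignment.records)} {alignment.n_columns}\n")
        for rec in alignment.records:
            fh.write(f"{rec.id}  {rec.sequence}\n")


REQUIRED_TABLE_COLUMNS = ["protein_name", "species_code", "phylum", "group_label"]
OPTIONAL_TABLE_COLUMNS = ["species", "accession"]


def read_reference_table(path: str | Path) -> list[ReferenceTableRow]:
    """Read the TSV metadata table mapping protein names to species/phylum/group.

    Requires columns ``protein_name``, ``species_code``, ``phylum``,
    ``group_label``; ``species`` and ``accession`` are optional. Missing cells
    become empty strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing)
    rows = []
    for _, r in df.iterrows():
        rows.append(
            ReferenceTableRow(
                protein_name=str(r["protein_name"]).strip(),
                species=str(r.get("species", "")).strip(),
                species_code=str(r["species_code"]).strip(),
                phylum=str(r["phylum"]).strip(),
                group_label=str(r["group_label"]).strip(),
                accession=str(r.get("accession", "")).strip(),
            )
        )
    return rows


def join_records_to_table(
    records: list[SequenceRecord], table: list[ReferenceTableRow]
) -> tuple[list[SequenceRecord], list[str]]:
    """Annotate records in place from the reference table by exact protein_name.

    Matching is by exact id == protein_name after whitespace trimming.
    Returns ``(matched_records, unmatched_ids)``; unmatched records are
    reported, never silently dropped.
    """
    by_name = {row.protein_name: row for row in table}
    matched, unmatched = [], []
    for rec in records:
        row = by_name.get(rec.id.strip())
        if row is None:
            unmatched.append(rec.id)
            continue
        rec.species_code = row.species_code
        rec.phylum = row.phylum
        rec.group_label = row.group_label
        matched.append(rec)
    if unmatched:
        logger.warning("%d record(s) not found in reference table: %s",
                       len(unmatched), ", ".join(unmatched[:10]))
    return matched, unmatched


def write_newick(tree, path: str | Path) -> None:
    """Write a :class:`~glur.tree_surrogate.PhyloTree` as a Newick file."""
    from .tree_surrogate import newick_string  # local import: avoid cycle

    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")
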