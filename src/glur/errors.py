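"""Typed exceptions raised across the pipeline.

Every parser and stage raises one of these instead of a bare ValueError so
that the orchestrator can surface the failing stage and the offending record.
"""


class GlurError(Exception):
    """Base class for all package errors."""


class FastaFormatError(GlurError):
    """Malformed or empty FASTA input."""


class DuplicateIdError(GlurError):
    """Two records share an id within one collection."""

    def __init__(self, record_id: str):
        self.record_id = record_id
        super().__init__(f"duplicate sequence id: {record_id!r}")


class SequenceCharacterError(GlurError):
    """A residue letter outside the amino-acid alphabet (plus X and gap)."""

    def __init__(self, record_id: str, char: str, position: int):
        self.record_id = record_id
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"illegal character {char!r} at position {position} in record {record_id!r}"
        )


class AlignmentShapeError(GlurError):
    """Ragged aligned FASTA: a record's gapped length differs from the rest."""

    def __init__(self, record_id: str, expected: int, got: int):
        self.record_id = record_id
        super().__init__(
            f"record {record_id!r} has {got} columns, expected {expected}"
        )


class SchemaError(GlurError):
    """A tabular input is missing required columns."""

    def __init__(self, missing: list):
        self.missing = list(missing)
        super().__init__(f"missing required column(s): {', '.join(self.missing)}")


class LabelError(GlurError):
    """Duplicate or missing leaf labels on a tree."""


class ConfigurationError(GlurError):
    """Invalid configuration value (unknown matrix, bad threshold, ...)."""


class RangeError(GlurError):
    """A position lies outside the sequence or template it indexes."""


class SaturationError(GlurError):
    """A p-distance beyond the domain of the distance correction."""

    def __init__(self, p: float):
        self.p = p
        super().__init__(f"p-distance {p:.4f} >= 0.85 saturates the Kimura correction")


class IncomparablePairError(GlurError):
    """Two aligned rows share no ungapped column."""

    def __init__(self, id_a: str, id_b: str):
        self.pair = (id_a, id_b)
        super().__init__(f"no comparable columns between {id_a!r} and {id_b!r}")


class NamingError(GlurError):
    """Invalid component passed to the protein-name composer."""


class JoinError(GlurError):
    """Records could not be joined to the reference table."""

    def __init__(self, ids: list):
        self.ids = list(ids)
        super().__init__(f"ids missing from reference table: {', '.join(self.ids)}")


class PipelineStageError(GlurError):
    """Wraps a typed error with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
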