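"""Sequence-quality filters.

Two filters gate entry into the phylogenetic analysis:

* iGluR candidates must conserve at least 4 of the 9 residues of the
  channel-gating SYTANLAAF motif ("less than four conserved" is discarded);
* mGluR candidates must present at least 6 of the 7 transmembrane helices
  ("lacking two or more" is discarded), counted with a Kyte–Doolittle
  hydropathy sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import RangeError
from .io_formats import SequenceRecord
from .reference_map import SiteAssignment

GATING_MOTIF = "SYTANLAAF"

#: residues treated as interchangeable when similarity-group counting is on
SIMILARITY_GROUPS = [
    set("AGST"), set("ILVM"), set("FYW"), set("DE"), set("KRH"), set("NQ"), set("C"), set("P"),
]


@dataclass
class MotifReport:
    """Per-query conservation of the gating motif."""

    query_id: str
    conserved_count: int
    flags: list[bool]
    location_method: str  # "mapped" | "scan"
    observed: str

    def __post_init__(self):
        assert self.conserved_count == sum(self.flags)


@dataclass
class TMReport:
    """Transmembrane segments detected on one query."""

    query_id: str
    n_segments: int
    segments: list[tuple[int, int]]  # 1-based inclusive residue spans
    window: int
    threshold: float


def _match(q: str, m: str, similarity: bool) -> bool:
    if q == m:
        return True
    if similarity:
        return any(q in g and m in g for g in SIMILARITY_GROUPS)
    return False


def _scan_motif(sequence: str, motif: str, similarity: bool) -> tuple[int, list[bool], str]:
    """Best sliding-window identity of ``motif`` against an ungapped query."""
    best = (-1, [False] * len(motif), "-" * len(motif))
    L = len(motif)
    if len(sequence) < L:
        window = sequence.ljust(L, "-")
        flags = [_match(window[k], motif[k], similarity) for k in range(L)]
        return sum(flags), flags, window
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        flags = [_match(window[k], motif[k], similarity) for k in range(L)]
        count = sum(flags)
        if count > best[0]:
            best = (count, flags, window)
    return best


def motif_conservation(
    assignment: SiteAssignment,
    query: SequenceRecord | None = None,
    motif: str = GATING_MOTIF,
    similarity: bool = False,
) -> MotifReport:
    """Count conserved gating-motif residues for a mapped query.

    Conservation is positional: the query residue aligned to each motif
    column must equal the motif letter (identity by default; residue
    similarity groups behind ``similarity=True``). When the mapped motif
    region is entirely gapped — a fragmented query — a sliding-window scan
    over the raw query maximising motif identity is used instead and the
    report is flagged ``location_method="scan"``.
    """
    mapped = assignment.motif_residues
    if mapped is not None and any(c != "-" for c in mapped):
        flags = [_match(mapped[k], motif[k], similarity) for k in range(len(motif))]
        return MotifReport(assignment.query_id, sum(flags), flags, "mapped", mapped)
    if query is None:
        flags = [False] * len(motif)
        return MotifReport(assignment.query_id, 0, flags, "mapped", "-" * len(motif))
    count, flags, window = _scan_motif(query.ungapped, motif, similarity)
    return MotifReport(assignment.query_id, count, flags, "scan", window)


def iglur_qc(report: MotifReport, min_conserved: int = 4) -> str:
    """``"keep"`` iff at least ``min_conserved`` motif residues are conserved."""
    return "keep" if report.conserved_count >= min_conserved else "discard"


def hydropathy_profile(sequence: str, window: int = 19) -> np.ndarray:
    """Sliding-window mean Kyte–Doolittle hydropathy.

    ``X`` scores 0.0. Output value ``i`` covers residues ``i..i+window-1``
    (0-based); length is ``len(sequence) - window + 1``.
    """
    if len(sequence) < window:
        raise RangeError(
            f"sequence length {len(sequence)} shorter than window {window}"
        )
    values = np.array([KYTE_DOOLITTLE.get(ch, 0.0) for ch in sequence])
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def detect_tm_segments(
    profile: np.ndarray,
    threshold: float = 1.6,
    min_gap: int = 5,
    window: int = 19,
    query_id: str = "",
) -> TMReport:
    """Segment the hydropathy profile into putative transmembrane helices.

    Maximal runs of windows at or above ``threshold`` become segments; runs
    whose window-index gap is smaller than ``min_gap`` merge into one.
    Window runs are converted back to 1-based inclusive residue spans.
    """
    above = np.asarray(profile) >= threshold
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    segments = [(s + 1, e + window) for s, e in merged]
    return TMReport(query_id, len(segments), segments, window, threshold)


def count_tm_segments(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_gap: int = 5,
    query_id: str = "",
) -> TMReport:
    """Convenience wrapper: hydropathy profile + segment detection."""
    if len(sequence) < window:
        return TMReport(query_id, 0, [], window, threshold)
    profile = hydropathy_profile(sequence, window)
    return detect_tm_segments(profile, threshold, min_gap, window, query_id)


def mglur_qc(report: TMReport, required_min: int = 6) -> str:
    """``"keep"`` iff at least ``required_min`` of the 7 TM helices are present.

    Lacking two or more helices (≤ 5 detected) discards the sequence.
    """
    return "keep" if report.n_segments >= required_min else "discard"
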