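"""Reciprocal-homology candidate screen.

The screen mirrors the two-tier identification procedure used for receptor
discovery: a forward similarity search of each candidate against a set of
known glutamate-receptor queries with an E-value gate at 0.05, followed by a
reciprocal search against a labelled protein database; the candidate is
accepted only when the reciprocal *top hit* is itself labelled a glutamate
receptor.

Tier 1 runs entirely on the in-house Smith–Waterman backend so it is
testable without external search engines; tier 2 (searches of genome or
transcriptome assemblies by an external engine) is supported by feeding the
engine's 12-column tabular output through :class:`TabularBackend` — the
decision logic is identical.

E-values follow the Karlin–Altschul formula ``E = K·m·n·exp(-λ·S)`` with the
standard gapped-BLOSUM62 constants λ=0.267, K=0.041 by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_formats import SequenceRecord
from .reference_map import _gotoh, _load_matrix

logger = logging.getLogger(__name__)

GAPPED_BLOSUM62_LAMBDA = 0.267
GAPPED_BLOSUM62_K = 0.041


@dataclass
class SearchHit:
    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    subject_label: str = ""


@dataclass
class ScreenDecision:
    """One candidate's fate in the reciprocal screen."""

    candidate_id: str
    forward_evalue: float
    forward_best_query: str
    reciprocal_top_hit: str
    reciprocal_top_label: str
    accepted: bool
    tier: int


def smith_waterman(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[float, tuple[str, str]]:
    """Optimal local alignment score under affine gaps; score is >= 0.

    Returns ``(raw_score, (aligned_a, aligned_b))``; the alignment is empty
    when no positive-scoring local alignment exists.
    """
    if not a or not b:
        raise ConfigurationError("smith_waterman requires two non-empty sequences")
    mat = _load_matrix(matrix)
    M, X, Y, S = _gotoh(a, b, mat, gap_open, gap_extend, local=True)
    best = float(M[1:, 1:].max()) if min(len(a), len(b)) else 0.0
    if best <= 0:
        return 0.0, ("", "")
    i, j = np.unravel_index(int(np.argmax(M[1:, 1:])), M[1:, 1:].shape)
    i, j = int(i) + 1, int(j) + 1
    out_a, out_b = [], []
    tol = 1e-6
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            if M[i, j] <= tol:
                break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if abs(target) < tol:
                break
            cand = (M[i, j], X[i, j], Y[i, j])
            state = int(np.argmax([c if abs(c - target) < tol else -1e30 for c in cand]))
        elif state == 1:
            out_a.append("-")
            out_b.append(b[j - 1])
            if j > 1 and abs(X[i, j] - (X[i, j - 1] - gap_extend)) < tol:
                j -= 1
            else:
                target = X[i, j] + gap_open + gap_extend
                j -= 1
                cand = (M[i, j], -1e30, Y[i, j])
                state = int(np.argmax([c if abs(c - target) < tol else -1e30 for c in cand]))
        else:
            out_a.append(a[i - 1])
            out_b.append("-")
            if i > 1 and abs(Y[i, j] - (Y[i - 1, j] - gap_extend)) < tol:
                i -= 1
            else:
                target = Y[i, j] + gap_open + gap_extend
                i -= 1
                cand = (M[i, j], X[i, j], -1e30)
                state = int(np.argmax([c if abs(c - target) < tol else -1e30 for c in cand]))
    return best, ("".join(reversed(out_a)), "".join(reversed(out_b)))


def sw_score(a: str, b: str, matrix="BLOSUM62", gap_open=11.0, gap_extend=1.0) -> float:
    """Local alignment score only (skips traceback; used by the screen loop)."""
    mat = _load_matrix(matrix) if isinstance(matrix, str) else matrix
    M, _, _, _ = _gotoh(a, b, mat, gap_open, gap_extend, local=True)
    return max(0.0, float(M.max()))


def karlin_evalue(
    raw_score: float,
    m: int,
    n: int,
    lam: float = GAPPED_BLOSUM62_LAMBDA,
    K: float = GAPPED_BLOSUM62_K,
) -> float:
    """Karlin–Altschul expectation: ``E = K · m · n · exp(-λ · S)``."""
    if lam <= 0 or K <= 0 or m < 1 or n < 1:
        raise ConfigurationError("karlin_evalue requires positive lambda, K, m, n")
    return K * m * n * math.exp(-lam * raw_score)


def bit_score(raw_score: float, lam: float = GAPPED_BLOSUM62_LAMBDA,
              K: float = GAPPED_BLOSUM62_K) -> float:
    return (lam * raw_score - math.log(K)) / math.log(2)


def _sort_hits(hits: list[SearchHit]) -> list[SearchHit]:
    return sorted(hits, key=lambda h: (h.evalue, -h.bit_score, h.subject_id))


class InHouseBackend:
    """Similarity search over an in-memory protein set via Smith–Waterman."""

    def __init__(self, matrix: str = "BLOSUM62", gap_open: float = 11.0,
                 gap_extend: float = 1.0, lam: float = GAPPED_BLOSUM62_LAMBDA,
                 K: float = GAPPED_BLOSUM62_K):
        self.matrix = _load_matrix(matrix)
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.lam = lam
        self.K = K

    def search(self, query: SequenceRecord, db: list[SequenceRecord],
               exclude_self: bool = True) -> list[SearchHit]:
        """All hits of ``query`` against ``db``, best E-value first."""
        if not db:
            raise ConfigurationError("search database is empty")
        n_db = sum(len(rec.ungapped) for rec in db)
        hits = []
        q = query.ungapped
        for rec in db:
            if exclude_self and rec.id == query.id:
                continue
            s = sw_score(q, rec.ungapped, self.matrix, self.gap_open, self.gap_extend)
            hits.append(
                SearchHit(
                    query_id=query.id,
                    subject_id=rec.id,
                    raw_score=s,
                    bit_score=bit_score(s, self.lam, self.K),
                    evalue=karlin_evalue(s, len(q), n_db, self.lam, self.K),
                    subject_label=rec.group_label,
                )
            )
        return _sort_hits(hits)


#: 12 columns of the standard tabular search-report format
TABULAR_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class TabularBackend:
    """Adapter over an external engine's 12-column tabular hit report.

    ``labels`` maps subject id -> label ("GluR" or other); unknown subjects
    get an empty label and therefore never count as glutamate receptors.
    """

    def __init__(self, hits_path, labels: dict[str, str]):
        df = pd.read_csv(hits_path, sep="\t", header=None, names=TABULAR_COLUMNS)
        self.labels = labels
        self._hits: dict[str, list[SearchHit]] = {}
        for _, r in df.iterrows():
            hit = SearchHit(
                query_id=str(r["query"]),
                subject_id=str(r["subject"]),
                raw_score=float(r["bitscore"]),
                bit_score=float(r["bitscore"]),
                evalue=float(r["evalue"]),
                subject_label=labels.get(str(r["subject"]), ""),
            )
            self._hits.setdefault(hit.query_id, []).append(hit)

    def search(self, query: SequenceRecord, db=None, exclude_self: bool = True) -> list[SearchHit]:
        hits = [h for h in self._hits.get(query.id, [])
                if not (exclude_self and h.subject_id == query.id)]
        return _sort_hits(hits)


def reciprocal_screen(
    candidates: list[SequenceRecord],
    query_set: list[SequenceRecord],
    reciprocal_db: list[SequenceRecord],
    e_threshold: float = 0.05,
    backend=None,
    reciprocal_backend=None,
    glur_label: str = "GluR",
    tier: int = 1,
) -> list[ScreenDecision]:
    """Run the two-step reciprocal screen over a candidate list.

    For each candidate the best forward E-value against ``query_set`` is
    recorded; only candidates passing the gate (E < ``e_threshold``) go to
    the reciprocal search, and acceptance requires the reciprocal top hit
    (self-hits excluded, ties broken by bit score then subject id) to carry
    ``glur_label``.
    """
    if not reciprocal_db:
        raise ConfigurationError("reciprocal database is empty")
    if backend is None:
        backend = InHouseBackend()
    if reciprocal_backend is None:
        reciprocal_backend = backend
    decisions = []
    for cand in candidates:
        fwd = backend.search(cand, query_set, exclude_self=True)
        best = fwd[0] if fwd else None
        fwd_e = best.evalue if best else math.inf
        if best is None or fwd_e >= e_threshold:
            decisions.append(
                ScreenDecision(cand.id, fwd_e, best.subject_id if best else "",
                               "", "", accepted=False, tier=tier)
            )
            continue
        rec_hits = reciprocal_backend.search(cand, reciprocal_db, exclude_self=True)
        top = rec_hits[0] if rec_hits else None
        if top is not None and len(rec_hits) > 1 and rec_hits[1].evalue == top.evalue:
            logger.info("reciprocal tie for %s broken by bit score/id: %s over %s",
                        cand.id, top.subject_id, rec_hits[1].subject_id)
        accepted = top is not None and top.subject_label == glur_label
        decisions.append(
            ScreenDecision(
                candidate_id=cand.id,
                forward_evalue=fwd_e,
                forward_best_query=best.subject_id,
                reciprocal_top_hit=top.subject_id if top else "",
                reciprocal_top_label=top.subject_label if top else "",
                accepted=accepted,
                tier=tier,
            )
        )
    return decisions


def write_decisions_tsv(decisions: list[ScreenDecision], path) -> None:
    pd.DataFrame([d.__dict__ for d in decisions]).to_csv(path, sep="\t", index=False)
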