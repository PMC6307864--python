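"""Reference-position mapping.

The residue rules downstream are written against fixed positions on two
reference proteins: the mature AMPA-receptor subunit GluA2 (iGluR scheme,
signal peptide removed, so e.g. the Q/R site is position 586) and mGluR1
(mGluR scheme, positions 78 and 409). Each query is globally aligned to the
scheme's reference sequence with an affine-gap Needleman–Wunsch aligner and
the residues sitting on the diagnostic columns are read off.

The shipped scheme sequences are synthetic stand-ins: deterministic
backgrounds with the field's diagnostic residues planted at the canonical
mature-numbering positions (see ``glur/data/*_synthetic.yaml``). Real
reference sequences can be supplied via :func:`load_scheme`'s override
arguments.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, RangeError
from .io_formats import MultipleAlignment, SequenceRecord

NEG_INF = -1e30


def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise ConfigurationError(f"unknown substitution matrix {name!r}") from exc


def _encode(seq: str, alphabet: str) -> np.ndarray:
    lookup = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lookup[ord(ch)] = i
    codes = lookup[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ConfigurationError(f"residue {bad!r} not in substitution matrix alphabet")
    return codes


def _score_grid(a: str, b: str, matrix) -> np.ndarray:
    alpha = str(matrix.alphabet)
    ca, cb = _encode(a, alpha), _encode(b, alpha)
    mat = np.asarray(matrix, dtype=np.float64)
    return mat[np.ix_(ca, cb)]


def _gotoh(a: str, b: str, matrix, gap_open: float, gap_extend: float, local: bool):
    """Affine-gap dynamic programme (Gotoh), row-vectorised.

    A gap of length L costs ``gap_open + gap_extend * L`` (NCBI convention).
    Returns the three state matrices plus the pairwise score grid.
    """
    m, n = len(a), len(b)
    S = _score_grid(a, b, matrix)
    M = np.full((m + 1, n + 1), NEG_INF)
    X = np.full((m + 1, n + 1), NEG_INF)  # gap in a (consumes b)
    Y = np.full((m + 1, n + 1), NEG_INF)  # gap in b (consumes a)
    j_idx = np.arange(n + 1, dtype=np.float64)
    if local:
        M[0, :] = 0.0
        M[:, 0] = 0.0
    else:
        M[0, 0] = 0.0
        X[0, 1:] = -(gap_open + gap_extend * j_idx[1:])
        Y[1:, 0] = -(gap_open + gap_extend * np.arange(1, m + 1))
    for i in range(1, m + 1):
        H_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        if local:
            diag = np.maximum(H_prev[:-1], 0.0)
        else:
            diag = H_prev[:-1]
        M[i, 1:] = S[i - 1] + diag
        Y[i, 1:] = np.maximum(
            H_prev[1:] - gap_open - gap_extend,
            Y[i - 1, 1:] - gap_extend,
        )
        # X[i,j] = max_{k<j} ( max(M,Y)[i,k] - gap_open - gap_extend*(j-k) )
        G = np.maximum(M[i], Y[i])
        if not local:
            G[0] = max(G[0], -(gap_open + gap_extend * i) if i else 0.0)
        run = np.maximum.accumulate(G + gap_extend * j_idx)
        X[i, 1:] = run[:-1] - gap_open - gap_extend * j_idx[1:]
    return M, X, Y, S


def _traceback_global(a, b, M, X, Y, gap_open, gap_extend, S):
    i, j = len(a), len(b)
    vals = (M[i, j], X[i, j], Y[i, j])
    state = int(np.argmax(vals))
    out_a, out_b = [], []
    tol = 1e-6
    while i > 0 or j > 0:
        if i == 0:
            state = 1
        elif j == 0:
            state = 2
        if state == 0:  # match state
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            cand = (M[i, j], X[i, j], Y[i, j])
            state = int(np.argmax([c if abs(c - target) < tol else NEG_INF for c in cand]))
        elif state == 1:  # gap in a
            out_a.append("-")
            out_b.append(b[j - 1])
            if abs(X[i, j] - (X[i, j - 1] - gap_extend)) < tol and j > 1:
                j -= 1
            else:
                target = X[i, j] + gap_open + gap_extend
                j -= 1
                cand = (M[i, j], NEG_INF, Y[i, j])
                state = int(np.argmax([c if abs(c - target) < tol else NEG_INF for c in cand]))
        else:  # gap in b
            out_a.append(a[i - 1])
            out_b.append("-")
            if abs(Y[i, j] - (Y[i - 1, j] - gap_extend)) < tol and i > 1:
                i -= 1
            else:
                target = Y[i, j] + gap_open + gap_extend
                i -= 1
                cand = (M[i, j], X[i, j], NEG_INF)
                state = int(np.argmax([c if abs(c - target) < tol else NEG_INF for c in cand]))
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def needleman_wunsch(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment of two ungapped protein strings.

    Affine gap cost: a gap of length L costs ``gap_open + gap_extend*L``.
    Returns ``(aligned_a, aligned_b, score)``.
    """
    if not a or not b:
        raise ConfigurationError("needleman_wunsch requires two non-empty sequences")
    if "-" in a or "-" in b:
        raise ConfigurationError("input sequences must be ungapped")
    mat = _load_matrix(matrix)
    M, X, Y, S = _gotoh(a, b, mat, gap_open, gap_extend, local=False)
    score = float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))
    aligned_a, aligned_b = _traceback_global(a, b, M, X, Y, gap_open, gap_extend, S)
    return aligned_a, aligned_b, score


# ---------------------------------------------------------------------------
# Reference schemes


@dataclass
class ReferenceScheme:
    """A reference protein plus its named diagnostic sites.

    ``sites`` maps a site label (e.g. ``"653"``) to a 1-based position in the
    (mature) reference sequence. ``motif_anchor`` locates the channel-gating
    SYTANLAAF motif on the iGluR scheme; ``tm_span`` brackets the
    seven-transmembrane region on the mGluR scheme.
    """

    name: str
    sequence: str
    sites: dict[str, int]
    motif_anchor: tuple[str, int] | None = None
    tm_span: tuple[int, int] | None = None
    description: str = ""

    def __post_init__(self):
        L = len(self.sequence)
        for label, pos in self.sites.items():
            if not 1 <= pos <= L:
                raise RangeError(f"site {label} position {pos} outside 1..{L}")
        if len(set(self.sites)) != len(self.sites):
            raise ConfigurationError("site labels must be unique")

    def site_residue(self, label: str) -> str:
        return self.sequence[self.sites[label] - 1]


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("glur") / "data" / name))


SCHEME_FILES = {
    "iglur": "iglur_glua2_synthetic.yaml",
    "mglur": "mglur_mglur1_synthetic.yaml",
}


def load_scheme(
    family: str,
    scheme_yaml: str | Path | None = None,
    sites_tsv: str | Path | None = None,
) -> ReferenceScheme:
    """Load a packaged reference scheme (``"iglur"`` or ``"mglur"``).

    ``scheme_yaml`` replaces the packaged scheme wholesale; ``sites_tsv``
    (columns ``label``, ``position``) overrides just the site table.
    """
    if scheme_yaml is None:
        if family not in SCHEME_FILES:
            raise ConfigurationError(f"unknown receptor family {family!r}")
        scheme_yaml = _data_path(SCHEME_FILES[family])
    with open(scheme_yaml) as fh:
        raw = yaml.safe_load(fh)
    sites = {str(k): int(v) for k, v in raw["sites"].items()}
    if sites_tsv is not None:
        df = pd.read_csv(sites_tsv, sep="\t", dtype={"label": str, "position": int})
        sites = {str(r.label): int(r.position) for r in df.itertuples()}
    motif = raw.get("motif")
    tm = raw.get("tm_span")
    return ReferenceScheme(
        name=raw["name"],
        sequence="".join(raw["sequence"].split()),
        sites=sites,
        motif_anchor=(motif["label"], int(motif["start"])) if motif else None,
        tm_span=(int(tm[0]), int(tm[1])) if tm else None,
        description=raw.get("description", ""),
    )


@dataclass
class SiteAssignment:
    """Query residues observed at each of a scheme's diagnostic sites.

    ``residues[label]`` is the query letter aligned to the reference site, or
    ``'-'`` when the query has a gap there. ``motif_residues`` is the
    9-character query slice under the motif anchor (iGluR scheme only).
    """

    query_id: str
    scheme_name: str
    residues: dict[str, str]
    alignment_score: float
    coverage: float
    motif_residues: str | None = None
    low_homology: bool = False

    def residue(self, label: str) -> str:
        return self.residues.get(str(label), "-")


def map_reference_sites(
    query: SequenceRecord,
    scheme: ReferenceScheme,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    coverage_floor: float = 0.30,
) -> SiteAssignment:
    """Globally align ``query`` to the scheme reference and read off its sites.

    Coverage is the fraction of reference positions aligned to a non-gap
    query residue; below ``coverage_floor`` the assignment is flagged
    ``low_homology`` (a warning, not an error).
    """
    aligned_q, aligned_r, score = needleman_wunsch(
        query.ungapped, scheme.sequence, matrix, gap_open, gap_extend
    )
    # reference position (1-based) -> query residue or '-'
    ref_to_query: dict[int, str] = {}
    rpos = 0
    for qc, rc in zip(aligned_q, aligned_r):
        if rc != "-":
            rpos += 1
            ref_to_query[rpos] = qc if qc != "-" else "-"
    n_ref = len(scheme.sequence)
    covered = sum(1 for p in range(1, n_ref + 1) if ref_to_query.get(p, "-") != "-")
    coverage = covered / n_ref
    residues = {label: ref_to_query.get(pos, "-") for label, pos in scheme.sites.items()}
    motif_res = None
    if scheme.motif_anchor is not None:
        label, start = scheme.motif_anchor
        motif_res = "".join(
            ref_to_query.get(start + k, "-") for k in range(len(label))
        )
    return SiteAssignment(
        query_id=query.id,
        scheme_name=scheme.name,
        residues=residues,
        alignment_score=score,
        coverage=coverage,
        motif_residues=motif_res,
        low_homology=coverage < coverage_floor,
    )


def column_for_reference_position(
    alignment: MultipleAlignment, reference_id: str, position: int
) -> int:
    """0-based alignment column holding the reference row's ``position``-th residue.

    ``position`` is a 1-based index into the ungapped reference row (mature
    numbering when the reference row is the mature sequence).
    """
    row = alignment.get(reference_id)
    count = 0
    for col, ch in enumerate(row.sequence):
        if ch != "-":
            count += 1
            if count == position:
                return col
    raise RangeError(
        f"position {position} beyond ungapped length {count} of {reference_id!r}"
    )
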