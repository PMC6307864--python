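"""Independent brute-force oracles used by the alignment tests.

These enumerate the alignment space directly (no dynamic programming, no
shared code with the implementation under test).
"""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(x: str, y: str) -> float:
    return float(_B62[x, y])


def brute_global(a: str, b: str, open_: float = 11.0, ext: float = 1.0) -> float:
    """Best global affine-gap score by exhaustive enumeration of alignments.

    A gap run of length L costs ``open_ + ext * L``; a run is broken by any
    column that does not extend it (including a gap in the other sequence).
    """
    best = [float("-inf")]

    def rec(i, j, score, gap_a, gap_b):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + blosum62(a[i], b[j]), False, False)
        if j < len(b):  # gap in a, consuming b[j]
            cost = ext if gap_a else open_ + ext
            rec(i, j + 1, score - cost, True, False)
        if i < len(a):  # gap in b, consuming a[i]
            cost = ext if gap_b else open_ + ext
            rec(i + 1, j, score - cost, False, True)

    rec(0, 0, 0.0, False, False)
    return best[0]


def brute_local(a: str, b: str, open_: float = 11.0, ext: float = 1.0) -> float:
    """Best local affine-gap score: max global score over all substring pairs."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    s = brute_global(a[i0:i1], b[j0:j1], open_, ext)
                    if s > best:
                        best = s
    return best


def all_words(alphabet: str, max_len: int):
    """Every word over ``alphabet`` of length 1..max_len."""
    words = [""]
    for _ in range(max_len):
        words = [w + c for w in words for c in alphabet] + words
    return sorted({w for w in words if w}, key=lambda w: (len(w), w))
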