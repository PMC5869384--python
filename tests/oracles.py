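"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method available —
exhaustive dynamic programming, hand-coded translation tables, set
enumeration — without calling the library's own implementations.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def local_affine_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Exhaustive Gotoh local alignment score: gap of length g costs
    gap_open + (g-1)*gap_extend."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def global_affine_identity(a: str, b: str) -> float:
    """Identity via a tiny exhaustive global aligner (for short sequences):
    enumerate all alignments is infeasible, so use Needleman-Wunsch-Gotoh DP
    with traceback and count identities / shorter length."""
    n, m = len(a), len(b)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = max(H[0][j - 1] - 11, E[0][j - 1] - 1)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = max(H[i - 1][0] - 11, F[i - 1][0] - 1)
        H[i][0] = F[i][0]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - 11, E[i][j - 1] - 1)
            F[i][j] = max(H[i - 1][j] - 11, F[i - 1][j] - 1)
            H[i][j] = max(H[i - 1][j - 1] + _B62[a[i - 1], b[j - 1]], E[i][j], F[i][j])
    # traceback (greedy through the recurrences)
    i, j, ident = n, m, 0
    while i > 0 and j > 0:
        if H[i][j] == H[i - 1][j - 1] + _B62[a[i - 1], b[j - 1]]:
            if a[i - 1] == b[j - 1]:
                ident += 1
            i, j = i - 1, j - 1
        elif H[i][j] == E[i][j]:
            j -= 1
        else:
            i -= 1
    return ident / min(n, m)


# hand-coded standard genetic code
CODON_TABLE = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    CODON_TABLE[_b1 + _b2 + _b3] = _AA[_i]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def _translate_codon(codon: str) -> str:
    if "N" not in codon:
        return CODON_TABLE[codon]
    options = {CODON_TABLE["".join(c)] for c in
               itertools.product(*[("ACGT" if x == "N" else x) for x in codon])}
    if len(options) == 1:
        return options.pop()
    return "X"


def six_frame_orfs(contig: str, min_len_aa: int = 40):
    """All maximal stop-free stretches >= min_len_aa in all six frames.

    Returns a set of (frame, start, end, aa_seq, is_complete) tuples with
    forward-strand 0-based half-open nt spans.
    """
    contig = contig.upper()
    length = len(contig)
    rc = "".join(_COMP[c] for c in reversed(contig))
    out = set()
    for strand, seq in ((1, contig), (-1, rc)):
        for offset in range(3):
            codons = [seq[k:k + 3] for k in range(offset, length - 2, 3)]
            aa = "".join(_translate_codon(c) for c in codons)
            segs = aa.split("*")
            pos = 0
            for si, seg in enumerate(segs):
                if len(seg) >= min_len_aa:
                    s_nt = offset + 3 * pos
                    e_nt = s_nt + 3 * len(seg)
                    complete = (si > 0) and (si < len(segs) - 1 or pos + len(seg) < len(aa))
                    # right bound: followed by a stop in this frame
                    right_closed = pos + len(seg) < len(aa)
                    complete = (si > 0) and right_closed
                    if strand == 1:
                        start, end = s_nt, e_nt
                    else:
                        start, end = length - e_nt, length - s_nt
                    out.add((strand * (offset + 1), start, end, seg, complete))
                pos += len(seg) + 1
    return out


def venn_regions_bruteforce(sets: dict[str, set]) -> dict[str, int]:
    names = sorted(sets)
    out: dict[str, int] = {}
    universe = set().union(*sets.values())
    membership = {}
    for x in universe:
        key = tuple(n for n in names if x in sets[n])
        membership[key] = membership.get(key, 0) + 1
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            out["&".join(combo)] = membership.get(tuple(combo), 0)
    return out


def confusion_bruteforce(predicted: set, truth: set):
    tp = sum(1 for x in predicted if x in truth)
    fp = sum(1 for x in predicted if x not in truth)
    fn = sum(1 for x in truth if x not in predicted)
    precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return precision, recall, f1
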