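"""Alignment scoring: BLOSUM62 with BLAST-style affine gaps and Karlin-Altschul statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

#: standard gapped Karlin-Altschul parameters for BLOSUM62 / gap open 11 / extend 1
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(_BLOSUM62.alphabet)


def sanitize_protein(seq: str) -> str:
    """Uppercase and map residues outside the BLOSUM62 alphabet to X."""
    seq = seq.upper()
    if set(seq) <= _ALPHABET:
        return seq
    return "".join(c if c in _ALPHABET else "X" for c in seq)


@dataclass(frozen=True)
class ScoringScheme:
    """BLOSUM62 scoring with affine gap *costs*: a gap of length g costs
    gap_open + gap_extend*(g-1), i.e. open 11 / extend 1 by default, matching
    blastp defaults. ``lam`` and ``k`` are the gapped Karlin-Altschul
    constants used for bit scores and E-values.
    """

    gap_open: int = 11
    gap_extend: int = 1
    lam: float = DEFAULT_LAMBDA
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def matrix(self):
        return _BLOSUM62

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)


DEFAULT_SCHEME = ScoringScheme()


@lru_cache(maxsize=8)
def _make_aligner(mode: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    # Biopython applies open_gap_score to the first gapped position and
    # extend_gap_score to each further one: total -(open + (g-1)*extend).
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


def local_aligner(scheme: ScoringScheme = DEFAULT_SCHEME) -> Align.PairwiseAligner:
    return _make_aligner("local", scheme.gap_open, scheme.gap_extend)


def global_aligner(scheme: ScoringScheme = DEFAULT_SCHEME) -> Align.PairwiseAligner:
    return _make_aligner("global", scheme.gap_open, scheme.gap_extend)
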