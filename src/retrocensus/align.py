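"""Local alignment and homology-search statistics.

Classification of retroelement peptides uses optimal Smith–Waterman local
alignment with affine gaps and BLOSUM62 scores, with significance summarized
by Karlin–Altschul statistics: a raw score ``S`` is converted to a bit score

    S' = (lambda * S - ln K) / ln 2

and an expectation value ``E = m * n * 2**(-S')`` over a search space of
query length ``m`` times database length ``n``.  Gap costs follow the BLAST
convention — a gap of length L costs ``gap_open + L * gap_extend``.

The dynamic programming itself is delegated to Biopython's C
``PairwiseAligner``; this module fixes the scoring conventions and exposes the
(raw score, bit score, coverage, aligned intervals) contract used everywhere
else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices


@lru_cache(maxsize=None)
def _blosum62_x_zero():
    # X (unknown residue) is scored 0 against everything; '*' never occurs in
    # validated domain sequences.
    m = substitution_matrices.load("BLOSUM62").copy()
    xi = m.alphabet.index("X")
    m[xi, :] = 0.0
    m[:, xi] = 0.0
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring and e-value parameters.

    ``K`` and ``lam`` default to standard gapped BLOSUM62 Karlin–Altschul
    constants (K = 0.041, lambda = 0.267).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    K: float = 0.041
    lam: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("Karlin-Altschul K and lambda must be positive")

    def aligner(self) -> PairwiseAligner:
        a = PairwiseAligner()
        a.mode = "local"
        if self.matrix == "BLOSUM62":
            a.substitution_matrix = _blosum62_x_zero()
        else:
            a.substitution_matrix = substitution_matrices.load(self.matrix)
        # BLAST convention: a gap of length L costs open + L*extend.
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - np.log(self.K)) / np.log(2.0)


#: Default nucleotide scoring (blastn-like): match +2, mismatch -3, gap 5 + 2L.
@dataclass(frozen=True)
class NucleotideScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def aligner(self) -> PairwiseAligner:
        a = PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a


def local_align(
    a: str, b: str, scheme: ScoringScheme | NucleotideScoring | None = None
) -> tuple[float, float, float, tuple[tuple[int, int], tuple[int, int]]]:
    """Optimal local alignment of query ``a`` against subject ``b``.

    Returns ``(raw_score, bit_score, coverage, (a_span, b_span))`` where
    coverage is the aligned fraction of the *query* (span length / len(a), in
    [0, 1]) and the spans are 0-based half-open intervals of the locally
    aligned region on each sequence.  Empty input or a best score of zero
    yields score 0 and coverage 0.
    """
    scheme = scheme or ScoringScheme()
    has_bits = isinstance(scheme, ScoringScheme)
    if not a or not b:
        bit = float(scheme.bit_score(0.0)) if has_bits else 0.0
        return 0.0, bit, 0.0, ((0, 0), (0, 0))
    aligner = scheme.aligner()
    raw = max(0.0, float(aligner.score(a, b)))
    bit = float(scheme.bit_score(raw)) if has_bits else raw
    if raw == 0.0:
        return 0.0, bit, 0.0, ((0, 0), (0, 0))
    aln = aligner.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    a_span = (int(a_blocks[0][0]), int(a_blocks[-1][1]))
    b_span = (int(b_blocks[0][0]), int(b_blocks[-1][1]))
    coverage = (a_span[1] - a_span[0]) / len(a)
    return raw, bit, coverage, (a_span, b_span)


def self_score(a: str, scheme: ScoringScheme | NucleotideScoring | None = None) -> float:
    """Raw local-alignment score of a sequence against itself."""
    scheme = scheme or ScoringScheme()
    if not a:
        return 0.0
    return float(scheme.aligner().score(a, a))


def evalue(bit_score: float, m: int, n: int) -> float:
    """Karlin–Altschul expectation value ``E = m * n * 2**(-bit_score)``."""
    if m < 0 or n < 0:
        raise ValueError("search-space dimensions must be non-negative")
    return float(m) * float(n) * float(2.0 ** (-bit_score))
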