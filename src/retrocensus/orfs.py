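"""Open-reading-frame extraction.

Genomic copy counting (and classification of candidate elements) starts from
all maximal start-to-stop ORFs on both strands and all three frames, keeping
those of at least 450 bp — long enough to hold a recognizable fragment of a
retroelement polyprotein.  Intervals include both the start and the stop
codon; peptides are reported without the trailing stop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

_VALID = re.compile(r"[^ACGTN]")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ORF:
    """One open reading frame on a source sequence.

    ``start``/``end`` are 0-based half-open coordinates on the forward strand
    of the source, spanning start codon through stop codon inclusive; ``frame``
    is the reading frame (0, 1, 2) on the reading strand.
    """

    source_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if not self.aa_seq.startswith("M"):
            raise ValueError("ORF peptide must start with M")

    @property
    def nt_len(self) -> int:
        return self.end - self.start


def _scan_strand(seq: str, min_nt: int):
    """Yield (frame, start, end_incl_stop) of maximal start->stop ORFs."""
    n = len(seq)
    for frame in range(3):
        start_candidate = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in _STOPS:
                if start_candidate is not None:
                    orf_len = pos + 3 - start_candidate
                    if orf_len >= min_nt:
                        yield frame, start_candidate, pos + 3
                start_candidate = None
            elif codon == "ATG" and start_candidate is None:
                start_candidate = pos
        # ORFs lacking a stop codon are not reported (they are not
        # start-to-stop regions).


def extract_orfs(seq: str, min_nt: int = 450, source_id: str = "seq") -> list[ORF]:
    """All maximal start->stop ORFs of at least ``min_nt`` bp, both strands.

    Returns ORFs sorted by forward-strand position.  Raises ``ValueError``
    naming the first offending position if the sequence contains characters
    outside A/C/G/T/N.
    """
    seq = seq.upper()
    m = _VALID.search(seq)
    if m:
        raise ValueError(
            f"{source_id}: illegal nucleotide {seq[m.start()]!r} at position {m.start()}"
        )
    if min_nt < 6:
        raise ValueError("min_nt must cover at least a start and a stop codon")
    out: list[ORF] = []
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for frame, start, end in _scan_strand(s, min_nt):
            pep = str(Seq(s[start:end - 3]).translate())
            if strand == "+":
                fstart, fend = start, end
            else:
                fstart, fend = n - end, n - start
            out.append(
                ORF(source_id=source_id, strand=strand, frame=frame,
                    start=fstart, end=fend, aa_seq=pep)
            )
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out
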