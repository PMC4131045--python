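"""Assignment of sequences to LTR retroelement types via their RT domains.

A query peptide (a genomic ORF, a translated candidate inner region, or a
translated transcript segment) is aligned against every reverse-transcriptase
reference in the library; it is assigned to the best-scoring type whose
e-value passes the mode's threshold (1e-40 for genome searches, 1e-30 for
transcriptome searches — transcript fragments are shorter and more diverged,
so the transcriptome screen is more permissive).  Queries with no qualifying
hit stay unassigned.

Near-duplicate peptides can be collapsed before phylogenetic placement with a
greedy longest-first clustering at 80% identity, discarding fragments shorter
than 120 aa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from retrocensus.align import ScoringScheme, evalue, local_align
from retrocensus.reference import ReferenceLibrary

log = logging.getLogger(__name__)

MODES = ("genome_orf", "genome_ltr", "transcriptome")

DEFAULT_THRESHOLDS = {"genome_orf": 1e-40, "genome_ltr": 1e-40, "transcriptome": 1e-30}


@dataclass(frozen=True)
class ElementAssignment:
    query_id: str
    type_name: str
    family: str
    raw_score: float
    bit_score: float
    e_value: float
    coverage: float
    mode: str

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage must be in (0, 1]")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


def classify(
    queries: dict[str, str],
    lib: ReferenceLibrary,
    mode: str = "genome_orf",
    threshold: float | None = None,
    scheme: ScoringScheme | None = None,
) -> list[ElementAssignment]:
    """Assign each query peptide to the best qualifying RT reference.

    Ties on raw score break by higher coverage, then lexicographic type name.
    Queries without a hit at ``E <= threshold`` are dropped (count logged).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    threshold = DEFAULT_THRESHOLDS[mode] if threshold is None else threshold
    scheme = scheme or ScoringScheme()
    rts = lib.rt_domains()
    if not rts:
        raise ValueError("reference library has no RT domains")
    db_len = sum(len(d.aa_seq) for d in rts)
    out: list[ElementAssignment] = []
    unassigned = 0
    for qid, pep in queries.items():
        best = None
        for ref in sorted(rts, key=lambda d: d.type_name):
            raw, bit, cov, _spans = local_align(pep, ref.aa_seq, scheme)
            if raw <= 0.0:
                continue
            e = evalue(bit, len(pep), db_len)
            if e > threshold:
                continue
            key = (raw, cov, _NegStr(ref.type_name))
            if best is None or key > best[0]:
                best = (key, ref, raw, bit, cov, e)
        if best is None:
            unassigned += 1
            continue
        _key, ref, raw, bit, cov, e = best
        out.append(
            ElementAssignment(
                query_id=qid, type_name=ref.type_name, family=ref.family,
                raw_score=raw, bit_score=bit, e_value=e, coverage=cov, mode=mode,
            )
        )
    if unassigned:
        log.info("%d/%d queries had no hit at E <= %g", unassigned, len(queries), threshold)
    return out


class _NegStr(str):
    """Reversed string ordering, so lexicographically smaller wins under max()."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def six_frame_segments(seq: str, min_aa: int = 50) -> dict[str, str]:
    """Stop-to-stop peptide segments of all six frames, keyed by frame/offset.

    This is the translated search space for nucleotide queries (blastx-style):
    no start codon is required, only an open stretch between stops.
    """
    seq = seq.upper()
    out: dict[str, str] = {}
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            tail = (len(s) - frame) % 3
            coding = s[frame:len(s) - tail]
            if not coding:
                continue
            pep = str(Seq(coding).translate())
            pos = 0
            for seg in pep.split("*"):
                if len(seg) >= min_aa:
                    out[f"{strand}{frame}:{pos}"] = seg
                pos += len(seg) + 1
    return out


def classify_nucleotide(
    seqs: dict[str, str],
    lib: ReferenceLibrary,
    mode: str = "transcriptome",
    threshold: float | None = None,
    scheme: ScoringScheme | None = None,
    min_aa: int = 50,
) -> list[ElementAssignment]:
    """Classify nucleotide sequences through their six-frame translations.

    Each sequence contributes at most one assignment: the best-scoring
    qualifying hit over all of its stop-to-stop translated segments.
    """
    out: list[ElementAssignment] = []
    for sid, seq in seqs.items():
        segs = {f"{sid}|{k}": p for k, p in six_frame_segments(seq, min_aa).items()}
        if not segs:
            continue
        hits = classify(segs, lib, mode=mode, threshold=threshold, scheme=scheme)
        if not hits:
            continue
        best = max(hits, key=lambda a: (a.raw_score, a.coverage, _NegStr(a.type_name)))
        out.append(
            ElementAssignment(
                query_id=sid, type_name=best.type_name, family=best.family,
                raw_score=best.raw_score, bit_score=best.bit_score,
                e_value=best.e_value, coverage=best.coverage, mode=best.mode,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Greedy clustering of near-duplicate peptides
# ---------------------------------------------------------------------------

def _identity_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = 0.0
    a.extend_gap_score = 0.0
    return a


def cluster_peptides(
    peptides: dict[str, str], identity: float = 0.80, min_len: int = 120
) -> dict[str, str]:
    """Greedy longest-first clustering; returns the representative set.

    Sequences shorter than ``min_len`` aa are discarded first.  Remaining
    peptides are visited longest-first (ties: by id); each joins the first
    existing representative with identity >= ``identity``, where identity is
    the maximal number of matched residues in a global alignment divided by
    the shorter sequence's length; otherwise it founds a new cluster.
    """
    aligner = _identity_aligner()
    kept = [(pid, p) for pid, p in peptides.items() if len(p) >= min_len]
    kept.sort(key=lambda t: (-len(t[1]), t[0]))
    reps: dict[str, str] = {}
    for pid, pep in kept:
        placed = False
        for rep in reps.values():
            matches = float(aligner.score(pep, rep))
            if matches / min(len(pep), len(rep)) >= identity:
                placed = True
                break
        if not placed:
            reps[pid] = pep
    return reps
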