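"""De novo detection of candidate LTR retroelements.

An LTR retroelement is bounded by two near-identical direct repeats (long
terminal repeats, LTRs).  The detector finds such structures from sequence
alone with a seed-and-extend contract:

1. enumerate exact seed matches of length ``seed_len`` between genome
   positions whose separation (distance between seed starts) lies within
   ``[min_element - 2*max_ltr, max_element]``;
2. extend each seed pair without gaps, first rightwards then leftwards, one
   aligned base at a time, accepting a step only while the running repeat
   identity (matches / aligned length, seed included) stays at or above
   ``min_similarity``; each direction is then trimmed back to the extent
   maximizing the ungapped score (+1 match / -1 mismatch; first maximum,
   i.e. the shortest extent, wins);
3. keep extended repeat pairs whose repeat length falls in
   ``[min_ltr, max_ltr]`` and whose element span (start of the 5' repeat to
   end of the 3' repeat) falls in ``[min_element, max_element]``, with the
   two repeats non-overlapping;
4. merge candidates with overlapping element intervals, keeping the
   highest-similarity one (ties: longest span, then leftmost); output sorted
   by (contig, start).

Similarity is reported as ``100 * matches / repeat length``.  The defaults
mirror a permissive de novo scan (seed 20, repeat length 30–2000 bp,
similarity >= 70%) with an element-length window bracketing typical
full-length LTR retroelements.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

log = logging.getLogger(__name__)

#: k-mers occurring more often than this per contig are treated as
#: low-complexity and not used as seeds.
MAX_KMER_OCCURRENCES = 200


@dataclass(frozen=True)
class LTRScanParams:
    seed_len: int = 20
    min_ltr: int = 30
    max_ltr: int = 2000
    min_similarity: float = 70.0
    min_element: int = 1000
    max_element: int = 12000

    def __post_init__(self) -> None:
        if self.seed_len < 1:
            raise ValueError("seed_len must be positive")
        if not (0 < self.min_ltr <= self.max_ltr):
            raise ValueError("need 0 < min_ltr <= max_ltr")
        if not (0.0 < self.min_similarity <= 100.0):
            raise ValueError("min_similarity must be in (0, 100]")
        if not (0 < self.min_element <= self.max_element):
            raise ValueError("need 0 < min_element <= max_element")


@dataclass(frozen=True)
class LTRCandidate:
    """A candidate element: paired direct repeats flanking an inner region.

    All intervals are 0-based half-open on the contig.  ``inner`` spans from
    the end of the 5' repeat to the start of the 3' repeat.
    """

    contig: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_similarity: float

    @property
    def inner(self) -> tuple[int, int]:
        return (self.ltr5[1], self.ltr3[0])

    @property
    def span(self) -> int:
        return self.end - self.start

    def validate(self, params: LTRScanParams) -> None:
        l5, l3 = self.ltr5, self.ltr3
        if not (self.start == l5[0] and self.end == l3[1]):
            raise AssertionError("element interval must span ltr5 start to ltr3 end")
        if l5[1] > l3[0]:
            raise AssertionError("5' repeat must end before 3' repeat starts")
        for iv in (l5, l3):
            if not (params.min_ltr <= iv[1] - iv[0] <= params.max_ltr):
                raise AssertionError("repeat length outside [min_ltr, max_ltr]")
        if not (params.min_element <= self.span <= params.max_element):
            raise AssertionError("element span outside [min_element, max_element]")
        if self.ltr_similarity < params.min_similarity:
            raise AssertionError("similarity below threshold")


def _extend_pair(seq: str, i: int, j: int, params: LTRScanParams):
    """Extend an exact seed pair at starts (i, j); return (l, r, matches).

    ``l``/``r`` are the trimmed left/right extension lengths beyond the seed;
    ``matches`` counts matching bases over the final repeat (length
    ``l + seed_len + r``).
    """
    k = params.seed_len
    thr = params.min_similarity / 100.0
    n = len(seq)

    # rightwards: compare seq[i+k+r] vs seq[j+k+r]
    m, t = k, k
    best_r, best_score, best_m = 0, 0, k
    score = 0
    r = 0
    max_r = min(n - (j + k), (j - i) - k)  # stay in bounds, repeats disjoint
    while r < max_r:
        d = 1 if seq[i + k + r] == seq[j + k + r] and seq[i + k + r] != "N" else 0
        if (m + d) / (t + 1) < thr:
            break
        r += 1
        m += d
        t += 1
        score += 2 * d - 1
        if score > best_score:
            best_score, best_r, best_m = score, r, m
    r, m = best_r, best_m
    t = k + r

    # leftwards: compare seq[i-1-l] vs seq[j-1-l]
    right_end = i + k + r
    best_l, best_score, best_lm = 0, 0, 0
    score = 0
    l = 0
    max_l = min(i, (j - right_end))
    lm = 0
    while l < max_l:
        d = 1 if seq[i - 1 - l] == seq[j - 1 - l] and seq[i - 1 - l] != "N" else 0
        if (m + lm + d) / (t + l + 1) < thr:
            break
        l += 1
        lm += d
        score += 2 * d - 1
        if score > best_score:
            best_score, best_l, best_lm = score, l, lm
    return best_l, r, m + best_lm


def _merge(cands: list[LTRCandidate]) -> list[LTRCandidate]:
    """Collapse overlapping element intervals; best candidate per cluster."""
    if not cands:
        return []
    cands = sorted(cands, key=lambda c: (c.start, c.end))
    clusters: list[list[LTRCandidate]] = [[cands[0]]]
    cur_end = cands[0].end
    for c in cands[1:]:
        if c.start < cur_end:
            clusters[-1].append(c)
            cur_end = max(cur_end, c.end)
        else:
            clusters.append([c])
            cur_end = c.end
    out = []
    for cl in clusters:
        best = max(cl, key=lambda c: (c.ltr_similarity, c.span, -c.start, -c.ltr5[0]))
        out.append(best)
    return out


def find_ltr_candidates(
    genome: dict[str, str], params: LTRScanParams | None = None
) -> list[LTRCandidate]:
    """Scan a genome (mapping contig -> sequence) for candidate LTR elements."""
    params = params or LTRScanParams()
    k = params.seed_len
    sep_lo = max(1, params.min_element - 2 * params.max_ltr)
    sep_hi = params.max_element
    results: list[LTRCandidate] = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        if len(seq) < params.min_element:
            log.info("contig %s shorter than min_element (%d bp); skipped",
                     contig, params.min_element)
            continue
        index: dict[str, list[int]] = defaultdict(list)
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos:pos + k]
            if "N" not in kmer:
                index[kmer].append(pos)
        cands: list[LTRCandidate] = []
        for positions in index.values():
            if len(positions) < 2:
                continue
            if len(positions) > MAX_KMER_OCCURRENCES:
                continue  # low-complexity seed
            for ai, i in enumerate(positions):
                for j in positions[ai + 1:]:
                    sep = j - i
                    if sep < sep_lo:
                        continue
                    if sep > sep_hi:
                        break
                    l, r, matches = _extend_pair(seq, i, j, params)
                    length = l + k + r
                    if not (params.min_ltr <= length <= params.max_ltr):
                        continue
                    start = i - l
                    end = j + k + r
                    if not (params.min_element <= end - start <= params.max_element):
                        continue
                    ltr5 = (start, i + k + r)
                    ltr3 = (j - l, end)
                    if ltr5[1] > ltr3[0]:
                        continue
                    sim = 100.0 * matches / length
                    if sim < params.min_similarity:
                        continue
                    cands.append(
                        LTRCandidate(contig=contig, start=start, end=end,
                                     ltr5=ltr5, ltr3=ltr3, ltr_similarity=sim)
                    )
        merged = _merge(cands)
        for c in merged:
            c.validate(params)
        results.extend(merged)
    results.sort(key=lambda c: (c.contig, c.start))
    return results


def extract_inner(genome: dict[str, str], cand: LTRCandidate) -> str:
    """Sequence of the candidate's inner region (element minus its LTRs)."""
    seq = genome.get(cand.contig)
    if seq is None:
        raise ValueError(f"contig {cand.contig!r} not in genome")
    s, e = cand.inner
    if not (0 <= s <= e <= len(seq)):
        raise ValueError(f"inner interval {cand.inner} outside contig bounds")
    if s == e:
        log.warning("candidate at %s:%d-%d has an empty inner region",
                    cand.contig, cand.start, cand.end)
    return seq[s:e]
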