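"""Copy-number census and proliferation statistics of LTR retroelements.

Two independent genome search methods count full-length-ish copies per
element type: GSM1 counts genomic ORFs whose translation hits an RT
reference, GSM2 counts de novo LTR-detector candidates validated by an RT
hit.  The census row for a type combines them into an average abundance
estimate AAE = round_half_up((GSM1 + GSM2) / 2) and a genome fraction

    %  =  100 * mean(GSM1, GSM2) * AEL / G

where AEL is the catalogued average element length (bp) and G the genome
size.  The fraction uses the exact (unrounded) mean; only AAE is rounded.

Proliferation of a type is summarized by its relative relatedness

    R = ln( sum over ordered pairs (i != j) of coverage_ij * score_ij )

over all within-type element pairs; a higher R means more, and more similar,
copies — the signature of recent proliferation.  Self-pairs are excluded:
self-hits carry no proliferation signal and would dominate the sum.  Both an
amino-acid variant (RT peptides, BLOSUM62) and a nucleotide variant (whole
inner regions) are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from retrocensus.align import NucleotideScoring, ScoringScheme, local_align
from retrocensus.classify import ElementAssignment
from retrocensus.reference import ReferenceLibrary, default_ael

#: Default genome size (bp) for the genome-fraction column: the refined
#: value (to 6 significant digits) consistent with the reference census's
#: published per-type genome fractions; configurable per assembly.
DEFAULT_GENOME_SIZE = 1.45569e9


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (134.5 -> 135)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CensusRow:
    family: str
    type_name: str
    gsm1: int
    gsm2: int
    ael: int
    genome_size: float

    def __post_init__(self) -> None:
        if self.gsm1 < 0 or self.gsm2 < 0:
            raise ValueError("counts must be >= 0")
        if self.ael <= 0 or self.genome_size <= 0:
            raise ValueError("AEL and genome size must be positive")

    @property
    def mean_count(self) -> float:
        return (self.gsm1 + self.gsm2) / 2.0

    @property
    def aae(self) -> int:
        return round_half_up(self.mean_count)

    @property
    def bp(self) -> float:
        """Estimated bp occupied: exact mean count times average element length."""
        return self.mean_count * self.ael

    @property
    def fraction_pct(self) -> float:
        return 100.0 * self.bp / self.genome_size


@dataclass
class CensusReport:
    rows: list[CensusRow]
    genome_size: float

    @property
    def total_gsm1(self) -> int:
        return sum(r.gsm1 for r in self.rows)

    @property
    def total_gsm2(self) -> int:
        return sum(r.gsm2 for r in self.rows)

    @property
    def total_aae(self) -> int:
        return sum(r.aae for r in self.rows)

    @property
    def total_bp(self) -> float:
        return sum(r.bp for r in self.rows)

    @property
    def total_fraction_pct(self) -> float:
        return sum(r.fraction_pct for r in self.rows)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("family\ttype\tGSM1\tGSM2\tAAE\tAEL_bp\tpct\n")
            for r in self.rows:
                fh.write(
                    f"{r.family}\t{r.type_name}\t{r.gsm1}\t{r.gsm2}\t{r.aae}\t"
                    f"{r.ael}\t{r.fraction_pct:.5f}\n"
                )
            fh.write(
                f"Total\t\t{self.total_gsm1}\t{self.total_gsm2}\t{self.total_aae}\t\t"
                f"{self.total_fraction_pct:.5f}\n"
            )


def count_by_type(
    assignments: list[ElementAssignment], mode: str, lib: ReferenceLibrary
) -> dict[str, int]:
    """Per-type assignment counts for one mode; absent types count 0."""
    counts = {t: 0 for t in lib.catalogue}
    for a in assignments:
        if a.mode != mode:
            continue
        if a.type_name not in counts:
            raise KeyError(f"assignment to uncatalogued type {a.type_name!r}")
        counts[a.type_name] += 1
    return counts


def build_census(
    counts1: dict[str, int],
    counts2: dict[str, int],
    lib: ReferenceLibrary,
    genome_size: float = DEFAULT_GENOME_SIZE,
) -> CensusReport:
    """One census row per catalogued type from the two counting methods."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    rows = []
    for type_name, (family, _ael) in lib.catalogue.items():
        rows.append(
            CensusRow(
                family=family,
                type_name=type_name,
                gsm1=int(counts1.get(type_name, 0)),
                gsm2=int(counts2.get(type_name, 0)),
                ael=default_ael(lib, type_name),
                genome_size=genome_size,
            )
        )
    return CensusReport(rows=rows, genome_size=genome_size)


@dataclass(frozen=True)
class RelatednessScore:
    type_name: str
    n_elements: int
    R: float

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("relatedness is defined only for >= 2 elements")


def relatedness(
    seqs: dict[str, str],
    type_name: str = "",
    level: str = "aa",
    scheme: ScoringScheme | NucleotideScoring | None = None,
) -> RelatednessScore | None:
    """Relative relatedness R = ln sum(coverage * score) over ordered pairs.

    ``level`` selects amino-acid (BLOSUM62) or nucleotide scoring.  Returns
    ``None`` (missing) for fewer than two elements.  An all-zero pair sum
    yields R = -inf.
    """
    if len(seqs) < 2:
        return None
    if scheme is None:
        scheme = ScoringScheme() if level == "aa" else NucleotideScoring()
    total = 0.0
    ids = list(seqs)
    for qid in ids:
        for sid in ids:
            if qid == sid:
                continue
            raw, _bit, cov, _spans = local_align(seqs[qid], seqs[sid], scheme)
            total += cov * raw
    R = math.log(total) if total > 0 else float("-inf")
    return RelatednessScore(type_name=type_name, n_elements=len(seqs), R=R)


def write_relatedness(
    scores: dict[str, tuple[RelatednessScore | None, RelatednessScore | None]],
    path: str | Path,
) -> None:
    """TSV of per-type relatedness: type, n, R_aa, R_nt ('NA' where missing)."""

    def fmt(s: RelatednessScore | None) -> str:
        return "NA" if s is None else f"{s.R:.6f}"

    with open(path, "w") as fh:
        fh.write("type\tn\tR_aa\tR_nt\n")
        for t, (r_aa, r_nt) in scores.items():
            n = r_aa.n_elements if r_aa else (r_nt.n_elements if r_nt else 0)
            fh.write(f"{t}\t{n}\t{fmt(r_aa)}\t{fmt(r_nt)}\n")
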