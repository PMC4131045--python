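"""Synthetic data with planted ground truth.

Every downstream stage of the pipeline is testable without external data
because this module fabricates its inputs with known truth:

* genomes with planted LTR retroelements of configurable type, LTR length and
  similarity, inner length, ORF content and per-copy divergence;
* "transcript" sets derived from the planted elements;
* short single-end reads drawn from element sequences at chosen abundances
  with a uniform per-base substitution error;
* negative-binomial count matrices with planted per-sample library-size
  factors and per-group means, emulating raw RNA-seq counts per element.

All generators take an explicit seed and are deterministic given it.  Copies
planted with an ORF are mutated under a purifying-selection rule: a
substitution that would create an in-frame stop codon (or destroy the start
codon) inside the planted ORF is reverted, so that divergent but active
copies keep an intact reading frame, as real proliferating elements do.
Substitution-only divergence; no indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from retrocensus.orfs import _STOPS
from retrocensus.reference import ReferenceLibrary, synthetic_reference_library

_NT = np.array(list("ACGT"))

#: Sense codons (61), used for random in-frame padding and back-translation.
_CODON_TABLE: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _c = _b1 + _b2 + _b3
            if _c not in _STOPS:
                from Bio.Seq import Seq as _Seq

                _CODON_TABLE.setdefault(str(_Seq(_c).translate()), []).append(_c)


@dataclass(frozen=True)
class PlantSpec:
    """How to plant copies of one element type."""

    type_name: str
    n_copies: int
    ltr_len: int = 300
    inner_len: int = 4400
    ltr_identity: float = 1.0
    copy_divergence: float = 0.0
    include_orf: bool = True

    def __post_init__(self) -> None:
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")
        if self.ltr_len < 1 or self.inner_len < 0:
            raise ValueError("need ltr_len >= 1 and inner_len >= 0")
        if not (0.0 <= self.ltr_identity <= 1.0):
            raise ValueError("ltr_identity must be in [0, 1]")
        if not (0.0 <= self.copy_divergence <= 1.0):
            raise ValueError("copy_divergence must be in [0, 1]")

    @property
    def element_len(self) -> int:
        return 2 * self.ltr_len + self.inner_len


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth location of one planted copy (0-based half-open)."""

    contig: str
    start: int
    end: int
    type_name: str
    copy_id: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]

    def __post_init__(self) -> None:
        ok = (self.start <= self.ltr5[0] <= self.ltr5[1]
              <= self.ltr3[0] <= self.ltr3[1] <= self.end)
        if not ok:
            raise ValueError("LTR intervals must nest inside the element, 5' before 3'")


def _random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_NT, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitution with probability ``rate`` (to a different base)."""
    if rate <= 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    idx = np.flatnonzero(hit & (arr != "N"))
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _backtranslate(rng: np.random.Generator, pep: str) -> str:
    return "".join(_CODON_TABLE[aa][rng.integers(len(_CODON_TABLE[aa]))] for aa in pep)


def _repair_orf(original: str, mutated: str, orf_start: int, orf_end: int) -> str:
    """Revert mutations that break the reading frame of the planted ORF."""
    out = list(mutated)
    out[orf_start:orf_start + 3] = original[orf_start:orf_start + 3]  # start codon
    for pos in range(orf_start + 3, orf_end - 3, 3):
        if "".join(out[pos:pos + 3]) in _STOPS:
            out[pos:pos + 3] = original[pos:pos + 3]
    out[orf_end - 3:orf_end] = original[orf_end - 3:orf_end]  # stop codon
    return "".join(out)


def _build_master(
    rng: np.random.Generator, spec: PlantSpec, gc: float, lib: ReferenceLibrary
) -> tuple[str, int, int]:
    """Master element sequence and the ORF interval within it (or (-1, -1))."""
    ltr5 = _random_nt(rng, spec.ltr_len, gc)
    ltr3 = _mutate(rng, ltr5, 1.0 - spec.ltr_identity)
    inner = _random_nt(rng, spec.inner_len, gc)
    orf_iv = (-1, -1)
    if spec.include_orf:
        rts = [d for d in lib.rt_domains() if d.type_name == spec.type_name]
        if not rts:
            raise ValueError(f"library has no RT domain for type {spec.type_name!r}")
        pep = "M" + rts[0].aa_seq
        orf_nt = _backtranslate(rng, pep) + "TAA"
        if len(orf_nt) > spec.inner_len:
            raise ValueError(
                f"{spec.type_name}: inner_len {spec.inner_len} too short for the "
                f"planted ORF ({len(orf_nt)} bp)"
            )
        off = int(rng.integers(0, spec.inner_len - len(orf_nt) + 1))
        inner = inner[:off] + orf_nt + inner[off + len(orf_nt):]
        orf_iv = (spec.ltr_len + off, spec.ltr_len + off + len(orf_nt))
    return ltr5 + inner + ltr3, orf_iv


def generate_genome(
    specs: list[PlantSpec],
    background_len: int,
    gc: float = 0.4,
    seed: int = 0,
    lib: ReferenceLibrary | None = None,
    contig: str = "chr1",
    min_gap: int = 0,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """One contig of i.i.d. background with planted copies at uniform positions.

    ``background_len`` is the *total* contig length; planted copies replace
    none of it — they are inserted into background such that the final contig
    has exactly ``background_len`` bases.  Copies are non-overlapping and the
    truth records are exact.  Deterministic given ``seed``.

    ``min_gap`` enforces a minimum background distance between consecutive
    planted copies.  Copies of one master element share near-identical LTRs,
    so two copies planted close together present a cross-element direct
    repeat (3' LTR of one against 5' LTR of the next) that an LTR detector
    may legitimately report instead of the planted pair; spacing copies
    further apart than the detector's maximum element span isolates them.
    """
    lib = lib or synthetic_reference_library()
    rng = np.random.default_rng(seed)
    copies: list[tuple[PlantSpec, str, int, int]] = []  # spec, seq, orf interval
    for spec in specs:
        if spec.n_copies == 0:
            continue
        master, orf_iv = _build_master(rng, spec, gc, lib)
        for _ in range(spec.n_copies):
            mut = _mutate(rng, master, spec.copy_divergence)
            if orf_iv[0] >= 0:
                mut = _repair_orf(master, mut, *orf_iv)
            copies.append((spec, mut, *orf_iv))
    total_planted = sum(len(c[1]) for c in copies)
    free = background_len - total_planted
    if free < 0:
        raise ValueError(
            f"background_len {background_len} < total planted length {total_planted}"
        )
    background = _random_nt(rng, free, gc)
    # uniform non-overlapping placement: sorted insertion points in background,
    # at least min_gap apart
    slack = free - max(0, len(copies) - 1) * min_gap
    if len(copies) and slack < 0:
        raise ValueError(
            f"background_len {background_len} too small for {len(copies)} copies "
            f"with min_gap {min_gap}"
        )
    insert_at = np.sort(rng.integers(0, slack + 1, size=len(copies)))
    insert_at = insert_at + min_gap * np.arange(len(copies))
    pieces: list[str] = []
    truth: list[TruthRecord] = []
    prev = 0
    offset = 0
    counters: dict[str, int] = {}
    for (spec, seq, _o1, _o2), ins in zip(copies, insert_at):
        pieces.append(background[prev:ins])
        offset += ins - prev
        start = offset
        end = start + len(seq)
        n = counters.get(spec.type_name, 0)
        counters[spec.type_name] = n + 1
        truth.append(
            TruthRecord(
                contig=contig, start=start, end=end, type_name=spec.type_name,
                copy_id=f"{spec.type_name}.{n}",
                ltr5=(start, start + spec.ltr_len),
                ltr3=(end - spec.ltr_len, end),
            )
        )
        pieces.append(seq)
        offset = end
        prev = ins
    pieces.append(background[prev:])
    genome = {contig: "".join(pieces)}
    assert len(genome[contig]) == background_len
    return genome, truth


def transcripts_from_truth(
    genome: dict[str, str],
    truth: list[TruthRecord],
    noise: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Emit each planted element's sequence as a 'transcript', optionally mutated."""
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for rec in truth:
        seq = genome.get(rec.contig)
        if seq is None or rec.end > len(seq) or rec.start < 0:
            raise ValueError(f"truth record {rec.copy_id} out of genome bounds")
        out[rec.copy_id] = _mutate(rng, seq[rec.start:rec.end], noise)
    return out


def simulate_reads(
    element_seqs: dict[str, str],
    abundances: dict[str, float],
    read_len: int = 50,
    n_reads: int = 1000,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Single-end reads drawn from elements proportional to abundances.

    Elements shorter than ``read_len`` are skipped with a warning.  Read names
    encode the element of origin (``read<i>|<element>``) so that read-level
    truth is available to tests.  Forward strand only.
    """
    import logging

    log = logging.getLogger(__name__)
    rng = np.random.default_rng(seed)
    names, weights = [], []
    for name, w in abundances.items():
        if name not in element_seqs:
            raise ValueError(f"abundance given for unknown element {name!r}")
        if len(element_seqs[name]) < read_len:
            log.warning("element %s shorter than read length %d; skipped", name, read_len)
            continue
        names.append(name)
        weights.append(float(w))
    reads: list[tuple[str, str]] = []
    if not names or n_reads == 0:
        return reads
    p = np.array(weights) / np.sum(weights)
    origins = rng.choice(len(names), size=n_reads, p=p)
    for i, oi in enumerate(origins):
        seq = element_seqs[names[oi]]
        pos = int(rng.integers(0, len(seq) - read_len + 1))
        read = _mutate(rng, seq[pos:pos + read_len], error_rate)
        reads.append((f"read{i}|{names[oi]}", read))
    return reads


@dataclass
class CountSimSpec:
    """Negative-binomial count-matrix simulation.

    ``means`` is an (n_elements x n_groups) array of per-group expected counts
    at size factor 1; ``groups`` assigns each sample to a group (by index into
    the columns of ``means``); ``size_factors`` scales each sample's library;
    ``alpha`` is the NB dispersion (variance mu + alpha * mu^2; 0 = Poisson).
    """

    means: np.ndarray
    groups: list[int]
    size_factors: np.ndarray
    alpha: float = 0.1
    group_labels: list[str] | None = None
    element_names: list[str] | None = None
    sample_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if (self.means < 0).any():
            raise ValueError("means must be >= 0")
        if self.alpha < 0:
            raise ValueError("dispersion alpha must be >= 0")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be > 0")
        if len(self.groups) != len(self.size_factors):
            raise ValueError("one group label and one size factor per sample")
        if max(self.groups) >= self.means.shape[1]:
            raise ValueError("group index exceeds columns of means")


def simulate_counts(spec: CountSimSpec, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate counts; returns (counts DataFrame, sample metadata DataFrame)."""
    rng = np.random.default_rng(seed)
    n_el = spec.means.shape[0]
    n_s = len(spec.groups)
    counts = np.zeros((n_el, n_s), dtype=np.int64)
    for j, (g, s) in enumerate(zip(spec.groups, spec.size_factors)):
        mu = spec.means[:, g] * s
        if spec.alpha == 0.0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / spec.alpha
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(mu > 0, r / (r + mu), 1.0)
            counts[:, j] = np.where(mu > 0, rng.negative_binomial(r, p), 0)
    elements = spec.element_names or [f"el{i}" for i in range(n_el)]
    samples = spec.sample_names or [f"s{j}" for j in range(n_s)]
    labels = spec.group_labels or [f"g{g}" for g in range(spec.means.shape[1])]
    meta = pd.DataFrame(
        {"sample": samples, "group": [labels[g] for g in spec.groups]}
    ).set_index("sample")
    return pd.DataFrame(counts, index=elements, columns=samples), meta


# ---------------------------------------------------------------------------
# Truth serialization (BED6 + ltr columns, 0-based half-open)
# ---------------------------------------------------------------------------

def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tname\tscore\tstrand\ttype\tltr5\tltr3\n")
        for r in truth:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.copy_id}\t0\t+\t{r.type_name}\t"
                f"{r.ltr5[0]}-{r.ltr5[1]}\t{r.ltr3[0]}-{r.ltr3[1]}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            l5 = tuple(int(x) for x in f[7].split("-"))
            l3 = tuple(int(x) for x in f[8].split("-"))
            out.append(
                TruthRecord(contig=f[0], start=int(f[1]), end=int(f[2]),
                            type_name=f[6], copy_id=f[3], ltr5=l5, ltr3=l3)
            )
    return out
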