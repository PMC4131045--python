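"""End-to-end orchestration of the census and expression workflows.

``run_census`` chains detection -> ORF extraction/classification -> census ->
relatedness and writes every intermediate artifact as TSV/FASTA;
``run_expression`` chains read counting (or ingest of a precomputed count
matrix) -> median-of-ratios normalization -> NRC_rel -> the statistical test
battery -> stage profiles.  Both are deterministic given the config's seed
and echo a manifest (package version, seed, input checksums) into the output
directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from retrocensus import __version__
from retrocensus.align import ScoringScheme
from retrocensus.census import (
    DEFAULT_GENOME_SIZE,
    CensusReport,
    build_census,
    count_by_type,
    relatedness,
    write_relatedness,
)
from retrocensus.classify import (
    DEFAULT_THRESHOLDS,
    classify,
    classify_nucleotide,
    six_frame_segments,
)
from retrocensus.detect import LTRScanParams, extract_inner, find_ltr_candidates
from retrocensus.expression import count_reads, normalize_counts, stage_profile, test_all
from retrocensus.io import read_counts, read_fasta, read_fastq, write_fasta
from retrocensus.orfs import extract_orfs
from retrocensus.reference import (
    ReferenceLibrary,
    bundled_library_path,
    load_library,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An identifiable pipeline stage failed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Keyed configuration for the full workflow; loadable from YAML."""

    outdir: str = "retrocensus_out"
    genome: str | None = None
    transcripts: str | None = None
    library: str | None = None
    counts: str | None = None
    elements: str | None = None
    samples: dict[str, str] = field(default_factory=dict)
    metadata: str | None = None
    stage_order: list[str] = field(default_factory=list)
    seed: int = 0
    genome_size: float = DEFAULT_GENOME_SIZE
    scan: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=lambda: dict(
        genome=DEFAULT_THRESHOLDS["genome_orf"],
        transcriptome=DEFAULT_THRESHOLDS["transcriptome"],
    ))
    counting: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, thr in self.thresholds.items():
            if thr <= 0:
                raise ValueError(f"threshold {name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def scan_params(self) -> LTRScanParams:
        return LTRScanParams(**self.scan)

    def scoring_scheme(self) -> ScoringScheme:
        return ScoringScheme(**self.scoring)

    def load_reference(self) -> ReferenceLibrary:
        return load_library(self.library or bundled_library_path())


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: PipelineConfig, outdir: Path, inputs: list[str]) -> None:
    manifest = {
        "retrocensus_version": __version__,
        "seed": config.seed,
        "inputs": {p: _sha256(p) for p in inputs if p and Path(p).exists()},
        "config": {k: v for k, v in config.__dict__.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_census(config: PipelineConfig) -> CensusReport:
    """Detection -> classification -> census -> relatedness; writes artifacts.

    If ``config.counts`` is set (counts-only mode), the dual GSM counts are
    read from a TSV with columns family/type/GSM1/GSM2 and only the census
    arithmetic runs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lib = config.load_reference()
    scheme = config.scoring_scheme()
    thr = config.thresholds.get("genome", DEFAULT_THRESHOLDS["genome_orf"])

    if config.counts:
        try:
            tbl = pd.read_csv(config.counts, sep="\t")
            counts1 = dict(zip(tbl["type"], tbl["GSM1"].astype(int)))
            counts2 = dict(zip(tbl["type"], tbl["GSM2"].astype(int)))
        except Exception as e:
            raise StageError("ingest-counts", e)
        report = build_census(counts1, counts2, lib, config.genome_size)
        report.to_tsv(outdir / "census.tsv")
        _write_manifest(config, outdir, [config.counts])
        return report

    if not config.genome or not Path(config.genome).exists():
        raise StageError("config", FileNotFoundError(f"genome FASTA {config.genome!r}"))
    genome = read_fasta(config.genome)

    # GSM1: genomic ORFs vs RT references
    try:
        orfs = [o for cname, cseq in genome.items()
                for o in extract_orfs(cseq, source_id=cname)]
        queries = {f"{o.source_id}:{o.start}-{o.end}({o.strand})": o.aa_seq for o in orfs}
        gsm1_assign = classify(queries, lib, mode="genome_orf", threshold=thr, scheme=scheme)
    except StageError:
        raise
    except Exception as e:
        raise StageError("genome-orfs", e)

    # GSM2: de novo LTR candidates validated by an RT hit
    try:
        cands = find_ltr_candidates(genome, config.scan_params())
        inners = {
            f"{c.contig}:{c.start}-{c.end}": extract_inner(genome, c) for c in cands
        }
        gsm2_assign = classify_nucleotide(
            inners, lib, mode="genome_ltr", threshold=thr, scheme=scheme
        )
    except Exception as e:
        raise StageError("ltr-detection", e)

    counts1 = count_by_type(gsm1_assign, "genome_orf", lib)
    counts2 = count_by_type(gsm2_assign, "genome_ltr", lib)
    report = build_census(counts1, counts2, lib, config.genome_size)

    # relatedness per type over validated candidates
    try:
        by_type_nt: dict[str, dict[str, str]] = {}
        by_type_aa: dict[str, dict[str, str]] = {}
        for a in gsm2_assign:
            by_type_nt.setdefault(a.type_name, {})[a.query_id] = inners[a.query_id]
            pep = _best_segment(inners[a.query_id], lib, scheme, thr)
            if pep:
                by_type_aa.setdefault(a.type_name, {})[a.query_id] = pep
        rel = {
            t: (
                relatedness(by_type_aa.get(t, {}), t, level="aa"),
                relatedness(by_type_nt.get(t, {}), t, level="nt"),
            )
            for t in lib.catalogue
        }
    except Exception as e:
        raise StageError("relatedness", e)

    # artifacts
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write("contig\tstart\tend\tltr5\tltr3\tsimilarity\n")
        for c in cands:
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\t{c.ltr5[0]}-{c.ltr5[1]}\t"
                f"{c.ltr3[0]}-{c.ltr3[1]}\t{c.ltr_similarity:.2f}\n"
            )
    if inners:
        write_fasta(inners, outdir / "inner_regions.fasta")
    with open(outdir / "assignments.tsv", "w") as fh:
        fh.write("query\ttype\tfamily\traw\tbit\tevalue\tcoverage\tmode\n")
        for a in gsm1_assign + gsm2_assign:
            fh.write(
                f"{a.query_id}\t{a.type_name}\t{a.family}\t{a.raw_score:.1f}\t"
                f"{a.bit_score:.2f}\t{a.e_value:.3e}\t{a.coverage:.3f}\t{a.mode}\n"
            )
    report.to_tsv(outdir / "census.tsv")
    write_relatedness(rel, outdir / "relatedness.tsv")
    _write_manifest(config, outdir, [config.genome, str(config.library or "")])
    return report


def _best_segment(inner: str, lib, scheme, thr) -> str | None:
    """Best RT-matching translated segment of a candidate inner region."""
    segs = six_frame_segments(inner)
    hits = classify(segs, lib, mode="genome_ltr", threshold=thr, scheme=scheme)
    if not hits:
        return None
    best = max(hits, key=lambda a: a.raw_score)
    return segs[best.query_id]


def run_expression(config: PipelineConfig):
    """Counting/ingest -> normalization -> NRC_rel -> tests -> stage profiles.

    Returns (NormalizedCounts, tests DataFrame or None, profile DataFrame or
    None).  Sample metadata (TSV: sample <tab> group) drives the test battery;
    ``stage_order`` drives the profile.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        if config.counts:
            counts = read_counts(config.counts)
        else:
            if not config.elements or not config.samples:
                raise ValueError("need either a counts TSV or elements + samples")
            elements = read_fasta(config.elements)
            cols = {}
            pol = config.counting
            for sample, fq in sorted(config.samples.items()):
                reads = read_fastq(fq)
                cols[sample] = count_reads(
                    reads, elements,
                    max_hits=pol.get("max_hits", 20),
                    min_matchlen=pol.get("min_matchlen", 30),
                    seed_len=pol.get("seed_len", 15),
                    fractional=pol.get("fractional", False),
                )
            counts = pd.DataFrame(cols)
        if counts.empty:
            raise ValueError("empty count matrix")
    except Exception as e:
        raise StageError("counting", e)

    try:
        norm = normalize_counts(counts)
    except Exception as e:
        raise StageError("normalization", e)

    tests = None
    if config.metadata:
        meta = pd.read_csv(config.metadata, sep="\t", index_col=0)
        unmatched = [s for s in counts.columns if s not in meta.index]
        if unmatched:
            raise StageError(
                "metadata", ValueError(f"samples without metadata: {unmatched}")
            )
        try:
            tests = test_all(norm.nrc_rel, meta["group"])
        except Exception as e:
            raise StageError("tests", e)
        tests.to_csv(outdir / "tests.tsv", sep="\t")

    profile = None
    if config.stage_order:
        try:
            profile = stage_profile(norm.nrc, config.stage_order)
        except Exception as e:
            raise StageError("profile", e)
        profile.to_csv(outdir / "stage_profile.tsv", sep="\t")

    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="element")
    norm.nrc.to_csv(outdir / "nrc.tsv", sep="\t", index_label="element")
    norm.nrc_rel.to_csv(outdir / "nrc_rel.tsv", sep="\t", index_label="element")
    norm.size_factors.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t")
    inputs = [config.counts or "", config.elements or "", config.metadata or ""]
    inputs += list(config.samples.values())
    _write_manifest(config, outdir, inputs)
    return norm, tests, profile
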