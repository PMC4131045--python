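"""Reference library of retroelement protein domains.

LTR retroelements fall into four families — Bel/Pao, Ty1/Copia, Ty3/Gypsy and
Retroviridae — and are detected and classified here through their most
conserved protein region, the reverse-transcriptase (RT) domain.  A
:class:`ReferenceLibrary` holds amino-acid domain sequences (RT for
classification; GAG/POL/ENV/CHR references for a minimal element-integrity
screen), each tagged with the element *type* it represents (Kobel, Amn-san,
SnRV, ...), together with a catalogue mapping each type to its family and an
average element length (AEL, bp) used by the genome-fraction census.

Libraries are stored as protein FASTA with pipe-separated headers::

    >id|family|type|domain_kind

A small synthetic library (random peptides, one RT per catalogued type) is
bundled so the whole pipeline is testable without any external database.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

FAMILIES = ("Bel/Pao", "Ty1/Copia", "Ty3/Gypsy", "Retroviridae")

DOMAIN_KINDS = ("RT", "GAG", "POL-AP", "POL-RN", "POL-INT", "ENV", "CHR")

#: 20 standard amino acids; X is allowed (scored as zero in alignments).
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}

#: Catalogue of element types: type -> (family, default average element length in bp).
DEFAULT_CATALOGUE: dict[str, tuple[str, int]] = {
    "Kobel": ("Bel/Pao", 7000),
    "Hydra3.1": ("Bel/Pao", 7000),
    "Hydra1.1": ("Ty1/Copia", 4000),
    "Mtanga": ("Ty1/Copia", 4000),
    "Amn-san": ("Ty3/Gypsy", 5000),
    "Cer": ("Ty3/Gypsy", 7000),
    "Gmr": ("Ty3/Gypsy", 8000),
    "Mag": ("Ty3/Gypsy", 4000),
    "MuERV": ("Retroviridae", 6000),
    "SnRV": ("Retroviridae", 10000),
    "XEN1": ("Retroviridae", 10000),
}


class LibraryError(ValueError):
    """Raised for malformed or inconsistent reference libraries."""


@dataclass(frozen=True)
class ReferenceDomain:
    """One amino-acid domain sequence tagged with element family and type."""

    id: str
    family: str
    type_name: str
    domain_kind: str
    aa_seq: str

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise LibraryError(f"{self.id}: empty amino-acid sequence")
        bad = set(self.aa_seq) - AA_ALPHABET
        if bad:
            raise LibraryError(
                f"{self.id}: illegal amino-acid characters {sorted(bad)} "
                "(20 standard residues plus X allowed; '*' is forbidden)"
            )
        if self.family not in FAMILIES:
            raise LibraryError(f"{self.id}: unknown family {self.family!r}")
        if self.domain_kind not in DOMAIN_KINDS:
            raise LibraryError(f"{self.id}: unknown domain kind {self.domain_kind!r}")


@dataclass
class ReferenceLibrary:
    """Collection of reference domains plus the type catalogue.

    Parameters
    ----------
    domains
        Validated :class:`ReferenceDomain` records with unique ids.
    catalogue
        Mapping ``type_name -> (family, default AEL bp)``.  Defaults to the
        bundled eleven-type catalogue.
    """

    domains: list[ReferenceDomain]
    catalogue: dict[str, tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_CATALOGUE)
    )

    def __post_init__(self) -> None:
        ids = [d.id for d in self.domains]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise LibraryError(f"duplicate domain ids: {dup}")
        for type_name, (family, ael) in self.catalogue.items():
            if family not in FAMILIES:
                raise LibraryError(f"catalogue type {type_name}: unknown family {family!r}")
            if ael <= 0:
                raise LibraryError(f"catalogue type {type_name}: AEL must be positive")
        for d in self.domains:
            if d.type_name not in self.catalogue:
                raise LibraryError(f"{d.id}: type {d.type_name!r} not in catalogue")
            if self.catalogue[d.type_name][0] != d.family:
                raise LibraryError(
                    f"{d.id}: family {d.family!r} contradicts catalogue "
                    f"({self.catalogue[d.type_name][0]!r}) for type {d.type_name!r}"
                )

    # -- queries ---------------------------------------------------------
    @property
    def families(self) -> set[str]:
        return {d.family for d in self.domains}

    @property
    def type_names(self) -> list[str]:
        return sorted(self.catalogue)

    def rt_domains(self) -> list[ReferenceDomain]:
        """RT domains only — the classification database."""
        return [d for d in self.domains if d.domain_kind == "RT"]

    def domains_of_kind(self, kind: str) -> list[ReferenceDomain]:
        return [d for d in self.domains if d.domain_kind == kind]

    def family_of(self, type_name: str) -> str:
        if type_name not in self.catalogue:
            raise KeyError(f"unknown element type {type_name!r}")
        return self.catalogue[type_name][0]


def default_ael(lib: ReferenceLibrary, type_name: str) -> int:
    """Catalogued average element length (bp) for an element type."""
    if type_name not in lib.catalogue:
        raise KeyError(f"unknown element type {type_name!r}")
    return lib.catalogue[type_name][1]


def load_library(path: str | Path, catalogue: dict | None = None) -> ReferenceLibrary:
    """Load a reference library from pipe-tagged protein FASTA.

    Each record header must read ``id|family|type|domain_kind``.  Raises
    :class:`LibraryError` naming the offending record for malformed headers,
    unknown families/kinds, duplicate ids or an empty file.
    """
    path = Path(path)
    domains = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 4:
            raise LibraryError(
                f"record {rec.id!r}: header must be 'id|family|type|domain_kind', "
                f"got {rec.description!r}"
            )
        rid, family, type_name, kind = (p.strip() for p in parts)
        domains.append(
            ReferenceDomain(
                id=rid, family=family, type_name=type_name,
                domain_kind=kind, aa_seq=str(rec.seq).upper(),
            )
        )
    if not domains:
        raise LibraryError(f"{path}: no reference domains")
    lib = ReferenceLibrary(domains, dict(catalogue or DEFAULT_CATALOGUE))
    counts = Counter(d.family for d in lib.domains)
    log.info("loaded %d domains from %s: %s", len(domains), path,
             ", ".join(f"{f}={counts[f]}" for f in FAMILIES if counts[f]))
    return lib


def write_library(lib: ReferenceLibrary, path: str | Path) -> None:
    """Write a library back to pipe-tagged protein FASTA."""
    records = [
        SeqRecord(
            Seq(d.aa_seq),
            id=f"{d.id}|{d.family}|{d.type_name}|{d.domain_kind}",
            description="",
        )
        for d in lib.domains
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# Synthetic stand-in library
# ---------------------------------------------------------------------------

#: Background amino-acid frequencies (Robinson–Robinson order of BLOSUM alphabet).
_AA = np.array(list("ARNDCQEGHILKMFPSTWYV"))
_AA_FREQ = np.array(
    [
        0.078, 0.051, 0.045, 0.054, 0.019, 0.043, 0.063, 0.074, 0.022, 0.051,
        0.091, 0.057, 0.022, 0.039, 0.052, 0.071, 0.058, 0.013, 0.032, 0.065,
    ]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


def random_peptide(rng: np.random.Generator, length: int) -> str:
    """Random peptide at background amino-acid frequencies."""
    return "".join(rng.choice(_AA, size=length, p=_AA_FREQ))


def synthetic_reference_library(seed: int = 20140723) -> ReferenceLibrary:
    """Deterministic synthetic stand-in for a curated domain database.

    One random RT peptide (240–300 aa) per catalogued type, plus GAG/POL/ENV/CHR
    reference peptides for the integrity screen (ENV only for Retroviridae, CHR
    only for the chromovirus-like Amn-san).  The sequences are random — they
    carry no biological signal and exist so that planted elements in synthetic
    genomes can be classified against a known truth.
    """
    rng = np.random.default_rng(seed)
    domains: list[ReferenceDomain] = []
    for type_name in sorted(DEFAULT_CATALOGUE):
        family = DEFAULT_CATALOGUE[type_name][0]
        slug = type_name.replace(".", "_").replace("-", "_")
        rt_len = int(rng.integers(240, 301))
        domains.append(
            ReferenceDomain(
                id=f"RT_{slug}", family=family, type_name=type_name,
                domain_kind="RT", aa_seq=random_peptide(rng, rt_len),
            )
        )
        domains.append(
            ReferenceDomain(
                id=f"GAG_{slug}", family=family, type_name=type_name,
                domain_kind="GAG", aa_seq=random_peptide(rng, int(rng.integers(120, 181))),
            )
        )
        domains.append(
            ReferenceDomain(
                id=f"POLINT_{slug}", family=family, type_name=type_name,
                domain_kind="POL-INT", aa_seq=random_peptide(rng, int(rng.integers(150, 201))),
            )
        )
        if family == "Retroviridae":
            domains.append(
                ReferenceDomain(
                    id=f"ENV_{slug}", family=family, type_name=type_name,
                    domain_kind="ENV", aa_seq=random_peptide(rng, int(rng.integers(150, 201))),
                )
            )
        if type_name == "Amn-san":
            domains.append(
                ReferenceDomain(
                    id=f"CHR_{slug}", family=family, type_name=type_name,
                    domain_kind="CHR", aa_seq=random_peptide(rng, 50),
                )
            )
    return ReferenceLibrary(domains)


def bundled_library_path() -> Path:
    """Path of the bundled synthetic reference FASTA."""
    return Path(str(resources.files("retrocensus").joinpath("data/synthetic_reference.fasta")))


def bundled_census_counts_path() -> Path:
    """Path of the bundled published genome copy-number table (TSV)."""
    return Path(str(resources.files("retrocensus").joinpath("data/silurana_genome_counts.tsv")))
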