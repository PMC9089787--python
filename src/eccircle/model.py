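"""Domain types shared by all pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based conventions happens only in the parsers and writers
(:mod:`eccircle.io`).  The size of a circle is therefore always
``end - start``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "Genotype",
    "Origin",
    "Tissue",
    "LibraryType",
    "EccDNARecord",
    "AlignedFragment",
    "GenomeElementSet",
    "StrainSNP",
    "SampleMeta",
    "Genome",
]


class Genotype(str, Enum):
    """Mouse genotype groups compared throughout the analysis."""

    WT = "WT"
    DNASE1_KO = "Dnase1_KO"
    DNASE1L3_KO = "Dnase1l3_KO"
    OTHER = "other"


class Origin(str, Enum):
    """Per-molecule origin call in the pregnancy model."""

    UNASSIGNED = "unassigned"
    FETAL_SPECIFIC = "fetal_specific"
    SHARED = "shared"


class Tissue(str, Enum):
    PLASMA = "plasma"
    LIVER = "liver"
    BUFFY_COAT = "buffy_coat"
    OTHER = "other"


class LibraryType(str, Enum):
    TAGMENTATION = "tagmentation"
    ROLLING_CIRCLE = "rolling_circle"


@dataclass(frozen=True)
class EccDNARecord:
    """One identified eccDNA species (locus).

    A locus is the unit counted throughout the analysis: all junction
    evidence with the same breakpoints collapses into one record whose
    ``support`` is the number of distinct junction-spanning fragments.
    """

    chrom: str
    start: int
    end: int
    support: int = 1
    sample_id: str = ""
    genotype: Genotype = Genotype.OTHER
    origin: Origin = Origin.UNASSIGNED

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.support < 1:
            raise ValueError(f"support must be >= 1, got {self.support}")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples."""
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


@dataclass
class AlignedFragment:
    """One aligned read, the caller's view of a SAM record."""

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    cigar: str
    mapq: int
    seq: str
    is_reverse: bool = False
    is_paired: bool = False
    is_proper: bool = False
    is_supplementary: bool = False
    is_read1: bool = True
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    mate_is_reverse: bool = False

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        self._ops = parse_cigar(self.cigar)
        qlen = sum(n for n, op in self._ops if op in _QUERY_OPS)
        if self.seq and qlen != len(self.seq):
            raise ValueError(
                f"CIGAR {self.cigar} consumes {qlen} bases but read "
                f"{self.read_id} has {len(self.seq)}"
            )
        self._ref_end = self.pos + sum(n for n, op in self._ops if op in _REF_OPS)

    @property
    def cigar_ops(self) -> List[Tuple[int, str]]:
        return self._ops

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the aligned span on the reference."""
        return self._ref_end

    def base_at(self, ref_pos: int) -> Optional[str]:
        """Read base aligned to ``ref_pos``, or None if not covered (or in a
        clip/deletion)."""
        q, r = 0, self.pos
        for n, op in self.cigar_ops:
            if op in ("M", "=", "X"):
                if r <= ref_pos < r + n:
                    return self.seq[q + (ref_pos - r)]
                q += n
                r += n
            elif op in ("I", "S"):
                q += n
            elif op in ("D", "N"):
                if r <= ref_pos < r + n:
                    return None
                r += n
        return None


ELEMENT_CLASSES = (
    "five_prime_UTR",
    "three_prime_UTR",
    "gene_body",
    "CpG_island",
    "repeat",
)


@dataclass
class GenomeElementSet:
    """Genomic-element annotation: per-class sorted interval lists
    (0-based half-open)."""

    intervals: Dict[str, List[Tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, ivs in self.intervals.items():
            for chrom, s, e in ivs:
                if e < s or s < 0:
                    raise ValueError(f"bad interval in {cls}: {chrom}:{s}-{e}")
            self.intervals[cls] = sorted(ivs)

    @property
    def classes(self) -> List[str]:
        return list(self.intervals)

    def total_length(self, element_class: str) -> int:
        return sum(e - s for _, s, e in self.intervals[element_class])


@dataclass(frozen=True)
class StrainSNP:
    """A biallelic position with fixed different alleles in two inbred
    strains (A = maternal strain, B = paternal strain)."""

    chrom: str
    pos: int  # 0-based
    allele_A: str
    allele_B: str

    def __post_init__(self) -> None:
        for a in (self.allele_A, self.allele_B):
            if a not in "ACGT" or len(a) != 1:
                raise ValueError(f"allele must be a single ACGT base, got {a!r}")
        if self.allele_A == self.allele_B:
            raise ValueError(
                f"identical alleles at {self.chrom}:{self.pos}: {self.allele_A}"
            )


@dataclass
class SampleMeta:
    sample_id: str
    genotype: Genotype = Genotype.OTHER
    tissue: Tissue = Tissue.PLASMA
    library: LibraryType = LibraryType.TAGMENTATION
    mappable_reads: int = 0


class Genome:
    """In-memory reference genome: chromosome name -> uppercase sequence.

    Toy genomes used in this package are small enough to hold as plain
    strings; :meth:`from_fasta` loads an on-disk FASTA through pyfaidx.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def __iter__(self):
        return iter(self._seqs)

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 0-based half-open interval [start, end)."""
        seq = self[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"of length {len(seq)}"
            )
        return seq[start:end]
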