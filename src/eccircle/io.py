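"""Readers and writers for the standard formats the pipeline touches.

All conversions between coordinate conventions live here: BED and internal
coordinates are 0-based half-open; SAM and the SNP TSV are 1-based in the
file and shifted at the boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

import pysam

from .model import (
    AlignedFragment,
    EccDNARecord,
    Genome,
    GenomeElementSet,
    Genotype,
    Origin,
    StrainSNP,
)

__all__ = [
    "AlignmentReader",
    "read_alignments",
    "write_records_bed",
    "read_records_bed",
    "read_snp_table",
    "write_snp_table",
    "read_elements_bed",
    "write_elements_bed",
    "write_fasta",
    "write_sam",
]


class UnsortedInputError(ValueError):
    """Raised when an alignment file is not coordinate-sorted."""


def _fragment_from_pysam(rec: pysam.AlignedSegment) -> AlignedFragment:
    return AlignedFragment(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        pos=rec.reference_start,
        cigar=rec.cigarstring or "",
        mapq=rec.mapping_quality,
        seq=rec.query_sequence or "",
        is_reverse=rec.is_reverse,
        is_paired=rec.is_paired,
        is_proper=rec.is_proper_pair,
        is_supplementary=rec.is_supplementary,
        is_read1=not rec.is_read2,
        mate_chrom=rec.next_reference_name if rec.is_paired else None,
        mate_pos=rec.next_reference_start if rec.is_paired else None,
        mate_is_reverse=rec.mate_is_reverse if rec.is_paired else False,
    )


class AlignmentReader:
    """Stream primary mapped records with ``mapq >= mapq_min`` from a
    coordinate-sorted SAM/BAM file.

    After iteration, :attr:`mappable_reads` holds the number of read *pairs*
    that passed the filter (read-1 records counted), the denominator used
    for EPM normalisation.
    """

    def __init__(self, path, mapq_min: int = 30):
        self.path = str(path)
        self.mapq_min = mapq_min
        self.mappable_reads = 0
        self._consumed = False

    def __iter__(self) -> Iterator[AlignedFragment]:
        self.mappable_reads = 0
        mode = "rb" if self.path.endswith(".bam") else "r"
        with pysam.AlignmentFile(self.path, mode, check_sq=False) as fh:
            so = fh.header.to_dict().get("HD", {}).get("SO", "")
            last = (-1, -1)
            for i, rec in enumerate(fh):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                key = (rec.reference_id, rec.reference_start)
                if key < last and so != "coordinate":
                    raise UnsortedInputError(
                        f"{self.path} is not coordinate-sorted "
                        f"(record {i}: {rec.query_name})"
                    )
                last = key
                if rec.mapping_quality < self.mapq_min:
                    continue
                try:
                    frag = _fragment_from_pysam(rec)
                except ValueError as exc:
                    raise ValueError(
                        f"malformed record {i} ({rec.query_name}) in "
                        f"{self.path}: {exc}"
                    ) from exc
                if frag.is_read1:
                    self.mappable_reads += 1
                yield frag
        self._consumed = True


def read_alignments(path, mapq_min: int = 30) -> AlignmentReader:
    """Open a coordinate-sorted SAM/BAM for filtered streaming."""
    return AlignmentReader(path, mapq_min=mapq_min)


# --- eccDNA records as BED6+2 (name=sample_id, score=support, +size, +origin)


def write_records_bed(records: Iterable[EccDNARecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.sample_id or '.'}\t"
                f"{r.support}\t.\t{r.size}\t{r.origin.value}\n"
            )


def read_records_bed(path, genotype: Genotype = Genotype.OTHER) -> List[EccDNARecord]:
    records: List[EccDNARecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{ln}: bad interval {start}-{end}")
            sample = f[3] if len(f) > 3 and f[3] != "." else ""
            support = int(f[4]) if len(f) > 4 else 1
            origin = Origin(f[7]) if len(f) > 7 else Origin.UNASSIGNED
            records.append(
                EccDNARecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    support=support,
                    sample_id=sample,
                    genotype=genotype,
                    origin=origin,
                )
            )
    return records


# --- strain SNP table (TSV, 1-based positions in the file)


def read_snp_table(path) -> List[StrainSNP]:
    snps: List[StrainSNP] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for ln, row in enumerate(reader, 1):
            if not row or row[0].startswith("#") or row[0] == "chrom":
                continue
            if len(row) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(row)}")
            chrom, pos1, a, b = row[0], int(row[1]), row[2].upper(), row[3].upper()
            try:
                snps.append(StrainSNP(chrom=chrom, pos=pos1 - 1, allele_A=a, allele_B=b))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return snps


def write_snp_table(snps: Iterable[StrainSNP], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tallele_A\tallele_B\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.allele_A}\t{s.allele_B}\n")


# --- genomic-element annotations, one BED per class


def read_elements_bed(paths_by_class: Mapping[str, object]) -> GenomeElementSet:
    intervals: Dict[str, list] = {}
    for cls, path in paths_by_class.items():
        ivs = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                ivs.append((f[0], int(f[1]), int(f[2])))
        intervals[cls] = ivs
    return GenomeElementSet(intervals=intervals)


def write_elements_bed(elements: GenomeElementSet, outdir) -> Dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for cls, ivs in elements.intervals.items():
        p = outdir / f"{cls}.bed"
        with open(p, "w") as fh:
            for chrom, s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\t{cls}\n")
        paths[cls] = p
    return paths


# --- FASTA / SAM emission (used by the simulator and the CLI)


def write_fasta(genome: Genome, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(genome[c]), id=c, description="") for c in genome]
    SeqIO.write(recs, str(path), "fasta")


def write_sam(fragments: Sequence[AlignedFragment], genome: Genome, path) -> None:
    """Write fragments as a coordinate-sorted SAM file."""
    chroms = list(genome)
    tid = {c: i for i, c in enumerate(chroms)}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    ordered = sorted(fragments, key=lambda f: (tid[f.chrom], f.pos, f.read_id))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for f in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f.read_id
            a.query_sequence = f.seq
            a.reference_id = tid[f.chrom]
            a.reference_start = f.pos
            a.cigarstring = f.cigar
            a.mapping_quality = f.mapq
            flag = 0
            if f.is_paired:
                flag |= 0x1
                if f.is_proper:
                    flag |= 0x2
                flag |= 0x40 if f.is_read1 else 0x80
                if f.mate_is_reverse:
                    flag |= 0x20
            if f.is_reverse:
                flag |= 0x10
            a.flag = flag
            if f.is_paired and f.mate_chrom is not None:
                a.next_reference_id = tid[f.mate_chrom]
                a.next_reference_start = f.mate_pos
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.query_qualities = pysam.qualitystring_to_array("I" * len(f.seq))
            out.write(a)
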