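"""Fetal/maternal partitioning of eccDNA molecules via strain SNPs.

In the pregnancy model the mother is homozygous strain A (C57BL/6-like) and
the father strain B (BALB/c-like), so the fetus is heterozygous at every
strain-informative SNP.  A molecule showing a strain-B allele at any covered
informative SNP must be fetal; molecules showing only strain-A alleles are
"shared" (predominantly maternal, plus the fetus's maternal-strain
haplotype).  Because the heterozygous fetus contributes the strain-B allele
on only half of its molecules, the fetal fraction carries a factor of two.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .model import AlignedFragment, EccDNARecord, Origin, StrainSNP
from .size import SizeProfile, size_profile

__all__ = [
    "MoleculeGenotypeEvidence",
    "FetalFraction",
    "classify_origin",
    "classify_records",
    "fetal_fraction",
    "partition_size_profiles",
]


@dataclass
class MoleculeGenotypeEvidence:
    record: EccDNARecord
    informative_snps_covered: int
    n_allele_A: int
    n_allele_B: int
    origin: Origin


@dataclass
class FetalFraction:
    """Fetal eccDNA fraction, both raw (count share of classified
    molecules) and corrected for the heterozygous fetus contributing the
    paternal-strain allele on only half of its molecules."""

    n_fetal_specific: int
    n_shared: int

    @property
    def raw_percent(self) -> Optional[float]:
        n = self.n_fetal_specific + self.n_shared
        return 100.0 * self.n_fetal_specific / n if n else None

    @property
    def percent(self) -> Optional[float]:
        n = self.n_fetal_specific + self.n_shared
        return 100.0 * 2 * self.n_fetal_specific / n if n else None


def _snp_index(snps: Iterable[StrainSNP]) -> Dict[str, Dict[int, StrainSNP]]:
    idx: Dict[str, Dict[int, StrainSNP]] = defaultdict(dict)
    for s in snps:
        idx[s.chrom][s.pos] = s
    return idx


def classify_origin(
    record: EccDNARecord,
    reads: Sequence[AlignedFragment],
    snps: Iterable[StrainSNP],
) -> Tuple[Origin, MoleculeGenotypeEvidence]:
    """Assign a molecule's origin from its supporting read sequences.

    At each informative SNP inside the circle interval, base observations
    across the supporting reads vote; a tie at any SNP, or discordant SNP
    calls within the molecule, leave it unassigned.  Bases matching neither
    strain allele (sequencing errors) are ignored.
    """
    idx = snps if isinstance(snps, dict) else _snp_index(snps)
    by_pos = idx.get(record.chrom, {})
    calls: List[str] = []
    n_a = n_b = covered = 0
    tie = False
    for pos in range(record.start, record.end):
        snp = by_pos.get(pos)
        if snp is None:
            continue
        votes_a = votes_b = 0
        for read in reads:
            base = read.base_at(pos)
            if base == snp.allele_A:
                votes_a += 1
            elif base == snp.allele_B:
                votes_b += 1
        if votes_a == 0 and votes_b == 0:
            continue
        covered += 1
        n_a += votes_a
        n_b += votes_b
        if votes_a == votes_b:
            tie = True
        elif votes_b > votes_a:
            calls.append("B")
        else:
            calls.append("A")

    if tie or covered == 0:
        origin = Origin.UNASSIGNED
    elif "B" in calls and "A" in calls:
        origin = Origin.UNASSIGNED  # discordant evidence vetoes the call
    elif "B" in calls:
        origin = Origin.FETAL_SPECIFIC
    else:
        origin = Origin.SHARED

    ev = MoleculeGenotypeEvidence(
        record=record,
        informative_snps_covered=covered,
        n_allele_A=n_a,
        n_allele_B=n_b,
        origin=origin,
    )
    return origin, ev


def classify_records(
    records: Sequence[EccDNARecord],
    fragments: Sequence[AlignedFragment],
    snps: Sequence[StrainSNP],
) -> Tuple[List[EccDNARecord], List[MoleculeGenotypeEvidence]]:
    """Classify every record using the fragments overlapping its interval."""
    import bisect

    idx = _snp_index(snps)
    by_chrom: Dict[str, List[AlignedFragment]] = defaultdict(list)
    for f in fragments:
        by_chrom[f.chrom].append(f)
    positions: Dict[str, List[int]] = {}
    max_span: Dict[str, int] = {}
    for chrom, frags in by_chrom.items():
        frags.sort(key=lambda f: f.pos)
        positions[chrom] = [f.pos for f in frags]
        max_span[chrom] = max(f.reference_end - f.pos for f in frags)

    labeled: List[EccDNARecord] = []
    evidence: List[MoleculeGenotypeEvidence] = []
    for rec in records:
        frags = by_chrom.get(rec.chrom, [])
        pos_list = positions.get(rec.chrom, [])
        lo = bisect.bisect_left(pos_list, rec.start - max_span.get(rec.chrom, 0))
        hi = bisect.bisect_left(pos_list, rec.end)
        support = [f for f in frags[lo:hi] if f.reference_end > rec.start]
        origin, ev = classify_origin(rec, support, idx)
        labeled.append(
            EccDNARecord(
                chrom=rec.chrom,
                start=rec.start,
                end=rec.end,
                support=rec.support,
                sample_id=rec.sample_id,
                genotype=rec.genotype,
                origin=origin,
            )
        )
        evidence.append(ev)
    return labeled, evidence


def fetal_fraction(n_fetal_specific: int, n_shared: int) -> FetalFraction:
    if n_fetal_specific + n_shared <= 0:
        raise ValueError("no classified molecules; fetal fraction undefined")
    return FetalFraction(n_fetal_specific=n_fetal_specific, n_shared=n_shared)


def partition_size_profiles(
    records: Sequence[EccDNARecord], lo: int = 0, hi: int = 1000
) -> Dict[Origin, SizeProfile]:
    """Separate size profiles for the fetal-specific and shared subsets."""
    return {
        origin: size_profile([r for r in records if r.origin is origin], lo=lo, hi=hi)
        for origin in (Origin.FETAL_SPECIFIC, Origin.SHARED)
    }
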