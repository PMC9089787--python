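"""Genomic context of eccDNA loci.

Element enrichment is measured against a Monte-Carlo expectation: random
loci are drawn on the same genome with sizes resampled from the observed
circles, so the expected overlap frequency controls for the size dependence
of hitting an annotation.  Junctional sequence context is summarised as the
four trinucleotides flanking the two breakpoints (motifs I-IV: outside and
inside the circle start, inside and outside the circle end).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .model import EccDNARecord, Genome, GenomeElementSet

__all__ = [
    "Locus",
    "ElementEnrichment",
    "JunctionMotifCombo",
    "SharedLoci",
    "simulate_expected_loci",
    "element_enrichment",
    "fold_change_percent_increase",
    "shared_loci",
    "junction_motifs",
]


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int
    end: int

    @property
    def interval(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class ElementEnrichment:
    element_class: str
    observed_freq: float
    expected_freq: float
    fold_change: Optional[float]
    n_sim: int
    seed: Optional[int] = None


@dataclass(frozen=True)
class JunctionMotifCombo:
    """Trinucleotides at the junction: I = upstream-outside of the circle
    start, II = inside at the start, III = inside at the end,
    IV = downstream-outside of the end."""

    motif_I: str
    motif_II: str
    motif_III: str
    motif_IV: str
    count: int
    rank: int


@dataclass
class SharedLoci:
    n_shared: int
    n_a: int
    n_b: int

    @property
    def pct_of_a(self) -> Optional[float]:
        return 100.0 * self.n_shared / self.n_a if self.n_a else None

    @property
    def pct_of_b(self) -> Optional[float]:
        return 100.0 * self.n_shared / self.n_b if self.n_b else None

    def rounded(self, ndigits: int = 2) -> Tuple[Optional[float], Optional[float]]:
        a, b = self.pct_of_a, self.pct_of_b
        return (
            None if a is None else round(a, ndigits),
            None if b is None else round(b, ndigits),
        )


def simulate_expected_loci(
    chrom_sizes: Mapping[str, int],
    observed_sizes: Sequence[int],
    n_sim: int,
    seed=None,
) -> List[Locus]:
    """Random loci matching the observed size multiset.

    Chromosome drawn with probability proportional to its length, start
    uniform on the chromosome, size resampled with replacement from the
    observed sizes; a locus running off the chromosome end is redrawn
    (start re-sampled), which leaves starts uniform on the feasible range.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    sizes = np.asarray(observed_sizes, dtype=np.int64)
    if len(sizes) == 0:
        raise ValueError("need at least one observed size")
    if sizes.max() > lengths.max():
        raise ValueError(
            f"size {sizes.max()} exceeds the longest chromosome ({int(lengths.max())})"
        )
    probs = lengths / lengths.sum()

    loci: List[Locus] = []
    while len(loci) < n_sim:
        m = max(256, int((n_sim - len(loci)) * 1.4))
        ci = rng.choice(len(chroms), size=m, p=probs)
        size = sizes[rng.integers(len(sizes), size=m)]
        clen = lengths[ci]
        start = np.floor(rng.random(m) * clen).astype(np.int64)
        ok = start + size <= clen  # off-end draws are redrawn wholesale
        for c, s, z in zip(ci[ok], start[ok], size[ok]):
            if len(loci) >= n_sim:
                break
            loci.append(Locus(chrom=chroms[c], start=int(s), end=int(s + z)))
    return loci


def _trees(elements: GenomeElementSet) -> Dict[str, Dict[str, IntervalTree]]:
    trees: Dict[str, Dict[str, IntervalTree]] = {}
    for cls, ivs in elements.intervals.items():
        per_chrom: Dict[str, IntervalTree] = {}
        for chrom, s, e in ivs:
            if e > s:
                per_chrom.setdefault(chrom, IntervalTree()).addi(s, e)
        trees[cls] = per_chrom
    return trees


def _overlap_freq(loci, per_chrom: Dict[str, IntervalTree]) -> float:
    n = hit = 0
    for loc in loci:
        n += 1
        tree = per_chrom.get(loc.chrom)
        if tree is not None and tree.overlaps(loc.start, loc.end):
            hit += 1
    return hit / n if n else 0.0


def element_enrichment(
    records: Sequence,
    elements: GenomeElementSet,
    simulated: Sequence[Locus],
    seed=None,
) -> Dict[str, ElementEnrichment]:
    """Observed vs expected overlap frequency per element class.

    A locus overlaps a class iff its half-open interval intersects any
    class interval by >= 1 bp; observed and expected frequencies use the
    identical rule.  Fold change is observed/expected, undefined (None)
    when the expectation is zero.
    """
    if not simulated:
        raise ValueError("empty simulated locus set")
    if not records:
        raise ValueError("no observed records")
    trees = _trees(elements)
    out: Dict[str, ElementEnrichment] = {}
    for cls in elements.classes:
        obs = _overlap_freq(records, trees[cls])
        exp = _overlap_freq(simulated, trees[cls])
        out[cls] = ElementEnrichment(
            element_class=cls,
            observed_freq=obs,
            expected_freq=exp,
            fold_change=(obs / exp) if exp > 0 else None,
            n_sim=len(simulated),
            seed=seed,
        )
    return out


def fold_change_percent_increase(fc_a: float, fc_b: float) -> float:
    """Percent increase of sample B's fold change over sample A's."""
    if fc_a == 0:
        raise ValueError("reference fold change is zero")
    return 100.0 * (fc_b - fc_a) / fc_a


def shared_loci(set_a: Sequence, set_b: Sequence) -> SharedLoci:
    """Loci present in both samples, by exact (chrom, start, end)."""
    a = {r.interval for r in set_a}
    b = {r.interval for r in set_b}
    return SharedLoci(n_shared=len(a & b), n_a=len(a), n_b=len(b))


def junction_motifs(
    records: Sequence[EccDNARecord],
    genome: Genome,
    top_k: int = 5,
    window: int = 3,
) -> Tuple[List[JunctionMotifCombo], int]:
    """Ranked trinucleotide combinations flanking the junctions.

    Motifs are read from the reference forward strand (circles are
    unstranded).  Records whose breakpoints lie within ``window`` bases of
    a chromosome edge are skipped and tallied.  Ties in count are broken
    lexicographically for a deterministic ranking.
    """
    counter: Counter = Counter()
    skipped = 0
    for r in records:
        clen = len(genome[r.chrom])
        if r.start - window < 0 or r.end + window > clen:
            skipped += 1
            continue
        combo = (
            genome.fetch(r.chrom, r.start - window, r.start),
            genome.fetch(r.chrom, r.start, r.start + window),
            genome.fetch(r.chrom, r.end - window, r.end),
            genome.fetch(r.chrom, r.end, r.end + window),
        )
        counter[combo] += 1
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    out = [
        JunctionMotifCombo(
            motif_I=c[0], motif_II=c[1], motif_III=c[2], motif_IV=c[3],
            count=n, rank=i + 1,
        )
        for i, (c, n) in enumerate(ranked[:top_k] if top_k else ranked)
    ]
    return out, skipped
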