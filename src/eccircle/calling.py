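"""Identify eccDNA loci from paired-end alignments.

A circular molecule linearised by library preparation leaves two kinds of
evidence in an alignment against the linear reference:

* **split reads** — a read that traverses the circle junction aligns with a
  soft-clipped prefix or suffix; the clipped sequence re-aligns exactly at
  the opposite breakpoint.  These pin both breakpoints at base resolution.
* **outward-facing pairs** — both mates map to the same chromosome facing
  away from each other (leftmost mate reverse, rightmost forward); they
  bracket, but do not pin, the breakpoints.

Split-read pinning is required for 1-bp size profiles and the 10-bp
periodicity, so by default a locus must carry at least one split read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

from .model import AlignedFragment, EccDNARecord, Genome, Genotype, SampleMeta, StrainSNP

__all__ = [
    "Evidence",
    "JunctionSignal",
    "CallerConfig",
    "ExtractionResult",
    "extract_junction_signals",
    "call_eccdna",
    "call_eccdna_dual_genome",
]


class Evidence(str, Enum):
    SPLIT_READ = "split_read"
    OUTWARD_PAIR = "outward_pair"


@dataclass(frozen=True)
class JunctionSignal:
    chrom: str
    left_bp: int  # 0-based circle start
    right_bp: int  # 0-based exclusive circle end
    evidence: Evidence
    read_id: str

    def __post_init__(self) -> None:
        if self.right_bp <= self.left_bp:
            raise ValueError("right_bp must exceed left_bp")


@dataclass
class CallerConfig:
    """Tunables of the junction caller.

    ``min_softclip`` is the shortest clipped segment considered re-alignable
    (shorter clips carry too little sequence to place uniquely);
    ``require_split`` demands base-resolution evidence for every locus.
    """

    min_size: int = 50
    max_size: int = 10_000
    min_softclip: int = 10
    min_support: int = 1
    require_split: bool = True
    mapq_min: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.min_size < self.max_size):
            raise ValueError("need 0 < min_size < max_size")
        if self.min_softclip < 5:
            raise ValueError("min_softclip must be >= 5")


@dataclass
class ExtractionResult:
    signals: List[JunctionSignal] = field(default_factory=list)
    n_ambiguous: int = 0  # clipped segments with >=2 exact placements
    n_clipped_reads: int = 0  # reads with a usable soft clip
    n_outward_pairs: int = 0

    def __iter__(self):
        return iter(self.signals)

    def __len__(self) -> int:
        return len(self.signals)


def _find_all(haystack: str, needle: str) -> List[int]:
    """All start offsets of exact occurrences of needle in haystack."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _softclips(frag: AlignedFragment) -> Tuple[int, int]:
    ops = frag.cigar_ops
    pre = ops[0][0] if ops and ops[0][1] == "S" else 0
    suf = ops[-1][0] if ops and ops[-1][1] == "S" else 0
    return pre, suf


def extract_junction_signals(
    fragments: Iterable[AlignedFragment],
    genome: Genome,
    cfg: CallerConfig,
) -> ExtractionResult:
    """Scan aligned fragments for circle-junction evidence.

    For a suffix clip the aligned part ends at the candidate circle end; the
    clipped sequence is the continuation past the junction and must re-align
    exactly at the circle start, upstream within ``max_size``.  A prefix clip
    is the mirror case: the aligned part starts at the candidate circle
    start and the clip is the sequence leading into the junction, ending at
    the circle end downstream.  Clips that place at two or more positions in
    the search window are ambiguous and dropped (tallied).
    """
    res = ExtractionResult()
    pending_mates: Dict[str, AlignedFragment] = {}

    for frag in fragments:
        if frag.chrom not in genome:
            raise KeyError(f"no reference sequence for chromosome {frag.chrom!r}")
        chrom_seq = genome[frag.chrom]
        pre, suf = _softclips(frag)

        if suf >= cfg.min_softclip:
            res.n_clipped_reads += 1
            clip = frag.seq[len(frag.seq) - suf :]
            right_bp = frag.reference_end
            lo = max(0, right_bp - cfg.max_size - suf)
            hits = [
                lo + h
                for h in _find_all(chrom_seq[lo:right_bp], clip)
                if cfg.min_size <= right_bp - (lo + h) <= cfg.max_size
            ]
            if len(hits) > 1:
                res.n_ambiguous += 1
            elif len(hits) == 1:
                res.signals.append(
                    JunctionSignal(
                        chrom=frag.chrom,
                        left_bp=hits[0],
                        right_bp=right_bp,
                        evidence=Evidence.SPLIT_READ,
                        read_id=frag.read_id,
                    )
                )

        if pre >= cfg.min_softclip:
            res.n_clipped_reads += 1
            clip = frag.seq[:pre]
            left_bp = frag.pos
            hi = min(len(chrom_seq), left_bp + cfg.max_size)
            hits = [
                left_bp + h + pre
                for h in _find_all(chrom_seq[left_bp:hi], clip)
                if cfg.min_size <= (left_bp + h + pre) - left_bp <= cfg.max_size
            ]
            if len(hits) > 1:
                res.n_ambiguous += 1
            elif len(hits) == 1:
                res.signals.append(
                    JunctionSignal(
                        chrom=frag.chrom,
                        left_bp=left_bp,
                        right_bp=hits[0],
                        evidence=Evidence.SPLIT_READ,
                        read_id=frag.read_id,
                    )
                )

        # outward-facing pair detection: handled once per template when the
        # second mate arrives
        if frag.is_paired and not frag.is_supplementary:
            mate = pending_mates.pop(frag.read_id, None)
            if mate is None:
                pending_mates[frag.read_id] = frag
            else:
                sig = _outward_signal(mate, frag, cfg)
                if sig is not None:
                    res.signals.append(sig)
                    res.n_outward_pairs += 1

    return res


def _outward_signal(
    a: AlignedFragment, b: AlignedFragment, cfg: CallerConfig
) -> Optional[JunctionSignal]:
    if a.chrom != b.chrom:
        return None
    left, right = (a, b) if a.pos <= b.pos else (b, a)
    if not (left.is_reverse and not right.is_reverse):
        return None
    left_bp = left.pos
    right_bp = right.reference_end
    size = right_bp - left_bp
    if not (cfg.min_size <= size <= cfg.max_size):
        return None
    return JunctionSignal(
        chrom=left.chrom,
        left_bp=left_bp,
        right_bp=right_bp,
        evidence=Evidence.OUTWARD_PAIR,
        read_id=left.read_id,
    )


def call_eccdna(
    signals: Iterable[JunctionSignal],
    cfg: CallerConfig,
    sample: Optional[SampleMeta] = None,
) -> List[EccDNARecord]:
    """Merge junction signals into eccDNA loci.

    Signals with identical (chrom, left_bp, right_bp) collapse into one
    locus; support is the number of distinct templates (read ids), so a
    rolling-circle concatemer re-reading the same junction from the same
    template never double-counts.
    """
    by_locus: Dict[Tuple[str, int, int], Dict[str, set]] = {}
    for sig in signals:
        key = (sig.chrom, sig.left_bp, sig.right_bp)
        slot = by_locus.setdefault(key, {"reads": set(), "split": set()})
        slot["reads"].add(sig.read_id)
        if sig.evidence is Evidence.SPLIT_READ:
            slot["split"].add(sig.read_id)

    records: List[EccDNARecord] = []
    for (chrom, left, right), slot in by_locus.items():
        size = right - left
        if not (cfg.min_size <= size <= cfg.max_size):
            continue
        if cfg.require_split and not slot["split"]:
            continue
        support = len(slot["reads"])
        if support < cfg.min_support:
            continue
        records.append(
            EccDNARecord(
                chrom=chrom,
                start=left,
                end=right,
                support=support,
                sample_id=sample.sample_id if sample else "",
                genotype=sample.genotype if sample else Genotype.OTHER,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def call_eccdna_dual_genome(
    records_A: Iterable[EccDNARecord],
    records_B: Iterable[EccDNARecord],
    snps: Optional[List[StrainSNP]] = None,
) -> List[EccDNARecord]:
    """Keep only loci called under both strain genomes.

    The two strain genomes are colinear (they differ only at the listed
    SNPs), so the intersection is by exact (chrom, start, end).  Records
    from genome A are retained as the canonical representation.
    """
    keys_b = {r.interval for r in records_B}
    return [r for r in records_A if r.interval in keys_b]
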