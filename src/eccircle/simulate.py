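"""Synthetic inputs for the whole pipeline, with full truth logs.

The generator emulates the structure of cell-free eccDNA sequencing data:

* a toy reference genome pair — two colinear "strains" differing only at a
  listed set of SNPs (stand-in for C57BL/6 vs BALB/c) — with planted
  genomic-element annotations;
* circle populations whose sizes follow a two-Gaussian mixture with
  clusters near 202 bp and 338 bp, thinned by a 10-bp periodic comb, and
  whose mixture weight shifts with genotype (wild type is dominated by the
  first cluster; Dnase1l3 knockout by the second);
* paired-end reads drawn from each circle via a single-cut fragment model:
  the circle is opened at a uniformly random position and 75-bp reads are
  taken off both fragment ends, so reads that traverse the junction emerge
  as soft-clipped split alignments and the rest provide interior coverage
  for SNP genotyping.  Rolling-circle libraries use many short fragments
  per circle instead of one full-length fragment;
* a linear-DNA background of concordant inward-facing pairs;
* pregnancy scenarios mixing maternal circles with fetal circles whose
  reads are haplotyped over the strain SNPs (the heterozygous fetus
  contributes strain-A and strain-B haplotypes in equal proportion).

Everything is driven by one integer seed through named per-stage
generators, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .io import write_elements_bed, write_fasta, write_sam, write_snp_table
from .model import (
    ELEMENT_CLASSES,
    AlignedFragment,
    EccDNARecord,
    Genome,
    GenomeElementSet,
    Genotype,
    LibraryType,
    Origin,
    SampleMeta,
    StrainSNP,
)

__all__ = [
    "SizeLaw",
    "ScenarioConfig",
    "SyntheticReference",
    "TrueCircle",
    "SimulatedSample",
    "WT_SIZE_LAW",
    "D1L3KO_SIZE_LAW",
    "stage_rng",
    "make_genome",
    "write_reference",
    "sample_circles",
    "emit_reads",
    "simulate_scenario",
    "scenario_preset",
    "SCENARIOS",
]

_STAGE_IDS = {"genome": 1, "circles": 2, "reads": 3, "expected": 4, "background": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one pipeline stage, derived from the run
    seed so stages are reproducible in isolation."""
    return np.random.default_rng([int(seed), _STAGE_IDS[stage]])


# --------------------------------------------------------------------------
# size law


@dataclass(frozen=True)
class SizeLaw:
    """Bimodal circle-size law: two Gaussian clusters plus a 10-bp comb.

    ``w1`` is the weight of the first (short) cluster; ``comb_depth`` in
    [0, 1] thins sizes away from the comb phase, producing the sharp 10-bp
    periodic subpeaks seen in plasma eccDNA profiles (depth 0 disables the
    comb).  Sampled sizes are integers >= ``min_size``.
    """

    mean1: float = 202.0
    sd1: float = 22.0
    mean2: float = 338.0
    sd2: float = 30.0
    w1: float = 0.78
    comb_period: int = 10
    comb_depth: float = 0.0
    comb_phase: int = 2
    min_size: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.w1 <= 1.0):
            raise ValueError("w1 must be in [0, 1]")
        if self.comb_period <= 0:
            raise ValueError("comb period must be positive")
        if not (0.0 <= self.comb_depth <= 1.0):
            raise ValueError("comb depth must be in [0, 1]")

    def with_weight(self, w1: float) -> "SizeLaw":
        return replace(self, w1=w1)

    def _accept_prob(self, sizes: np.ndarray) -> np.ndarray:
        if self.comb_depth == 0.0:
            return np.ones_like(sizes, dtype=float)
        phase = 2.0 * np.pi * (sizes - self.comb_phase) / self.comb_period
        return 1.0 - self.comb_depth * (1.0 - np.cos(phase)) / 2.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n integer sizes by rejection sampling."""
        out: List[np.ndarray] = []
        remaining = n
        while remaining > 0:
            m = max(64, int(remaining * 1.8))
            comp2 = rng.random(m) >= self.w1
            x = np.where(
                comp2,
                rng.normal(self.mean2, self.sd2, m),
                rng.normal(self.mean1, self.sd1, m),
            )
            s = np.rint(x).astype(np.int64)
            keep = s >= self.min_size
            keep &= rng.random(m) < self._accept_prob(s)
            s = s[keep][:remaining]
            out.append(s)
            remaining -= len(s)
        return np.concatenate(out)

    def cdf_discrete(self, s) -> np.ndarray:
        """P(size <= s) for integer s, comb disabled.

        Sizes are rounded normals truncated below at ``min_size``, so the
        discrete CDF is the continuous mixture CDF evaluated at s + 0.5,
        renormalised over [min_size, inf).
        """
        if self.comb_depth != 0.0:
            raise ValueError("closed-form CDF only available with comb_depth=0")
        s = np.asarray(s, dtype=float)

        def f0(x):
            return self.w1 * norm.cdf(x, self.mean1, self.sd1) + (
                1.0 - self.w1
            ) * norm.cdf(x, self.mean2, self.sd2)

        lo = f0(self.min_size - 0.5)
        return np.clip((f0(s + 0.5) - lo) / (1.0 - lo), 0.0, 1.0)


WT_SIZE_LAW = SizeLaw(w1=0.78)
D1L3KO_SIZE_LAW = SizeLaw(w1=0.30)


# --------------------------------------------------------------------------
# reference genomes


@dataclass
class SyntheticReference:
    genome_a: Genome  # maternal strain
    genome_b: Genome  # paternal strain (colinear, differs only at SNPs)
    elements: GenomeElementSet
    snps: List[StrainSNP]
    element_fractions: Dict[str, float] = field(default_factory=dict)


_ELEMENT_LENGTHS = {
    "five_prime_UTR": (100, 400),
    "three_prime_UTR": (200, 800),
    "gene_body": (2_000, 10_000),
    "CpG_island": (300, 1_000),
    "repeat": (150, 500),
}

DEFAULT_ELEMENT_FRACTIONS = {
    "five_prime_UTR": 0.01,
    "three_prime_UTR": 0.02,
    "gene_body": 0.35,
    "CpG_island": 0.01,
    "repeat": 0.20,
}

_BASES = np.array(list("ACGT"))


def make_genome(
    n_chroms: int = 2,
    lengths: Optional[Sequence[int]] = None,
    gc: float = 0.42,
    n_snps: int = 600,
    element_fractions: Optional[Dict[str, float]] = None,
    seed: int = 0,
) -> SyntheticReference:
    """Random toy genome pair with planted elements and strain SNPs.

    Strain B equals strain A except for substitutions at the emitted SNP
    positions, so the two genomes share coordinates exactly.
    """
    rng = stage_rng(seed, "genome")
    if lengths is None:
        lengths = [300_000] * n_chroms
    if any(l < 10_000 for l in lengths):
        raise ValueError("chromosome lengths must be >= 10 kb")
    fracs = dict(DEFAULT_ELEMENT_FRACTIONS if element_fractions is None else element_fractions)

    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs_a: Dict[str, str] = {}
    for i, length in enumerate(lengths):
        codes = rng.choice(4, size=length, p=p)
        seqs_a[f"chr{i + 1}"] = base_bytes[codes].tobytes().decode("ascii")
    genome_a = Genome(seqs_a)
    chroms = list(seqs_a)
    total = sum(lengths)

    # planted element intervals, non-overlapping within each class
    intervals: Dict[str, List[Tuple[str, int, int]]] = {}
    achieved: Dict[str, float] = {}
    for cls, frac in fracs.items():
        lo, hi = _ELEMENT_LENGTHS.get(cls, (200, 1_000))
        placed: List[Tuple[str, int, int]] = []
        occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
        covered = 0
        attempts = 0
        target = frac * total
        while covered < target and attempts < 50 * max(1, int(target / lo)):
            attempts += 1
            ci = int(rng.integers(n_chroms))
            chrom, clen = chroms[ci], lengths[ci]
            span = int(rng.integers(lo, hi + 1))
            if span >= clen:
                continue
            start = int(rng.integers(0, clen - span))
            end = start + span
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            placed.append((chrom, start, end))
            covered += span
        intervals[cls] = placed
        achieved[cls] = covered / total
    elements = GenomeElementSet(intervals=intervals)

    # strain SNPs at distinct positions
    flat = rng.choice(total, size=n_snps, replace=False)
    offsets = np.cumsum([0] + list(lengths))
    snps: List[StrainSNP] = []
    for fp in sorted(int(x) for x in flat):
        ci = int(np.searchsorted(offsets, fp, side="right") - 1)
        chrom = chroms[ci]
        pos = fp - int(offsets[ci])
        ref = genome_a[chrom][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snps.append(StrainSNP(chrom=chrom, pos=pos, allele_A=ref, allele_B=alt))

    seqs_b = {c: list(s) for c, s in seqs_a.items()}
    for snp in snps:
        seqs_b[snp.chrom][snp.pos] = snp.allele_B
    genome_b = Genome({c: "".join(s) for c, s in seqs_b.items()})

    return SyntheticReference(
        genome_a=genome_a,
        genome_b=genome_b,
        elements=elements,
        snps=snps,
        element_fractions=achieved,
    )


def write_reference(ref: SyntheticReference, outdir) -> Dict[str, object]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, object] = {}
    paths["genome_a"] = outdir / "strainA.fa"
    paths["genome_b"] = outdir / "strainB.fa"
    write_fasta(ref.genome_a, paths["genome_a"])
    write_fasta(ref.genome_b, paths["genome_b"])
    paths["elements"] = write_elements_bed(ref.elements, outdir / "elements")
    paths["snps"] = outdir / "strain_snps.tsv"
    write_snp_table(ref.snps, paths["snps"])
    return paths


# --------------------------------------------------------------------------
# circles


@dataclass(frozen=True)
class TrueCircle:
    chrom: str
    start: int
    end: int
    is_fetal: bool = False
    haplotype: str = "A"  # which strain genome the molecule carries

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def sample_circles(
    genome: Genome,
    size_law: SizeLaw,
    n: int,
    rng: np.random.Generator,
    snps: Optional[Sequence[StrainSNP]] = None,
    snp_clearance: int = 0,
    is_fetal: bool = False,
    haplotype: str = "A",
) -> List[TrueCircle]:
    """Place n circles with sizes from the law and uniform starts.

    With ``snp_clearance > 0`` a circle is redrawn if any strain SNP lies
    within that many bases of either breakpoint (inside the circle), so
    junction-spanning reads are haplotype-neutral while interior SNPs
    remain available for genotyping.
    """
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    snp_pos: Dict[str, np.ndarray] = {}
    if snps and snp_clearance > 0:
        by_chrom: Dict[str, List[int]] = {}
        for s in snps:
            by_chrom.setdefault(s.chrom, []).append(s.pos)
        snp_pos = {c: np.asarray(sorted(v)) for c, v in by_chrom.items()}

    circles: List[TrueCircle] = []
    sizes = size_law.sample(n, rng)
    i = 0
    while len(circles) < n:
        if i >= len(sizes):
            sizes = np.concatenate([sizes, size_law.sample(n, rng)])
        size = int(sizes[i])
        i += 1
        ci = int(rng.choice(len(chroms), p=probs))
        chrom, clen = chroms[ci], int(lengths[ci])
        if size > clen:
            continue
        start = int(rng.integers(0, clen - size + 1))
        end = start + size
        if snp_pos:
            pos = snp_pos.get(chrom)
            if pos is not None:
                near_left = np.searchsorted(pos, start) != np.searchsorted(
                    pos, min(start + snp_clearance, end)
                )
                near_right = np.searchsorted(
                    pos, max(end - snp_clearance, start)
                ) != np.searchsorted(pos, end)
                if near_left or near_right:
                    sizes = np.append(sizes, size)  # size kept, position redrawn
                    continue
        circles.append(
            TrueCircle(chrom=chrom, start=start, end=end, is_fetal=is_fetal, haplotype=haplotype)
        )
    return circles


# --------------------------------------------------------------------------
# scenarios and read emission


@dataclass
class ScenarioConfig:
    """One simulated sample's generating conditions."""

    name: str = "wt"
    genotype: Genotype = Genotype.WT
    size_law: SizeLaw = WT_SIZE_LAW
    n_circles: int = 500
    fragments_per_circle: int = 12
    read_length: int = 75
    n_background_pairs: int = 1_000
    error_rate: float = 0.001
    library: LibraryType = LibraryType.TAGMENTATION
    rca_fragment_mean: int = 200
    rca_fragments_per_circle: int = 30
    fetal_proportion: float = 0.0
    fetal_size_law: Optional[SizeLaw] = None
    snp_clearance: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_circles < 0 or self.n_background_pairs < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.fetal_proportion <= 1.0):
            raise ValueError("fetal_proportion must be in [0, 1]")


@dataclass
class SimulatedSample:
    config: ScenarioConfig
    meta: SampleMeta
    circles: List[TrueCircle]
    fragments: List[AlignedFragment]
    truth: Dict


def _segments(
    circle: TrueCircle, c0: int, i0: int, i1: int
) -> List[Tuple[int, int]]:
    """Reference intervals covered by fragment offsets [i0, i1)."""
    size = circle.size
    o0 = (c0 + i0) % size
    length = i1 - i0
    if o0 + length <= size:
        return [(circle.start + o0, circle.start + o0 + length)]
    len1 = size - o0
    return [
        (circle.start + o0, circle.end),
        (circle.start, circle.start + length - len1),
    ]


def _read_for(
    circle: TrueCircle,
    c0: int,
    i0: int,
    i1: int,
    hap_genome: Genome,
    read_id: str,
    is_read1: bool,
    is_reverse: bool,
    rng: np.random.Generator,
    error_rate: float,
) -> Tuple[AlignedFragment, int]:
    """Build one aligned read; returns the fragment and, for a
    junction-spanning read, the shorter of its two segment lengths
    (0 for a contiguous read)."""
    segs = _segments(circle, c0, i0, i1)
    seq = "".join(hap_genome.fetch(circle.chrom, s, e) for s, e in segs)
    if error_rate > 0:
        seq = _mutate(seq, rng, error_rate)
    if len(segs) == 1:
        pos = segs[0][0]
        cigar = f"{len(seq)}M"
        min_seg = 0
    else:
        len1 = segs[0][1] - segs[0][0]
        len2 = segs[1][1] - segs[1][0]
        min_seg = min(len1, len2)
        if len1 >= len2:
            pos = segs[0][0]
            cigar = f"{len1}M{len2}S"
        else:
            pos = segs[1][0]
            cigar = f"{len1}S{len2}M"
    frag = AlignedFragment(
        read_id=read_id,
        chrom=circle.chrom,
        pos=pos,
        cigar=cigar,
        mapq=60,
        seq=seq,
        is_reverse=is_reverse,
        is_paired=True,
        is_proper=len(segs) == 1,
        is_read1=is_read1,
    )
    return frag, min_seg


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        chars[pos] = str(rng.choice([b for b in "ACGT" if b != chars[pos]]))
    return "".join(chars)


def emit_reads(
    circles: Sequence[TrueCircle],
    genome_a: Genome,
    cfg: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    genome_b: Optional[Genome] = None,
) -> Tuple[List[AlignedFragment], Dict]:
    """Paired-end reads for a circle population plus linear background.

    Each fragment is the circle opened at a uniform cut (tagmentation) or a
    shorter sonicated piece of a rolling-circle concatemer; 75-bp reads off
    both fragment ends are aligned back to the linear reference, junction
    crossers becoming soft-clipped split reads.  The truth log records, per
    circle, the largest "minimum split-segment length" over its emitted
    junction reads — enough to score caller recall at any soft-clip
    threshold — and marks circles with no junction-spanning read as
    undetectable.
    """
    if rng is None:
        rng = stage_rng(cfg.seed, "reads")
    read_len = cfg.read_length
    fragments: List[AlignedFragment] = []
    truth_circles = []
    n_pairs = 0

    for ci, circle in enumerate(circles):
        hap = genome_a if circle.haplotype == "A" else genome_b
        if hap is None:
            raise ValueError("haplotype B circle but no strain-B genome given")
        size = circle.size
        if cfg.library is LibraryType.ROLLING_CIRCLE:
            n_frags = cfg.rca_fragments_per_circle
        else:
            n_frags = cfg.fragments_per_circle
        best_min_seg = 0
        n_junction_reads = 0
        for fi in range(n_frags):
            c0 = int(rng.integers(size))
            if cfg.library is LibraryType.ROLLING_CIRCLE:
                fl = int(
                    np.clip(rng.normal(cfg.rca_fragment_mean, 30), 60, size)
                )
            else:
                fl = size
            rid = f"{cfg.name}.c{ci}.f{fi}"
            r1_len = min(read_len, fl)
            r1, ms1 = _read_for(
                circle, c0, 0, r1_len, hap, rid, True, False, rng, cfg.error_rate
            )
            r2_lo = max(0, fl - read_len)
            r2, ms2 = _read_for(
                circle, c0, r2_lo, fl, hap, rid, False, True, rng, cfg.error_rate
            )
            r1.mate_chrom, r1.mate_pos, r1.mate_is_reverse = r2.chrom, r2.pos, True
            r2.mate_chrom, r2.mate_pos, r2.mate_is_reverse = r1.chrom, r1.pos, False
            fragments.extend([r1, r2])
            n_pairs += 1
            for ms in (ms1, ms2):
                if ms > 0:
                    n_junction_reads += 1
                    best_min_seg = max(best_min_seg, ms)
        truth_circles.append(
            {
                "chrom": circle.chrom,
                "start": circle.start,
                "end": circle.end,
                "size": size,
                "is_fetal": circle.is_fetal,
                "haplotype": circle.haplotype,
                "n_junction_reads": n_junction_reads,
                "best_min_split_segment": best_min_seg,
                "detectable": n_junction_reads > 0,
            }
        )

    # linear background: concordant inward-facing pairs on the maternal genome
    chroms = list(genome_a)
    lengths = np.array([len(genome_a[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    for bi in range(cfg.n_background_pairs):
        ci = int(rng.choice(len(chroms), p=probs))
        chrom, clen = chroms[ci], int(lengths[ci])
        fl = int(np.clip(rng.normal(166, 15), 60, 400))
        start = int(rng.integers(0, max(1, clen - fl)))
        rid = f"{cfg.name}.bg{bi}"
        r1_len = min(read_len, fl)
        seq1 = genome_a.fetch(chrom, start, start + r1_len)
        seq2 = genome_a.fetch(chrom, start + fl - r1_len, start + fl)
        if cfg.error_rate > 0:
            seq1 = _mutate(seq1, rng, cfg.error_rate)
            seq2 = _mutate(seq2, rng, cfg.error_rate)
        r1 = AlignedFragment(
            read_id=rid, chrom=chrom, pos=start, cigar=f"{r1_len}M", mapq=60,
            seq=seq1, is_reverse=False, is_paired=True, is_proper=True,
            is_read1=True, mate_chrom=chrom, mate_pos=start + fl - r1_len,
            mate_is_reverse=True,
        )
        r2 = AlignedFragment(
            read_id=rid, chrom=chrom, pos=start + fl - r1_len, cigar=f"{r1_len}M",
            mapq=60, seq=seq2, is_reverse=True, is_paired=True, is_proper=True,
            is_read1=False, mate_chrom=chrom, mate_pos=start,
            mate_is_reverse=False,
        )
        fragments.extend([r1, r2])
        n_pairs += 1

    truth = {
        "scenario": cfg.name,
        "seed": cfg.seed,
        "n_circles": len(circles),
        "n_read_pairs": n_pairs,
        "n_background_pairs": cfg.n_background_pairs,
        "circles": truth_circles,
    }
    return fragments, truth


def simulate_scenario(
    cfg: ScenarioConfig, ref: SyntheticReference
) -> SimulatedSample:
    """Sample circles per the scenario's size law(s) and emit reads."""
    rng_c = stage_rng(cfg.seed, "circles")
    n_fetal = int(round(cfg.n_circles * cfg.fetal_proportion))
    n_maternal = cfg.n_circles - n_fetal
    clearance = cfg.snp_clearance
    circles = sample_circles(
        ref.genome_a, cfg.size_law, n_maternal, rng_c,
        snps=ref.snps, snp_clearance=clearance, is_fetal=False, haplotype="A",
    )
    if n_fetal:
        fetal_law = cfg.fetal_size_law or cfg.size_law
        # each fetal molecule carries one of the two fetal haplotypes
        n_b = int(rng_c.binomial(n_fetal, 0.5))
        for hap, n_hap in (("B", n_b), ("A", n_fetal - n_b)):
            if n_hap:
                circles.extend(
                    sample_circles(
                        ref.genome_a, fetal_law, n_hap, rng_c,
                        snps=ref.snps, snp_clearance=clearance,
                        is_fetal=True, haplotype=hap,
                    )
                )
    rng_r = stage_rng(cfg.seed, "reads")
    fragments, truth = emit_reads(
        circles, ref.genome_a, cfg, rng=rng_r, genome_b=ref.genome_b
    )
    meta = SampleMeta(
        sample_id=cfg.name,
        genotype=cfg.genotype,
        library=cfg.library,
        mappable_reads=truth["n_read_pairs"],
    )
    return SimulatedSample(
        config=cfg, meta=meta, circles=circles, fragments=fragments, truth=truth
    )


def write_sample(sample: SimulatedSample, genome: Genome, outdir) -> Dict[str, Path]:
    """Write a simulated sample's SAM, truth BED and truth log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = sample.config.name
    paths = {
        "sam": outdir / f"{name}.sam",
        "truth_bed": outdir / f"{name}.truth.bed",
        "truth_json": outdir / f"{name}.truth.json",
    }
    write_sam(sample.fragments, genome, paths["sam"])
    with open(paths["truth_bed"], "w") as fh:
        for c in sample.circles:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.haplotype}\t0\t.\n")
    with open(paths["truth_json"], "w") as fh:
        json.dump(sample.truth, fh, indent=1)
    return paths


def write_fastq(sample: SimulatedSample, outdir) -> Tuple[Path, Path]:
    """Optional FASTQ emission for end-to-end runs with a real aligner."""
    comp = str.maketrans("ACGTN", "TGCAN")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p1 = outdir / f"{sample.config.name}_R1.fastq"
    p2 = outdir / f"{sample.config.name}_R2.fastq"
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for frag in sample.fragments:
            seq = frag.seq.translate(comp)[::-1] if frag.is_reverse else frag.seq
            out = f1 if frag.is_read1 else f2
            out.write(f"@{frag.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return p1, p2


# --------------------------------------------------------------------------
# presets: the study's group structure

_PREGNANCY_BASE = dict(
    fetal_proportion=0.25,
    snp_clearance=80,
    n_circles=500,
)

SCENARIOS: Dict[str, Dict] = {
    "wt": dict(genotype=Genotype.WT, size_law=SizeLaw(w1=0.78)),
    "d1ko": dict(genotype=Genotype.DNASE1_KO, size_law=SizeLaw(w1=0.78)),
    "d1l3ko": dict(genotype=Genotype.DNASE1L3_KO, size_law=SizeLaw(w1=0.30)),
    # systemic nuclease effect: fetally produced DNASE1L3 shifts the whole
    # plasma pool, so maternal and fetal circles share the scenario's law
    "pregnancy_wtxwt": dict(
        genotype=Genotype.WT, size_law=SizeLaw(w1=0.68), **_PREGNANCY_BASE
    ),
    "pregnancy_koxko": dict(
        genotype=Genotype.DNASE1L3_KO, size_law=SizeLaw(w1=0.22), **_PREGNANCY_BASE
    ),
    "pregnancy_koxhet": dict(
        genotype=Genotype.DNASE1L3_KO, size_law=SizeLaw(w1=0.31), **_PREGNANCY_BASE
    ),
}


def scenario_preset(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    kwargs = dict(SCENARIOS[name])
    kwargs.update(overrides)
    return ScenarioConfig(name=name, seed=seed, **kwargs)
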