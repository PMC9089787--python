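# Methods

This note documents the models and procedures implemented in `eccircle`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Junction-based eccDNA calling

A circular molecule aligned to a linear reference betrays itself at the
junction where the locus end joins back to the locus start. Two evidence
operators are implemented:

* **Split reads.** A read with a soft-clipped prefix or suffix of at
  least `min_softclip` bases (default 10) whose clipped sequence re-aligns
  as an exact match, on the same chromosome and strand, at the opposite
  breakpoint. A suffix clip anchors the circle end (the aligned part's
  reference end) and its clip must place at the circle start, upstream
  within `max_size`; a prefix clip is the mirror case. Split reads pin
  both breakpoints at base resolution, which is what makes 1-bp size
  profiles and the 10-bp periodicity observable. A clip that places at
  two or more positions in the search window is ambiguous: the signal is
  dropped and tallied, never guessed.
* **Outward-facing pairs.** Both mates on one chromosome, leftmost mate
  on the reverse strand and rightmost on the forward strand, with implied
  circle size inside `[min_size, max_size]`. These only bracket the
  breakpoints, so by default (`require_split=True`) they corroborate but
  cannot found a locus on their own.

Signals with identical `(chrom, left, right)` merge into one locus — the
unit counted everywhere downstream. Support counts distinct templates
(read ids), so a rolling-circle concatemer re-reading its junction from
one template, or the two mates of one fragment both crossing the
junction, never double-count. Defaults: `min_size=50`, `max_size=10000`,
`min_support=1`, `mapq_min=30`. Support 1 is deliberate: junction reads
are rare per circle at plasma sequencing depths, and the locus counts of
such studies (tens of thousands per ~17M read pairs) imply no deeper
support filter. Exact-match realignment (no mismatch tolerance) keeps the
caller deterministic; tolerant realignment would be a config extension.

Rolling-circle libraries go through the same operators: concatemer
fragments hit the same junction repeatedly and simply raise support. No
de-concatenation is needed at locus level.

**Dual-genome confirmation.** For strain-mixture samples, loci are called
independently against both strain genomes and intersected by exact
coordinates. This is valid because the synthetic strain pair is colinear
by construction (real strain assemblies would need liftover, out of
scope).

## Abundance and size statistics

EPM = loci / mappable read pairs × 10⁶, with mappable pairs counted after
the primary/mapped/`mapq ≥ mapq_min` filter. The published analyses this
mirrors state only "mappable reads"; the quality floor is a standard
uniqueness proxy and configurable.

Size profiles use 1-bp bins over [0, 1000] bp (needed to resolve the
10-bp subpeaks); frequencies are percent of molecules inside the range,
and pooling samples is summing count vectors. Cluster windows are
[150, 250] and [300, 450] bp, inclusive on both ends; the gap between
them belongs to neither cluster, which is why AUC1 + AUC2 < 100 for real
profiles. An empty first cluster makes the AUC ratio undefined — it is
reported as missing, never infinity, and excluded from group tests.
Ratios are reported at two decimals; internal arithmetic is full
precision.

## Genomic-context statistics

The expected overlap frequency for an element class comes from a
Monte-Carlo draw: chromosome with probability proportional to length,
start uniform, size resampled with replacement from the observed circle
sizes (controlling for the strong size-dependence of overlap
probability), and loci that would run off the chromosome redrawn — which
leaves starts uniform on the feasible range. A locus overlaps a class iff
its half-open interval intersects any class interval by ≥ 1 bp; the same
rule is applied to observed and simulated loci. Both the overlap rule
(interval vs junction-point) and end handling (redraw vs clip) are
genuinely underdetermined choices; both defaults are explicit and
config-visible. Recommended `n_sim ≥ 10⁴`; at `10⁵` the expected
frequencies are stable to well under half a percentage point.

Shared loci between two samples are counted by exact coordinates after
per-sample deduplication; percentages are reported to two decimals.

Junction motifs are the four trinucleotides around the breakpoints:
I = [start−3, start), II = [start, start+3), III = [end−3, end),
IV = [end, end+3), read from the reference forward strand (circles are
unstranded). Records within 3 bp of a chromosome edge are skipped and
tallied, so motif counts plus the skip tally always equal the input
count. Window length and offsets are parameters; the inside/outside
layout is a convention that must not be silently changed.

## Fetal/maternal partitioning

Model assumptions: mother homozygous strain A, father strain B, so the
fetus is heterozygous at every informative SNP and each fetal molecule
carries exactly one haplotype. Per molecule, base observations at covered
informative SNPs vote; a tie at any SNP, or discordant SNP calls within
the molecule, yield `unassigned` — a deliberately conservative veto
instead of probabilistic genotyping, because it is deterministic and
auditable (a fetal-specific call always has at least one strain-B
observation in its evidence record). Bases matching neither allele
(sequencing errors) are ignored; there is no base-quality weighting
(config-extensible).

Fetal fraction: FF = 100 × 2·n_fetal/(n_fetal + n_shared). The factor 2
reflects that the heterozygous fetus contributes the paternal-strain
allele on only half its molecules; the other half is counted as shared.
The summary reports both the corrected and the raw count share, since
published fractions do not state which convention was used.

A known conditioning effect: classification requires covering an
informative SNP, which favours larger circles (more interior sequence).
Fetal and shared molecules are affected identically when they share a
size law, so the FF estimate stays unbiased, but partitioned size
profiles are shifted long relative to the whole sample. Tests compare
fetal vs shared against each other, never against the unconditioned
profile.

## Group statistics

Implemented from first principles with explicit tie handling:

* Kruskal–Wallis H on mid-ranks, divided by the tie correction
  1 − Σ(t³−t)/(N³−N); p from χ² with k−1 df. All-identical input makes
  the statistic undefined (reported as such, p = 1).
* Dunn's post hoc: z = (R̄ᵢ − R̄ⱼ)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)],
  two-sided normal p. The original analyses used Prism, whose Dunn
  adjustment is ambiguous; the default here is Holm (uniformly no worse
  than Bonferroni and deterministic), with Bonferroni and none
  selectable.
* Wilcoxon rank-sum: exact null distribution (dynamic programming over
  the Gaussian-binomial recurrence) when min(n) ≤ 8 and there are no
  ties; otherwise normal approximation with tie-corrected variance and a
  0.5 continuity correction. Two-sided throughout; α = 0.05.

scipy supplies only the reference distributions (χ², normal) — and serves
as an independent oracle in the test suite, never as the implementation.

## Synthetic-data generator

What it emulates:

* **Reference pair.** Random-sequence chromosomes (GC 0.42); strain B
  equals strain A except at the emitted SNP positions, so coordinates are
  shared exactly. Elements are planted as non-overlapping intervals per
  class with recorded achieved fractions (defaults: gene body 35%,
  repeat 20%, 3′UTR 2%, 5′UTR 1%, CpG island 1%).
* **Size law.** Two Gaussian clusters (means 202 and 338 bp, sd 22 and
  30) with mixture weight `w1` on the short cluster, integerised and
  truncated at 50 bp, thinned by an optional 10-bp cosine comb
  (`comb_depth` ∈ [0,1]) to produce the periodic subpeaks. Genotype
  presets: wild type and Dnase1-knockout `w1 = 0.78`,
  Dnase1l3-knockout `w1 = 0.30` — chosen to echo the reported first-peak
  AUC contrast (medians 77.9% vs 30.3%); they are scenario parameters,
  not claims about any real dataset. Pregnancy presets place both
  maternal and fetal circles on one law per mating group
  (w1 = 0.68 / 0.31 / 0.22 for wt×wt, ko×het, ko×ko), encoding the
  *systemic* action of fetally produced nuclease; the ko×het value
  between the other two is the partial-restoration condition.
* **Reads.** A single-cut fragment model: each fragment is the circle
  opened at a uniform cut (tagmentation) or a shorter piece of a
  concatemer (~200 bp sonication, rolling circle); 75-bp reads come off
  both fragment ends. Reads crossing the junction are written exactly as
  an aligner would represent them — soft-clipped split alignments — and
  the rest give interior coverage for SNP genotyping; fragments whose
  reads both stay interior produce the outward-facing pair signature
  naturally. Twelve fragments per circle by default, so that even a
  ~450 bp circle yields a usable split read (both segments ≥ 10 bp) with
  probability above 0.96. Linear background: concordant inward pairs at
  the ~166 bp linear cfDNA fragment length. Substitution errors at rate
  0.001; mapq 60 everywhere.
* **Pregnancy mixtures.** A configured fraction of circles is fetal; each
  fetal molecule draws haplotype A or B with probability ½. Circle
  breakpoints are kept at least one read length clear of any SNP, so
  junction reads are haplotype-neutral and calling is identical under
  both strain genomes — the condition under which dual-genome
  intersection retains essentially all calls.
* **Truth logs** record every circle's coordinates, haplotype, and the
  best "minimum split-segment length" over its emitted junction reads,
  sufficient to score recall and precision at any soft-clip threshold
  without re-deriving anything.

All randomness flows from one integer seed through named per-stage
generators (genome/circles/reads/expected), so any stage reproduces in
isolation; fixed seeds give byte-identical FASTA and SAM output.

What it does **not** emulate — and hence what passing tests do not show
about real data: realistic base-quality and indel error profiles, PCR
duplicates, mappability structure and repeats that cause genuine
multi-mapping, chimeric/multi-fragment circles, mitochondrial circles,
real strain-genome structural differences, and aligner-specific clipping
behaviour. Recall/precision near 1 on this generator demonstrates the
caller's logic is correct, not that real-library recall is near 1.

## Numerical and testing choices

* Coordinates are 0-based half-open everywhere internally; BED is native,
  SAM and the SNP TSV are shifted at the parser/writer boundary, and
  `size = end − start` by construction.
* Motif ranking breaks count ties lexicographically; caller output is
  coordinate-sorted — both for determinism.
* Integer-valued size distributions are tested against their discrete
  CDFs with a sup-over-support KS statistic (the continuous-CDF KS
  machinery systematically inflates the statistic by the modal
  probability mass on tied data); the Kolmogorov p-value is then
  conservative.
* Problem sizes in tests and the acceptance script (toy genomes of
  0.6–32 Mb, 120–5,000 circles, 10⁵ Monte-Carlo loci, 2,000 null
  replicates) were chosen as the smallest scales at which the recovered
  quantities are statistically stable; parameter-recovery runs use large
  genomes specifically to keep circle density low, because overlapping
  circles contaminate each other's SNP evidence (see limitations).

## Known limitations

* Classification by majority vote can be confused when independent
  circles overlap positionally: reads from a neighbouring molecule vote
  at shared SNPs. At the circle densities of real plasma data this is
  negligible, but on small toy genomes it produces a slight downward bias
  of the fetal fraction; the discordance veto converts most such clashes
  to `unassigned` rather than misclassification.
* Exact-match clip realignment loses junction reads with an error in the
  clipped segment (~rate × clip length per read); with several junction
  reads per circle the effect on recall is negligible, but single-read
  circles are fragile.
* The fetal-fraction correction assumes a strictly heterozygous fetus;
  other crosses need a different factor.
* Outward-pair evidence contributes support only when its bracket
  coincides exactly with split-read breakpoints; a tolerance-based
  association is not implemented.
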