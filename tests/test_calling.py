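"""Junction-signal extraction and locus calling."""

import numpy as np
import pytest

import eccircle as ec
from eccircle.calling import (
    CallerConfig,
    Evidence,
    JunctionSignal,
    call_eccdna,
    call_eccdna_dual_genome,
    extract_junction_signals,
)
from eccircle.model import AlignedFragment, EccDNARecord, Genome, SampleMeta


def _random_genome(n=4000, seed=1):
    rng = np.random.default_rng(seed)
    return Genome({"chrT": "".join(rng.choice(list("ACGT"), size=n))})


@pytest.fixture(scope="module")
def genome():
    return _random_genome()


CFG = CallerConfig(min_size=50, max_size=2000, min_softclip=10)


class TestSplitReadDetection:
    def _junction_read(self, genome, start, end, matched=40, clipped=35,
                       style="suffix"):
        """Read traversing the junction of circle [start, end)."""
        seq_end = genome.fetch("chrT", end - matched, end)
        seq_start = genome.fetch("chrT", start, start + clipped)
        if style == "suffix":
            # aligned over the circle-end segment, start-segment soft-clipped
            return AlignedFragment(
                read_id="jr", chrom="chrT", pos=end - matched,
                cigar=f"{matched}M{clipped}S", mapq=60, seq=seq_end + seq_start)
        return AlignedFragment(
            read_id="jr", chrom="chrT", pos=start,
            cigar=f"{matched}S{clipped}M", mapq=60,
            seq=genome.fetch("chrT", end - matched, end)[-matched:]
            + genome.fetch("chrT", start, start + clipped))

    @pytest.mark.parametrize("style", ["suffix", "prefix"])
    def test_junction_read_pins_both_breakpoints(self, genome, style):
        start, end = 1000, 1350
        if style == "suffix":
            frag = self._junction_read(genome, start, end, style="suffix")
        else:
            matched, clipped = 40, 35
            frag = AlignedFragment(
                read_id="jr", chrom="chrT", pos=start,
                cigar=f"{matched}S{clipped}M", mapq=60,
                seq=genome.fetch("chrT", end - matched, end)
                + genome.fetch("chrT", start, start + clipped))
        res = extract_junction_signals([frag], genome, CFG)
        (sig,) = res.signals
        assert sig.evidence is Evidence.SPLIT_READ
        assert (sig.left_bp, sig.right_bp) == (start, end)

    def test_concordant_inward_pair_yields_nothing(self, genome):
        r1 = AlignedFragment(read_id="p", chrom="chrT", pos=500, cigar="50M",
                             mapq=60, seq=genome.fetch("chrT", 500, 550),
                             is_paired=True, is_read1=True,
                             mate_chrom="chrT", mate_pos=600, mate_is_reverse=True)
        r2 = AlignedFragment(read_id="p", chrom="chrT", pos=600, cigar="50M",
                             mapq=60, seq=genome.fetch("chrT", 600, 650),
                             is_reverse=True, is_paired=True, is_read1=False,
                             mate_chrom="chrT", mate_pos=500)
        res = extract_junction_signals([r1, r2], genome, CFG)
        assert len(res.signals) == 0

    def test_outward_pair_brackets_circle(self, genome):
        # leftmost mate reverse, rightmost forward; implied size 200
        left = AlignedFragment(read_id="q", chrom="chrT", pos=800, cigar="50M",
                               mapq=60, seq=genome.fetch("chrT", 800, 850),
                               is_reverse=True, is_paired=True, is_read1=True,
                               mate_chrom="chrT", mate_pos=950)
        right = AlignedFragment(read_id="q", chrom="chrT", pos=950, cigar="50M",
                                mapq=60, seq=genome.fetch("chrT", 950, 1000),
                                is_paired=True, is_read1=False,
                                mate_chrom="chrT", mate_pos=800,
                                mate_is_reverse=True)
        res = extract_junction_signals([left, right], genome, CFG)
        (sig,) = res.signals
        assert sig.evidence is Evidence.OUTWARD_PAIR
        assert (sig.left_bp, sig.right_bp) == (800, 1000)
        assert res.n_outward_pairs == 1

    def test_ambiguous_clip_dropped_and_tallied(self):
        # duplicated 60-mer: the clipped segment matches at two positions
        core = "ACGTGGCTAA" * 6
        rng = np.random.default_rng(3)
        pad = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        seq = pad(200) + core + pad(100) + core + pad(600)
        genome = Genome({"chrT": seq})
        end = len(seq) - 500
        frag = AlignedFragment(
            read_id="amb", chrom="chrT", pos=end - 40, cigar="40M15S", mapq=60,
            seq=genome.fetch("chrT", end - 40, end) + core[:15])
        res = extract_junction_signals([frag], genome, CFG)
        assert res.signals == []
        assert res.n_ambiguous == 1

    def test_missing_chromosome_is_an_error(self, genome):
        frag = AlignedFragment(read_id="x", chrom="chrZ", pos=0, cigar="20M",
                               mapq=60, seq="A" * 20)
        with pytest.raises(KeyError):
            extract_junction_signals([frag], genome, CFG)


class TestLocusCalling:
    def test_empty(self):
        assert call_eccdna([], CFG) == []

    def test_merge_distinct_reads_support_two(self):
        sigs = [JunctionSignal("chrT", 100, 300, Evidence.SPLIT_READ, "r1"),
                JunctionSignal("chrT", 100, 300, Evidence.SPLIT_READ, "r2")]
        (rec,) = call_eccdna(sigs, CFG)
        assert (rec.start, rec.end, rec.support) == (100, 300, 2)

    def test_same_template_never_double_counts(self):
        sigs = [JunctionSignal("chrT", 100, 300, Evidence.SPLIT_READ, "r1"),
                JunctionSignal("chrT", 100, 300, Evidence.SPLIT_READ, "r1")]
        (rec,) = call_eccdna(sigs, CFG)
        assert rec.support == 1

    def test_require_split_filters_outward_only_loci(self):
        sigs = [JunctionSignal("chrT", 100, 300, Evidence.OUTWARD_PAIR, "r1")]
        assert call_eccdna(sigs, CFG) == []
        relaxed = CallerConfig(min_size=50, max_size=2000, require_split=False)
        assert len(call_eccdna(sigs, relaxed)) == 1

    def test_size_window_enforced(self):
        sigs = [JunctionSignal("chrT", 0, 30, Evidence.SPLIT_READ, "r1"),
                JunctionSignal("chrT", 0, 3000, Evidence.SPLIT_READ, "r2")]
        assert call_eccdna(sigs, CFG) == []

    def test_output_sorted_and_deterministic(self, wt_calls):
        intervals = [r.interval for r in wt_calls]
        assert intervals == sorted(intervals)


class TestEndToEndRecovery:
    def test_simulated_circles_recovered(self, toy_ref, wt_sample, wt_calls):
        truth = {c.interval for c in wt_sample.circles}
        called = {r.interval for r in wt_calls}
        tp = len(truth & called)
        assert tp / len(called) >= 0.99
        assert tp / len(truth) >= 0.95

    def test_caller_deterministic(self, toy_ref, wt_sample, wt_calls):
        cfg = CallerConfig()
        again = call_eccdna(
            extract_junction_signals(wt_sample.fragments, toy_ref.genome_a, cfg).signals,
            cfg, wt_sample.meta)
        assert again == wt_calls

    def test_library_styles_agree_on_size_profile(self, toy_ref):
        """Tagmentation and rolling-circle reads from one circle population
        give matching cluster AUCs (cross-method validation)."""
        from dataclasses import replace

        from eccircle.model import LibraryType
        from eccircle.simulate import emit_reads, sample_circles, scenario_preset
        from eccircle.size import cluster_auc, size_profile

        rng = np.random.default_rng(21)
        circles = sample_circles(toy_ref.genome_a, ec.WT_SIZE_LAW, 400, rng)
        cfg = CallerConfig()
        aucs = {}
        support = {}
        for lib in (LibraryType.TAGMENTATION, LibraryType.ROLLING_CIRCLE):
            scen = replace(scenario_preset("wt", seed=22, n_circles=0),
                           library=lib, name=lib.value)
            frags, _ = emit_reads(circles, toy_ref.genome_a, scen,
                                  genome_b=toy_ref.genome_b)
            recs = call_eccdna(extract_junction_signals(frags, toy_ref.genome_a, cfg).signals, cfg)
            aucs[lib] = cluster_auc(size_profile(recs))
            support[lib] = np.mean([r.support for r in recs])
        tag, rca = aucs[LibraryType.TAGMENTATION], aucs[LibraryType.ROLLING_CIRCLE]
        assert abs(tag.auc1 - rca.auc1) < 5.0
        assert abs(tag.auc2 - rca.auc2) < 5.0
        # concatemers re-read the same junction, raising support
        assert support[LibraryType.ROLLING_CIRCLE] > support[LibraryType.TAGMENTATION]


class TestDualGenome:
    def _recs(self, intervals):
        return [EccDNARecord(chrom=c, start=s, end=e) for c, s, e in intervals]

    def test_identical_lists_unchanged(self):
        recs = self._recs([("chr1", 0, 100), ("chr1", 50, 400)])
        assert call_eccdna_dual_genome(recs, list(recs)) == recs

    def test_disjoint_lists_empty(self):
        a = self._recs([("chr1", 0, 100)])
        b = self._recs([("chr1", 5, 100)])
        assert call_eccdna_dual_genome(a, b) == []

    def test_strain_pair_retains_calls(self, toy_ref):
        """With breakpoints kept clear of SNPs, calling under either strain
        genome gives (nearly) the same loci."""
        cfg = ec.scenario_preset("pregnancy_koxhet", seed=5, n_circles=200)
        sample = ec.simulate_scenario(cfg, toy_ref)
        ccfg = CallerConfig()
        rec_a = call_eccdna(
            extract_junction_signals(sample.fragments, toy_ref.genome_a, ccfg).signals, ccfg)
        rec_b = call_eccdna(
            extract_junction_signals(sample.fragments, toy_ref.genome_b, ccfg).signals, ccfg)
        both = call_eccdna_dual_genome(rec_a, rec_b)
        assert len(both) >= 0.99 * len(rec_a)
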