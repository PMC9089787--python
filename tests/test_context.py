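"""Monte-Carlo element enrichment, shared loci, junction motifs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import discrete_ks_pvalue

from eccircle.context import (
    Locus,
    element_enrichment,
    fold_change_percent_increase,
    junction_motifs,
    shared_loci,
    simulate_expected_loci,
)
from eccircle.model import EccDNARecord, Genome, GenomeElementSet


class TestExpectedLociSimulation:
    def test_exact_count_returned(self):
        loci = simulate_expected_loci({"chr1": 10_000}, [100], 500, seed=1)
        assert len(loci) == 500

    def test_starts_uniform_on_feasible_range(self):
        loci = simulate_expected_loci({"chr1": 1_000}, [100], 4_000, seed=2)
        starts = np.array([l.start for l in loci])
        assert starts.min() >= 0 and (starts + 100).max() <= 1_000
        # uniform on the 901 feasible start positions [0, 900]
        p = discrete_ks_pvalue(starts, lambda v: np.clip((v + 1) / 901.0, 0, 1))
        assert p > 0.01

    def test_chromosome_sampling_proportional_to_length(self):
        n = 100_000
        loci = simulate_expected_loci({"c1": 50_000, "c2": 100_000}, [100], n, seed=3)
        frac2 = sum(l.chrom == "c2" for l in loci) / n
        # binomial 99.9% CI around 2/3
        se = np.sqrt(2 / 3 * 1 / 3 / n)
        assert abs(frac2 - 2 / 3) < 3.3 * se

    def test_oversized_locus_is_an_error(self):
        with pytest.raises(ValueError):
            simulate_expected_loci({"chr1": 1_000}, [2_000], 10, seed=4)


class TestElementEnrichment:
    def test_whole_genome_element_gives_unit_fold_change(self):
        elements = GenomeElementSet(intervals={"gene_body": [("chr1", 0, 10_000)]})
        recs = [EccDNARecord(chrom="chr1", start=i * 10, end=i * 10 + 100) for i in range(50)]
        sim = simulate_expected_loci({"chr1": 10_000}, [100], 1_000, seed=5)
        res = element_enrichment(recs, elements, sim)["gene_body"]
        assert res.observed_freq == 1.0
        assert res.expected_freq == 1.0
        assert res.fold_change == 1.0

    def test_null_self_consistency(self, toy_ref):
        """Records drawn by the expected-locus simulator itself show no
        enrichment in any class."""
        sizes = [int(s) for s in np.random.default_rng(6).normal(300, 60, 2_000)]
        sizes = [max(60, s) for s in sizes]
        obs = simulate_expected_loci(toy_ref.genome_a.chrom_sizes, sizes, 100_000, seed=7)
        sim = simulate_expected_loci(toy_ref.genome_a.chrom_sizes, sizes, 100_000, seed=8)
        res = element_enrichment(obs, toy_ref.elements, sim)
        for cls, e in res.items():
            assert e.fold_change is not None
            assert 0.9 <= e.fold_change <= 1.1, (cls, e.fold_change)

    def test_expected_frequency_convergence(self, toy_ref):
        sizes = [300] * 100
        e1 = element_enrichment(
            simulate_expected_loci(toy_ref.genome_a.chrom_sizes, sizes, 1_000, seed=9),
            toy_ref.elements,
            simulate_expected_loci(toy_ref.genome_a.chrom_sizes, sizes, 100_000, seed=10),
        )
        e2 = element_enrichment(
            simulate_expected_loci(toy_ref.genome_a.chrom_sizes, sizes, 1_000, seed=9),
            toy_ref.elements,
            simulate_expected_loci(toy_ref.genome_a.chrom_sizes, sizes, 200_000, seed=11),
        )
        for cls in e1:
            assert abs(e1[cls].expected_freq - e2[cls].expected_freq) < 0.005

    def test_percent_increase_arithmetic(self):
        assert fold_change_percent_increase(1.0, 1.53) == pytest.approx(53.0)

    def test_empty_simulation_rejected(self, toy_ref):
        recs = [EccDNARecord(chrom="chr1", start=0, end=100)]
        with pytest.raises(ValueError):
            element_enrichment(recs, toy_ref.elements, [])


class TestSharedLoci:
    @pytest.mark.parametrize(
        "n_a,n_b,n_shared,pct_a,pct_b",
        [
            (246_855, 371_816, 603, 0.24, 0.16),
            (34_376, 128_351, 68, 0.20, 0.05),
            (13_941, 55_280, 12, 0.09, 0.02),
        ],
    )
    def test_reported_overlap_percentages(self, n_a, n_b, n_shared, pct_a, pct_b):
        """Shared-locus percentages reproduce the reported cohort values."""
        shared = [("chr1", i * 1000, i * 1000 + 200) for i in range(n_shared)]
        only_a = [("chr2", i * 1000, i * 1000 + 200) for i in range(n_a - n_shared)]
        only_b = [("chr3", i * 1000, i * 1000 + 200) for i in range(n_b - n_shared)]
        set_a = [Locus(*t) for t in shared + only_a]
        set_b = [Locus(*t) for t in shared + only_b]
        res = shared_loci(set_a, set_b)
        assert res.n_shared == n_shared
        assert res.rounded() == (pct_a, pct_b)

    def test_identical_sets(self):
        recs = [Locus("chr1", 0, 100), Locus("chr1", 500, 800)]
        res = shared_loci(recs, recs)
        assert res.rounded() == (100.0, 100.0)

    def test_empty_set_percentage_undefined(self):
        res = shared_loci([], [Locus("chr1", 0, 100)])
        assert res.pct_of_a is None and res.pct_of_b == 0.0

    loci_strategy = st.lists(
        st.tuples(st.sampled_from(["c1", "c2"]), st.integers(0, 50)).map(
            lambda t: Locus(t[0], t[1] * 10, t[1] * 10 + 100)
        ),
        max_size=40,
    )

    @settings(max_examples=50, deadline=None)
    @given(a=loci_strategy, b=loci_strategy)
    def test_symmetry_and_subset_monotonicity(self, a, b):
        res = shared_loci(a, b)
        assert res.n_shared == shared_loci(b, a).n_shared
        assert shared_loci(a[: len(a) // 2], b).n_shared <= res.n_shared


class TestJunctionMotifs:
    def test_deterministic_substring_extraction(self):
        genome = Genome({"chrM": "AAACCCGGGTTTAAACCCGGGTTT"})
        rec = EccDNARecord(chrom="chrM", start=6, end=15)
        (combo,), skipped = junction_motifs([rec], genome, top_k=5)
        assert (combo.motif_I, combo.motif_II, combo.motif_III, combo.motif_IV) == (
            "CCC", "GGG", "AAA", "CCC")
        assert combo.count == 1 and combo.rank == 1 and skipped == 0

    def test_edge_records_skipped_and_tallied(self):
        genome = Genome({"chrM": "ACGTACGTACGTACGT"})
        records = [
            EccDNARecord(chrom="chrM", start=1, end=8),   # start-3 < 0
            EccDNARecord(chrom="chrM", start=4, end=15),  # end+3 > len
            EccDNARecord(chrom="chrM", start=4, end=12),
        ]
        combos, skipped = junction_motifs(records, genome, top_k=0)
        assert skipped == 2
        assert sum(c.count for c in combos) + skipped == len(records)

    def test_planted_motif_ranks_first(self):
        """Breakpoints planted next to one motif context dominate the
        ranking."""
        rng = np.random.default_rng(12)
        seq = list(rng.choice(list("ACGT"), size=20_000))
        starts = [1_000 + 700 * i for i in range(20)]
        for s in starts:
            seq[s - 3 : s + 3] = list("CCATCC")      # motifs I, II
            seq[s + 197 : s + 203] = list("GGATGG")  # motifs III, IV
        genome = Genome({"chrP": "".join(seq)})
        records = [EccDNARecord(chrom="chrP", start=s, end=s + 200) for s in starts]
        # a few background records with random contexts
        records += [EccDNARecord(chrom="chrP", start=15_000 + 97 * i,
                                 end=15_000 + 97 * i + 150) for i in range(5)]
        combos, _ = junction_motifs(records, genome, top_k=5)
        top = combos[0]
        assert (top.motif_I, top.motif_II, top.motif_III, top.motif_IV) == (
            "CCA", "TCC", "GGA", "TGG")
        assert top.count == 20
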