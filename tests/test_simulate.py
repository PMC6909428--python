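"""Simulator behaviour: mutation spectrum, meiosis, pooling and read sampling."""

import numpy as np
import pytest

from bsamap import (
    CrossDesign,
    F2Individual,
    GenomeModel,
    MutationSet,
    Snp,
    pool_individuals,
    recombination_fraction,
    simulate_ems_mutations,
    simulate_f2_population,
    simulate_pooled_reads,
)
from bsamap.simulate import EMS_TRANSITIONS


def one_scaffold(length=10_000_000, rate=2.6):
    return GenomeModel((("scf01", length),), recomb_rate=rate)


class TestEmsMutations:
    def test_zero_density_gives_no_mutations(self, toy_genome):
        assert len(simulate_ems_mutations(toy_genome, 0.0, seed=1)) == 0

    def test_pure_spectrum_is_all_gc_to_at(self):
        muts = simulate_ems_mutations(one_scaffold(), 10, spectrum=1.0, seed=7)
        assert len(muts) > 0
        assert all((s.ref, s.alt) in EMS_TRANSITIONS for s in muts)

    def test_mixed_spectrum_fraction(self):
        muts = simulate_ems_mutations(one_scaffold(), 500, spectrum=0.6, seed=3)
        frac = np.mean([(s.ref, s.alt) in EMS_TRANSITIONS for s in muts])
        se = np.sqrt(0.6 * 0.4 / len(muts))
        assert abs(frac - 0.6) < 3 * se

    def test_count_is_poisson_with_expected_mean(self):
        # density 100/Mb over 10 Mb -> Poisson(1000) per replicate
        genome = one_scaffold()
        counts = [
            len(simulate_ems_mutations(genome, 100, seed=s)) for s in range(1000)
        ]
        se = np.sqrt(1000 / len(counts))  # Poisson var = mean
        assert abs(np.mean(counts) - 1000) < 3 * se

    def test_positions_unique_and_in_range(self):
        muts = simulate_ems_mutations(one_scaffold(length=1000), 5000, seed=5)
        positions = [s.pos for s in muts]
        assert len(set(positions)) == len(positions)
        assert all(1 <= p <= 1000 for p in positions)

    def test_empty_genome_is_an_error(self):
        with pytest.raises(ValueError):
            simulate_ems_mutations(GenomeModel(()), 10, seed=1)

    def test_deterministic_under_seed(self, toy_genome):
        a = simulate_ems_mutations(toy_genome, 20, seed=42)
        b = simulate_ems_mutations(toy_genome, 20, seed=42)
        assert a.snps == b.snps


def small_mutation_set():
    return MutationSet(
        [Snp("scf01", 1_000, "C", "T"), Snp("scf01", 500_000, "G", "A"),
         Snp("scf01", 1_500_000, "C", "T")]
    )


class TestF2Population:
    def test_zero_progeny_gives_empty_list(self):
        muts = small_mutation_set()
        design = CrossDesign(muts.ids[0], 0)
        assert simulate_f2_population(design, muts, one_scaffold(2_000_000), 1) == []

    def test_missing_causal_is_an_error(self):
        muts = small_mutation_set()
        with pytest.raises(ValueError, match="causal"):
            simulate_f2_population(
                CrossDesign("scf01_999999", 5), muts, one_scaffold(2_000_000), 1
            )

    def test_no_recombination_means_full_cosegregation(self):
        genome = GenomeModel((("scf01", 2_000_000),), recomb_rate=0.0)
        muts = small_mutation_set()
        pop = simulate_f2_population(CrossDesign(muts.ids[0], 50), muts, genome, 2)
        for ind in pop:
            assert len(set(ind.dosage.tolist())) == 1

    def test_recessive_mendelian_ratio(self):
        genome = one_scaffold(2_000_000)
        muts = small_mutation_set()
        pop = simulate_f2_population(CrossDesign(muts.ids[1], 10_000), muts, genome, 3)
        frac = np.mean([ind.phenotype == "mutant" for ind in pop])
        se = np.sqrt(0.25 * 0.75 / len(pop))
        assert abs(frac - 0.25) < 3 * se

    def test_dominant_phenotype_rule(self):
        genome = one_scaffold(2_000_000)
        muts = small_mutation_set()
        design = CrossDesign(muts.ids[1], 500, inheritance="dominant")
        pop = simulate_f2_population(design, muts, genome, 4)
        causal_idx = 1
        for ind in pop:
            expected = "mutant" if ind.dosage[causal_idx] >= 1 else "wild_type"
            assert ind.phenotype == expected

    def test_deterministic_under_seed(self, toy_genome):
        muts = small_mutation_set()
        design = CrossDesign(muts.ids[0], 30)
        a = simulate_f2_population(design, muts, toy_genome, 9)
        b = simulate_f2_population(design, muts, toy_genome, 9)
        assert all(np.array_equal(x.dosage, y.dosage) for x, y in zip(a, b))


class TestPooling:
    def test_partition_by_phenotype(self, toy_cross):
        mt, wt = pool_individuals(toy_cross.population, toy_cross.design)
        assert len(mt) + len(wt) == len(toy_cross.population)
        assert all(i.phenotype == "mutant" for i in mt)
        assert all(i.phenotype == "wild_type" for i in wt)

    def test_published_split_gives_59_and_221(self):
        muts = small_mutation_set()
        ids = muts.ids
        pop = [
            F2Individual(f"p{i}", "mutant" if i < 59 else "wild_type",
                         np.array([2, 2, 2], dtype=np.int8), ids)
            for i in range(280)
        ]
        mt, wt = pool_individuals(pop, CrossDesign(ids[0], 280))
        assert (len(mt), len(wt)) == (59, 221)

    def test_empty_mt_pool_warns(self):
        muts = small_mutation_set()
        ids = muts.ids
        pop = [
            F2Individual(f"p{i}", "wild_type", np.zeros(3, dtype=np.int8), ids)
            for i in range(5)
        ]
        with pytest.warns(UserWarning, match="MT pool is empty"):
            mt, wt = pool_individuals(pop, CrossDesign(ids[0], 5))
        assert mt == [] and len(wt) == 5


class TestPooledReads:
    def test_zero_depth_gives_all_zero_dp4(self, toy_cross):
        counts = simulate_pooled_reads(
            toy_cross.mt_pool, toy_cross.mutations, 0.0, 0.0, 1
        )
        assert counts.dp4.sum() == 0

    def test_fixed_aa_pool_has_no_ref_reads(self):
        muts = small_mutation_set()
        pool = [
            F2Individual(f"p{i}", "mutant", np.full(3, 2, dtype=np.int8), muts.ids)
            for i in range(10)
        ]
        counts = simulate_pooled_reads(pool, muts, 80, 0.0, 2)
        assert (counts.dp4[:, :2] == 0).all()
        assert (counts.depth > 0).all()  # Poisson(80): zero depth has prob ~1e-35

    def test_error_rate_flips_alleles(self):
        muts = small_mutation_set()
        pool = [F2Individual("p0", "mutant", np.full(3, 2, dtype=np.int8), muts.ids)]
        counts = simulate_pooled_reads(pool, muts, 10_000, 0.1, 3)
        ref_frac = counts.dp4[:, :2].sum() / counts.dp4.sum()
        se = np.sqrt(0.1 * 0.9 / counts.dp4.sum())
        assert abs(ref_frac - 0.1) < 3 * se

    def test_heterozygous_pool_samples_alleles_binomially(self):
        # 1000 sites, q = 0.5 at each (a single Aa individual), depth 100
        n_sites = 1000
        snps = [Snp("scf01", 10 * (i + 1), "C", "T") for i in range(n_sites)]
        muts = MutationSet(snps)
        pool = [F2Individual("p0", "mutant", np.ones(n_sites, dtype=np.int8), muts.ids)]
        counts = simulate_pooled_reads(pool, muts, 100, 0.0, 4)
        alt_frac = counts.dp4[:, 2:].sum() / counts.dp4.sum()
        se = np.sqrt(0.25 / counts.dp4.sum())
        assert abs(alt_frac - 0.5) < 3 * se

    def test_strand_split_is_balanced(self):
        muts = small_mutation_set()
        pool = [F2Individual("p0", "mutant", np.full(3, 2, dtype=np.int8), muts.ids)]
        counts = simulate_pooled_reads(pool, muts, 50_000, 0.0, 5)
        fwd = counts.dp4[:, [0, 2]].sum()
        total = counts.dp4.sum()
        se = np.sqrt(0.25 / total)
        assert abs(fwd / total - 0.5) < 3 * se

    def test_empty_pool_at_positive_depth_is_an_error(self):
        with pytest.raises(ValueError, match="empty pool"):
            simulate_pooled_reads([], small_mutation_set(), 10, 0.0, 1)

    def test_deterministic_under_seed(self, toy_cross):
        a = simulate_pooled_reads(toy_cross.mt_pool, toy_cross.mutations, 30, 0.01, 8)
        b = simulate_pooled_reads(toy_cross.mt_pool, toy_cross.mutations, 30, 0.01, 8)
        assert np.array_equal(a.dp4, b.dp4)


class TestLinkage:
    def test_causal_locus_fixed_in_mt_pool_without_error(self, toy_cross):
        """Recessive design, error-free reads: MT pool is all aa at the causal SNP."""
        i = toy_cross.mutations.index_of(toy_cross.causal)
        dp4 = toy_cross.mt_counts.dp4[i]
        assert dp4[:2].sum() == 0 and dp4.sum() > 0

    def test_unlinked_locus_frequency_is_half_in_both_pools(self):
        """At an unlinked locus the F2 ratio 1:2:1 gives allele frequency 0.5."""
        genome = GenomeModel(
            (("scf01", 1_000_000), ("scf02", 1_000_000)), recomb_rate=2.6
        )
        muts = MutationSet(
            [Snp("scf01", 500_000, "C", "T"), Snp("scf02", 500_000, "G", "A")]
        )
        design = CrossDesign(muts.ids[0], 4000)
        pop = simulate_f2_population(design, muts, genome, 12)
        mt, wt = pool_individuals(pop, design)
        for pool in (mt, wt):
            q = np.mean([ind.dosage[1] for ind in pool]) / 2
            se = np.sqrt(0.25 / (2 * len(pool)))  # binomial over gametes
            assert abs(q - 0.5) < 3.5 * se

    def test_haldane_recombination_fraction(self, toy_genome):
        a = Snp("scf01", 1, "C", "T")
        b = Snp("scf01", 1_000_001, "G", "A")  # 1 Mb apart, 2.6 cM
        c = Snp("scf02", 1, "C", "T")
        r = recombination_fraction(toy_genome, a, b)
        assert r == pytest.approx(0.5 * (1 - np.exp(-2 * 0.026)))
        assert recombination_fraction(toy_genome, a, c) == 0.5
        assert recombination_fraction(toy_genome, a, a) == 0.0
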