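import numpy as np
import pytest

from bsamap import (
    CrossDesign,
    GenomeModel,
    build_pooled_variants,
    pool_individuals,
    simulate_ems_mutations,
    simulate_f2_population,
    simulate_pooled_reads,
)


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeModel((("scf01", 2_000_000), ("scf02", 2_000_000)), recomb_rate=2.6)


class SimulatedCross:
    """One seeded cross: mutations, population, pools, pooled counts, variants."""

    def __init__(self, genome, density=10.0, n_progeny=280, depth=100.0, seed=11):
        seeds = np.random.SeedSequence(seed).spawn(4)
        self.genome = genome
        self.mutations = simulate_ems_mutations(genome, density, 1.0, seeds[0])
        rng = np.random.default_rng(seeds[1])
        self.causal = self.mutations.ids[int(rng.integers(len(self.mutations)))]
        self.design = CrossDesign(self.causal, n_progeny)
        self.population = simulate_f2_population(
            self.design, self.mutations, genome, seeds[2]
        )
        self.mt_pool, self.wt_pool = pool_individuals(self.population, self.design)
        child = seeds[3].spawn(2)
        self.mt_counts = simulate_pooled_reads(
            self.mt_pool, self.mutations, depth, 0.0, child[0]
        )
        self.wt_counts = simulate_pooled_reads(
            self.wt_pool, self.mutations, depth, 0.0, child[1]
        )
        self.variants = build_pooled_variants(
            self.mutations, self.mt_counts, self.wt_counts
        )


@pytest.fixture(scope="session")
def toy_cross(toy_genome):
    return SimulatedCross(toy_genome)


@pytest.fixture(scope="session")
def make_cross(toy_genome):
    def _make(**kwargs):
        return SimulatedCross(toy_genome, **kwargs)

    return _make
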