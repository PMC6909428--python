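"""Synthetic F2 mapping populations and pooled read counts.

This module emulates the data-generating process behind bulked segregant
analysis of an EMS mutant: a mutagenized genome carrying mostly G:C→A:T
transitions, an F2 population from a mutant × wild-type cross, phenotype-based
pooling, and shotgun read counts over each pool at every SNP site.

The simulation starts at the allele-count level — no reads, alignments or
base qualities are modelled. Meiosis uses the Haldane map function (Poisson
crossovers, no interference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "GenomeModel",
    "Snp",
    "MutationSet",
    "CrossDesign",
    "F2Individual",
    "PooledReadCounts",
    "simulate_ems_mutations",
    "simulate_f2_population",
    "pool_individuals",
    "simulate_pooled_reads",
    "recombination_fraction",
    "EMS_TRANSITIONS",
    "GENOTYPE_CODES",
]

Inheritance = Literal["recessive", "dominant"]
Phenotype = Literal["mutant", "wild_type"]

#: EMS predominantly alkylates guanine, producing G:C→A:T transitions.
EMS_TRANSITIONS = (("C", "T"), ("G", "A"))

#: Genotype codes: A = reference (wild) allele, a = alternative (mutant) allele,
#: indexed by alternative-allele dosage 0/1/2.
GENOTYPE_CODES = ("AA", "Aa", "aa")

_BASES = "ACGT"
_ALL_SUBSTITUTIONS = [(r, a) for r in _BASES for a in _BASES if r != a]
_NON_EMS_SUBSTITUTIONS = [s for s in _ALL_SUBSTITUTIONS if s not in EMS_TRANSITIONS]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GenomeModel:
    """A genome as a list of scaffolds with a uniform recombination rate.

    Parameters
    ----------
    scaffolds:
        ``(name, length_bp)`` pairs; names unique, lengths positive.
    recomb_rate:
        Genome-wide recombination rate in centimorgans per megabase. The
        default of 2.6 cM/Mb is a typical genome-wide average for small
        legume genomes.
    map_function:
        Only ``"haldane"`` (no crossover interference) is supported.
    """

    scaffolds: tuple[tuple[str, int], ...]
    recomb_rate: float = 2.6
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        scaffolds = tuple((str(n), int(l)) for n, l in self.scaffolds)
        object.__setattr__(self, "scaffolds", scaffolds)
        names = [n for n, _ in scaffolds]
        if len(set(names)) != len(names):
            raise ValueError("scaffold names must be unique")
        if any(l <= 0 for _, l in scaffolds):
            raise ValueError("scaffold lengths must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        if self.map_function != "haldane":
            raise ValueError(f"unsupported map function: {self.map_function!r}")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.scaffolds)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.scaffolds)


@dataclass(frozen=True, order=True)
class Snp:
    """A biallelic single-nucleotide variant (1-based, fully closed coords)."""

    scaffold: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")
        if self.ref not in _BASES or self.alt not in _BASES or self.ref == self.alt:
            raise ValueError(f"invalid substitution {self.ref}->{self.alt}")

    @property
    def id(self) -> str:
        return f"{self.scaffold}_{self.pos}"


@dataclass
class MutationSet:
    """The SNPs induced in the mutant line, heterozygous in the F1."""

    snps: list[Snp]
    spectrum: float = 1.0

    def __post_init__(self) -> None:
        seen = set()
        for s in self.snps:
            key = (s.scaffold, s.pos)
            if key in seen:
                raise ValueError(f"duplicate SNP position {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.snps)

    def index_of(self, snp_id: str) -> int:
        try:
            return self.ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in mutation set") from None

    def validate_against(self, genome: GenomeModel) -> None:
        lengths = genome.lengths
        for s in self.snps:
            if s.scaffold not in lengths:
                raise ValueError(f"SNP {s.id} on unknown scaffold {s.scaffold!r}")
            if s.pos > lengths[s.scaffold]:
                raise ValueError(f"SNP {s.id} beyond scaffold end")


@dataclass(frozen=True)
class CrossDesign:
    """Mating scheme and pooling rule for a monogenic F2 mapping cross.

    A single mutant line is crossed to its wild-type parent; the F1 is
    heterozygous at every induced SNP (coupling phase), and F2 progeny are
    pooled by phenotype.
    """

    causal_snp: str
    n_progeny: int
    inheritance: Inheritance = "recessive"
    generation: str = "F2"
    mt_pool_phenotype: Phenotype = "mutant"
    wt_pool_phenotype: Phenotype = "wild_type"

    def __post_init__(self) -> None:
        if self.inheritance not in ("recessive", "dominant"):
            raise ValueError(f"unsupported inheritance: {self.inheritance!r}")
        if self.generation != "F2":
            raise ValueError(f"unsupported generation: {self.generation!r}")
        if self.n_progeny < 0:
            raise ValueError("n_progeny must be non-negative")

    def phenotype_of(self, causal_dosage: int) -> Phenotype:
        """Phenotype implied by alternative-allele dosage at the causal SNP."""
        if self.inheritance == "recessive":
            return "mutant" if causal_dosage == 2 else "wild_type"
        return "mutant" if causal_dosage >= 1 else "wild_type"


@dataclass
class F2Individual:
    """One F2 plant: alternative-allele dosages at every SNP plus phenotype."""

    id: str
    phenotype: Phenotype
    dosage: np.ndarray  # int8, aligned with snp_ids
    snp_ids: tuple[str, ...]

    def genotype(self, snp_id: str) -> str:
        return GENOTYPE_CODES[int(self.dosage[self.snp_ids.index(snp_id)])]

    @property
    def genotypes(self) -> dict[str, str]:
        return {
            sid: GENOTYPE_CODES[int(d)] for sid, d in zip(self.snp_ids, self.dosage)
        }


@dataclass
class PooledReadCounts:
    """Stranded read counts (DP4) per SNP for one phenotype pool.

    ``dp4`` has shape (n_snps, 4) with columns
    (ref_forward, ref_reverse, alt_forward, alt_reverse).
    """

    snp_ids: tuple[str, ...]
    dp4: np.ndarray

    def __post_init__(self) -> None:
        self.dp4 = np.asarray(self.dp4, dtype=np.int64)
        if self.dp4.shape != (len(self.snp_ids), 4):
            raise ValueError("dp4 must have shape (n_snps, 4)")
        if (self.dp4 < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.dp4.sum(axis=1)

    def dp4_of(self, snp_id: str) -> tuple[int, int, int, int]:
        i = self.snp_ids.index(snp_id)
        return tuple(int(x) for x in self.dp4[i])


def _sample_positions(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    """k distinct 1-based positions on [1, length], uniform."""
    if k > length:
        raise ValueError("more mutations requested than available positions")
    pos = np.unique(rng.integers(1, length + 1, size=k))
    while pos.size < k:  # resample collisions, keeps the draw exact
        extra = rng.integers(1, length + 1, size=k - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos)


def simulate_ems_mutations(
    genome: GenomeModel,
    density: float,
    spectrum: float = 1.0,
    seed=None,
) -> MutationSet:
    """Scatter EMS-induced SNPs over a genome.

    The number of SNPs per scaffold is Poisson with mean
    ``density × length / 1e6``; positions are uniform without duplicates.
    A fraction ``spectrum`` of mutations are G:C→A:T transitions (C→T or
    G→A with equal probability); the remainder are uniform over the other
    ten substitution types.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if not 0.0 <= spectrum <= 1.0:
        raise ValueError("spectrum must be in [0, 1]")
    if not genome.scaffolds or genome.total_length == 0:
        raise ValueError("cannot mutagenize an empty genome")
    rng = _rng(seed)
    snps: list[Snp] = []
    for name, length in genome.scaffolds:
        k = min(int(rng.poisson(density * length / 1e6)), length)
        if k == 0:
            continue
        positions = _sample_positions(rng, length, k)
        is_ems = rng.random(k) < spectrum
        which_transition = rng.integers(2, size=k)
        which_other = rng.integers(len(_NON_EMS_SUBSTITUTIONS), size=k)
        for p, e, t, o in zip(positions, is_ems, which_transition, which_other):
            ref, alt = EMS_TRANSITIONS[t] if e else _NON_EMS_SUBSTITUTIONS[o]
            snps.append(Snp(name, int(p), ref, alt))
    return MutationSet(snps, spectrum=spectrum)


def _gamete(
    rng: np.random.Generator,
    length_bp: int,
    morgans_per_bp: float,
    positions: np.ndarray,
) -> np.ndarray:
    """One F1 gamete over a scaffold: 1 where the mutant haplotype is inherited.

    Crossovers on a single chromatid form a Poisson process at the map rate
    (Haldane model, no interference); the parental haplotype alternates at
    each crossover starting from a random parent.
    """
    n_xo = rng.poisson(length_bp * morgans_per_bp)
    start = rng.integers(2)
    if n_xo == 0:
        return np.full(positions.shape, start, dtype=np.int8)
    breaks = np.sort(rng.uniform(0.0, length_bp, size=n_xo))
    segment = np.searchsorted(breaks, positions)
    return ((start + segment) % 2).astype(np.int8)


def simulate_f2_population(
    design: CrossDesign,
    mutations: MutationSet,
    genome: GenomeModel,
    seed=None,
) -> list[F2Individual]:
    """Simulate F2 progeny of mutant × wild type.

    Each individual is the union of two independent F1 gametes. All induced
    SNPs are in coupling phase on the mutant haplotype, so a gamete carries
    the alternative allele wherever it inherited the mutant haplotype.
    Phenotype follows deterministically from the causal-SNP genotype under
    the design's inheritance mode (full penetrance).
    """
    ids = mutations.ids
    if design.causal_snp not in ids:
        raise ValueError(f"causal SNP {design.causal_snp!r} not in mutation set")
    mutations.validate_against(genome)
    rng = _rng(seed)
    causal_idx = ids.index(design.causal_snp)
    morgans_per_bp = genome.recomb_rate / 1e8  # cM/Mb -> Morgans/bp

    # group SNP coordinates per scaffold, keeping the global ordering
    by_scaffold: list[tuple[int, np.ndarray, np.ndarray]] = []
    snp_scaffolds = np.array([s.scaffold for s in mutations])
    snp_positions = np.array([s.pos for s in mutations], dtype=float)
    for name, length in genome.scaffolds:
        idx = np.flatnonzero(snp_scaffolds == name)
        if idx.size:
            by_scaffold.append((length, snp_positions[idx], idx))

    n_snps = len(ids)
    population: list[F2Individual] = []
    width = max(4, len(str(design.n_progeny)))
    for i in range(design.n_progeny):
        dosage = np.zeros(n_snps, dtype=np.int8)
        for length, positions, idx in by_scaffold:
            g1 = _gamete(rng, length, morgans_per_bp, positions)
            g2 = _gamete(rng, length, morgans_per_bp, positions)
            dosage[idx] = g1 + g2
        phenotype = design.phenotype_of(int(dosage[causal_idx]))
        population.append(
            F2Individual(f"F2_{i + 1:0{width}d}", phenotype, dosage, ids)
        )
    return population


def pool_individuals(
    population: Sequence[F2Individual], design: CrossDesign
) -> tuple[list[F2Individual], list[F2Individual]]:
    """Partition a population into (MT pool, WT pool) by phenotype."""
    mt = [p for p in population if p.phenotype == design.mt_pool_phenotype]
    wt = [p for p in population if p.phenotype == design.wt_pool_phenotype]
    if population and not mt:
        warnings.warn("MT pool is empty: no individuals with mutant phenotype")
    if population and not wt:
        warnings.warn("WT pool is empty: no individuals with wild-type phenotype")
    return mt, wt


def simulate_pooled_reads(
    pool: Sequence[F2Individual],
    mutations: MutationSet,
    depth: float,
    error_rate: float = 0.0,
    seed=None,
) -> PooledReadCounts:
    """Shotgun read counts over a DNA pool at every SNP.

    Per site the realized depth is Poisson(``depth``). Each read samples a
    pool member uniformly (equal DNA contribution per individual) and one of
    its two alleles, is miscalled to the other allele with probability
    ``error_rate``, and lands on either strand with probability 1/2.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    n_snps = len(mutations)
    if not pool:
        if depth > 0:
            raise ValueError("cannot sequence an empty pool at positive depth")
        return PooledReadCounts(mutations.ids, np.zeros((n_snps, 4), dtype=np.int64))
    rng = _rng(seed)
    dosages = np.stack([ind.dosage for ind in pool]).astype(np.float64)
    q = dosages.mean(axis=0) / 2.0  # alt-allele frequency in the pool
    p_alt = q * (1.0 - error_rate) + (1.0 - q) * error_rate
    n = rng.poisson(depth, size=n_snps)
    alt = rng.binomial(n, p_alt)
    ref = n - alt
    alt_fwd = rng.binomial(alt, 0.5)
    ref_fwd = rng.binomial(ref, 0.5)
    dp4 = np.column_stack([ref_fwd, ref - ref_fwd, alt_fwd, alt - alt_fwd])
    return PooledReadCounts(mutations.ids, dp4)


def recombination_fraction(genome: GenomeModel, snp_a: Snp, snp_b: Snp) -> float:
    """Haldane recombination fraction between two SNPs; 0.5 if unlinked."""
    if snp_a.scaffold != snp_b.scaffold:
        return 0.5
    d_morgans = abs(snp_a.pos - snp_b.pos) * genome.recomb_rate / 1e8
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))
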