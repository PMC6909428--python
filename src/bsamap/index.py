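"""SNP-index computation and the dual-pool screening criterion.

The SNP-index of a pool at a site is the fraction of reads carrying the
alternative (mutant) allele. For a monogenic recessive F2 cross the causal
locus is fixed for the mutant allele among mutant-phenotype plants (index
1.0 in the MT pool), while phenotypically wild-type plants segregate
AA:Aa:aa = 1:2:0, giving an expected index of 1/3 in the WT pool. Screening
keeps sites that are fixed in the MT pool and fall inside a band around 0.3
in the WT pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

from .io import PooledVariant
from .simulate import CrossDesign, Inheritance, Phenotype

__all__ = [
    "IndexResult",
    "ScreenCriterion",
    "snp_index",
    "compute_indices",
    "expected_indices",
    "expected_marker_index",
    "screen_candidates",
]


def snp_index(dp4: Sequence[int]) -> Optional[float]:
    """Alternative-allele read fraction from a DP4 quadruple.

    ``dp4`` is (ref_forward, ref_reverse, alt_forward, alt_reverse); the
    index is (alt_fwd + alt_rev) / total, or ``None`` at zero depth.
    """
    if len(dp4) != 4:
        raise ValueError("DP4 must have exactly 4 counts")
    if any(c < 0 for c in dp4):
        raise ValueError("read counts must be non-negative")
    total = sum(dp4)
    if total == 0:
        return None
    return (dp4[2] + dp4[3]) / total


@dataclass(frozen=True)
class IndexResult:
    """Per-site SNP-indices and depths for both pools."""

    variant: PooledVariant
    index_mt: Optional[float]
    index_wt: Optional[float]
    depth_mt: int
    depth_wt: int


def compute_indices(variants: Sequence[PooledVariant]) -> list[IndexResult]:
    out = []
    for v in variants:
        out.append(
            IndexResult(
                variant=v,
                index_mt=snp_index(v.dp4_mt),
                index_wt=snp_index(v.dp4_wt),
                depth_mt=sum(v.dp4_mt),
                depth_wt=sum(v.dp4_wt),
            )
        )
    return out


def _phenotype_classes(inheritance: Inheritance):
    """Enumerate F1 gamete pairs at a single locus.

    Yields (alt dosage, probability) over the four equiprobable gamete
    combinations of an Aa × Aa selfing-equivalent F1 intercross.
    """
    for g1 in (0, 1):
        for g2 in (0, 1):
            yield g1 + g2, Fraction(1, 4)


def expected_indices(design: CrossDesign) -> tuple[Fraction, Fraction]:
    """Expected SNP-index at the causal locus in (MT pool, WT pool).

    Derived by enumerating F2 genotype frequencies conditional on pool
    phenotype; exact fractions are returned. For a recessive mutation the
    MT pool contains only aa plants (index 1), and the WT pool segregates
    AA:Aa:aa = 1:2:0 (index 1/3).
    """
    if design.generation != "F2":
        raise ValueError(f"unsupported generation: {design.generation!r}")
    totals = {"mutant": Fraction(0), "wild_type": Fraction(0)}
    alt_mass = {"mutant": Fraction(0), "wild_type": Fraction(0)}
    for dosage, prob in _phenotype_classes(design.inheritance):
        phen = design.phenotype_of(dosage)
        totals[phen] += prob
        alt_mass[phen] += prob * Fraction(dosage, 2)
    if totals["mutant"] == 0 or totals["wild_type"] == 0:
        raise ValueError("design produces an empty phenotype class")
    return (
        alt_mass[design.mt_pool_phenotype] / totals[design.mt_pool_phenotype],
        alt_mass[design.wt_pool_phenotype] / totals[design.wt_pool_phenotype],
    )


def expected_marker_index(
    r: float,
    pool_phenotype: Phenotype = "mutant",
    inheritance: Inheritance = "recessive",
) -> float:
    """Expected SNP-index at a marker linked to the causal locus.

    Enumerates the four F1 gamete haplotypes over (causal, marker) with
    recombination fraction ``r`` — coupling phase, so the parental gametes
    carry both mutant or both wild alleles — squares them into the sixteen
    gamete pairs, and conditions on the phenotype class of the pool. For the
    MT pool of a recessive cross this reduces to 1 − r; at r = 0.5 both
    pools give 0.5.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5]")
    # haplotype = (causal allele, marker allele), 1 = mutant/alternative
    gametes = [
        ((1, 1), (1.0 - r) / 2.0),
        ((1, 0), r / 2.0),
        ((0, 1), r / 2.0),
        ((0, 0), (1.0 - r) / 2.0),
    ]
    mass = 0.0
    alt_mass = 0.0
    for (c1, m1), p1 in gametes:
        for (c2, m2), p2 in gametes:
            prob = p1 * p2
            if inheritance == "recessive":
                phen = "mutant" if c1 + c2 == 2 else "wild_type"
            elif inheritance == "dominant":
                phen = "mutant" if c1 + c2 >= 1 else "wild_type"
            else:
                raise ValueError(f"unsupported inheritance: {inheritance!r}")
            if phen == pool_phenotype:
                mass += prob
                alt_mass += prob * (m1 + m2) / 2.0
    if mass == 0.0:
        raise ValueError("pool phenotype class has zero probability")
    return alt_mass / mass


@dataclass(frozen=True)
class ScreenCriterion:
    """Dual-pool screening rule for causal-SNP candidates.

    ``mt_epsilon`` = 0 demands literal fixation in the MT pool (zero
    reference reads at nonzero depth); a relaxed run may set it > 0 to
    accept index ≥ 1 − ε, since exact unity is fragile under sequencing
    error. The WT band is centred on 0.3 with half-width 0.1, endpoints
    inclusive; the analytic expectation 1/3 lies inside. ``min_depth``
    (default 10 reads per pool) guards against low-coverage noise — a
    conventional floor, not derived from data.
    """

    mt_epsilon: Fraction = Fraction(0)
    wt_center: Fraction = Fraction(3, 10)
    wt_halfwidth: Fraction = Fraction(1, 10)
    min_depth: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "mt_epsilon", Fraction(self.mt_epsilon))
        object.__setattr__(self, "wt_center", Fraction(self.wt_center))
        object.__setattr__(self, "wt_halfwidth", Fraction(self.wt_halfwidth))
        if not 0 <= self.wt_center <= 1:
            raise ValueError("wt_center must be in [0, 1]")
        if self.wt_halfwidth <= 0:
            raise ValueError("wt_halfwidth must be positive")
        if not 0 <= self.mt_epsilon < 1:
            raise ValueError("mt_epsilon must be in [0, 1)")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")

    def passes(self, result: IndexResult) -> bool:
        if result.depth_mt < self.min_depth or result.depth_wt < self.min_depth:
            return False
        if result.depth_mt == 0 or result.depth_wt == 0:
            return False
        v = result.variant
        alt_mt = v.dp4_mt[2] + v.dp4_mt[3]
        alt_wt = v.dp4_wt[2] + v.dp4_wt[3]
        # MT pool: exact count-level comparison, no float rounding
        if Fraction(alt_mt, result.depth_mt) < 1 - self.mt_epsilon:
            return False
        index_wt = Fraction(alt_wt, result.depth_wt)
        return abs(index_wt - self.wt_center) <= self.wt_halfwidth


def screen_candidates(
    results: Sequence[IndexResult],
    criterion: ScreenCriterion | None = None,
) -> list[IndexResult]:
    """Retain sites meeting the dual-pool criterion, sorted by scaffold, position."""
    criterion = criterion or ScreenCriterion()
    kept = [r for r in results if criterion.passes(r)]
    kept.sort(key=lambda r: (r.variant.scaffold, r.variant.pos))
    return kept
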