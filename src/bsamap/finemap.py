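"""Fine-mapping with individual genotypes: candidate exclusion and recombinants.

Once the pooled screen leaves a handful of candidate SNPs, genotyping every
mapping-population individual at those sites discriminates among them. Under
recessive inheritance with full penetrance, a candidate is inconsistent for
an individual if a mutant plant is not aa there or a wild-type plant is aa;
a candidate with no inconsistent individual among the informative ones is
completely linked to the phenotype. F3 progeny tests are represented by
appending the F3-derived calls as further rows of the genotype table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .io import GenotypeTable
from .simulate import Inheritance

__all__ = [
    "CandidateConsistency",
    "ConsistencyReport",
    "exclude_candidates",
    "find_recombinants",
]

Status = Literal["completely_linked", "excluded", "undetermined"]


@dataclass(frozen=True)
class CandidateConsistency:
    locus: str
    n_informative: int
    n_inconsistent: int
    inconsistent_individuals: tuple[str, ...]
    status: Status


@dataclass
class ConsistencyReport:
    candidates: dict[str, CandidateConsistency]

    @property
    def completely_linked(self) -> list[str]:
        return [
            l for l, c in self.candidates.items() if c.status == "completely_linked"
        ]

    @property
    def excluded(self) -> list[str]:
        return [l for l, c in self.candidates.items() if c.status == "excluded"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus": c.locus,
                    "n_informative": c.n_informative,
                    "n_inconsistent": c.n_inconsistent,
                    "inconsistent_individuals": ",".join(c.inconsistent_individuals),
                    "status": c.status,
                }
                for c in self.candidates.values()
            ]
        )


def exclude_candidates(
    table: GenotypeTable, inheritance: Inheritance = "recessive"
) -> ConsistencyReport:
    """Classify each candidate locus as completely linked or excluded.

    Missing calls are uninformative. A locus with no informative individual
    is flagged ``undetermined`` with a warning rather than classified.
    """
    if inheritance not in ("recessive", "dominant"):
        raise ValueError(f"unsupported inheritance: {inheritance!r}")
    candidates: dict[str, CandidateConsistency] = {}
    mutant = table.data["phenotype"] == "mutant"
    for locus in table.loci:
        calls = table.calls(locus)
        informative = calls.notna()
        n_informative = int(informative.sum())
        if inheritance == "recessive":
            bad = (mutant & (calls != "aa")) | (~mutant & (calls == "aa"))
        else:
            bad = (mutant & (calls == "AA")) | (~mutant & (calls != "AA"))
        bad &= informative
        bad_ids: list[str] = list(table.data.loc[bad, "individual"])
        if n_informative == 0:
            warnings.warn(f"no informative individuals for candidate {locus!r}")
            status: Status = "undetermined"
        elif bad_ids:
            status = "excluded"
        else:
            status = "completely_linked"
        candidates[locus] = CandidateConsistency(
            locus=locus,
            n_informative=n_informative,
            n_inconsistent=len(bad_ids),
            inconsistent_individuals=tuple(bad_ids),
            status=status,
        )
    return ConsistencyReport(candidates)


def find_recombinants(
    table: GenotypeTable, locus_a: str, locus_b: str
) -> list[str]:
    """Individuals whose two-locus genotypes require a crossover between the loci.

    In an F2 from coupling-phase parents the only gametes available without
    a crossover carry the same allele at both loci, so an individual's
    genotype codes must agree at the two loci; any discordant non-missing
    pair implies at least one recombinant gamete. A doubly heterozygous
    individual (Aa/Aa) cannot be classified without phase and is not
    flagged.
    """
    a = table.calls(locus_a)
    b = table.calls(locus_b)
    both = a.notna() & b.notna()
    flagged = both & (a != b)
    return list(table.data.loc[flagged, "individual"])
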