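"""Codon-level consequence classification of SNPs against gene models.

Given a strand-aware CDS structure (GFF3) and the reference sequence, a SNP
inside the coding region is located in transcription order, its codon is
substituted (with strand complementation for minus-strand genes) and both
codons are translated under the standard genetic code to call the
consequence: synonymous, missense, stop_gained or stop_lost. SNPs outside
any CDS exon are non_coding (intronic or intergenic). Splice sites, UTRs
and multi-transcript models are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import gffutils
from Bio.Seq import Seq

__all__ = ["GeneModel", "SnpEffect", "annotate_effect", "read_gene_models"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware CDS structure of one transcript.

    ``exons`` are 1-based closed genomic intervals of CDS segments in
    transcription order (ascending coordinates on '+', descending on '−');
    the reading frame is anchored at the first base of the first exon.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene model needs at least one CDS exon")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        for a, b in exons:
            if a > b or a < 1:
                raise ValueError(f"bad exon interval ({a}, {b})")
        starts = [a for a, _ in exons]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise ValueError("exons must be sorted in transcription order")
        spans = sorted(exons)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("exons must not overlap")
        if self.cds_length % 3 != 0:
            warnings.warn(
                f"CDS length of {self.gene_id} ({self.cds_length}) is not a multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return min(a for a, _ in self.exons), max(b for _, b in self.exons)


@dataclass(frozen=True)
class SnpEffect:
    snp_id: str
    gene_id: str
    region: str  # "cds", "intron" or "intergenic"
    exon: Optional[int]  # 1-based, transcription order
    codon_number: Optional[int]  # 1-based within the CDS
    ref_codon: Optional[str]
    alt_codon: Optional[str]
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    consequence: str  # synonymous | missense | stop_gained | stop_lost | non_coding


def _fetch(sequence, scaffold: str, start: int, end: int) -> str:
    """Reference bases on [start, end], 1-based closed; plus strand."""
    if isinstance(sequence, str):
        seq = sequence
    elif isinstance(sequence, Mapping) or hasattr(sequence, "__getitem__"):
        seq = sequence[scaffold]
    else:
        raise TypeError("sequence must be a string or a mapping of scaffold -> bases")
    return str(seq[start - 1 : end]).upper()


def annotate_effect(snp, gene: GeneModel, sequence) -> SnpEffect:
    """Classify the coding consequence of ``snp`` on ``gene``.

    ``snp`` needs ``scaffold``/``pos``/``ref``/``alt`` attributes (1-based,
    plus-strand alleles, as in VCF). ``sequence`` is the plus-strand
    reference: either the gene's scaffold as a string or a mapping/FASTA
    object indexable by scaffold name. A mismatch between ``snp.ref`` and
    the reference base is an error.
    """
    snp_id = getattr(snp, "id", f"{snp.scaffold}_{snp.pos}")
    ref = snp.ref.upper()
    alt = snp.alt.upper()

    def non_coding(region: str) -> SnpEffect:
        return SnpEffect(
            snp_id, gene.gene_id, region, None, None, None, None, None, None,
            "non_coding",
        )

    if snp.scaffold != gene.scaffold:
        return non_coding("intergenic")

    genome_base = _fetch(sequence, snp.scaffold, snp.pos, snp.pos)
    if genome_base != ref:
        raise ValueError(
            f"reference mismatch at {snp.scaffold}:{snp.pos}: "
            f"SNP says {ref}, sequence says {genome_base}"
        )

    # locate the SNP within the CDS, in transcription order
    offset = None
    exon_number = None
    running = 0
    for i, (a, b) in enumerate(gene.exons, start=1):
        if a <= snp.pos <= b:
            within = (snp.pos - a) if gene.strand == "+" else (b - snp.pos)
            offset = running + within
            exon_number = i
            break
        running += b - a + 1
    if offset is None:
        lo, hi = gene.span
        return non_coding("intron" if lo <= snp.pos <= hi else "intergenic")

    cds = "".join(
        _fetch(sequence, gene.scaffold, a, b)
        if gene.strand == "+"
        else str(Seq(_fetch(sequence, gene.scaffold, a, b)).reverse_complement())
        for a, b in gene.exons
    )
    coding_ref = ref if gene.strand == "+" else _COMPLEMENT[ref]
    coding_alt = alt if gene.strand == "+" else _COMPLEMENT[alt]
    if cds[offset] != coding_ref:
        raise ValueError(
            f"internal inconsistency: CDS base {cds[offset]} != SNP ref {coding_ref}"
        )

    codon_i, codon_off = divmod(offset, 3)
    ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(ref_codon) < 3:
        warnings.warn(
            f"SNP {snp_id} falls in an incomplete trailing codon of {gene.gene_id}"
        )
        return non_coding("cds")
    alt_codon = ref_codon[:codon_off] + coding_alt + ref_codon[codon_off + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "stop_gained"
    elif ref_aa == "*":
        consequence = "stop_lost"
    else:
        consequence = "missense"
    return SnpEffect(
        snp_id=snp_id,
        gene_id=gene.gene_id,
        region="cds",
        exon=exon_number,
        codon_number=codon_i + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
    )


def read_gene_models(gff_path) -> list[GeneModel]:
    """Load transcript CDS structures from GFF3 (CDS features only)."""
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [cds.id])[0]
        groups.setdefault(parent, []).append(cds)
    models = []
    for tid, feats in sorted(groups.items()):
        strands = {f.strand for f in feats}
        scaffolds = {f.seqid for f in feats}
        if len(strands) != 1 or len(scaffolds) != 1:
            raise ValueError(f"inconsistent strand/scaffold for transcript {tid!r}")
        strand = strands.pop()
        exons = sorted(((f.start, f.end) for f in feats), reverse=strand == "-")
        models.append(GeneModel(tid, scaffolds.pop(), strand, tuple(exons)))
    return models
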