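"""Reading and writing the variant and genotype formats the pipeline touches.

Two VCF dialects carry the per-pool stranded read counts:

* ``"samples"`` (default): one VCF 4.2 file with two samples, ``MT`` and
  ``WT``, whose stranded allelic depths are stored in the standard
  bcftools-style ``FORMAT/ADF`` and ``FORMAT/ADR`` tags (Number=R).
* ``"info_dp4"``: one file per pool with the bcftools ``INFO/DP4`` quadruple
  (ref-forward, ref-reverse, alt-forward, alt-reverse).

Genotype tables for fine-mapping are plain TSV with one row per individual.
All coordinates are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .simulate import (
    GENOTYPE_CODES,
    F2Individual,
    GenomeModel,
    MutationSet,
    PooledReadCounts,
    Snp,
    recombination_fraction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PooledVariant",
    "GenotypeTable",
    "build_pooled_variants",
    "write_pooled_vcf",
    "read_pooled_vcf",
    "read_genotype_table",
    "write_genotype_table",
    "write_truth_table",
    "read_truth_table",
]

_MISSING_CODES = {"", "NA", "N/A", "./.", ".", "nan", "NaN"}
_PHENOTYPES = {"mutant", "wild_type"}


@dataclass(frozen=True)
class PooledVariant:
    """A biallelic SNP with stranded read counts (DP4) for both pools."""

    scaffold: str
    pos: int
    ref: str
    alt: str
    dp4_mt: tuple[int, int, int, int]
    dp4_wt: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for dp4 in (self.dp4_mt, self.dp4_wt):
            if len(dp4) != 4 or any(c < 0 for c in dp4):
                raise ValueError("DP4 must be 4 non-negative counts")

    @property
    def id(self) -> str:
        return f"{self.scaffold}_{self.pos}"


def build_pooled_variants(
    mutations: MutationSet,
    mt_counts: PooledReadCounts,
    wt_counts: PooledReadCounts,
) -> list[PooledVariant]:
    """Zip simulated mutations with per-pool counts into PooledVariant records."""
    if mt_counts.snp_ids != mutations.ids or wt_counts.snp_ids != mutations.ids:
        raise ValueError("read counts are not aligned with the mutation set")
    return [
        PooledVariant(
            s.scaffold,
            s.pos,
            s.ref,
            s.alt,
            tuple(int(x) for x in mt_counts.dp4[i]),
            tuple(int(x) for x in wt_counts.dp4[i]),
        )
        for i, s in enumerate(mutations)
    ]


def _vcf_header(
    contigs: dict[str, int] | None,
    variants: Sequence[PooledVariant],
    extra_header: Iterable[str],
    dialect: str,
    samples: Sequence[str] = (),
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for v in variants:
            contigs[v.scaffold] = max(contigs.get(v.scaffold, 0), v.pos)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    if dialect == "samples":
        header.formats.add("ADF", "R", "Integer", "Allelic depths on the forward strand")
        header.formats.add("ADR", "R", "Integer", "Allelic depths on the reverse strand")
        header.formats.add("DP", "1", "Integer", "Read depth")
        for s in samples:
            header.add_sample(s)
    elif dialect == "info_dp4":
        header.info.add(
            "DP4",
            "4",
            "Integer",
            "Number of high-quality ref-forward, ref-reverse, alt-forward and alt-reverse bases",
        )
    else:
        raise ValueError(f"unknown VCF dialect: {dialect!r}")
    for line in extra_header:
        header.add_line(line if line.startswith("##") else f"##{line}")
    return header


def write_pooled_vcf(
    variants: Sequence[PooledVariant],
    path,
    contigs: dict[str, int] | None = None,
    dialect: str = "samples",
    extra_header: Iterable[str] = (),
) -> None:
    """Write pooled variants as VCF 4.2.

    With ``dialect="samples"`` ``path`` is a single file; with
    ``dialect="info_dp4"`` ``path`` must be a ``(mt_path, wt_path)`` pair and
    one single-pool file is written per element.
    """
    if dialect == "samples":
        header = _vcf_header(contigs, variants, extra_header, dialect, ("MT", "WT"))
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for v in variants:
                rec = out.new_record(
                    contig=v.scaffold,
                    start=v.pos - 1,
                    stop=v.pos,
                    alleles=(v.ref, v.alt),
                    id=v.id,
                )
                for sample, dp4 in (("MT", v.dp4_mt), ("WT", v.dp4_wt)):
                    rec.samples[sample]["ADF"] = (dp4[0], dp4[2])
                    rec.samples[sample]["ADR"] = (dp4[1], dp4[3])
                    rec.samples[sample]["DP"] = sum(dp4)
                out.write(rec)
    elif dialect == "info_dp4":
        mt_path, wt_path = path
        for p, which in ((mt_path, "dp4_mt"), (wt_path, "dp4_wt")):
            header = _vcf_header(contigs, variants, extra_header, dialect)
            with pysam.VariantFile(str(p), "w", header=header) as out:
                for v in variants:
                    rec = out.new_record(
                        contig=v.scaffold,
                        start=v.pos - 1,
                        stop=v.pos,
                        alleles=(v.ref, v.alt),
                        id=v.id,
                    )
                    rec.info["DP4"] = getattr(v, which)
                    out.write(rec)
    else:
        raise ValueError(f"unknown VCF dialect: {dialect!r}")


def _is_simple_snv(rec: pysam.VariantRecord) -> bool:
    if rec.alts is None or len(rec.alts) != 1:
        logger.warning(
            "skipping non-biallelic record %s:%d (%d ALT alleles)",
            rec.chrom,
            rec.pos,
            0 if rec.alts is None else len(rec.alts),
        )
        return False
    if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
        logger.warning("skipping indel record %s:%d", rec.chrom, rec.pos)
        return False
    return True


def _sample_dp4(rec: pysam.VariantRecord, sample: str) -> tuple[int, int, int, int]:
    fmt = rec.samples[sample]
    if "ADF" not in fmt or "ADR" not in fmt or fmt["ADF"] is None:
        raise ValueError(
            f"record {rec.chrom}:{rec.pos} sample {sample} lacks stranded counts (ADF/ADR)"
        )
    adf, adr = fmt["ADF"], fmt["ADR"]
    if adf is None or adr is None or None in adf or None in adr:
        raise ValueError(
            f"record {rec.chrom}:{rec.pos} sample {sample} lacks stranded counts (ADF/ADR)"
        )
    return (int(adf[0]), int(adr[0]), int(adf[1]), int(adr[1]))


def read_pooled_vcf(path, dialect: str = "samples") -> list[PooledVariant]:
    """Read pooled variants back from VCF.

    Multiallelic and indel records are skipped with a logged warning; a
    biallelic SNP record lacking its count field is an error naming the
    record.
    """
    variants: list[PooledVariant] = []
    if dialect == "samples":
        with pysam.VariantFile(str(path)) as vcf:
            if not {"MT", "WT"} <= set(vcf.header.samples):
                raise ValueError("VCF must contain samples 'MT' and 'WT'")
            for rec in vcf:
                if not _is_simple_snv(rec):
                    continue
                variants.append(
                    PooledVariant(
                        rec.chrom,
                        rec.pos,
                        rec.ref,
                        rec.alts[0],
                        _sample_dp4(rec, "MT"),
                        _sample_dp4(rec, "WT"),
                    )
                )
        return variants
    if dialect == "info_dp4":
        mt_path, wt_path = path
        per_pool: list[dict[tuple[str, int], tuple]] = []
        for p in (mt_path, wt_path):
            records: dict[tuple[str, int], tuple] = {}
            with pysam.VariantFile(str(p)) as vcf:
                for rec in vcf:
                    if not _is_simple_snv(rec):
                        continue
                    if "DP4" not in rec.info:
                        raise ValueError(
                            f"record {rec.chrom}:{rec.pos} lacks INFO/DP4"
                        )
                    records[(rec.chrom, rec.pos)] = (
                        rec.ref,
                        rec.alts[0],
                        tuple(int(x) for x in rec.info["DP4"]),
                    )
            per_pool.append(records)
        mt_recs, wt_recs = per_pool
        if set(mt_recs) != set(wt_recs):
            raise ValueError("MT and WT single-pool VCFs cover different sites")
        for (chrom, pos), (ref, alt, dp4_mt) in mt_recs.items():
            ref_w, alt_w, dp4_wt = wt_recs[(chrom, pos)]
            if (ref_w, alt_w) != (ref, alt):
                raise ValueError(f"allele mismatch between pools at {chrom}:{pos}")
            variants.append(PooledVariant(chrom, pos, ref, alt, dp4_mt, dp4_wt))
        variants.sort(key=lambda v: (v.scaffold, v.pos))
        return variants
    raise ValueError(f"unknown VCF dialect: {dialect!r}")


@dataclass
class GenotypeTable:
    """Per-individual genotype calls at candidate SNPs.

    Wraps a DataFrame with columns ``individual``, ``phenotype`` and one
    column per candidate locus holding codes ``AA``/``Aa``/``aa`` (missing
    calls as NA).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = ["individual", "phenotype"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"genotype table lacks column {col!r}")
        loci = [c for c in df.columns if c not in required]
        if not loci:
            raise ValueError("genotype table must have at least one candidate SNP column")
        if df["individual"].duplicated().any():
            dup = df.loc[df["individual"].duplicated(), "individual"].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")
        bad_phen = set(df["phenotype"]) - _PHENOTYPES
        if bad_phen:
            raise ValueError(f"unknown phenotype value(s): {sorted(bad_phen)}")
        for locus in loci:
            col = df[locus].astype("string")
            col = col.where(~col.isin(_MISSING_CODES), other=pd.NA)
            bad = col.dropna()[~col.dropna().isin(GENOTYPE_CODES)]
            if len(bad):
                raise ValueError(
                    f"unknown genotype code {bad.iloc[0]!r} at locus {locus!r}"
                )
            df[locus] = col
        self.data = df.reset_index(drop=True)

    @property
    def loci(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("individual", "phenotype")]

    def __len__(self) -> int:
        return len(self.data)

    def calls(self, locus: str) -> pd.Series:
        if locus not in self.loci:
            raise KeyError(f"locus {locus!r} not in genotype table")
        return self.data[locus]

    @classmethod
    def from_population(
        cls, population: Sequence[F2Individual], loci: Sequence[str]
    ) -> "GenotypeTable":
        """Error-free genotype calls of simulated individuals at chosen loci."""
        if not population:
            raise ValueError("population is empty")
        pos = {sid: i for i, sid in enumerate(population[0].snp_ids)}
        idx = [pos[l] for l in loci]
        codes = np.array(GENOTYPE_CODES)
        df = pd.DataFrame(
            {
                "individual": [ind.id for ind in population],
                "phenotype": [ind.phenotype for ind in population],
            }
        )
        dosages = np.stack([ind.dosage[idx] for ind in population])
        for j, locus in enumerate(loci):
            df[locus] = codes[dosages[:, j]]
        return cls(df)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a TSV, skipping leading full-line comments only.

    Individual ids may legitimately contain '#' (e.g. plant "#130"), so
    pandas' in-line comment stripping cannot be used.
    """
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines(keepends=True)
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        start += 1
    from io import StringIO

    return pd.read_csv(StringIO("".join(lines[start:])), sep="\t", **kwargs)


def read_genotype_table(path) -> GenotypeTable:
    df = _read_tsv(path, dtype=str)
    return GenotypeTable(df)


def write_genotype_table(table: GenotypeTable, path, comments: Iterable[str] = ()) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        out = table.data.copy()
        for locus in table.loci:
            out[locus] = out[locus].fillna("NA")
        out.to_csv(fh, sep="\t", index=False)


_TRUTH_COLUMNS = [
    "snp_id",
    "scaffold",
    "pos",
    "ref",
    "alt",
    "is_causal",
    "r_to_causal",
]


def write_truth_table(
    mutations: MutationSet,
    genome: GenomeModel,
    causal_snp: str,
    path,
    comments: Iterable[str] = (),
) -> None:
    """TSV of simulated truth: every SNP, causality flag and Haldane r to the causal locus."""
    causal = mutations.snps[mutations.index_of(causal_snp)]
    rows = [
        {
            "snp_id": s.id,
            "scaffold": s.scaffold,
            "pos": s.pos,
            "ref": s.ref,
            "alt": s.alt,
            "is_causal": s.id == causal_snp,
            "r_to_causal": recombination_fraction(genome, s, causal),
        }
        for s in mutations
    ]
    path = Path(path)
    with path.open("w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(
            fh, sep="\t", index=False, float_format="%.6g"
        )


def read_truth_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table lacks column(s) {sorted(missing)}")
    return df
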