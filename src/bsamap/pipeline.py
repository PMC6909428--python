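"""End-to-end orchestration: simulate → index → screen → finemap → annotate.

A run is fully specified by a YAML config plus a master seed; the seed is
split deterministically per stage (mutations / causal choice / meiosis /
reads), so a stored config reproduces every output byte for byte. Every
output file carries a short hash of the scientific parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import effects as fx
from . import io as vio
from .finemap import ConsistencyReport, exclude_candidates
from .index import IndexResult, ScreenCriterion, compute_indices, screen_candidates
from .segregation import SegregationTest, chisq_segregation
from .simulate import (
    CrossDesign,
    GenomeModel,
    MutationSet,
    pool_individuals,
    simulate_ems_mutations,
    simulate_f2_population,
    simulate_pooled_reads,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All stage parameters of one reproducible run."""

    scaffolds: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"scf{i:02d}", 2_000_000) for i in range(1, 6)]
    )
    recomb_rate: float = 2.6  # cM/Mb
    density: float = 50.0  # mutations per Mb
    spectrum: float = 1.0  # fraction of G:C->A:T transitions
    inheritance: str = "recessive"
    n_progeny: int = 280
    depth: float = 50.0  # mean reads per site per pool
    error_rate: float = 0.0
    wt_center: float = 0.3
    wt_halfwidth: float = 0.1
    min_depth: int = 10
    mt_epsilon: float = 0.0
    causal_snp: Optional[str] = None  # default: drawn uniformly from the mutation set
    gff: Optional[str] = None
    fasta: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "scaffolds" in raw:
            raw["scaffolds"] = [
                (s["name"], int(s["length"])) if isinstance(s, dict) else (s[0], int(s[1]))
                for s in raw["scaffolds"]
            ]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scaffolds"] = [list(s) for s in self.scaffolds]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @property
    def genome(self) -> GenomeModel:
        return GenomeModel(tuple(self.scaffolds), recomb_rate=self.recomb_rate)

    @property
    def criterion(self) -> ScreenCriterion:
        return ScreenCriterion(
            mt_epsilon=Fraction(str(self.mt_epsilon)),
            wt_center=Fraction(str(self.wt_center)),
            wt_halfwidth=Fraction(str(self.wt_halfwidth)),
            min_depth=self.min_depth,
        )


@dataclass
class RunReport:
    config_hash: str
    n_snps: int
    n_progeny: int
    n_mt_pool: int
    n_wt_pool: int
    segregation: SegregationTest
    n_candidates: int
    candidate_ids: list[str]
    causal_snp: str
    causal_in_candidates: bool
    completely_linked: list[str]
    causal_uniquely_linked: bool
    effects: list[fx.SnpEffect]
    outputs: dict[str, str]

    def to_dict(self) -> dict:
        d = {
            "config_hash": self.config_hash,
            "n_snps": self.n_snps,
            "n_progeny": self.n_progeny,
            "n_mt_pool": self.n_mt_pool,
            "n_wt_pool": self.n_wt_pool,
            "segregation": self.segregation.to_dict(),
            "n_candidates": self.n_candidates,
            "candidate_ids": self.candidate_ids,
            "causal_snp": self.causal_snp,
            "causal_in_candidates": self.causal_in_candidates,
            "completely_linked": self.completely_linked,
            "causal_uniquely_linked": self.causal_uniquely_linked,
            "effects": [asdict(e) for e in self.effects],
            "outputs": self.outputs,
        }
        return d


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, str(exc)) from exc

    return wrap


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    """Execute all stages and write the artifacts into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash
    comments = [f"bsamap_config={tag}"]
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    genome = config.genome

    logger.info("stage mutations: density=%.3g/Mb spectrum=%.3g", config.density, config.spectrum)
    mutations: MutationSet = _stage("mutations")(
        simulate_ems_mutations, genome, config.density, config.spectrum, seeds[0]
    )
    if len(mutations) == 0:
        raise PipelineError("mutations", "no SNPs were generated; increase density")
    logger.info("stage mutations: %d SNPs", len(mutations))

    def pick_causal() -> str:
        if config.causal_snp is not None:
            if config.causal_snp not in mutations.ids:
                raise ValueError(f"configured causal SNP {config.causal_snp!r} absent")
            return config.causal_snp
        rng = np.random.default_rng(seeds[1])
        return mutations.ids[int(rng.integers(len(mutations)))]

    causal = _stage("design")(pick_causal)
    design = CrossDesign(
        causal_snp=causal, n_progeny=config.n_progeny, inheritance=config.inheritance
    )

    def make_population():
        if config.n_progeny <= 0:
            raise ValueError("n_progeny must be positive for a mapping population")
        return simulate_f2_population(design, mutations, genome, seeds[2])

    population = _stage("population")(make_population)
    mt_pool, wt_pool = _stage("pools")(pool_individuals, population, design)
    logger.info("stage pools: %d mutant / %d wild type", len(mt_pool), len(wt_pool))

    def make_reads():
        child = seeds[3].spawn(2)
        mt = simulate_pooled_reads(
            mt_pool, mutations, config.depth, config.error_rate, child[0]
        )
        wt = simulate_pooled_reads(
            wt_pool, mutations, config.depth, config.error_rate, child[1]
        )
        return mt, wt

    mt_counts, wt_counts = _stage("reads")(make_reads)

    vcf_path = outdir / "pooled.vcf"
    truth_path = outdir / "truth.tsv"

    def write_sim():
        variants = vio.build_pooled_variants(mutations, mt_counts, wt_counts)
        vio.write_pooled_vcf(
            variants,
            vcf_path,
            contigs=genome.lengths,
            extra_header=[f"##bsamap_config={tag}"],
        )
        vio.write_truth_table(mutations, genome, causal, truth_path, comments=comments)
        return variants

    variants = _stage("write")(write_sim)

    def do_screen():
        results = compute_indices(variants)
        candidates = screen_candidates(results, config.criterion)
        _write_index_tsv(results, outdir / "indices.tsv", comments)
        _write_index_tsv(candidates, outdir / "candidates.tsv", comments)
        return results, candidates

    results, candidates = _stage("screen")(do_screen)
    logger.info("stage screen: %d of %d sites retained", len(candidates), len(results))

    def do_segregation():
        if config.inheritance == "recessive":
            observed, ratio = (len(wt_pool), len(mt_pool)), (3, 1)
        else:
            observed, ratio = (len(mt_pool), len(wt_pool)), (3, 1)
        test = chisq_segregation(observed, ratio)
        payload = {"config_hash": tag, **test.to_dict()}
        (outdir / "segregation.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        return test

    segregation = _stage("segregation")(do_segregation)

    def do_finemap():
        loci = [r.variant.id for r in candidates]
        if not loci:
            return None, ConsistencyReport({})
        table = vio.GenotypeTable.from_population(population, loci)
        vio.write_genotype_table(table, outdir / "genotypes.tsv", comments=comments)
        report = exclude_candidates(table, config.inheritance)
        with (outdir / "finemap.tsv").open("w") as fh:
            for c in comments:
                fh.write(f"# {c}\n")
            report.to_frame().to_csv(fh, sep="\t", index=False)
        return table, report

    _, consistency = _stage("finemap")(do_finemap)

    def do_annotate():
        if not (config.gff and config.fasta):
            return []
        import pyfaidx

        genes = fx.read_gene_models(config.gff)
        reference = pyfaidx.Fasta(config.fasta)
        out: list[fx.SnpEffect] = []
        for r in candidates:
            v = r.variant
            for gene in genes:
                if gene.scaffold != v.scaffold:
                    continue
                eff = fx.annotate_effect(v, gene, reference)
                if eff.region != "intergenic":
                    out.append(eff)
        if out:
            import pandas as pd

            with (outdir / "effects.tsv").open("w") as fh:
                for c in comments:
                    fh.write(f"# {c}\n")
                pd.DataFrame([asdict(e) for e in out]).to_csv(fh, sep="\t", index=False)
        return out

    effect_list = _stage("annotate")(do_annotate)

    linked = consistency.completely_linked
    candidate_ids = [r.variant.id for r in candidates]
    report = RunReport(
        config_hash=tag,
        n_snps=len(mutations),
        n_progeny=len(population),
        n_mt_pool=len(mt_pool),
        n_wt_pool=len(wt_pool),
        segregation=segregation,
        n_candidates=len(candidates),
        candidate_ids=candidate_ids,
        causal_snp=causal,
        causal_in_candidates=causal in candidate_ids,
        completely_linked=linked,
        causal_uniquely_linked=linked == [causal],
        effects=effect_list,
        # file names relative to the run directory, so reports from identical
        # seeds are byte-identical wherever they are written
        outputs={
            "vcf": vcf_path.name,
            "truth": truth_path.name,
            "indices": "indices.tsv",
            "candidates": "candidates.tsv",
            "segregation": "segregation.json",
        },
    )
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    config.to_yaml(outdir / "config.yaml")
    return report


def _write_index_tsv(results: list[IndexResult], path: Path, comments) -> None:
    import pandas as pd

    rows = [
        {
            "snp_id": r.variant.id,
            "scaffold": r.variant.scaffold,
            "pos": r.variant.pos,
            "ref": r.variant.ref,
            "alt": r.variant.alt,
            "depth_mt": r.depth_mt,
            "depth_wt": r.depth_wt,
            "index_mt": "" if r.index_mt is None else f"{r.index_mt:.6g}",
            "index_wt": "" if r.index_wt is None else f"{r.index_wt:.6g}",
        }
        for r in results
    ]
    columns = [
        "snp_id", "scaffold", "pos", "ref", "alt",
        "depth_mt", "depth_wt", "index_mt", "index_wt",
    ]
    with path.open("w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        pd.DataFrame(rows, columns=columns).to_csv(fh, sep="\t", index=False)
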