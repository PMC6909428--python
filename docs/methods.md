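# Methods

This note records the model behind `bsamap`, the defaults it ships with,
and the numerical and statistical choices made, so results can be
interpreted and reproduced without reading the source.

## Genetic model

**Cross design.** A single mutagenised individual (genotype `aa` at the
causal SNP and homozygous alternative at every other induced mutation) is
crossed to the non-mutagenised parent; the F1 is selfed to give an F2
mapping population. All induced mutations are therefore in *coupling
phase*: each F1 chromosome carries either all reference or all alternative
alleles. Phenotype is deterministic from the causal genotype (full
penetrance, no phenocopies): under `recessive` inheritance an individual is
mutant iff it is `aa` at the causal SNP; under `dominant`, iff it carries
at least one `a`.

**Mutation spectrum.** EMS overwhelmingly induces G:C→A:T transitions; the
simulator draws the number of mutations per scaffold as
Poisson(density × length / 10⁶), places them uniformly at unique positions,
and assigns C→T or G→A with equal probability for the fraction `spectrum`
(default 1.0) of sites; the remainder are uniform other substitutions.

**Meiosis.** Crossovers per gamete per scaffold are Poisson with mean
(recomb_rate / 10⁸) × length Morgans, positions uniform, no interference —
i.e. the Haldane model, under which the recombination fraction at map
distance *d* Morgans is r = ½(1 − e^(−2d)), and r = ½ across scaffolds.

**Pooled reads.** For each pool and site, read depth is Poisson(depth);
each read is alternative with probability q(1 − e) + (1 − q)e where q is
the pool's true alternative-allele frequency and e the per-base error rate;
reads split 50/50 between strands binomially. Counts are reported as
DP4-style (ref_fwd, ref_rev, alt_fwd, alt_rev).

The simulator does **not** model: mapping bias or duplicated regions,
natural standing variation between the crossed parents, indels or
multi-allelic sites, sequencing-quality variation along reads, selection or
segregation distortion, or incomplete penetrance.

## SNP-index and screening

SNP-index = alternative reads / total reads at a site in one pool; it is
undefined (reported as missing) at zero depth. Expected values, by
enumeration of the four equally likely F1 × F1 gamete pairs conditioned on
pool phenotype: recessive MT pool **1**, WT pool **1/3**; dominant MT pool
2/3, WT pool 0. At a marker with recombination fraction r to the causal
SNP, the recessive MT-pool expectation decays as **1 − r** (enumeration of
the 16 gamete-pair combinations at two loci), reaching 0.5 for unlinked
markers.

The screen keeps sites with MT index ≥ 1 − ε (default ε = 0, i.e. exactly
all-alternative reads) and WT index within wt_center ± wt_halfwidth
(default 0.3 ± 0.1, endpoints **inclusive**), each pool at depth ≥
min_depth (default 10, a conventional floor below which the index is too
noisy to band-test). Band membership is evaluated with exact rational
arithmetic (`fractions.Fraction`) on the raw read counts, so a count of
exactly 40/100 passes a 0.3 ± 0.1 band with no floating-point edge effects.

**Power at 50× depth.** At the causal SNP the WT-pool count is
Binomial(depth, 1/3); for Poisson(50) depth the probability of landing in
[0.2, 0.4] is ≈ 0.82. A single 50× experiment therefore misses the causal
SNP in roughly one run in five — the screen is an enrichment step, not a
proof — and any demand that the causal SNP pass in every one of many
replicates is statistically unattainable at this depth (P(100/100) ≈
0.82¹⁰⁰ ≈ 2 × 10⁻⁹). Deeper sequencing or a wider band trades specificity
for sensitivity.

## Segregation test

Phenotype counts are tested against an expected ratio with Pearson's
chi-square goodness-of-fit (scipy), df = k − 1, **no Yates continuity
correction**: for 221:59 vs 3:1 this gives χ² = 2.305, p = 0.129 (≈ 0.13),
whereas the corrected statistic would give ≈ 0.15. The uncorrected p-value
agrees with a Monte-Carlo multinomial null for large samples; for small
two-category counts the exact binomial tail can differ noticeably (e.g.
≈ 0.147 for 221:59) because of discreteness, so the asymptotic p should be
read as approximate near conventional thresholds.

## Fine mapping

Given genotype calls (`AA`/`Aa`/`aa`, missing allowed) for each individual
at each candidate: under recessive inheritance an individual is
*inconsistent* with a candidate if it is mutant but not `aa`, or wild type
but `aa`. A candidate with zero inconsistent calls among ≥ 1 informative
individuals is **completely linked**; with any inconsistent call,
**excluded**; with no informative calls, *undetermined* (warned). F3
progeny-test results enter as additional rows. Two loci show a
*recombinant* individual when both calls are non-missing and differ (a
doubly heterozygous individual cannot be phase-resolved and is not
flagged).

**Resolution limit.** With n individuals, 2n meioses are scored. Markers
closer than about 1/(2n) Morgans to the causal SNP are expected to show no
recombinant and remain completely linked. At the default 2.6 cM/Mb and 280
F2 plants this is a window of roughly ±137 kb; at 50 mutations/Mb it
typically contains a dozen or more co-segregating SNPs, so a unique
completely linked candidate is the exception, not the rule — effect
annotation (below) or more progeny are needed to finish the job. At sparse
marker densities (~5/Mb) a unique hit is common.

## Effect annotation

Gene models come from GFF3 (CDS features grouped by `Parent`, handled with
gffutils), the reference from FASTA (pyfaidx). The CDS is assembled in
transcription order, minus-strand features are reverse-complemented, the
affected codon is located from the CDS offset, and both codons are
translated (Biopython, standard table). Consequences: `synonymous`,
`missense`, `stop_gained`, `stop_lost`; SNPs in introns or outside genes
are `intron`/`intergenic`, and an incomplete trailing codon is reported as
`non_coding` with a warning. A reference-base mismatch between VCF and
FASTA is an error, not a silent skip. Note that a C→T transition can create
a stop from Gln (CAA→TAA, CAG→TAG) or Trp/Arg codons, but not from Glu
(GAA/GAG) — a useful sanity check when cross-reading annotations.

## Defaults and their justification

| parameter | default | rationale |
|---|---|---|
| recomb_rate | 2.6 cM/Mb | calibrated from an observed 3 recombinants in 560 meioses over a 205 kb interval in a legume mapping cross (0.54 cM / 0.21 Mb) |
| density | 50 /Mb | typical EMS census for a strongly mutagenised line |
| spectrum | 1.0 | EMS is essentially all G:C→A:T |
| n_progeny | 280 | a practical F2 population size for a single cross |
| depth | 50× | common pooled-resequencing depth; see the power note above |
| WT band | 0.3 ± 0.1 | brackets the 1/3 expectation with room for binomial noise at 50× |
| min_depth | 10 | conventional floor for a usable index |

## Reproducibility

A run is specified by a YAML config plus one integer seed. The seed is
split per stage with `numpy.random.SeedSequence.spawn`, so changing one
stage's code or adding stages cannot silently reshuffle another stage's
draws. A 12-hex-character SHA-256 hash of the canonical JSON of the config
is embedded in every artifact (VCF header, TSV comment lines, JSON
payloads); identical configs and seeds reproduce every output byte for
byte, wherever the run directory lives.
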