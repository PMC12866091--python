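# Methods

This note documents the models, conventions and numerical choices behind
`triovar`, and what the synthetic-data tests do and do not establish about
real cohorts.

## The triplet origin model

Each patient contributes three exome call sets: blood (B), cancer-adjacent
normal (A) and tumor (T).  Blood is taken as the germline reference — an
assumption that holds when blood is uncontaminated by circulating tumor DNA
and coverage is high enough that germline alleles are not missed.  Presence
of a canonical variant key (chrom, pos, ref, alt after suffix-then-prefix
allele trimming) in each tissue yields three bits, and the seven nonempty
bit patterns partition variants into mutually exclusive classes.  The
biologically central ones:

| bits (B,A,T) | class          | interpretation                       |
|--------------|----------------|--------------------------------------|
| 1,1,1        | germline_all   | inherited polymorphism               |
| 0,1,1        | shared_somatic | somatic, seeded before tumor/normal divergence (field effect) |
| 0,0,1        | tumor_private  | somatic, tumor-restricted            |
| 0,1,0        | normal_private | somatic clone confined to normal tissue |

"Present" means the variant survived whatever filtering was applied to the
sample handed to `classify_origin`; by default the analysis runs on
post-filter (high-functional-impact) sets, and gene-level sharing/Venn
counts use the gene symbols of those sets.  Two-tissue classes involving
blood (B∩A, B∩T) arise in real data from dropout of a germline allele in
one tissue; the classifier reports them rather than forcing them into the
four generative classes.  At gene level the reported per-tissue VAF is the
maximum over the gene's variants in that tissue (the strongest clonal
signal); variant level is the default for all VAF work.

The detection limit of a calling rule requiring `r` supporting reads at
coverage `c` is `r/c` — 0.10 in a ~100× normal sample and 0.05 in a ~200×
tumor for the default 10-read floor.  Consequently observed somatic VAF
distributions are left-censored, which all recovery tests account for.
`revalidate_presence` offers a second pass for borderline absences: a
one-sided exact binomial test of the alt-read count against a sequencing
error rate (default 0.01), with zero depth yielding an explicit no-call.

## Filters

Hard filters use strict inequalities exactly as conventionally printed
(DP < 4 fails, DP = 4 passes): SNVs fail on DP < 4, QD < 2, FS > 60,
MQ < 35, MQRankSum < −12.5 or ReadPosRankSum < −8; indels on DP < 4,
QD < 2, FS > 200, MQ < 35 or ReadPosRankSum < −20 (no MQRankSum rule);
both on GQ < 20.  A missing QC annotation skips its rule instead of
failing the record — failing on missingness would discard entire
annotation-poor cohorts.  Each dropped record is attributed to the first
violated rule in a fixed order, making report counts additive; the
conjunction itself is order-independent.  Non-silent exonic categories
follow the ANNOVAR vocabulary; splicing counts as non-silent by default
(configurable).  High functional impact is MetaSVM "D" OR ClinVar
pathogenic; "likely pathogenic" is included by default (configurable), and
missing annotations never qualify.

## Gene and pathway statistics

Differential mutation per gene uses the 2×2 table
[mutated_a, n_a−mutated_a; mutated_b, n_b−mutated_b] with the two-sided
exact p computed by the conventional "minlike" rule (sum of hypergeometric
probabilities ≤ the observed table's).  BH is the standard step-up.
Cramér's V is √(χ²/n) with no continuity correction; a degenerate margin
gives 0.  Odds ratios for ranking/display use Haldane–Anscombe +0.5 only
when a cell is empty, and never feed the exact test.  Mutation burden is
variants per megabase; the per-gene length comes from the gene model
(contiguous synthetic genes here; exonic sums in real annotation).

Preranked GSEA ranks genes by between-tissue log odds ratio (descending,
alphabetical ties).  The enrichment score is the classic weighted KS
running sum: hit increments |score|^p normalized over in-set genes (default
p = 1; p = 0 gives the unweighted statistic), miss decrements 1/(N−n_set);
ES is the extreme deviation, clipped to [−1, 1] against float drift, and a
set spanning the whole list scores 1 by convention.  The null is gene-label
permutation (default 1000 permutations, seeded); NES divides ES by the mean
|ES| of same-sign permutations; p is the same-sign tail fraction with +1
smoothing; FDR is BH across testable sets.  Permutation counts and the
weight exponent are configuration, not claims about any particular external
implementation.

Germline/somatic pathway attribution computes, per patient and pathway,
the percent of member genes hit by each origin group (denominator = full
pathway size), then averages over patients.  Definition A (somatic =
tumor-private, germline = shared-by-all) uses disjoint classes, so the two
percents sum to ≤ 100; definition B (somatic = normal-private + shared
somatic, germline = shared-by-all + blood∩normal) can overlap through
distinct variants of one gene.  A gene carrying both origins counts once
per origin.  Pathways with no member gene in the cohort's annotation
universe are excluded and flagged.

## Signatures

SBS-96 channels are pyrimidine-centered substitutions with 5'/3' flanks in
the COSMIC v3 row order (six substitution blocks × 16 contexts,
alphabetical).  Purine-reference SNVs map through the reverse complement,
making spectra strand-invariant; a reference-base mismatch raises (data
integrity), while indels and contig-edge positions are skipped and
tallied.  Refitting is per-sample nonnegative least squares onto the
catalog columns — the primary decomposition path — with exposures
normalized to fractions and reconstruction quality reported as cosine
similarity.  Attributed counts use largest-remainder rounding so per-group
totals are exact.  De novo extraction is fixed-rank NMF, best Frobenius
error over seeded random restarts; model selection across ranks
(stability/silhouette analysis) is deliberately out of scope.  The
Wilcoxon signed-rank comparison drops zero differences, uses the exact
distribution for n ≤ 25 (no ties) and a tie-corrected normal approximation
above, and reports fewer than 5 informative pairs as not testable.

## Synthetic cohorts

The generator emulates the study design at the variant-call level (no
reads): 24 patients by default, 500 genes of ~1.5 kb on a single synthetic
contig (GC 0.41), per-patient loads of 200 germline, 30 tumor-private, 15
normal-private and 15 shared-somatic variants — a germline-dominated
landscape.  Depth is Poisson (mean 100× blood/normal, 200× tumor; the
standard single-parameter shorthand for exome coverage), alt reads are
Binomial(depth, VAF), and a variant enters a tissue's call set only with
≥ 10 alt reads — reproducing detection-limit censoring.  Germline VAFs are
0.5/1.0 at 85/15 (a typical exome het/hom ratio; a knob, not a claim).
Somatic clonal fractions are Beta with shape a = 2 and b solved from the
target median 0.216 via the (a−1/3)/(a+b−2/3) approximation; one fraction
is drawn per somatic variant and shared by all carrying tissues, so
tumor/normal VAF ratios scatter around 1 purely through read sampling.
Substitution channels are drawn from a configurable signature mixture
(default 19.1/58.4/22.5 across three synthetic signatures named after the
age-associated SBS1/SBS5 plus SBS54); a channel is realized at a reference
position whose trinucleotide context matches, so context matrices rebuilt
from the FASTA agree with the generating channels exactly.  Annotations
(MetaSVM/ClinVar/exonic function) are sampled so a configured fraction
(default 0.6) passes the impact filter.  Per-patient RNG streams derive
from the global seed via `SeedSequence`, so cohorts are reproducible and
patients independent.

What passing tests show — and what they do not: recovery results certify
the *logic* (classification, censoring arithmetic, refitting) under the
stated generative model.  Real exomes add mapping artifacts, strand bias,
contamination, purity variation, multi-nucleotide events, shared population
polymorphisms and annotation errors, none of which the generator emulates;
quantitative results on synthetic cohorts therefore do not predict
cohort-level numbers on real data.

## Numerical choices and degenerate inputs

- Quartiles/IQR: linear interpolation between order statistics (type 7).
- Jaccard of two empty sets: 0 by convention.
- Tumor/normal ratio excludes zero-normal-VAF items into a diagnostics
  count instead of producing infinities.
- Zero-variance burden–age input returns an explicit undefined-correlation
  result, never NaN propagation.
- All-zero spectra refit to zero exposures with an undefined-similarity
  flag; empty VAF selections return an explicit empty summary.
- Signature catalogs must have 96 rows, nonnegative entries and column
  sums within 1e-3 of 1 (smaller drift renormalized; larger rejected).
- Multi-allelic VCF sites are split per ALT allele before any set logic;
  chromosome names lose the "chr" prefix on load; VCF coordinates are
  1-based, BED 0-based half-open, internal positions 1-based.

## Problem sizes

Default analyses run on 24-patient × 500-gene cohorts (~6,200 variants);
signature-recovery checks use ~10,000 mutations; GSEA calibration uses 200
null sets × 1,000 permutations on 300-gene lists; the exhaustive Fisher
check sweeps every 2×2 table with up to 30 patients per arm.  These sizes
were chosen to make sampling error small relative to the tolerances being
checked while keeping a full run on a single CPU in the minutes range.

## Known limitations

- Presence/absence is binary per tissue after filtering; there is no joint
  genotyping across tissues and no purity/contamination model.
- The de novo NMF path has no rank-selection machinery.
- GSEA uses gene-label permutation only (no phenotype permutation).
- The curated-pathway workflow expects user-supplied GMT files; the
  bundled generator produces synthetic stand-in gene sets for testing.
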