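# triovar

Mutational-landscape analysis of matched **blood / cancer-adjacent-normal /
tumor** exome triplets.

Histologically normal tissue adjacent to a tumor often already carries
somatic mutations — the molecular footprint of *field cancerization*.  With
a matched triplet per patient, the blood sample serves as the germline
reference: a variant seen in all three tissues is inherited, one seen in
normal and/or tumor but absent from blood is an acquired somatic mutation,
and a somatic variant shared by normal and tumor is evidence of early clonal
seeding.  `triovar` implements this origin analysis end to end for cohorts
of annotated VCFs, together with the statistics usually layered on top of
it, and ships a synthetic-cohort generator with full ground truth so the
whole pipeline is testable without protected patient data.

## What it computes

- **Quality + impact filtering** (`impact_filter`): GATK-style site hard
  filters with separate SNV/indel thresholds (DP < 4, QD < 2, FS > 60 / 200,
  MQ < 35, MQRankSum < −12.5, ReadPosRankSum < −8 / −20), a GQ < 20
  genotype floor, removal of non-exonic/silent calls, and the
  high-functional-impact rule (MetaSVM = D **or** ClinVar (likely)
  pathogenic).
- **Origin classification** (`triplet_classify`): the presence bits
  (B, A, T) partition variants into seven mutually exclusive classes
  (germline B∩A∩T, shared somatic A∩T, tumor-private, normal-private, …);
  Venn region counts and Jaccard indices at variant or gene level; VAF
  summaries (median/IQR, type-7 quartiles); tumor-to-normal VAF ratios of
  shared somatic variants; the detection limit `min_reads / coverage`
  implied by a supporting-read floor; and an optional binomial
  re-validation of weak variant support against the sequencing error rate.
- **Gene-level statistics** (`gene_stats`): per-gene two-sided Fisher exact
  tests between tissues on mutated/not-mutated 2×2 tables,
  Benjamini–Hochberg FDR, Cramér's V, log odds ratios (Haldane–Anscombe
  +0.5 on empty cells), mutation burden per megabase, and Pearson
  burden–age correlation.
- **Pathway analysis** (`pathway_analysis`): patient × pathway alteration
  matrices over GMT gene sets, germline-versus-somatic percent attribution
  per pathway (two origin definitions), and preranked GSEA with the
  weighted Kolmogorov–Smirnov enrichment score, gene-label permutation
  null, NES, and FDR.
- **Mutational signatures** (`signatures`): SBS-96 trinucleotide context
  matrices from a reference FASTA (strand-invariant, pyrimidine-centered),
  NNLS refitting against a signature catalog, fixed-rank NMF de novo
  extraction, per-group attributed counts/percents, and Wilcoxon
  signed-rank comparisons.
- **Synthetic cohorts** (`synthetic_cohort`): triplet cohorts with Poisson
  depth (~100× blood/normal, ~200× tumor), binomial allele sampling, a
  10-read emission floor, germline VAFs 0.5/1.0, Beta-distributed somatic
  clonal fractions (median VAF 0.216 by default), and substitution contexts
  drawn from a configurable signature mixture — all recorded in a truth
  table.

## Worked example

```python
from triovar import (SimConfig, simulate_cohort, classify_origin,
                     vaf_summary, shared_somatic_vaf_ratio, min_detectable_vaf)
import pandas as pd

cohort = simulate_cohort(SimConfig(seed=3))          # 24 patients, 500 genes
pooled = pd.concat(classify_origin(p) for p in cohort.patients)

print(pooled["origin_class"].value_counts().head(3))
s = vaf_summary(pooled, "shared_somatic", "normal")
print(f"shared-somatic VAF in normal: median={s.median:.3f} IQR={s.iqr:.3f}")
r = shared_somatic_vaf_ratio(pooled)
print(f"tumor/normal VAF ratio: mean={r.mean:.2f} range=({r.min:.2f}, {r.max:.2f})")
print(f"detection limits: normal {min_detectable_vaf(10, 100):.2f}, "
      f"tumor {min_detectable_vaf(10, 200):.2f}")
```

prints

```
origin_class
germline_all      4800
tumor_private      721
normal_private     304
Name: count, dtype: int64
shared-somatic VAF in normal: median=0.255 IQR=0.182
tumor/normal VAF ratio: mean=0.99 range=(0.49, 2.14)
detection limits: normal 0.10, tumor 0.05
```

Most variants are germline (shared by all three tissues); shared somatic
variants have comparable allele fractions in normal and tumor (ratio ≈ 1),
the pattern expected from early clonal seeding rather than contamination;
and the 10-supporting-read calling floor implies that VAFs below 0.10
(normal, ~100×) and 0.05 (tumor, ~200×) are underdetected.

The same run is available from the shell:

```bash
triovar all --outdir out/ --seed 3            # full pipeline, default cohort
triovar classify --config run.yaml --outdir out/ --seed 3
```

Each stage writes plain TSV/JSON tables; identical config + seed gives
byte-identical outputs.

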