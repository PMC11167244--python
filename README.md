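# lncaut

Discovery of DNA-methylation-dysregulated, autophagy-related lncRNAs in a
tumor/normal cohort, and of the drugs and prognostic signals attached to
them.

## The problem

Long non-coding RNAs can be silenced or activated in tumors by aberrant DNA
methylation of their promoters and enhancers. When such a dysregulated
lncRNA co-expresses with autophagy genes, it is a candidate regulator of
autophagy — and thereby a candidate biomarker and drug target. `lncaut`
implements that chain of reasoning as a tested, reusable pipeline for
epigenomics groups working with matched expression (log2), 450K/EPIC-style
methylation beta values, tumor purity estimates, perturbation signatures
and survival tables. Because the real cohorts behind such analyses are
access-restricted, the package ships a first-class synthetic-cohort
generator with planted effects, so every stage's sensitivity and false-call
behavior can be measured exactly.

## The method

The pipeline runs seven stages:

1. **Differential expression** (lncRNAs and genes): per-feature Wilcoxon
   rank-sum, Benjamini–Hochberg FDR; called at FDR < 0.05 and |log2FC| ≥ 1.
2. **Differential methylation**: per-CpG rank-sum on M-values
   M = log2((β+ε)/(1−β+ε)), effect reported as Δβ; a site is
   differentially methylated at FDR < 0.05.
3. **Dysregulation calls**: a lncRNA is methylation-dysregulated iff it is
   differentially expressed, ≥ 1 differentially methylated CpG lies in its
   promoter or enhancer (BED intervals, 0-based half-open), the methylation
   change opposes the expression change (hyper+down or hypo+up), and the
   site's β negatively correlates with the lncRNA across tumors
   (Spearman, BH FDR < 0.05 over tested pairs).
4. **lncAut screen** (three steps): rank all genes by the RS score
   RS(g) = partial Spearman ρ(lncRNA, g | purity) across tumor samples;
   compute the weighted Kolmogorov–Smirnov enrichment score (weight p = 1)
   of the differential autophagy gene set (DE genes ∩ autophagy database)
   in that ranking, with a gene-label permutation null giving the nominal
   p, NES = ES / mean |same-sign null ES|, and a pooled-NES FDR; convert
   lncAut = 1 − p and select lncRNAs with lncAut > 0.9 and FDR < 0.05.
5. **Regulatory network**: signed edges between selected lncRNAs and
   differential autophagy genes at |ρ| ≥ 0.3 and FDR < 0.05; one-sample
   Wilcoxon signed-rank tests over AT+ (autophagy-promoting) and AT−
   (autophagy-inhibiting) partners classify each lncRNA as
   autophagy-promoting or -inhibiting.
6. **Drug screen**: each lncRNA's network partners form its target set,
   scored by the same GSEA kernel against every drug's ranked perturbation
   signature; pairs with FDR < 0.01 are reported, NES > 0 meaning the drug
   induces the targets and NES < 0 that it represses them.
7. **Survival**: median-expression-split Kaplan–Meier + log-rank per
   selected lncRNA; survivors enter a multivariate Cox proportional-hazards
   model with the clinical covariates; a lncRNA with Cox p < 0.05 for its
   own term is an independent prognostic factor.

## Worked example

Simulate a cohort (60 tumor / 30 normal samples, 120 lncRNAs with 8 planted
dysregulated autophagy regulators, 1000 genes with 150 autophagy-annotated,
2000 CpGs, 20 drugs with 5 planted drug–lncRNA pairs) and run the pipeline:

```bash
lncaut simulate --out demo --seed 42
lncaut run --config demo/pipeline.yaml
```

The run prints the per-stage cascade:

```json
{
  "de_lncrnas": 8,
  "de_genes": 134,
  "dm_sites": 8,
  "dysregulated_lncrnas": 8,
  "dysregulated_promoter": 4,
  "dysregulated_enhancer": 4,
  "lncaut_candidates": 8,
  "differential_autophagy_genes": 134,
  "selected_autophagy_lncrnas": 8,
  "network_edges": 133,
  "network_genes": 114,
  "drug_pairs": 5,
  "drug_pairs_nes_positive": 3,
  "drug_pairs_nes_negative": 2,
  "drugs_involved": 5,
  "lncrnas_with_drugs": 5,
  "logrank_significant": 8,
  "prognostic_lncrnas": 8
}
```

Reading it: all 8 planted lncRNAs were differentially expressed, all 8
planted CpGs were recovered (4 promoter + 4 enhancer dysregulation calls,
no false calls), all 8 passed the lncAut > 0.9 / FDR < 0.05 screen, the
network linked them to 114 differential autophagy genes, and exactly the 5
planted drug–lncRNA pairs were reported at FDR < 0.01 — 3 inducing and 2
repressing, matching the planted signature signs. Stage outputs land in
`demo/results/*.tsv` (ids, effects, p, FDR, calls per stage) with a
machine-readable `report.json`.

Every stage is also a library function (`lncaut.differential`,
`lncaut.dysregulation`, `lncaut.gsea`, `lncaut.network`, `lncaut.survival`)
and a CLI subcommand (`lncaut de|dm|dysreg|lncaut|network|drugs|survival`)
for reruns on existing outputs.

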