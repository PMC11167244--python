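# Methods

This note documents the statistical choices, the synthetic-cohort model,
and the limitations a user should know before trusting the pipeline on
real data.

## Statistical kernels

**Multiple testing.** Wherever a stage reports an FDR outside GSEA, it is
Benjamini–Hochberg (step-up) over the stage's own family of tests: all
features for differential expression/methylation, all tested site–lncRNA
pairs for the dysregulation correlations, all (lncRNA, gene) pairs for
network edges, all function sets for over-representation.

**Two-group tests.** Tumor-vs-normal comparisons use the Wilcoxon rank-sum
test (scipy): exact null distribution for small tie-free samples,
otherwise the normal approximation with continuity and tie correction.
Rank tests were chosen because expression and beta scales are bounded and
skewed, and the choice makes the methylation test invariant to the
(monotone) M-value transform — the M-values are kept in the code path as
the documented testing scale, with effects reported as Δβ so hyper/hypo
calls read directly in methylation units. ε = 0.01 keeps β ∈ {0, 1}
finite.

**Correlation.** All co-expression quantities are Spearman (average ranks
on ties). The purity adjustment is the first-order partial correlation on
rank-transformed data,
r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)), clipped to [−1, 1].
Conventions for degenerate input: constant z falls back to the plain
Spearman correlation; constant x or y raises (the correlation is
undefined); a gene whose ranks coincide exactly with purity gets RS = 0
(nothing remains after adjustment). P-values for (partial) Spearman use
the t approximation with n − 2 − c degrees of freedom, c the number of
controlled covariates.

**GSEA kernel.** The enrichment score is the classic weighted
Kolmogorov–Smirnov running sum: hit increments |score|^p normalized over
in-set scores (p = 1), miss increments 1/(N − N_H); ES is the running-sum
value of largest magnitude, first occurrence on exact ties. A set whose
in-set weights are all zero falls back to uniform hit increments; a set
covering the whole list is an error (the miss denominator vanishes). The
null reassigns set membership uniformly at random with size preserved
(gene-label permutation): the ranking is a per-lncRNA correlation profile,
not a two-class phenotype, so phenotype permutation has no analogue here.
The nominal p is the add-one estimator over same-sign nulls,
p = (1 + #{same-sign |null ES| ≥ |ES|}) / (1 + #same-sign nulls),
which avoids zero p-values and is approximately uniform under the null.
NES divides ES by the mean magnitude of same-sign null ES. FDR across a
batch of tested sets is the standard pooled-NES positive/negative
procedure (normalized null NES pooled over all results, q clipped to
[0, 1] and made monotone per sign); BH on the nominal p-values is
available as an alternative (`fdr_method="bh"`).

**lncAut.** lncAut = 1 − nominal p, selected at lncAut > 0.9 (strict) and
FDR < 0.05. Pairing the 0.9 threshold with the p-value scale is the
natural reading of a score "converted" from a GSEA p-value, and keeps the
FDR gate as a separate, explicit criterion. n_perm defaults to 1000; a
seed is mandatory wherever permutations run.

**Dysregulation rule.** "Opposite correlation" is enforced as two joint
clauses: the direction of the region's most significant differentially
methylated site must oppose the expression direction, and that site's β
must correlate negatively with the lncRNA across tumors at BH FDR < 0.05.
Both clauses can be relaxed independently (`require_direction`,
`require_correlation`). Multi-site regions are summarized by the
minimum-FDR site (ties by site id), matching the "at least one site"
semantics. Promoter/enhancer definitions come from the input BED; strand
is carried but ignored in overlap, since array-summarized CpG methylation
is strand-symmetric.

**Network and roles.** Edges require |ρ| ≥ 0.3 and FDR < 0.05 (both
configurable); the sign of ρ is the edge sign. The
activator/inhibitor call uses one-sample Wilcoxon signed-rank tests on the
lncRNA's edge correlations, split by AT+/AT− annotation: promoting if
ρ(AT+) is significantly above zero and ρ(AT−) significantly below (both at
0.05), inhibiting for the mirror image, otherwise unclassified. At least
three annotated partners per side are required; note the exact signed-rank
test cannot reach p < 0.05 below n = 5, so sparse annotations yield
"unclassified" rather than a spurious call.

**Drug screen.** Each (drug, lncRNA) pair runs the same GSEA kernel on the
drug's ranked signature; target genes missing from a signature are dropped
(warning below 50% coverage). FDR is pooled across all screened pairs and
gated at 0.01; NES > 0 is reported as "induces", NES < 0 as "represses".
Signatures are consumed pre-ranked — building them from raw perturbation
profiles is out of scope.

**Survival.** Kaplan–Meier curves and the log-rank test come from
lifelines, as does the Cox proportional-hazards fit (Breslow tie
handling — the only method lifelines implements, and the documented choice
here). The KM grouping is a rank-based median split with ties broken by
sample id, so even sample counts split exactly in half. Categorical
covariates are dummy-coded against a first-level reference; the lncRNA
enters as standardized continuous expression. Separation/non-convergence
is flagged (`CoxResult.converged`) rather than silently reported.

## The synthetic cohort

The generator emulates a tumor/normal multi-omics study with planted
effects; its defaults are the study conditions under which the package's
guarantees are stated.

Sizes: 60 tumor / 30 normal samples; 120 lncRNAs (8 planted); 1000 genes,
of which 150 autophagy-annotated (90 AT+, 45 AT−, 10 both, 5 unknown);
2000 CpGs (1 promoter + 2 enhancer CpGs per lncRNA, the rest background);
20 drugs (5 planted pairs); survival for all tumor samples.

Mechanisms, with defaults and rationale:

* **Expression.** Baselines U(2, 10) log2 units, residual sd 1.0. Planted
  lncRNAs shift by ±2.0 log2 units in tumors (alternating down/up),
  comfortably beyond the |log2FC| ≥ 1 call threshold at n = 60/30.
* **Methylation.** β values arise by inverse-logit of a per-site latent
  (site means U(0.1, 0.9), logit-scale noise sd 0.4), keeping [0, 1]
  support with realistic heteroscedasticity. Each planted lncRNA's CpG
  (promoter or enhancer, alternating) separates tumor/normal means by
  Δβ = 0.3 symmetric around 0.5, in the direction opposite to expression;
  within tumors the site's logit-β loads −0.8 on the same latent factor as
  the lncRNA's residual, making the β–expression correlation negative by
  construction (≈ −0.5 to −0.7 after the lncRNA's other variance terms).
* **Private target blocks.** Each planted lncRNA drives a disjoint block
  of 7 AT+ genes positively and 5 AT− genes negatively at partial
  correlation ≈ 0.7; blocks are deliberately unbalanced because a
  half-top/half-bottom set makes the running-sum statistic sign-unstable,
  and 5 is the smallest AT− block at which the signed-rank role test can
  reach significance. Targets carry a ±1.5 log2 tumor shift so they enter
  the differential autophagy set. Disjointness keeps each drug's planted
  effect specific to one lncRNA.
* **Shared autophagy program.** A per-tumor-sample "autophagy activity"
  factor loads +0.5 on non-target AT+ genes, −0.5 on non-target AT− genes
  (which also receive the ±1.5 differential shift) and +0.9 on every
  planted lncRNA. This models the co-regulation that gives a genuine
  regulator a broad, consistent correlation profile over the autophagy
  set — the feature GSEA actually detects — while leaving the private
  blocks module-free. The factor correlates 0.6 with tumor purity:
  autophagy activity tracks microenvironment content, which is precisely
  why purity adjustment matters — without adjustment, any purity-loaded
  lncRNA inherits a spurious correlation with the whole module. The
  gene-side and lncRNA-side loadings are separate parameters because they
  control different things: gene-side coherence sets how strongly a
  *chance* lncRNA–factor alignment masquerades as enrichment (a known
  blind spot of gene-label permutation nulls), lncRNA-side loading sets
  the true regulator's signal.
* **Purity.** Tumor purity ~ U(0.4, 0.95); an additive purity factor loads
  on a random 30% of genes and lncRNAs with loadings U(0.5, 1.5).
* **Drugs.** Signature scores are iid N(0, 1) per gene; a planted
  (drug, lncRNA, sign) pair shifts that lncRNA's targets by sign × 3.0
  before ranking. Ties in ranks are broken by gene id.
* **Survival.** Exponential event times with log-hazard 0.7 × standardized
  expression of the prognostic lncRNA (a hypo+up planted one) plus small
  fixed effects of two categorical covariates (gender ±0.2; three-level
  race +0.1/−0.1); baseline median 500 days; administrative censoring at
  5 years (≈ 20–30% censoring).

`CohortConfig.null()` zeroes every planted magnitude (including the purity
factor), giving an exact global null for calibration studies. The spec of
the generator admits zero for all effect magnitudes for exactly this
purpose. Identical configurations reproduce byte-identical output; the
generator, drug signatures and survival draw from independent seed streams
(`SeedSequence([seed, k])`, k = 0, 1, 2).

**What the generator does not model** — and hence what passing tests do
not establish about real data: genomic coordinate realism, linkage
disequilibrium among CpGs, count-based expression noise, copy-number and
batch effects, probe cross-reactivity, non-exponential hazards,
informative censoring, and any correlation structure beyond the single
autophagy module and purity factor. Real-data thresholds (edge ρ, DE
log2FC) should be re-examined per cohort.

## Pipeline determinism and sizes

The pipeline expands its single seed into per-stage sub-seeds via a fixed
counter scheme (`SeedSequence([seed, counter])`; the lncAut and drug
stages are the only consumers), so a stage rerun in isolation reproduces
its in-pipeline output byte for byte. The validation suite measures
recovery over 10 fixed default-size cohorts, null calibration over 20
zero-effect cohorts, and Cox recovery over 50 survival draws at n = 500 —
sizes at which each check's sampling noise is far from its decision
boundary while the whole suite stays interactive.

## Known limitations

* The gene-label permutation null ignores gene–gene correlation; under
  strong co-regulation the nominal p for an unrelated lncRNA can be
  anti-conservative (visible in the confounded synthetic cohort as a small
  number of false selections even after purity adjustment). Sample
  permutation would fix this but breaks the per-lncRNA profile semantics.
* The pooled-NES FDR is coarse when few candidates are tested; the BH
  alternative is exposed for that regime.
* BH-adjusted q-values are reported as monotone step-up values; applying
  the procedure to already-adjusted values is not an identity, so q-values
  should never be re-adjusted downstream.
* lifelines provides only Breslow tie handling; with heavily tied event
  times the hazard-ratio estimates are mildly biased toward zero.
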