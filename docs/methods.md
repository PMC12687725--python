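# Methods

This note documents the models, procedures and design choices behind
`oomethkit`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The biological system being modelled

Growing mouse oocytes deposit H3K36me2 broadly and H3K36me3 over
transcribed gene bodies; DNMT3A reads these marks and methylates DNA,
while H3K4me3 blocks it. CpG islands (CGIs) bound by variant PRC1 carry
H2AK119u1/H3K27me3 and normally stay unmethylated. KDM2A/KDM2B keep
H3K36me2 off these islands (and KDM2B's CXXC domain recruits vPRC1);
when both are lost, islands with low H3K4me3 gain H3K36me2 and then DNA
methylation, genes under them are derepressed, and the aberrant maternal
methylation persists into embryos where it represses maternal alleles.

## Synthetic-data generator

The generator (`synthetic_data`) emulates the study's data *structure*
post-alignment — it is the test-bed every analysis stage is validated
on, with planted ground truth throughout. Conventions:

* **Annotation.** Genes 6–70 kb, non-overlapping, on one autosome;
  intergenic 10-kb tiles (cut downstream into 20 × 500-bp bins) on a
  second; five genes each on chrX/chrY for sex inference. CGIs (widths
  300–1,200 nt around the 533-nt median used for resized windows) sit at
  60% of promoters, some gene bodies, and intergenic space, each with a
  generated sequence whose CCG/CGG density is drawn from a configurable
  range (default 0.5–4 per 100 bp).
* **Latent epigenome.** Each region draws a class — PRC1 CGI,
  transcribed (transcription-coupled, methylated already in control),
  inactive, intergenic — with lognormal within-class mark spread.
  H3K4me3 at transcribed CGIs spans a wide range (lognormal around 2.2,
  σ = 0.6): it is the key negative predictor of methylation and needs a
  realistic dynamic range to be identifiable.
* **Planted methylation model.**
  `meth = clamp(β0 + β1·K36me2 + β2·K36me3 − β3·K4me3 + ε, 0, 1)` on
  enrichments rescaled by 10, defaults β = (0.02, 0.6, 0.3, 0.2),
  ε ~ N(0, 0.02). Clamped regions are flagged; noise-free truth restricted
  to unclamped regions returns the coefficients exactly under OLS (tested).
* **Mutant rule.**
  `K36me2_mut = K36me2_ctrl + gain · max(H2AK119u1 − 1, 0) · 1{H3K4me3 < 2}`.
  The floor keeps regions with only background H2AK119u1 — gene bodies
  of stably expressed genes — unchanged, which is exactly the assumption
  the stable-gene CUT&RUN normalization rests on. Double mutants lose
  H2AK119u1 (×0.02) and derepress PRC1-target genes 4-fold.
* **Counts.** CUT&RUN fragments are Poisson (enrichment × width plus a
  uniform background spread over the *whole* genome, so most background
  lands outside counted windows); the background fraction (default 0.2)
  is an assumption — the source study does not quantify it. RNA-seq
  counts are negative-binomial (gene dispersions 0.05–0.4) so dispersion
  estimation is actually exercised; oocyte libraries modulate expression
  by a per-gene loading times a cubic smooth of diameter, letting
  diameter confound genotype when the scenario assigns diameters
  unevenly. A quarter of intergenic tile bins are signal-free
  (detection-limit bins) so the 15th-centile min-shift has a background
  pedestal to estimate.
* **WGBS.** CpG positions are fixed per region (genomic features, shared
  across libraries); coverage is Poisson, methylated counts Binomial
  with observed level `m + (1−m)·conversion_failure`, and non-CpG sites
  (true level 0) expose the conversion-failure rate. Hybrid mode tags
  calls by haplotype.
* **Hybrid reads.** A read's SNP count is zero-truncated Poisson;
  sequencing errors at SNP positions flip mismatches between genomes
  (`own = e ~ Bin(k, error)`, `other = k − e`). Errors at non-SNP
  positions hit both alignments equally and are omitted as
  label-irrelevant.

What the generator does **not** emulate: read-level artefacts (PCR
duplicates, mapping bias, M-bias), linked methylation along reads,
realistic genome composition, or trans effects. Passing recovery tests
therefore demonstrates correctness of the *algorithms* under the stated
statistical model, not robustness to every artefact of real libraries.

## Analysis stages and numerical choices

**Coordinates.** 0-based half-open everywhere; BED on disk. Promoters
are [TSS−1500, TSS+500) on the transcription axis; gene bodies
[TSS+500, TES); CGI windows are resized to fixed width about the island
midpoint, `floor((start+end)/2)` for even widths (a deterministic
tie-break; the choice is flagged as a convention, not a derived fact).

**Counting.** Fragments are assigned to windows by midpoint — a single
unambiguous assignment per window system, orientation-insensitive.

**Expression.** RPKM normalizes to exonic length and total exonic reads;
`log2(RPKM + 0.1) − log2(0.1)` maps zero counts to exactly 0. Genes enter
DE analysis with ≥1 CPM in ≥3 samples.

**CUT&RUN normalization.** Stable genes: |log2CPM| > 0.25 and
|log2FC| < 0.25 (the absolute-value reading of the expression criterion
is implemented as stated; a strictly-positive variant exists). Factors =
stable-window totals over their geometric mean, so factors multiply to 1
and no library is privileged; note that rescaling one library rescales
*all* normalized values by the common anchor shift c^(1/n) — only
between-library ratios are strictly invariant. The min-shift subtracts
the nearest-rank 15th-centile order statistic and clamps at zero
(shifted counts feed log-scale displays); an interpolated-quantile
variant is behind a flag.

**Metagene matrices.** 10 × 500-bp flank windows each side, 20
equal-width gene-body windows, genes restricted to 5–80 kb bodies,
strand-oriented columns. Smoothing is a width-5 running mean with
shrinking edge windows; display clipping at the global 2nd/98th
centiles (interpolated quantiles). Whether rows are z-scored before or
after smoothing is not fixed by the source procedure; both orders are
exposed (`zscore_before_smoothing`), default before.

**k-means.** Best of 100 seeded restarts; labels canonicalized by
descending cluster size (ties: centroid norm) so figures and reruns
agree. CGI methylome clustering runs on absolute percent levels, not
z-scores, and relabels by descending methylation in the first condition.

**Differential expression.** Per-gene NB GLM, log link, log total-count
offset. Dispersion: within-genotype method-of-moments (with the
E[m̂²] = μ² + Var(m̂) denominator correction), pooled by degrees of
freedom and shrunk toward the *mean* of positive raw estimates with
prior weight 30 pseudo-samples. The heavy shrinkage is deliberate for
~12-sample cohorts: unshrunk moment estimates are far too noisy, and a
median target under-shoots the true dispersion of a right-skewed
estimator, inflating type-I error (measured calibration across seeds:
0.042–0.058 at nominal 0.05; recomputed by the acceptance script). The
LRT refits the design projected onto the null space of the contrast
vector (df = 1 per contrast; sex-averaged contrasts average the
genotype:sex coefficients). Natural cubic splines use boundary knots at
min/max and df−1 interior quantile knots — the "covariate values as
knots" phrasing in the source is ambiguous; explicit knots can be
supplied. The shuffled-covariate control reruns the identical pipeline
with the covariate permuted and flags overfitting when shuffled calls
exceed real calls by more than max(5, 10%). The control is
interpretable only when covariate and genotype are independent: in a
confounded design, permutation necessarily floods the genotype term —
which is the artefact the control exists to expose.

**Pseudotime.** A documented stand-in for trajectory inference: rank of
samples on PC1 of log-CPM after excluding sex-chromosome and imprinted
genes, min-max scaled, oriented by anchor genes. Sex inference calls M
when the chrY read fraction exceeds 10× the median of the lower 2-means
component (absolute floor 1e−4); unclear cases are flagged, not forced.

**WGBS QC.** Fail on ≤1e7 reads, ≥7% pooled CHG+CHH methylation, or
tile-MDS outliers. The outlier rule — median Euclidean distance to
same-genotype peers exceeding the cohort median of those medians by
>3×MAD — is an explicit substitute for an unspecified manual step; the
full audit is emitted. Classical (Torgerson) MDS reproduces distances
exactly for 2-embeddable configurations; otherwise the strain is
reported. Region methylation is the pooled (read-weighted) estimator
100·Σm/Σtotal — variance-efficient; per-CpG mean available by flag.
Allelic methylation requires ≥5 informative calls per allele (configurable).

**Lasso.** Objective (1/2n)‖y − b0 − Xb‖² + λ‖b‖₁ on z-scored
predictors, solved by coordinate descent with warm starts down the fixed
grid 10^(−2…−6, step −0.05); 10-fold CV with seeded uniform fold
assignment (no stratification), MSE loss, SE = SD across folds/√10;
λ.1se = largest λ within one SE of the minimum. *Responses are on the
percent scale* (mCpG/CpG %): the fixed grid is calibrated to that scale,
and a fraction-scale response drives λ.1se to the grid ceiling.
Differential fits put the wild-type level among the predictors and
exclude it from reported rankings; the residualization alternative
(lasso on OLS residuals of mutant on wild-type) is provided and agrees
on top predictors in the recovery scenario. Multicollinearity is
documented via the predictor correlation matrix
(`CGILassoModel.predictor_correlations`). KKT subgradient conditions of
selected solutions are verified against an independent coordinate-descent
oracle in the tests. The H2AK119u1 low/high split (2-means on log
enrichments) replaces an unstated threshold; equal-count H3K4me3 bins
keep ties in one bin.

**Set statistics.** Over/under-representation uses the two-sided
hypergeometric p (summing all tables at most as probable as observed —
chosen because both directions are displayed; one-sided is a flag away),
with stars at p ≤ 1e−5 (\*\*\*\*), 1e−3 (\*\*), 1e−2 (\*), 5e−2 (·).
Gene-set maps embed pairwise Jaccard distances by classical MDS.

**Passive dilution.** Strand-symmetric accounting: one replication maps
m → m·(1+p)/2 with maintenance probability p, so p = 1 conserves and
p = 0 halves; `post_replication` adds one S phase for cells sampled
after DNA synthesis. Two divisions from oocyte to four-cell give the
4-fold (pre-replication) to 8-fold (post-replication) window for purely
passive loss.

## Problem sizes

Scenario sizes were chosen so the full battery runs interactively on a
laptop-class CPU: the default pipeline uses 60 genes / 80 CGIs / 10
tiles; calibration scenarios use 2,000 genes × 12 samples (DE), 2,000
tile bins (normalization), 400 CGIs (lasso), 20,000 reads (allelic).
The tile-MDS tile count scales automatically to what the synthetic
genome offers (`min(1e5, available)`).

## Known limitations

* The NB dispersion scheme is a calibrated lightweight substitute for
  full Cox-Reid/empirical-Bayes machinery; quasi-likelihood F-tests are
  out of scope.
* The pseudotime stand-in is a PC1 rank, valid for one dominant monotone
  program only.
* Recovery tolerances (normalization log-ratio within 10%, lasso R²
  within ±0.07, etc.) hold under the generator's stated noise model;
  real data carry artefacts the generator does not emulate.
* The lasso reports no inference on coefficients (no p-values or
  selective inference), matching its descriptive use.
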