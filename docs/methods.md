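# Methods

`popkit` implements the analysis pipeline used to characterise a
low-diversity crop germplasm collection from genotyping-by-sequencing (GBS)
SNP calls: genotype and variant filtering, distance-based population
structure, within-group diversity, composite linkage disequilibrium,
haplotype-window introgression scanning, between-group differentiation, and
structure-corrected association testing.  This note documents the models,
the numerical choices, and what the synthetic-data validation does and does
not demonstrate.

## Genotype model and filtering

Genotypes are unordered diploid calls at biallelic SNPs, stored as
alternate-allele dosages (0/1/2) with an explicit missing state.  Phase is
never used: GBS data are unphased and every downstream statistic is defined
for unknown phase.  Positions are 1-based (as in VCF); all genomic windows
are half-open `[start, end)` intervals on those coordinates.

The **tier1** filter cascade mirrors standard GBS practice for a selfing
crop.  Per-call: genotypes with quality strictly below 5 are set to missing
("below" is strict — a call at exactly the threshold is kept; calls without
a GQ value also pass, since absence of evidence is no reason to mask).
Per-locus, a variant is retained when all four independent filters pass:
variant quality ≥ 50, observed heterozygosity ≤ 0.1 (hets / non-missing
calls), call rate ≥ 0.6 (non-missing / total samples), and the minor allele
carried (het or hom) by at least 3 samples.  Because every sub-filter is a
per-locus predicate evaluated on the input matrix, the cascade is
order-independent and idempotent, and per-filter drop counts are logged as
the audit trail.  The heterozygosity ceiling of 0.1 presumes a highly
autogamous species; the synthetic generator honours this by sampling
genotypes with a within-sample selfing coefficient (below).

**Pericentromeres** are delimited per chromosome by a continuous 3-segment
(2-breakpoint) piecewise-linear regression of genetic position (cM) on
physical position (bp): an exhaustive coarse grid over interior breakpoint
pairs minimising least squares, followed by Nelder–Mead refinement, with
continuity enforced through the basis {1, x, (x−b₁)₊, (x−b₂)₊}.  A
chromosome is assigned a pericentromeric interval only when the middle
slope is below half the mean arm slope; otherwise no plateau is reported.
On simulated maps (40 points per chromosome, cM noise SD 0.5) the mean
absolute breakpoint error is well under 5% of the chromosome length.  The
package also ships the tomato SL2.50 pericentromere coordinates as a data
fixture (1-based inclusive in the file, converted to half-open internally).

**Structure markers** for ordination are selected from the euchromatic
tier1 set: call rate ≥ 0.95, minor allele in ≥ 3 samples, then up to 2000
loci on an even physical grid across the concatenated genome (the locus
nearest each grid point, ties to the lower position), and finally a
consecutive-pair prune that drops a marker whose absolute dosage
correlation with the previously kept one exceeds 0.95.  "Evenly
distributed" is read genome-wide rather than per chromosome; the grid is a
cap, not a quota.

## Distances, ordination, diversity

The **Kosman dissimilarity** between two diploid genotypes counts shared
alleles: per-locus similarity = |multiset intersection of the two allele
pairs| / 2, hence 1 − |d₁ − d₂|/2 on dosages; the sample distance is one
minus the mean similarity over loci called in both samples (pairwise
deletion).  It is a semimetric: symmetric, zero exactly when the two
samples agree at every co-called locus.

**PCoA** is classical metric scaling: double-centre −D²/2, eigendecompose,
keep the top non-negative eigenpairs, scale eigenvectors by √eigenvalue.
Negative eigenvalues (non-Euclidean D) are dropped and their relative mass
reported; no Cailliez/Lingoes correction is applied.  Axis signs are fixed
by making each axis's largest-magnitude loading positive, so runs are
reproducible.  Hierarchical (nested) analyses recompute marker selection
and distances on the subset, so pruning and frequencies are
subset-relative.

**Diversity** uses plug-in estimators throughout: per-locus expected
heterozygosity He = 1 − p² − (1−p)², percent polymorphic at threshold t =
share of loci whose major-allele frequency is ≤ t (boundary inclusive,
default t = 0.95).  Group comparisons use the resampling scheme of the
study design: 100 replicates of 20 samples drawn without replacement, with
frequencies, He, and %P recomputed inside each draw and restricted to the
loci variable in the draw; the mean over all loci (`he_all`), over variable
loci, and over the polymorphic subset are all reported, since the
literature is ambiguous about which restriction backs published figures.
Rarefaction reports the segregating-locus count versus subsample size; an
exact hypergeometric closed form —
P(not segregating) = [C(n₀+nₘ, n) + C(n₂+nₘ, n) − C(nₘ, n)] / C(N, n)
with genotype-class counts (n₀, n₁, n₂, nₘ) — backs the Monte-Carlo
estimator in tests.

**LD** is the Rogers–Huff composite estimate for unphased data: Pearson
correlation of dosage vectors over pairwise-complete samples.  Decay curves
are computed per genetic group after restricting to loci with within-group
major-allele frequency strictly below 0.98, for intra-chromosomal pairs
binned at (0,5], (5,25], (25,100], (100,1000] kb — anchored to the
distances at which the study reports r² values.  For independent loci the
finite-sample expectation E[r²] ≈ 1/n is the reference baseline.

**Group distances**: Nei's (1972) standard distance from gene identities
(J_A, J_B, J_AB over shared defined loci; monomorphic loci retained — they
contribute identity 1 to all terms) and Jost's Dest with plug-in H_S/H_T
and the n/(n−1) = 2 factor for deme pairs, averaged over loci polymorphic
in at least one of the two groups (jointly monomorphic loci carry no
differentiation signal and are excluded).  The sample-size-corrected
(Nei–Chesser) variants are deliberately out of scope.  Neighbor joining is
delegated to scikit-bio (negative branch lengths clamped to zero) and
exports Newick; a Nexus TAXA+DISTANCES file provides the input for external
split-network software.

## Introgression scan

The genome is tiled into fixed windows (default 1 Mb; windows with fewer
than 3 loci are uninformative).  Within a window, each reference-panel
sample's genotype vector is one catalog "haplotype" — on near-homozygous
GBS data the unphased vector is an adequate haplotype surrogate, and true
phasing is out of scope.  A query's minimum Kosman distance to the catalog
(missing positions wildcarded on both sides) flags the window when it
exceeds a threshold.  `scan_sample`'s default threshold is 0 — the strict
"any non-zero distance" rule.  The reclassification layer defaults to a
tolerant threshold of 0.25: a single private variant in a 25-locus window
produces a minimum distance of order 1/(2·25) ≈ 0.02, while a wild-donor
introgression block drives the distance towards 1, so 0.25 cleanly
separates mutation/genotyping noise from donor haplotypes.  A sample whose
flagged-window fraction exceeds the (configurable, always-reported) cutoff
of 0.005 is *proposed* modern-like; original passport labels are never
overwritten.  Queries that are themselves part of the reference panel are
scanned leave-one-out (their singleton haplotypes removed), so panel
members are not trivially at distance zero.  Enlarging the panel can only
remove flags — the minimum over a superset cannot increase.

## GWAS

Quantitative traits are Box–Cox normalised (maximum-likelihood λ via
scipy, offset 1 − min applied and logged when values are not strictly
positive; a QQ correlation summarises post-transform normality) and tested
per locus with a Wald test in the linear model trait ~ 1 + PCs + dosage,
against the t reference with residual degrees of freedom (honest at small
n).  Binary traits use the Rao score test of the dosage term at the null
logistic fit, χ²(1).  Structure correction uses the top q = 5 (default,
configurable) principal components of the LD-pruned dosage matrix: greedy
first-kept-wins pruning at r² > 0.3 within a 500 kb scan window, missing
dosages mean-imputed for the PCA only; per-locus tests are complete-case.
Tests run on the polymorphic set (95% threshold) and the Bonferroni flag
is exact: significant ⇔ p ≤ α/m with m the loci actually tested for that
trait.  With 298 polymorphic loci and α = 0.05 the threshold is ≈ 1.68e-4.
No kinship or mixed model is used — the correction is PC-based only.

## The synthetic collection

The generator emulates the study design's four strata (default 400 samples,
20 000 loci on 12 chromosomes of 65 Mb):

* Ancestral alternate-allele frequencies ~ U(0.05, 0.95).  **Wild** and
  **semi-domesticated** strata drift under the Balding–Nichols F-model,
  p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F), with F = 0.1 and 0.3.  Genotypes are
  drawn with a within-sample selfing coefficient F_is = 0.95 (the species
  is autogamous; this is also what makes the tier1 heterozygosity filter
  meaningful on simulated data).
* The **traditional** stratum is a diversity desert with islands: 300 loci
  in 30 clusters of 10 consecutive loci carry common minor frequencies
  U(0.1, 0.5) — the "diversity-rich loci" — while every other locus is
  fixed on the drifted major allele up to a singleton-scale private minor
  (frequency U(0.005, 0.02), realised as heterozygous carriers).  Island
  genotypes are built from 8 founder haplotypes by segmental mosaic
  inheritance (switch rate 3e-6/bp), which creates long-range haplotype
  blocks (near-range r² ≫ far-range) and makes window vectors founder-
  quantised.  Six traditional sub-groups differ in Dirichlet-distributed
  founder-usage weights, producing the group-differentiated frequencies the
  heatmap/distance analyses need.  Founder allele counts per island locus
  are conditioned on 1..K−1 so every island truly segregates.
* **Modern** samples are traditional-like genomes carrying homozygous
  donor blocks (allele opposite to the traditional major at every in-block
  locus) of 5 Mb: two *backbone* blocks present in every modern sample —
  mirroring the near-universal resistance-gene introgressions of real
  modern cultivars — plus one variable block drawn from the remaining four
  of the six-block catalog.  Block positions and per-sample assignments are
  recorded in the truth object.
* **Traits** are linear in the dosages of causal loci chosen one per
  island (so causal loci are unlinked) plus N(0, 1) noise; one trait is
  exponentiated to exercise the Box–Cox step and one is binarised at the
  liability median.  Missingness (3%, with 1% of loci boosted to 55%),
  per-call GQ (2% of calls below the masking threshold), and site QUAL
  (1% of loci below 50) layer realistic noise on top.

Closed-form expectations back the recovery tests.  For the drifted strata
E[He] = 2·E_anc[p(1−p)]·(1−F); the traditional expectation combines the
island term — with the founder-quantisation factor (1−1/K), the
truncated-binomial correction for conditioning founder counts on 1..K−1,
and the founder-weight dispersion factor — with the rare-variant term
2(E[ε]−E[ε²]); the modern expectation adds the block-presence
Bernoulli(1/4) heterozygosity of the variable blocks and zeroes for the
backbone.  When estimates come from n-sample draws the plug-in bias factor
1 − (1+F_eq)/(2n_eff) applies, with F_eq the variance-equivalent selfing
coefficient of the relevant sampling scheme (F_is for drifted loci, 0 for
het-only rare carriers, 1 for homozygous block presence) and n_eff
discounted by the expected missing-call rate.  Measured resampled He lands
within 3 Monte-Carlo SD of these targets across seeds.

What the generator does **not** emulate: coalescent site-frequency
spectra, recombination-calibrated LD decay (LD comes from the founder
mosaic, not from a genetic map), linked selection, allele-frequency
correlation between strata beyond the shared ancestral draw, genotyping
error biased by allele, or reference-mapping artefacts.  Passing the
recovery suite therefore demonstrates that the pipeline's statistics
measure what they claim on data with the assumed structure — not that the
pipeline would reproduce any particular real-data value.

## Problem sizes and determinism

All simulations run at the default study scale (400 × 20 000) for the
recovery criteria: diversity and introgression recovery use 5 seeds, GWAS
power and inflation 20 seeds, segmented-regression recovery 50 simulated
maps, and null calibration 1000 independent loci — sizes chosen so the
whole validation completes on a desktop machine in minutes.  The
end-to-end CLI determinism check runs a reduced collection (76 samples,
1500 loci, 3 chromosomes), since byte-reproducibility is scale-invariant.
Every random draw in the package flows from an explicit seed; reruns with
the same configuration and seed are byte-identical (no timestamps are
written to any artifact).

## Known limitations

* The "haplotype" of the scan is an unphased genotype vector; heterozygous
  windows blur the catalog, which matters for outcrossing species.
* Dest and Nei D use plug-in frequencies; with very small groups the
  estimators are biased (no Nei–Chesser correction).
* The Wald test assumes homoscedastic residuals after Box–Cox; the score
  test requires the null logistic fit to converge (separation skips the
  locus with a reason).
* PC correction removes broad stratification but not cryptic relatedness;
  a mixed model is explicitly out of scope.
* The %P/He published-figure restriction ("after applying the 95%
  threshold") is ambiguous; both restricted and unrestricted means are
  reported rather than guessing.
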