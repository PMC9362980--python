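# Methods

`sigconn` implements the signature-analysis core of connectivity-map style
transcriptomics: constructing differential-expression signatures, collapsing
replicates into consensus signatures, and ranking a library of signatures by
their similarity (or anti-similarity) to a query. This note records the
statistical models, the numerical choices made where the methodology is
genuinely open, and the limits of what the synthetic-data tests demonstrate.

## The signature model

A signature over N genes is the pair of vectors **d** = (d_1, …, d_N)
(log-scale differential expression: log2 ratios or z-scores, unitless) and
**p** = (p_1, …, p_N) (two-sided p-values in (0, 1]). The p vector is
optional: user uploads sometimes carry only fold changes. Gene identifiers
are opaque strings, upper-cased at load time; libraries harmonize their gene
spaces to the intersection so that correlation metrics never see missing
values.

## Connectivity metrics

The metric is keyed to the query type.

**Extreme Pearson (library signature vs library).** Per gene the signed
significance is s_i = sign(d_i)·(−log10 p_i). The extreme signature keeps
s_i only when it reaches the k-th most positive or k-th most negative value
(k = 100 per side by default, matching the L1000 landmark scale where a
978-gene signature keeps its top and bottom ~10%) and zeroes the rest; the
inequalities are non-strict, so ties at the boundary are retained and more
than 2k survivors are possible. When N < 2k the vector is left whole with a
warning. The score is the ordinary Pearson correlation of the two extreme
vectors over the full intersected gene space, zeros included; a
`extreme_support="union_nonzero"` switch restricts the support to genes
extreme in at least one signature for users who prefer the sparse
convention. p-values come from the usual t-transform
t = r·sqrt((n−2)/(1−r²)) with n the number of genes scored.

**Weighted correlation (uploaded signature vs library).** The score is the
weighted Pearson correlation of the two d vectors with per-gene weight
w_i = (−log10 p_query,i)·(−log10 p_lib,i), falling back to the library term
alone when the query has no p-values. The product reading of the weight
makes a gene count only when both experiments found it significant; genes
with w_i = 0 (p = 1 on either side) drop out. p-values are clipped below at
1e−300 before the logarithm so weights stay finite in double precision.

The significance of a weighted correlation needs an effective sample size.
The familiar Kish size (Σw)²/Σw² treats the weights as external survey
weights, but here the weights are functions of the very values being
correlated — a gene gets a large weight exactly when |d| is large on both
sides — and this coupling inflates the null variance of r well beyond
1/n_eff(Kish); in simulation the 5% test rejected 22% of independent
signature pairs. We therefore use the sign-randomization effective size

    n_eff = (Σ w x²)(Σ w y²) / Σ w² x² y²,

with x, y the weighted-centered d vectors: its reciprocal is the exact
variance of r under random sign flips of the per-gene products, conditional
on the weights and magnitudes. It reduces to ≈ n for equal weights and
keeps the 5% test at 4–5% across product, library-only and uniform weight
regimes. The t-transform then uses this n_eff; when n_eff ≤ 2 the result is
reported with p = 1 and a flag.

**Up/down lists.** Upregulated genes are encoded +1, downregulated −1, and
the score is the Pearson correlation of this encoding with the library d
over matched genes. The p-value is the t-transform of that point-biserial
correlation on n−2 df, which is algebraically identical to the pooled
equal-variance two-sample t-test comparing d between the up and down sets
(verified against an independent t-test implementation to 10 significant
digits). A query whose up or down side vanishes after matching degrades to
the gene-list metric with a warning.

**Gene lists (Random Set).** Each library gene is scored g_i = −log10 p_i.
The statistic is the mean score X̄ of the m matched query genes,
standardized by the exact moments of the mean of a uniformly random size-m
set drawn without replacement: μ = mean(g), σ_m² = ((N−m)/(N−1))·σ²/m with
σ² the population variance. The reported score is z = (X̄−μ)/σ_m with a
two-sided normal p. The normal approximation is standard Random Set
practice; exhaustive enumeration over all C(G, m) sets confirms the moments
exactly for G ≤ 12, and z is calibrated (mean 0 ± 0.03, variance 1 ± 0.05)
at G = 1,000, m = 20 in simulation. A constant score vector yields z = 0,
p = 1 by convention.

**Ranking.** `connect_query` computes one result per library signature,
applies Benjamini–Hochberg FDR across the queried library (default
significance threshold 0.05), and sorts by p ascending, then |score|
descending, then signature id — the last two purely to make output
deterministic.

**Perturbagen connectivity.** All individual query-vs-signature scores form
a scored universe; each perturbagen's signatures are a member set tested
with the same Random Set closed form, upper tail, on |score| by default
(connectivity strength regardless of direction; `--signed` ranks concordant
and discordant connections separately). The perturbagen universe is the
whole queried library; callers wanting a cell-line- or time-restricted
universe filter the library first.

## Replicate aggregation (MODZ)

Replicate z-score columns are combined by correlation-weighted averaging.
With one or two replicates the weights are equal. With three or more, the
raw weight of replicate i is the mean of its Spearman correlations with the
other replicates (computed over all genes — no landmark subset is assumed),
clipped below at 0.01 so anti-correlated outliers keep a token weight, then
normalized to sum to one; clipping precedes normalization. Spearman is
undefined against a constant column; such pairs are set to 0 with a
warning. The consensus value per gene is the weighted average, so identical
replicates reproduce themselves exactly and a column shift passes through
additively (ranks are shift-invariant).

Reproducibility QC is distil_cc_q75: the 75th percentile — linear
interpolation between order statistics, the numpy default — of the
R(R−1)/2 pairwise Spearman correlations. A signature passes when the value
is strictly greater than 0.2; failing groups are excluded from library
builds unless `--keep-failed-qc` is given. With a single replicate QC is
not assessable and no p-values are produced.

**Inference.** Each gene's consensus is compared to zero with an
empirical-Bayes weighted t-test using the same weights: weighted variance
s_g² = Σ w_i (Z_gi − MODZ_g)² / (1 − Σ w_i²) (unbiased under sum-to-one
weights), R−1 residual df. Gene variances are shrunk toward a scaled
inverse-chi-square prior fitted by moment matching on log variances
(digamma/trigamma inversion; the trigamma inverse is a Newton iteration).
When the spread of log variances does not exceed sampling noise the prior
df is infinite and all genes share the common variance with a normal
reference; a forced `prior_df=0` disables moderation and reproduces the
ordinary weighted t-test exactly. Genes with zero sample variance are
excluded from the prior fit and assigned the prior variance. The moderated
t is MODZ_g / sqrt(s̃_g²·Σw_i²) on d0 + R − 1 df.

Consensus gene signatures (CGS) reuse the identical machinery with member
signatures' d vectors as the replicate columns; members must agree on the
target gene. Identical members leave no residual variance, in which case
the consensus carries no p-values and is flagged.

## Two-group signatures

`create_signature` contrasts a treatment against a baseline group in a
log-scale matrix: d_g is the difference of group means, the pooled variance
has n_a + n_b − 2 df, and the same EB shrinkage and moderated t apply. Each
group needs at least two samples. Confounders are handled by filtering
samples before the contrast (filters are recorded in the signature's
provenance); covariate regression, multi-factor designs and count GLMs are
out of scope, and the loader warns when a matrix looks like raw counts
(integer-valued with max > 50), suggesting a log2(CPM+1) pre-transform.

## Synthetic data and what the tests show

The generators plant known structure so recovery is checkable:

* **Two-group expression**: gene baselines ~ Normal(8, 2²) log2 units,
  i.i.d. Normal(0, σ²) noise, an effect Δ added to a random gene subset in
  group A. Defaults N = 1,000 genes, 10 + 10 samples, 50 affected genes,
  Δ = 2, σ = 1 — a routine well-powered microarray-scale comparison.
* **Replicates**: latent consensus ~ Normal(0, 1) per gene plus
  Normal(0, σ²) replicate noise; defaults R = 5, N = 500, σ = 0.3, typical
  of reproducible L1000-style replicates.
* **Libraries**: standard-normal gene effects; planted partners are
  bivariate-normal with the query at correlation ρ; perturbagen plants are
  groups of such signatures sharing one label; p-values are the two-sided
  normal tails of the effects, so the plant is visible to both the
  signed-significance and the weighted metrics. Default gene space is 978
  (the L1000 landmark count).

Everything is driven by one `numpy.random.default_rng(seed)` per call; a
fixed seed reproduces byte-identical files.

These generators deliberately omit features of real data: gene–gene
correlation, heavy-tailed and heteroscedastic noise, batch structure,
dose–response and time dependence, and the L1000 Level-1→4 processing
chain. Passing tests therefore demonstrate internal correctness and
calibration under clean independence assumptions, not robustness to those
real-data pathologies.

## Numerical conventions

* p-value floor 1e−300 before −log10; reported p-values never reach 0.
* Correlations are clipped to [−1, 1] before the t-transform; |r| = 1 maps
  to the floor p.
* Zero-variance vectors: correlations raise a diagnostic error; Random Set
  returns z = 0, p = 1.
* Ties: extreme-signature boundaries keep all tied genes; ranking
  tie-breaks are |score| then id.
* Exhaustive enumeration replaces the normal approximation nowhere in the
  production path; it is used only as a test oracle (G ≤ 12).

## Problem sizes in the reproduction script

`scripts/acceptance.py` re-derives the package's headline numbers at sizes
chosen to finish in well under a minute of CPU while keeping every gene
space at production scale (978–1,000 genes): 500-pair oracle sweeps,
100 null-calibration runs of 100-signature libraries, 50 uniformity runs,
100,000 Monte-Carlo draws for the Random Set moments, and 30 runs per
planted-recovery experiment. The pytest acceptance suite uses the larger
run counts quoted above (e.g. 100 recovery runs, 200 calibration runs).

## Known limitations

* The weighted-correlation p-value is calibrated under independence of
  query and library signatures; correlated null structure (shared cell-line
  programs) will inflate it, as it does for all connectivity p-values here.
* The Random Set normal approximation thins out for very small m or very
  skewed score distributions; m of a few dozen against ~1,000 genes is the
  intended regime.
* MODZ weight clipping at 0.01 and the q75 percentile convention follow
  common practice but are isolated behind single functions
  (`aggregate.WEIGHT_CLIP`, `distil_cc_q75`) for easy revision.
* GCT support is the 1.2/1.3 text dialects only; GCTX/HDF5 is out of scope.
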