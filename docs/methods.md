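# Methods

This note records the models the package implements, the defaults it ships,
the numerical choices behind the p-values, and what the synthetic data do
and do not establish.

## Disease model and synthetic cohorts

Individuals are formed as random pairs of haplotypes from a pool of
independent bi-allelic sites (no linkage disequilibrium). Site frequencies
follow a truncated power-law spectrum, density ∝ f^(−shape) on
[1/n_haplotypes, 0.5]; shape 1 (the default of `simulate_haplotype_pool`)
is the neutral constant-size 1/f spectrum. Disease status is Bernoulli
under a logistic model

    logit P(y=1 | g) = α + Σ_j β_j g_j

over the designated causal sites, with β_j = min(c·|log10 MAF_j|, β_max),
all of one sign. Defaults: c = 0.4 and β_max = 1.6, so the cap is attained
exactly at MAF 10⁻⁴ (an odds ratio of e^1.6 ≈ 5 for the rarest causal
alleles); causal sites are drawn among sites below a MAF threshold (default
1%) at a configurable fraction. The intercept α is solved by bisection so
that the population prevalence over the realised genotype distribution
matches the configured baseline (default 1%; the underlying studies do not
report a prevalence, and severe early-onset obesity at the BMI-SDS > 3
level is of this order). Cases and controls are collected by rejection
sampling until the designed counts (defaults 1,811 targeted-sequencing
cases + 737 exome cases, 1,117 exome controls) are met exactly. The TS/WES
split is carried as labels only; no platform effect is simulated.

Reference frequency panels (13 "internal" + 7 "external", sized like
disease-cohort exome sets and WGS/ESP/1000G continental panels
respectively) are binomial resamples of the pool frequencies. Because a
site segregating in the pool is essentially never absent from all 20
realistically-sized panels by sampling alone, cohort-private variation is
modelled directly: each site with pool MAF < 0.5% is, with probability 5%,
private to the study cohort and absent from every panel. These are the
sites that come out *novel* downstream, mirroring how never-before-seen
variants actually arise in a cohort.

Planted QC failures (contamination, low depth, discordance, missingness,
non-European ancestry, relatedness) are placed on disjoint samples at
magnitudes far beyond the exclusion thresholds, and recorded in a truth
table, so exclusion-recovery tests are exact rather than statistical.

What the generator does **not** emulate: linkage disequilibrium (an
optional feature of real haplotypes that matters little for burden tests of
ultra-rare variants but shapes SKAT kernels for common ones), sequencing
error, platform batch effects, population substructure within Europeans,
and parent-of-origin effects (relevant to imprinted genes such as GNAS but
out of scope). Passing tests on synthetic cohorts therefore establish the
statistical machinery, not robustness to those artefacts.

## Filtering cascade

Functional consequences are the fixed set {essential splice site, stop
gained, stop lost, complex indel, frameshift coding, non synonymous coding,
within mature miRNA, partial codon}. For genes with a configured
clinically relevant transcript (the known human obesity genes) only that
transcript's consequence governs; otherwise the most severe consequence on
any transcript governs, under the shipped severity ranking (essential
splice site > stop gained > stop lost > frameshift coding > complex indel >
non synonymous coding > partial codon > within mature miRNA > synonymous >
other). The ranking and the tie behaviour (unknown terms rank last) are
data, overridable per call; no claim is made that this is the only
defensible order.

Rarity: *excluded* if pooled allele-count MAF across the 13 internal panels
exceeds 1%, or any single internal panel exceeds 10%, or any external panel
exceeds 1% (all strict); *novel* if unobserved in all 20 panels; *rare*
otherwise. Pooling by summed allele counts is the default because that is
how jointly-called cohorts are summarised; a mean-of-panel-MAFs variant is
available behind a flag. Deleteriousness uses the accepted label sets SIFT
"deleterious", PolyPhen "probably damaging"/"damaging", Condel
"deleterious"; absent or other labels (e.g. "possibly damaging") count as
not deleterious. The clinical triage retains novel functional variants and
rare functional variants with ClinVar Pathogenic/Likely pathogenic status.

## Sample QC

Stages run in a fixed order — contamination (FREEMIX ≥ 0.03 or the
skewed-hets flag), depth (below mean − 3 SD of the stage input),
concordance (< 90%, absent values pass), missingness (> 50%), ancestry,
relatedness — with counts logged per stage. Thresholds with no published
value are package defaults, configurable: FREEMIX 0.03 (a common
contamination cut-off), IBD π̂ 0.1875 (midpoint of the second/third-degree
expectations), ancestry 6 robust SDs (median ± 6·MAD·1.4826 on PC1/PC2
around the labelled European reference centroid). Reported non-European
ancestry excludes a sample regardless of genetics. Relatedness pruning
removes one individual at a time from the π̂-graph: highest degree first,
ties broken by group (diseased controls removed first, then non-diseased
controls, then cases), then lower mean depth, then sample id (logged).
Degenerate inputs: zero depth variance excludes nobody (warning logged).

## Association engine

The null model is a logistic regression of status on covariates
(intercept-only by default) fitted by maximum likelihood via statsmodels.
Missing dosages are mean-imputed for test statistics. MAF-based weights are
the Beta(1, 25) density evaluated at the combined-sample MAF (folded).

For the score family Q_ρ (see README), per-ρ p-values are tail
probabilities of Σ λ_k χ²₁ with λ_k the eigenvalues of
R_ρ^{1/2} (Z₁'Z₁) R_ρ^{1/2}, where Z₁ = V^{1/2}(I − X(X'VX)⁻¹X'V) G W and
R_ρ the compound-symmetry correlation. Tail probabilities use Imhof's
characteristic-function inversion, evaluated by panel-wise Gauss–Legendre
quadrature with panels sized to the fastest oscillation and a finite upper
limit chosen from the integrand envelope and the oscillation-cancellation
bound; the Liu–Tang–Zhang moment-matched chi-square is the fallback and the
vectorised path. Accuracy was checked against 10⁶-draw simulation (tests).
P-values are floored at machine precision.

The optimal test decomposes Q_ρ = (1−ρ)·κ + τ(ρ)·η₀ with η₀ ~ χ²₁
independent of the mixture part of κ, and computes
P(min_ρ p_ρ ≤ observed) by integrating, over η₀, the probability that every
Q_ρ stays below its min-p quantile. Numerical choices that matter:

* min-p quantiles per ρ come from the moment-matched surrogate in the bulk
  and are refined by bisecting the Imhof tail when the min-p is below 0.1 —
  the surrogate's lighter tail otherwise biases extreme quantiles low and
  the combined test conservative;
* the η₀ integral uses the substitution η₀ = s² (half-normal s) before
  Gauss–Legendre quadrature; integrating the χ²₁ density directly loses
  several digits to the x^{−1/2} singularity at zero, exactly in the tail
  that decides significance (this was verified against Monte-Carlo
  evaluation of the same integral);
* the remainder (cross) term of κ enters through the variance rescaling of
  the mixture law, and ρ = 1 is capped at 0.999 inside the integration so
  the burden constraint acts as a sharp cut on η₀;
* the combined p is clamped to [min_ρ p_ρ, 8·min_ρ p_ρ] (the Bonferroni
  bound over the grid) — the construction can never beat its best single ρ.

A gene with no alternate alleles yields a flagged no-test result, not an
exception. Single-variant genes degenerate to the common single-ρ test.

Allele-count 2×2 tables use per-sample margins (2 × n_samples) by default;
a per-variant-call margin variant exists behind a flag. Published
gene-level adjusted odds ratios of this study design (13.629 and 14.505 for
the two zero-control-cell rows) are reproduced to ~0.03% under the
per-sample convention — (15.5·2234.5)/(5081.5·0.5) = 13.632 — and not under
the per-variant one; the residual reflects rounding in the publicly
reported allele counts. The Haldane–Anscombe 0.5 adjustment is applied to every cell
whenever any cell is zero; confidence intervals use the log-OR normal
approximation on the possibly-adjusted table. Fisher's exact test (two-sided
by minimum-likelihood summation) and the Pearson chi-squared test
(1 df, no continuity correction by default) come from scipy; the test-suite
re-derives Fisher from exhaustive hypergeometric enumeration.

## Tiered analysis and multiplicity

Units are 119 genes plus 6 tiers (sizes 6/26/51/5/7/24; the distributed
tier table is a skeleton with placeholder symbols because the published
gene identities live in inaccessible supplementary material — the pipeline
needs the structure, user gene lists supply identity). Tier tests pool all
variants of the tier's genes into one unit, and an all-genes-combined unit
is always added. Eight scenarios = {rare, novel} × {synonymous, functional,
functional with ≥1 deleterious call, functional with all three}; the
synonymous stratum is the negative control. Significance accounting: two
primary tests per unit over 125 units (threshold 0.05/250 = 2×10⁻⁴) and
twelve once the ten secondary tests are included (0.05/1500 = 3.3×10⁻⁵).

## Power simulation

Per replicate: a random 2 kb subregion is drawn from a 200 kb pool of
10,000 haplotypes; 30% (configurable) of its MAF < 1% sites are designated
causal with the capped effect model; a cohort of 2,548 cases and 1,117
controls is rejection-sampled at 1% prevalence; the weighted burden test
runs; power is the fraction of 500 replicates with p < 2×10⁻⁴, with
binomial Monte-Carlo standard error. Subregions with no eligible site are
redrawn and counted. An optional `test_maf_threshold` restricts the
*tested* variant set by sample MAF: when causal effects sit among very rare
sites, narrowing the tested set toward that frequency removes dilution by
non-causal commoner variants and raises power (the analysis lever behind
testing "rare" and "novel" strata rather than all variants; note that
narrowing the *causal-designation* threshold instead shrinks the causal set
and lowers power — the two thresholds act in opposite directions).

The default power pool emulates the documented character of the calibrated
European coalescent haplotype panels used for such power studies: ~1
segregating site per 52 bp and a strongly rare-shifted spectrum (density ∝
f^{−1.5}, ~90% of sites below 1% MAF), reflecting post-bottleneck
expansion. This choice is load-bearing: under a flat 1/f spectrum,
intermediate-frequency sites (19% of sites above 10% MAF) dominate the
weighted-burden variance and power at this design drops to ~4–5%, although
the test itself is tail-calibrated (checked by permutation at α = 2×10⁻⁴).
With the rare-shifted pool the estimate is ~20%. Because the pool is a
synthetic stand-in and not the original haplotype data, the power figure is
approximate by construction; the package treats ±10 percentage points as
its fidelity band.

## Problem sizes used by the test-suite

Calibration suites run at reduced scale chosen to make the statistical
assertions sharp but cheap: type-I error on 2,000 null cohorts of 400
samples over a 2 kb region; permutation oracles at 10⁵ permutations on
100-sample fixtures; Fisher enumeration over margins ≤ 30; the full-scale
power run uses the study's own 3,665-sample, 500-replicate configuration.

## Known limitations

* No LD, no covariates in the shipped pipeline runs (the engine accepts
  them), no platform/batch structure.
* SKAT-O small-sample moment corrections beyond the variance rescaling are
  not implemented; with n ≲ 400 and ultra-rare variants the combined test
  is conservative in the far tail (measured, not hidden), as asymptotic
  kernel tests generally are for binary traits at that scale.
* The eight-scenario analysis treats scenarios as given strata; no
  cross-scenario dependence modelling.
* Tier identity is structural (placeholder symbols) unless user gene lists
  are supplied.
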