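# Methods

## Model and test

The package tests whether phenotypic similarity between samples
increases with their genetic similarity, allowing the genetic effect to
differ between subgroups (here: males and females). The statistic is

    U = 2 Σ_{i<j} w_ij S_ij,   w_ij = k_ij f(G_i, G_j),
    k_ij = 1 − |x_i − x_j|,

with x the heterogeneity code in [0, 1] (binary gender in every
exercised analysis: 0 = male, 1 = female). Self-pairs are excluded by
the classical U-statistic convention; under the residual cross-product
construction of S they would only add a data-independent offset, and an
`include_diagonal` flag exists for sensitivity analysis.

**Phenotypic similarity.** S_ij = r_i r_j, where r are the residuals of
the transformed phenotype regressed on an intercept plus covariates,
standardized to unit variance. The default transform is the rank-based
inverse normal (Blom offset 3/8, ties averaged), chosen because the
ordinal cigarettes-per-day category score follows no standard
distribution; `standardize` and `identity` are exposed. The covariate
set of the standard analysis is gender, race dummies, site dummies and
the top four genotype principal components; both columns of every scan
(with and without the gender weight) share one residualization so the
contrast isolates the background kernel.

**Genetic similarity.** The cross-product kernel of standardized
dosages, f_ij = (1/M′) Σ_l z_il z_jl with z = (g − 2p)/√(2p(1−p)), p
the counted-allele (minor) frequency. Monomorphic markers contribute
nothing and are excluded from the divisor M′. Standardization makes
rare and common alleles contribute comparably, and dividing by marker
count keeps U magnitudes comparable across genes of different sizes;
`maf_centered` and `raw` variants are exposed since the scaling choice
is not dictated by the statistic itself.

## Null distribution

With S a residual cross-product, U = r′Wr exactly (W the weight matrix
with zeroed diagonal). Treating the standardized residuals as
approximately i.i.d. standard normal, U is distributed as Σ_h λ_h
χ²_{1,h} with λ the eigenvalues of W. The right-tail probability is
computed by numerical inversion of the characteristic function
(Imhof's integral, evaluated with adaptive quadrature to an upper
limit of 2000/√Σλ²) — exposed under the conventional name `davies` —
falling back to the Liu–Tang–Zhang four-moment match whenever the
quadrature is unreliable (estimated error above max(1e-6, 10% of p),
p ≤ 1e-10, or a non-finite result). The moment match handles
negative-skew spectra by negating the form. Analytic p-values are
floored at 1e-16. Eigenvalues are computed per connected component of
the sparsity graph of W: with a binary-gender kernel W is exactly
block-diagonal, and the per-block decomposition is both faster and
identical to the dense path (tested).

The approximation is validated three ways rather than assumed: a
Monte-Carlo quadratic-form oracle (agreement within ±0.02 at n = 30),
a label-permutation test (|Δlog10 p| < 0.3 against 10,000 permutations
for moderate p at N = 200), and a 2,000-replicate null calibration
(empirical size at α = 0.05 inside the binomial 95% band at N = 500;
measured ≈ 0.052 pooled over 9,500 replicates). The permutation test
permutes residual labels against the fixed weight matrix —
`p = (1 + #{U_perm ≥ U_obs})/(1 + n_perm)` — with optional exhaustive
enumeration for N ≤ 9; permuting within gender strata is available
since gender also enters the weights. Covariate-projection-adjusted
eigenvalues (of PWP) were evaluated and found numerically
indistinguishable from the plain spectrum at the exercised design
sizes (≤ 6 covariate columns in N ≥ 200), so the simpler spectrum is
used.

## Quality control

Order: marker call rate → individual missingness → Hardy-Weinberg in
controls → (optional) relatedness → mean imputation. Boundaries follow
the complementary reading of the two filter rules: markers with call
fraction strictly below 0.90 are removed, individuals with missing
fraction strictly above 0.10 are removed (so exactly 10% missing
survives). The HWE screen uses the exact conditional test (probability
mass of heterozygote counts no more likely than observed, given allele
counts, computed via log-gamma; an asymptotic χ² variant is exposed) at
threshold 1e-4 — a common GWAS convention, configurable — among
controls defined by default as the lowest CPD category. Missing calls
are imputed with the marker's mean observed dosage, which preserves
each marker's observed mean exactly. The relatedness screen is a
deliberate simplification labelled as such: pairwise hard-call
concordance over ≥ 200 shared markers, removing the higher-missingness
member of any pair above the threshold; it detects duplicates, not
kinship, and is off by default.

## Stratified effect estimation

Because the U test yields significance but no effect size, per-SNP
effects are estimated with a zero-inflated Poisson model: logit π = Zγ
for the structural zero, log λ = Xβ for the count component, applied
with the ordinal CPD category score (0–3) as the count response — an
interpretation, documented as such, since a 0–3 score is not a true
count. The likelihood is maximized by L-BFGS with analytic gradients
from three starts (Poisson-GLM, zero-heavy, randomized); standard
errors come from the inverse observed information (central finite
differences of the analytic score) and inference is two-sided Wald,
matching how single coefficients are typically quoted. The zero model
defaults to intercept-only. Stratified fits exclude gender from the
design (it is the stratifier; aliases are rejected) and skip strata
below 50 samples. Parameter recovery on correctly specified data:
|bias| ≈ 0.001 for a true dosage coefficient of −0.18 at n = 2,000
over 200 replicates, with the statsmodels ZIP implementation as an
independent cross-check in the tests.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors (composite LD,
no phasing); D′ uses two-locus haplotype frequencies estimated by EM
from the 3×3 genotype table (phase ambiguous only in double
heterozygotes; convergence tolerance 1e-10, cap 1,000 iterations).
"Complete LD" is operationalized as connected components of the
r² ≥ 0.999 graph, singletons omitted — the metric and threshold are a
package choice, since "complete LD" has no universal operational
definition.

## Synthetic cohorts

The generator's defaults are the emulated study conditions: 2,717
samples, 46.82% male, ordinal CPD marginals 49.80/29.04/9.24/11.92%,
per-gender category distributions matching the observed male shift
toward higher categories, three study sites (33/46/20%) and a 70/30
Caucasian/African-American split, age ~ N(38.7, 10²) truncated to
[18, 80].

Genotypes: per gene, two latent haplotypes from a one-factor Gaussian
copula with exchangeable correlation ρ (default 0.5), thresholded at
the MAF quantile (MAF ~ U(0.05, 0.5) per SNP) and summed — HWE holds
by construction and MAF is controlled exactly in expectation. Genes
occupy disjoint 2-Mb windows (500-bp SNP spacing) cycling through
chromosomes 1–22. Options inject MCAR missingness, exact duplicate
columns (complete-LD groups), and Hardy-Weinberg violations drawn from
an inbreeding model with F = 0.5 at common frequencies (MAF ≥ 0.2),
where the heterozygote deficit is observable at fixture sample sizes.

Phenotype: liability = covariate effects (race 0.2, site 0/−0.3/+0.1,
age 0 by default) + Σ causal dosage × (β_male or β_female, per allele
copy) + N(0, 1) noise; CPD categories are assigned by gender-specific
thresholds at Gaussian quantiles of the within-gender liability
moments, so realized category frequencies hit the per-gender targets
up to Monte-Carlo error. Implementing the gender shift through
thresholds rather than a liability main effect keeps heterogeneity of
genetic effects cleanly separable from mean gender differences. Every
causal choice is written to a `truth` record that no pipeline stage
reads.

What the generator does **not** emulate: ancestry structure and
admixture LD (allele frequencies are shared across the population),
recombination-map LD decay (within-gene LD is exchangeable), family
structure, informative missingness, and genotyping batch effects.
Consequently the operating-characteristic studies residualize on
gender/race/site without genotype PCs — PCs computed from a handful of
LD-blocked candidate SNPs would absorb the very gene factors under
test, unlike the genome-wide ancestry PCs a real analysis uses — and
passing them demonstrates calibration and power under clean
stratification-free sampling, not robustness to confounding. The PC
machinery itself is validated separately on a two-population
drifted-frequency simulation (first PC separates the populations,
|r| > 0.9).

## Study sizes and numerical choices

Simulation studies run at: type-I error — 2,000 null replicates,
N = 500; analytic-vs-permutation agreement — 20 fixtures, N = 200,
10,000 permutations, compared where the analytic p lies in [0.01, 0.5]
(where the permutation Monte-Carlo error is small on the log scale);
power under a male-only effect of 0.3 SD per allele — 500 replicates,
N = 1,000, testing the causal locus itself (a gene-level variant with
null SNPs diluting the kernel is exposed via `snps_in_test`); ZIP
recovery — 200 replicates, n = 2,000. These sizes give binomial /
Monte-Carlo error well inside the asserted bands while keeping the
whole validation suite to a few minutes.

Degenerate inputs are errors, not silent results: all-monomorphic
kernels, constant phenotypes, rank-deficient designs, zero-margin
contingency tables, all-zero spectra. Monomorphic SNPs in a
single-locus scan return p = 1 with a `monomorphic` flag. Ties in the
rank transform use average ranks; the duplicate screen breaks ties
toward the later sample; per-unit permutation seeds derive from the
master seed via CRC32 of the unit label (stable across processes).

## Known limitations

* The quadratic-form null treats standardized regression residuals as
  i.i.d. normal; at the exercised sizes the measured size is ≈ 0.052
  at nominal 0.05. The permutation path is exact by construction and
  is the fallback of choice for very small samples.
* The ordinal-score-as-count reading of the ZIP response is an
  interpretation; with no zero category present the model degrades to
  (and warns toward) a plain Poisson.
* Gene membership depends on the annotation snapshot and the ±10-kb
  default flank; SNP counts per gene are therefore not comparable
  across annotation versions.
* The EM for D′ assumes random mating within the sample; composite r²
  does not.
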