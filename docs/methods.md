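# Methods

`diallelgen` implements the quantitative-genetic analysis of a full diallel
cross between two divergent purebred chicken lines — White Leghorn-type
(WW) and a local breed (YY) — and their reciprocal F1 crosses (WY, YW):
relationship-matrix construction, REML variance components, a two-effect
single-SNP GWAS with gene-action classification, cis/trans eQTL mapping,
and heterosis prediction from dominance effects. Because its target design
(about a thousand birds with whole-genome sequence) is not reproducible at
desk scale, the package ships a first-class synthetic generator whose
ground truth serves as the oracle for every downstream stage.

## Genetic model

At a biallelic locus with alternative-allele frequency `p` (and `q = 1-p`),
the genotypic values of the three genotypes are `-a`, `d`, `+a`: `a` is half
the homozygote difference and `d` the dominance deviation of the
heterozygote from the homozygote midpoint. The average allele-substitution
effect is

    alpha = a + (q - p) d,

which is what a purely additive regression on the dosage estimates. When
`a` and `d` have opposite signs, `alpha` can vanish in the pooled
population while both effects remain separately estimable — the reason a
model with an explicit dominance covariate detects loci an additive-only
model misses in a purebred-plus-crossbred population.

### Mixed models

For a trait vector `y` with fixed effects `X b` (genetic group with 4
levels and rack, both reference-coded; collinear columns dropped):

* model A:  `y = X b + u + e`,       `u ~ N(0, G sigma_a^2)`, `e ~ N(0, I sigma_e^2)`
* model AD: `y = X b + u + v + e`,   `v ~ N(0, D sigma_d^2)`

`G` is VanRaden's first genomic relationship matrix: dosages centered by
`2p` per SNP, `G = ZZ' / (2 sum p q)`. `D` is Vitezica's orthogonal
dominance matrix: genotypes coded `(-2p^2, 2pq, -2q^2)`,
`D = MM' / sum (2pq)^2`. With these codings the diagonal of each matrix
averages one under Hardy–Weinberg proportions, and additive and dominance
relationships are orthogonal. A frequently seen shorthand codes the
dominance covariate as the heterozygosity indicator minus `2pq`; that
variant does not have unit diagonal or orthogonality except at `p = 0.5`,
so the full coding is used here. Allele frequencies default to the
analyzed individuals; external frequencies are accepted.

### REML

Variance components maximize the restricted likelihood by
average-information (AI) updates with step halving, an expectation-
maximization fallback when the AI proposal fails, and an active-set
treatment of components pinned at the lower bound `1e-8 * var(y)` (a pinned
component re-enters when its gradient turns inward). Convergence is a
restricted-log-likelihood change below `1e-8`, at most 200 iterations;
non-convergence flags the result instead of raising. Standard errors come
from the inverse AI matrix at the optimum; an AI condition number above
`1e8` flags weak identifiability (e.g. `G = I`, where `sigma_a^2` and
`sigma_e^2` are confounded). Model AD is additionally started from the
model-A solution, so its reported optimum never falls below model A's
likelihood — the nesting inequality holds numerically on every fit.
`likelihood_profile` evaluates the same restricted likelihood directly on a
grid as a non-iterative oracle for the optimizer.

### GWAS

Scans are two-stage: the background covariance
`V = G sigma_a^2 (+ D sigma_d^2) + I sigma_e^2` is fixed from the null REML
fit and factorized once; each SNP is then tested by generalized least
squares of `y` on `[X, j]` (model A) or `[X, j, k]` (model AD), where `j`
is the 0/1/2 allele count and `k` the 0/1/0 heterozygosity indicator.
Coding `k` as 0/1/2 would duplicate `j` exactly and make the dominance
effect unidentifiable, so the indicator coding — matching the D-matrix
coding — is used. Standard errors come from the GLS information matrix and
p-values from the t distribution with `n - rank(design)` degrees of
freedom. Monomorphic SNPs are flagged `not_testable`; SNPs without a
heterozygote/homozygote contrast have the dominance columns flagged. Model
AD excludes sex chromosomes (Z/W), where a single observed allele makes
additive and dominance effects inseparable in females.

Multiple testing uses q-values: Benjamini–Hochberg, or Storey's method
(default) with the null proportion `pi0` estimated on the lambda grid
0.05–0.95 by a cubic smoother evaluated at the largest lambda, falling back
to plain BH when the estimate is unstable (fewer than 100 tests).
Significance is FDR < 0.01 throughout, applied separately per trait and per
effect type. Gene action is classified from `r = |t_dom / t_add|`:
additive (r <= 0.2), partial dominance (0.2 < r <= 0.8), complete dominance
(0.8 < r <= 1.2), over-dominance (r > 1.2); boundaries fall to the lower
class, and `t_add = 0` maps to over-dominance with an infinite ratio.
Significant SNPs can be thinned by sliding-window LD pruning (window 50
SNPs, step 5, r^2 > 0.2 removes the later SNP), and retained SNPs within
1 Mb on a chromosome merge into one independent region.

### eQTL mapping

Expression (TPM scale, untransformed by default; `log1p` optional) is
regressed per SNP x gene pair on covariates (genetic group, age, any
precomputed latent factors) plus the dosage. The implementation
residualizes both sides against the covariate design once and converts the
residual correlation to a t statistic — algebraically identical to
refitting the full regression per pair. A pair is cis when the SNP lies on
the gene's chromosome within 1 Mb (inclusive) of the TSS (annotated start
respecting strand), trans otherwise; the two sets get separate q-values
because their p-value thresholds at a common FDR differ by orders of
magnitude. Cis and trans pair counts always sum to #SNPs x #genes. A SNP
significant for two or more genes is pleiotropic; more than ten genes marks
a hotspot candidate.

### Heterosis

Observed heterosis per trait is
`H = 100 (mean(WY, YW) - mean(WW, YY)) / mean(WW, YY)` on least-squares
group means adjusted for rack imbalance. Predicted heterosis is the
classical dominance sum: the expected F1 deviation from the mid-parent is
`sum_i d_i y_i^2` with `y_i = p_W,i - p_Y,i` the parental-line frequency
difference; dividing by the trait's phenotypic SD makes the statistic
comparable across traits. Dominance effects are taken from the AD scan
(`beta_hat`), over all SNPs or the FDR-significant subset; parental
frequencies come from the purebred groups only. Pearson correlations
across traits carry the usual t-transform p-value, with an explicit warning
that cumulative traits share records and are not independent observations.

A caveat documented rather than resolved: published group-mean tables for
this design can carry heterosis percentages that are not reproducible from
the printed means under any mid-parent formula (they originate from a
different model's prediction machinery); this package uses the transparent
textbook definition only.

## The synthetic generator

`simcross` emulates the study's statistical structure, not its biology:

* **Line divergence** is Balding–Nichols: ancestral frequency uniform on
  (0.05, 0.95), line frequencies Beta-distributed with mean `p` and
  variance `F p (1-p)`. The default `F = 0.25` represents strongly
  differentiated purebred lines; the source design reports no divergence
  statistic, so this is a package choice, exposed in the config.
* **Mating design**: by default each line has 30 sires and 120 dams drawn
  HWE from the line frequencies; offspring receive one Mendelian allele
  from each parent, and the same sires produce the purebred and crossbred
  progeny of their line — mirroring the real design and creating the
  half/full-sib families the relationship matrices need for informative
  REML at desk-scale n. An unrelated mode (`family_structure=False`)
  draws alleles directly from the line frequencies for exact-HWE
  distributional tests. Group sizes default to the real design
  (210/268/240/286). Reciprocal crosses are identically distributed on
  autosomes; real reciprocal differences are sex-linked/parent-of-origin
  phenomena and out of scope.
* **Phenotypes**: a unit-scale genetic value (sparse QTL plus an optional
  polygenic background of small effects on every non-QTL SNP) is scaled
  per laying stage and combined with a rack effect and Gaussian noise;
  stage counts are rounded and floored at zero, and cumulative traits are
  exact partial sums. Truth variances are recorded in the statistical
  parameterization (`sigma_a^2 = sum 2pq alpha^2`,
  `sigma_d^2 = sum (2pq)^2 d^2`), the scale on which G/D-based REML is
  consistent with the planted effects. `target_sigma_a2`/`target_sigma_d2`
  rescale the effect vectors to hit requested components exactly (the
  additive target solves a quadratic because `alpha` contains `(q-p) d`).
* **Expression**: planted cis eQTLs (causal SNP within 1 Mb of the TSS)
  and trans eQTLs (causal SNP on another chromosome), group and age
  covariate effects, Gaussian noise, floor at zero. Causal SNPs are drawn
  among SNPs with MAF >= 0.1 in the sampled individuals — an eQTL at a
  non-segregating SNP is no signal. Planted effect sizes are at least
  twice the noise SD.

What passing tests on this generator do **not** show about real data: no
linkage disequilibrium beyond family co-inheritance (loci are independent),
no sequencing or genotype-calling error, no age-specific genetic
architectures (stages share one architecture rescaled), no sex chromosomes,
no parent-of-origin effects, and expression noise is Gaussian rather than
count-based.

## Problem sizes and numerical choices

Parameter-recovery suites run 20 replicates at n = 800 individuals and
5,000 SNPs with `sigma_a^2/sigma_p^2 = 0.2`, `sigma_d^2/sigma_p^2 = 0.3`
(fully polygenic architecture, so the fitted model is exactly specified)
and compare medians; single-QTL identities use n = 600–1,600 with one
planted locus; eQTL recovery uses the study's 120 expression samples.
Matrix-formula checks compare against literal double-loop implementations
at 10 x 50. Degenerate inputs are contracts, not crashes: empty QC output,
all-missing SNPs, zero mid-parent means, sub-minimal sample counts and
invalid thresholds raise informative errors; weakly identified or boundary
REML solutions return flagged results.

## Known limitations

* Mean imputation (flagged per cell) stands in for haplotype-based
  imputation when building relationship matrices; it attenuates
  relationships at low call rates.
* The two-stage GWAS fixes variance components from the null fit; with a
  very large single-SNP effect the background components are mildly
  misestimated, slightly conservative for that SNP.
* Storey's `pi0` estimate is unstable below ~100 tests and falls back to
  BH there.
* The group-class confounding filter implements one reading of its rule
  (a genotype class present in both pure lines with <= 5 carriers in
  each); the alternative reading (class observed in only one line) is
  documented but not implemented.
* LD pruning operates on the significant set only, as a thinning step; it
  is not a general-purpose LD toolkit.
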