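# Methods

`grammarqtl` implements a multi-stage genome-wide association workflow for
body-weight (BW) growth traits in a panel of several strongly differentiated
chicken breeds genotyped on a dense SNP chip, together with a synthetic data
generator that reproduces the statistical structure the models assume, so
every stage can be verified against planted ground truth.

## The statistical model

All association stages build on one polygenic linear mixed model per trait:

    y = F beta + G + e,   G ~ N(0, phi sigma2_G),   e ~ N(0, I sigma2_e)

where `y` is body weight (grams) at one week of age, `F` holds the fixed
effects — overall mean, breed (one-hot, reference level dropped), sex, and
birth weight — and `phi` is the genome-wide IBS kinship
`phi_ij = mean_l (2 - |g_il - g_jl|) / 2` over shared non-missing loci.

Raw allele sharing has a large constant baseline (two random birds share
~0.6-0.7 of alleles by chance) that is confounded with the intercept and
carries no relatedness information, so the fit uses the Gower-centred,
trace-normalised kinship plus a small ridge (`1e-6` times the mean
diagonal). Allele-sharing similarity is not guaranteed positive
semi-definite; eigenvalues above `-0.05 * max` are clipped to zero, anything
worse is an error. Variance components are REML estimates: the centred
kinship is eigen-decomposed once and the restricted likelihood is profiled
over the heritability ratio `h2 = sigma2_G / (sigma2_G + sigma2_e)` with a
bounded scalar optimiser (`xatol 1e-8`). When the likelihood is flat in the
ratio (e.g. an identity kinship) the fit returns the boundary
`sigma2_G = 0` with a warning.

### Per-marker tests

Two second-step statistics are implemented:

* **`mmscore` (default for genome scans)** — the variance-weighted score
  test `(x_c' V^-1 e)^2 / (x_c' P x_c)` with `e = y - F beta_hat` and `P`
  the GLS projection that also removes the whitened fixed design from the
  whitened marker. The projection matters: markers share breed structure
  with the design, and omitting it deflates the null by ~5-10%. The
  reported effect is the GLS estimate in grams per allele copy. This
  statistic stays calibrated (lambda ~ 1) under the panel's level of
  structure and is what we recommend.
* **`residual`** — ordinary regression of the GRAMMAR residuals
  `y - F beta_hat - BLUP(G)` on the marker. This is the literal two-step
  reading; it is intrinsically conservative under strong relatedness
  (measured lambda 0.5-0.8 on synthetic panels of this structure) because
  the BLUP absorbs part of any marker-aligned signal. It is retained as a
  config option and is the form used where a raw residual vector is the
  natural input.

Genomic control: `lambda = median(chi2) / 0.4549`; statistics are divided by
lambda only when `lambda > 1` (the correction never inflates significance by
deflating). Scans report both raw and corrected p-values.

Haplotype substitution/diplotype tests and the two-locus epistasis F-test
operate on the same engine: haplotype tests default to the calibrated
engine statistic (passing a raw residual vector selects plain regression);
the epistasis stage regresses GRAMMAR residuals, whose permutation null is
self-calibrating.

### Permutation thresholds

Genome-wide 1% and 5% thresholds per trait are upper quantiles of the
maximum `-log10 p` over scans of residual vectors permuted across
individuals *within breed* (preserving stratification; a global shuffle is
available). The same machinery, on the maximum F, gives the per-target
empirical significance of the epistasis scan (5% significant, 10%
suggestive). The family-wise error of the 5% threshold measures 0.05 on
fresh null panels (see `scripts/acceptance.py`).

### Conditional independence and QTL naming

When several significant markers share a chromosome, the strongest joins
the fixed design as a covariate, the polygenic model is refit, and the rest
are retested; iteration stops when nothing passes the trait's threshold.
Surviving core SNPs within 1 Mb merge into one QTL, named `BW_Q` plus the
chromosome (letters `a, b, ...` in map order when a chromosome holds
several). QTLs are retained when associated with more than one week's BW or
co-localized (1 Mb window) with an imported external association table.
Var% per SNP is `2 p q a^2 / Var(y) * 100` on the trait of its strongest
association.

### Haplotype stage

Blocks grow outward from a core SNP while adjacent pairs have `r^2 > 0.2`,
capped at six members. Phasing is an exact EM over the enumerable haplotype
space (<= 64 haplotypes): individuals' diplotype posteriors under current
frequencies, frequency update, `tol 1e-8`, 10 random restarts plus a
uniform start; tied optima with distinct frequency vectors (the symmetric
double-heterozygote ambiguity) are all reported. Hard maximum-posterior
diplotype calls feed the tests, matching 0/1/2 count coding; haplotypes
need >= 5% frequency in at least one subpopulation to be tested.
Substitution tests are Bonferroni-corrected by the total tested haplotypes
across loci; homozygote (diplotype) contrasts by the number of loci, and
need >= 3 target homozygotes.

### Variance-heterogeneity scan

The trait is adjusted for the fixed effects by OLS, rank inverse-normal
transformed (`z = Phi^-1((r - 0.375)/(n + 0.25))`, average ranks on ties),
squared, and pushed through the full polygenic + scan pipeline. Adjusting
before ranking is deliberate: ranking the raw trait orders birds almost
entirely by breed and destroys the within-group dispersion signal the scan
is after (unadjusted mode is a config flag). A genotype that multiplies the
residual SD shifts the mean of `z^2` and is detected by the ordinary scan
machinery.

### Epistasis scan

For each target SNP the null model regresses residuals on both markers
additively; the full model adds the product of centred codes (one extra
degree of freedom). `F = (RSS0 - RSS1) / (RSS1 / (n - 4))`. Partners within
1 Mb of the target are excluded (LD produces pseudo-interactions), as are
pairs with any occupied two-locus genotype cell under 5 birds — the
interaction term is otherwise driven by a handful of individuals. The scan
shares an orthonormal-basis decomposition across partners so the 2000-fold
permutation x partner grid is a few matrix products.

## The synthetic data generator

The generator emulates the study conditions: 4 subpopulations of ~100 birds
(divergent allele frequencies, distinct LD scales), a dense autosomal + Z
panel (~46K SNPs by default; everything scales down), weekly BW from hatch
to week 15.

* **Divergence** — ancestral frequencies `U(0.05, 0.95)`; per-breed
  frequencies by a Balding-Nichols Beta draw. Defaults
  `fst = (0.05, 0.05, 0.05, 0.15)`: three moderately diverged breeds and
  one clearly distinct, the typical range among indigenous chicken breeds.
  A breed with `fst = 0` shares the ancestral founder pool outright (zero
  divergence means one population).
* **LD and relatedness** — each breed has a pool of 16 founder haplotypes
  with Dirichlet(0.5) contribution weights; individuals' chromosomes are
  founder mosaics with crossovers at `1e-5`/bp between markers spaced 20 kb
  apart. Skewed weights mimic the unequal family contributions of a
  conserved flock: the effective pool (`1 / sum w^2` ~ 6) sets the LD
  baseline, while the weight concentration sets the mean within-breed
  kinship and its spread. That spread is what makes `sigma2_G` identifiable
  at n ~ 400 without simulating a pedigree; at the same time the mean
  baseline is kept low enough that the REML heritability (a statement about
  the kinship-scaled variance) and the within-breed variance fraction (what
  `SimTruth` records) agree to a few points. Z-chromosome females are
  hemizygous (never heterozygous).
* **Phenotypes** — per-breed logistic growth curves (asymptotes 1000-1800 g,
  rate ~0.34/week, inflection ~week 9, the familiar slow/fast indigenous
  breed contrast); sex effect reaching 30 g at week 15 and scaling with the
  curve (dimorphism grows with age); birth-weight carry-over of 1 g/g from
  week 1 on; planted additive QTLs (scalar effects act post-hatch — hatch
  weight is egg provisioning, not the bird's growth genetics, and putting
  genetics into BW0 would leak into the birth-weight covariate); optional
  variance-QTL (per-genotype residual SD multipliers) and epistatic pair
  (product of centred codes). The polygenic term is drawn from the
  simulated genome's own centred IBS kinship — the generative covariance is
  exactly the structure the null model assumes — and scaled, with the
  residual SD, to a common per-week scale (CV 0.12 of the mean curve, floor
  5 g) split by the target h2 (default 0.3, a standard value for chicken
  BW). Every component is recorded; the emitted phenotype is exactly their
  sum (negative weights, essentially impossible under the defaults, are
  clamped by absorbing the deficit into the recorded noise).

**What the generator does not emulate:** explicit pedigrees and parental
genotypes, genotyping error and missingness patterns, selection or
mutation, G x E, genetic correlations below 1 across weeks, W chromosome.
Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed model, not robustness to real-data artefacts
like batch effects or cryptic misgenotyping.

## Quality control

Phenotypes: per breed and week, records beyond `1.5 x IQR` outside the
quartiles are marked (strict inequality — a value exactly at the fence
survives); marked-high records are kept only when the bird is marked high
in at least half the weeks from its first marked week onward
("consistently high through the growth phase" — the fraction is config);
birds losing more than a third of their weekly records are dropped.
Genotypes, in order: samples with call rate < 0.9; SNPs with call rate
< 0.9, MAF < 0.05 (on surviving samples; female Z calls excluded from Z
MAF), or no map position; Z markers heterozygous in any female. The order
is fixed because marker statistics are computed on QC'd samples.

## Diversity statistics

Allele frequency is `mean(code)/2` over non-missing calls; He is
`2p(1-p)`. The HWE exact test conditions on allele totals and sums the
probabilities of heterozygote counts no more likely than observed (checked
against full enumeration for every table with n <= 50). Independent-marker
pruning is greedy by map position: keep a SNP iff `r^2 < 0.2` against every
kept SNP within a 1 Mb window (the ordering is a documented choice; the
rule itself only fixes the threshold). The LD-decay curve averages `r^2` in
1 kb distance bins up to 500 kb; the scale `L_{r2=0.2}` is the linearly
interpolated first downward crossing of 0.2 on the binned means (no curve
fitting; reported as unbounded when the curve never crosses). PCA is the
eigen-decomposition of the double-centred kinship; component signs are
fixed so the largest-magnitude loading is positive. The fraction of markers
in Hardy-Weinberg equilibrium is computed on the independent set by default
(all-marker mode is config). Missing genotypes are mean-imputed only inside
kinship/PCA; all other statistics use pairwise deletion.

## Problem sizes and numerical choices

The verification runs use panels of 400 birds x 2000-5000 markers over 10
chromosomes, 200 permutations, and 10-seed repeats — large enough that
calibration bands (lambda within 0.9-1.1, FWER 0.05 +- 0.03) are sharp, and
a comfortable fit for a single CPU. Tolerances: EM `1e-8` on the
log-likelihood (which is asserted non-decreasing every iteration); REML
`1e-8` on the ratio; two-locus collinearity by rank of the 4-column design;
ties in quantile computations follow numpy's linear interpolation. All
randomness flows from explicit integer seeds; identical seeds give
bit-identical datasets, thresholds, and tiers.

## Known limitations

* The ped/map dialect cannot represent a marker at which only allele2 is
  observed (no allele listing in the map); such markers reload as code 0.
  The bed/bim/fam dialect is exact.
* GRAMMAR-residual effect sizes are attenuated under strong relatedness;
  effect sizes worth reporting should come from the default engine
  statistic.
* The EM phaser enumerates at most 6-SNP blocks by design; it is not a
  genome-wide phaser.
* The conditional-independence loop reuses the trait's permutation
  thresholds as its significance rule; with very many co-significant
  markers on one chromosome it is greedy, not exhaustive.
* Reproducing the published tables requires the study's own genotype and
  phenotype files, which are distributed only as journal supplementary
  sheets; the pipeline accepts them in PLINK + CSV form
  (`data/supplementary/`, see `tests/test_acceptance.py`).
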