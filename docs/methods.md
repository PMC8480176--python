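# Methods

## Problem and model

`dimorphscan` asks whether the genetic control of a quantitative trait
differs between the sexes at individual loci.  The unit of inference is the
allele substitution effect `b` of a SNP — the expected change in trait value
per copy of the counted allele — estimated separately in males and females
by a mixed linear model association (MLMA) scan, and then contrasted between
the sexes.

The per-stratum association model is

    y = mu + x b + u + e,    u ~ N(0, G sigma_u2),   e ~ N(0, I sigma_e2)

where `y` are pre-adjusted phenotypes, `x` the SNP dosages, `G` a genomic
relationship matrix from autosomal SNPs, and `(sigma_u2, sigma_e2)` variance
components estimated once per stratum by REML and held fixed across SNPs.
For a SNP segregating in both sexes the dimorphism statistic is

    z = (b_m - b_f) / sqrt(SE_m^2 + SE_f^2)

with a two-sided standard-normal tail probability.  A SNP is *suggestively*
dimorphic at p <= 1e-5 and *significantly* dimorphic at p <= 1e-8, both
inclusive.  An alternative denominator that also divides the summed squared
errors by `n_m + n_f` is available (`denominator="printed"`) but is not the
default: the default is the form under which the worked examples in the test
suite reproduce their reference values from two-decimal (b, SE) inputs.

Two companion screens run per joined SNP: a contingency test of equal allele
frequency between the sexes (chi-square with continuity correction on the
2x2 allele-count table; Fisher's exact test when any expected cell is below
5 — the screen's test is a package choice, recorded here because the screen
itself does not prescribe one), and a minor-allele concordance flag (do the
sexes share the same minor allele; a frequency of exactly 0.5 counts as
concordant with either).

## Phenotype pre-adjustment

Field-scored type traits carry strong environmental structure, so the scan
consumes adjusted phenotypes rather than raw scores:

1. records with unrecorded dam parity are dropped; parity is recoded to
   classes 1, 2, 3, 4, 5+ ;
2. contemporary groups (herd-by-scoring-date within breed) with fewer than
   five records are removed;
3. scores are standardized to a common variance within classifier-by-year
   groups.  The target variance is the pooled within-group variance
   (weights `n_g - 1`); each group keeps its mean and is rescaled by
   `s_pooled / s_g`.  Groups with under two records or zero variance pass
   through with a warning;
4. the animal model `y = mu + HSD + AM + DP + animal + e`, with the animal
   effect covariance proportional to the GRM, is fitted by REML, and the
   adjusted phenotype is the raw (standardized) score minus the HSD, AM and
   DP fixed-effect solutions.  The intercept and the animal effect are
   deliberately not subtracted, so the genetic signal stays in the adjusted
   value.

The reference level of each factor is its first observed level; any
full-rank constraint gives the same adjusted values because only level
contrasts enter the subtraction.  A pedigree numerator relationship matrix
would normally play the role of the covariance kernel in this step; this
package uses the GRM throughout, since the fixed-effect solutions are what
is consumed downstream and the model class is unchanged.

## Numerical core

A single eigendecomposition `K = U D U'` rotates the mixed model so the
covariance is diagonal.  REML is a bounded 1-D optimization of the profile
restricted likelihood over `log10(lambda)`, `lambda = sigma_u2/sigma_e2`,
on [-8, 8], with the `lambda = 0` boundary evaluated explicitly so a null
heritability is an attainable optimum.  The optimizer is deterministic
(`scipy.optimize.minimize_scalar`, bounded, xatol 1e-8).  The per-SNP scan
solves the 2x2 weighted normal equations of `[1, x]` in the rotated basis,
vectorized over SNPs; missing dosages are mean-imputed per SNP for the
regression algebra only (QC call rates are computed before imputation).
p-values are two-sided normal (Wald) tails; values below 64-bit tail
precision are reported alongside as `log10_p` computed from the stable
log-survival function.

GRM: VanRaden-style standardized form, `G = Z Z'/m` with columns centered
by `2p` and scaled by `sqrt(2p(1-p))`, frequencies taken from the stratum
being analyzed, monomorphic SNPs dropped.  The GRM is autosomal-only; the X
is still scanned against it, with no dosage-compensation scaling.

X chromosome: the pseudoautosomal region (PAR) spans 143,861,798 to
148,823,899 bp, boundary inclusive.  Non-PAR male dosages are hemizygous
and coded homozygous (0 or 2).  A male non-PAR heterozygous call can only
arise in dirty external data; it is set missing, because a dosage of 1
does not identify which allele was actually called.  Simulated males never
produce such calls.

## Synthetic cohorts

The generator emulates a single-breed, field-recorded beef-cattle cohort:
70% males by default, subjective scores around a mean of 8, contemporary
group (40 levels, SD 0.5 trait units), age-in-months class (11 levels, SD
0.25) and dam parity (5 classes, SD 0.15) fixed effects, classifier and
scoring-year labels for the standardization step, and a male-female mean
difference of 0.5.  Genotypes are drawn per SNP under Hardy-Weinberg
equilibrium with MAF uniform on [0.002, 0.5] by default and no linkage
disequilibrium; the per-SNP statistics do not depend on LD, and window
co-occurrence is exercised with constructed fixtures instead.

The polygenic background is `u = Z g`, `g ~ N(0, h2/m I)`, with `Z` the
standardized dosage matrix of the `m` non-causal autosomal SNPs.  Since
`G = Z Z'/m`, this yields `u ~ N(0, h2 G)` exactly — the same law as
drawing through a matrix square root of `G`, without an O(n^3)
factorization.  The residual SD is `sqrt(1 - h2)`, so the trait SD net of
fixed and foreground effects is 1 and causal effect sizes are in phenotype
SD units.  Causal SNPs come in four classes — shared, male-only,
female-only, opposite-sign — with magnitudes `N(0, effect_size_sd^2)`
(default SD 0.3); the class fixes the male/female relationship exactly.

What the generator does **not** emulate: linkage disequilibrium and real
allele-frequency spectra, imputation error, genuinely sex-linked trait
architecture beyond the configured effect classes, non-random missingness,
and pedigree structure.  Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under its own
assumptions, not the biological findings obtainable from real cattle data.

## Calibration experiments and problem sizes

The reference experiments (`dimorphscan.experiments`, driven by the
`analysis/` scripts and `scripts/acceptance.py`) use cohorts of 2,000
animals (1,400 males / 600 females), ~5,000 SNPs over four chromosomes,
h2 = 0.4:

- **Split-half calibration** — 20 opposite-sign causal SNPs are present;
  ten random splits into two halves, each containing half the males and
  half the females, rerun the full per-group association + contrast.  Both
  halves share the sex composition, so the genome-wide minimum contrast p
  estimates the null floor; minima staying at or above 1e-8 support that
  significance threshold.
- **Null calibration** — cohorts whose causal effects are identical in the
  sexes; the contrast p distribution is checked for uniformity (KS) and the
  fraction at the suggestive threshold.
- **Parameter recovery** — REML h2 against the simulated 0.4; a known 0.5
  allele substitution effect at MAF 0.3; detection power for opposite-sign
  effects of 1.0 phenotype SD at n = 2,000 per sex.

Unit and property tests run the same machinery at 50-2,500 samples; the
REML optimum is cross-checked against a dense-algebra grid search, the GLS
scan against direct V-inverse solves and the OLS limit, and all counting
operations (filters, windows, overlaps) against brute-force recounts.
These sizes are the package's choices for fast, well-conditioned test
problems; tolerances follow the sampling variability at each size.

## Windows and overlap

Chromosomes are tiled from base 1 into non-overlapping 1,000-bp windows;
a 1-based position `pos` maps to window `(pos-1) // 1000`.  Whether tiling
starts at base 0 or 1 is a convention (only boundary SNPs differ); the
choice is recorded in the BED output header, and BED rows are converted to
the 0-based half-open convention.  A window is a hit when it contains at
least one SNP at or below the chosen contrast threshold; overlap tables
key windows by (chromosome, index) and attach (breed, trait) tags so
"shared by >= k" queries are a filter on the tag count.

## Reporting conventions

Summary reports count suggestive SNPs inclusively (a significant SNP is
also suggestive, shown "suggestive (significant)" style), report the
percentage of joined SNPs with the same minor allele in both sexes, and the
percentage with allele-frequency divergence at p <= 0.05.  Every reported
number is recomputable from the persisted TSVs, which the test suite
verifies.

## Known limitations

- No LD means windowed results on simulated data are sparser than on real
  sequence data; window logic is therefore validated combinatorially.
- The association model contains only the mean and the candidate SNP, as
  in the adjusted-phenotype design; covariates must be absorbed in the
  pre-adjustment.
- Variance components are not re-estimated per SNP; large-effect SNPs
  inflate `sigma_u2` slightly and the scan is correspondingly conservative
  at them.
- The allele-frequency divergence screen rebuilds allele counts from
  (n, frequency) rounding when only summary data are available.
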