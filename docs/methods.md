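# Methods

`wheatgs` re-implements, as a tested library, the analysis pipeline of a
multi-environment spring-wheat genomic-selection study: multi-environment
BLUP and heritability estimation, seven genomic prediction models compared
by genotype-level repeated cross-validation, and the integration of known
major adaptation genes (FT/Ppd/Rht/Vrn-family KASP assays) as fixed effects
in the kernel prediction model. Because panels of this kind are rarely
deposited, the package ships a synthetic-data generator that emulates the
study's data structure, so every stage is exercised end-to-end by code.

## Phenotype model and variance components

Plot-level records follow the all-random model

    Y_ijk = mu + E_j + R_i(E_j) + G_k + (GE)_jk + eps_ijk,

with environments E_j ~ N(0, s2_env), replicates within environment
R_i(E_j) ~ N(0, s2_r), genotype main effects G_k ~ N(0, s2_g), interaction
(GE)_jk ~ N(0, s2_ge) and residuals eps ~ N(0, s2_e), all independent.
Only the intercept is fixed. Genotype main-effect BLUPs, reported on the
trait scale as mu_hat + g_hat_k, pool the (possibly sparse) multi-
environment data into one phenotype per line and are the response used for
genomic prediction.

Components are estimated by EM-REML on the mixed-model equations.  The
coefficient matrix is assembled once per iteration with the current
variance ratios on its diagonal; the EM updates are the classical ones
(u_i'u_i plus the trace of the corresponding inverse block for each random
term, residual sum of squares over n - 1 for s2_e).  The restricted
log-likelihood is evaluated from the same factorisation via
-2 l_R = (n-1) ln s2_e + sum_i q_i ln(s2_i/s2_e) + ln|A| + y'Py.
Convergence is declared when its relative change drops below 1e-8 (500
iteration cap); every fourth iteration an Aitken-accelerated jump is tried
and kept only if it does not decrease the likelihood; component iterates
are clamped at 1e-10.  Starting values come from method-of-moments
splits of the within-cell and between-genotype variability, which makes the
balanced case converge in a handful of iterations.  On balanced designs the
stationary point coincides with the expected-mean-squares (ANOVA)
estimators; the test suite pins this to 1e-4.

Broad-sense heritability on an entry-mean basis is

    H2 = s2_g / (s2_g + s2_ge/n_envs + s2_e/(n_reps * n_envs)).

LSD and CV% are reported with the conventional across-environment formulas
LSD = t_(1-alpha/2, df) * sqrt(2 s2_e / (n_reps n_envs)) and
CV% = 100 sqrt(s2_e) / mu_hat, with df taken as the within-cell residual
degrees of freedom (records minus genotype-by-environment cells).  These
formulas are a documented convention, not a claim about any particular
software's defaults.

## Prediction models

All seven families share the scikit-learn fit/predict contract; matrix-
input models (GBLUP, RKHS, the fixed+kernel model) follow the precomputed-
kernel convention: `fit` receives the square training block, `predict` the
cross rows K(new, train).

* **GBLUP** — `y = mu + Zg + e`, `g ~ N(0, G s2_g)`, with the VanRaden
  relationship matrix `G = WW'/(2 sum p_j(1-p_j))` built from dosages
  centred by twice the allele frequency.  The variance ratio is estimated
  by spectral REML (eigendecomposition of the training block, scalar
  optimisation of the profiled restricted likelihood over log lambda in
  [-12, 12]).  Held-out genotypes are predicted through their relationship
  rows, which is algebraically identical to ridge regression on centred
  markers at lambda = c * s2_e/s2_g — an identity the tests verify to 1e-6.
  Per-genotype prediction error variance is computed in the eigenbasis,
  ignoring the (small) uncertainty of the GLS intercept.
* **Ridge / LASSO** — penalized regression on internally standardized
  markers, objective (1/2n)RSS + lam*P(b).  The lambda grid is 100
  log-spaced values from lambda_max (the smallest lambda zeroing all LASSO
  coefficients) down four decades; lambda is chosen by seeded 5-fold CV
  inside the training set, minimizing MSE, ties resolved toward heavier
  shrinkage.  Ridge solves the whole path via SVD; LASSO uses cyclic
  coordinate descent with soft thresholding (tolerance 1e-7, numba-
  compiled), warm-started along the path.  KKT (subgradient) conditions are
  asserted along the path in the tests.
* **BRR** — Gibbs sampler with a common normal prior on marker effects and
  scaled-inverse-chi-square priors on (s2_b, s2_e).  Prior scales follow the
  R2-matched rule S_b = var(y) R2 (df0+2)/MSx, S_e = var(y)(1-R2)(df0+2)
  with df0 = 5 and R2 = 0.5; chains default to 8,000 iterations, 2,000
  burn-in, thinning 3.  The sampler runs in the SVD basis of the
  standardized marker matrix: the row-space coefficients have a diagonal
  conditional posterior and are drawn jointly each iteration, and the
  null-space component (which never touches the likelihood) contributes to
  the prior-variance update through a chi-square draw of its squared norm.
  This blocked scan has the identical stationary posterior to a per-marker
  scan and makes full-length chains cheap.  With variances frozen the
  posterior mean provably equals the ridge solution at lam = s2_e/s2_b,
  which the tests check to RMSE < 0.02 at 20k draws.
* **RKHS** — `y = mu + u + e`, `u ~ N(0, K s2_u)` with the Gaussian kernel
  K_ij = exp(-h d_ij), d_ij the squared Euclidean distance between centred
  unit-variance marker profiles divided by the marker count (so h = 0.5,
  the default, is meaningful at any panel size).  Sampling runs in the
  eigenbasis of K with the same prior machinery as BRR (S_u additionally
  scaled by the mean kernel diagonal).  Held-out genotypes are predicted by
  kernel interpolation u_new = K(new,train) K(train,train)^+ u_train, which
  at the posterior mean coincides with the missing-phenotype treatment for
  PSD kernels; with a linear kernel and matched variances the model
  reproduces GBLUP.
* **SVM / RF** — nu-SVR with RBF kernel (C = 10, gamma = 0.001, nu = 0.5)
  on standardized markers, and random-forest regression with 500 trees and
  mtry = floor(p/3), both delegated to scikit-learn.  They satisfy the
  common contract but are excluded from exact-oracle tests.

## Cross-validation

Partitions are made at the genotype level (fold sizes differing by at most
one; 249 genotypes give {50, 50, 50, 50, 49}), uniformly at random without
stratification, repeated (default 50 times, 5 folds).  The fold of a
genotype is a function of its identifier rank and the repeat's child seed
`(seed, repeat)`, so consistently relabelled inputs keep their fold
membership and any single repeat can be regenerated in isolation.
Predictive ability is the Pearson correlation between observed values
(BLUPs, or single-environment values) and predictions for held-out
genotypes, computed per fold and summarized by the median; constant
prediction vectors yield a flagged missing value rather than r = 0.  The
engine records the exact phenotype indices each fit consumed, making the
no-leakage contract a machine-checkable assertion rather than a promise.
Hyperparameter tuning (the penalized models' lambda) always nests inside
the training fold.  The cross-environment scheme fixes folds once per
training source and evaluates the held-out lines against every target
environment, so the cells of a row are paired.

## Major-gene fixed effects

Promotion builds X = [1 | promoted gene dosages (+ optional structure
components)], mean-imputes missing calls (heterozygotes are 1 on the 0/1/2
scale), drops perfectly collinear columns with a log entry, removes the
panel SNPs tagging the promoted genes from the random universe, and
recomputes the kernel from the reduced panel.  The model
`y = X beta + u + e` is sampled with a flat prior on beta (joint GLS draw)
and the RKHS machinery for u.  Four strategies are compared on one shared
fold plan: the baseline panel, KASP calls appended as random markers, all
16 genes as fixed effects, and the trait-specific subset of genes whose
individual paired median CV improvement is strictly positive.  The
selection threshold (median paired delta > 0) is a configurable convention.
Screening may run on the evaluation folds (as the selected-subset
comparison is usually reported) or on fresh folds; the test suite
quantifies the optimism difference between the two on null traits.

## Synthetic data generator

The generator emulates the study's structure, not any particular panel:

* ~250 genotypes, ~5,000 SNPs assigned uniformly to 21 chromosomes with
  uniform Mb positions (default chromosome span 700 Mb);
* subpopulation structure via a Balding-Nichols-style hierarchical model:
  ancestral frequencies Uniform(0.05, 0.95), subpopulation frequencies
  Beta-distributed around them with dispersion set by a single F_ST-like
  divergence knob (default 0.1, 3 subpopulations);
* missing genotype calls injected completely at random (default 2%);
* 16 major-gene loci (FT/Ppd/Rht/Vrn-style) realized by default as columns
  inside the panel, so the promotion step's "remove the tagged SNP"
  bookkeeping is genuinely exercised; effects are per-allele and
  trait-specific;
* phenotypes from the all-random model above with variance-component
  defaults s2_g = 4, s2_ge = 2, s2_e = 2, s2_r = 0.25 on the trait scale,
  3 environments x 2 replicates, and sparse testing: early environments
  receive a random ~70% of lines, late environments the full panel.
  Per-trait environment subsets are supported because real designs measure
  different traits in different year sets.

Polygenic effects are drawn i.i.d. normal and rescaled so the in-sample
polygenic variance equals s2_g exactly, making realized heritability
reproducible rather than random; major-gene contributions add on top of
s2_g and are recorded in the simulation truth (their variance follows the
2p(1-p)a^2 law, which the tests verify).  When a target heritability is
requested, the residual variance is solved from the plug-in H2 formula.
G-by-E deviations are i.i.d. per genotype-environment cell, exactly as the
phenotype model assumes.

What the generator does **not** emulate: linkage-disequilibrium decay along
chromosomes, pedigree/family relatedness beyond subpopulation membership,
selection, array intensity artefacts, or non-random missingness.  Passing
tests therefore demonstrate correctness of the algorithms and the
qualitative behaviour of the methods under the stated model, not
reproduction of any real panel's accuracy values.

One consequence of the missing family structure is worth stating: on a
*completely* unstructured panel the genomic relationships fluctuate only
weakly, kernel predictions are comparatively weak, and adding five
flat-prior ordination covariates measurably hurts out-of-sample accuracy
(~0.02-0.04 median ability at n = 250; verified against a closed-form GLS
oracle).  On panels with genuine subpopulation structure — the regime real
germplasm occupies — the same covariates change the median ability by well
under 0.01, reproducing the published null result for structure
corrections.  The structure-covariate acceptance check therefore runs on
structured panels, and the acceptance script also reports the unstructured
delta for contrast.

## Problem sizes and numerical choices

The repeated-CV studies in the acceptance layer run at reduced but
structurally faithful sizes chosen as this package's own defaults: panels
of 120-250 genotypes with 300-1,000 markers, 5-fold CV with 2-5 repeats,
and Gibbs chains of 600 iterations (150 burn-in) for the strategy
screening, against 8,000/2,000 for the single-fit oracle checks.  Variance
component recovery uses the full 250-genotype, 3-environment, 2-replicate
design over 50 seeds.  Degenerate inputs are handled explicitly: zero
variance markers are excluded from kernel distances with a warning,
monomorphic panels raise on GRM construction, constant traits flag their
ANOVA p-value as undefined, and constant prediction vectors flag the fold
rather than contribute r = 0.

## Known limitations

* Single-trait models only; no multi-trait or reaction-norm covariance
  structures, and no LD-aware simulation.
* The EM-REML fit builds dense mixed-model equations; it is comfortable to
  a few hundred genotypes and a handful of environments, not to very large
  trials.
* PEV from GBLUP ignores intercept uncertainty.
* The Gibbs samplers use one joint coefficient block; posterior *means*
  match per-coordinate scans exactly in distribution, but users comparing
  chain autocorrelation traces against other software should expect
  different mixing profiles.
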