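# Methods

## The problem and the procedure

Genomic prediction infers a quantitative phenotype from genome-wide SNP
dosages (0/1/2 counts of one allele at biallelic markers). With far more
markers than individuals (p >> n), models trained on all SNPs can overfit
and waste signal on irrelevant markers. `ifsgp` implements incremental
feature selection (IFS): rank all SNPs by the strength of their
single-marker association with the phenotype, train prediction models on
growing prefixes of the ranking, and pick the prefix length that maximizes
a smoothed accuracy curve.

The full protocol is:

1. **Outer split.** The data are split once, 80 %/20 %, into a selection
   partition Φ and a hold-out partition Ψ. Ψ is untouched until the final
   prediction. |Φ| is round-half-up(0.8 n); the rounding rule is a package
   convention fixed for reproducibility.
2. **Repeated cross-validation on Φ.** Individuals are dealt into 5 folds
   (sizes differing by at most 1); the whole 5-fold pass is repeated 10
   times with freshly shuffled individuals.
3. **Leakage-safe ranking.** Within every (repetition, fold), a GWAS is
   run on the 80 % training individuals *only* and the SNPs are ranked by
   p-value. Ranking on data that includes the test fold would inflate the
   apparent accuracy, so the scan is repeated for every training set. The
   ranking does not depend on the prefix length, so it is computed once
   per (repetition, fold) and reused across all schedule steps.
4. **Sweep.** For every SNP count s in the step schedule, a random forest
   is trained on the top-s ranked SNPs of that fold's ranking and predicts
   the held-out fold. Per repetition, out-of-fold predictions from all 5
   folds are pooled and one R² against the observed phenotypes is computed
   per s (a per-fold-averaged alternative is available via `pooled=False`).
   The curve stores the mean and the standard error of the mean
   (SD/√n_reps, ddof=1) over the repetition values.
5. **Smoothing and selection.** The mean-R² curve is smoothed with
   Friedman's variable-span super smoother and the argmax of the smoothed
   values gives the optimal SNP count. Ties go to the smaller count
   (parsimony). If the argmax is the final point, the method recommends
   using all SNPs.
6. **Hold-out evaluation.** A fresh GWAS on all of Φ fixes the final
   ranking (most data without touching Ψ); one forest is trained on Φ with
   the selected top SNPs and one with all SNPs, and both are scored on Ψ.
   The difference is the *advantage* of feature selection. When the
   optimum is the full SNP set the selected-model entry is reported as
   absent — it would duplicate the baseline.

No SNPs are ever discarded from the ranking (markers that hurt accuracy
when first added can still contribute to the final model, e.g. through
interactions), and no LD pruning is performed — pruning correlated
markers can hurt prediction. No MAF/HWE quality control is applied beyond
removing missing data: individuals with missing phenotypes are dropped
first, then SNPs with any remaining missing dosage.

## Association scan

Each SNP is tested with simple linear regression, phenotype ~ intercept +
dosage, on the training individuals; the p-value is the two-sided Wald
t-test on the slope with n−2 degrees of freedom. This is the minimal
quantitative-trait association test without covariates or
population-structure correction. Monomorphic SNPs get p = 1 and slope 0; a
constant phenotype yields all p = 1 with a warning. p-values are used
purely as an ordering — no multiple-testing correction is ever applied.
Ties are broken by (chromosome, position), with chromosomes compared as
strings, so rankings are reproducible across platforms. The scan is
invariant to flipping the dosage orientation (p-values identical, slope
signs flip).

## Random forest

Bagged regression forest with the standard genomic-prediction settings:
500 trees, mtry = floor(√p_used) candidate features per split, minimal
node size 5, bootstrap resampling with replacement per tree, prediction =
mean over trees. mtry is recomputed at every sweep step from the number of
SNPs actually supplied, since the model's input dimension changes every
step. "Minimal node size 5" follows the convention that a node with at
most 5 training samples becomes terminal; in the scikit-learn engine this
maps to `min_samples_split = min_node_size + 1`.

Results are bit-deterministic for a fixed seed and thread count; across
thread counts only statistical equivalence should be expected. Every
randomized stage (split, fold shuffles, per-fit forest seeds) draws a
named child seed from the master seed through `numpy.random.SeedSequence`,
so a whole run is reproducible from one integer.

## Accuracy metric

R² = 1 − SS_res/SS_tot on held-out (observed, predicted) pairs. This
definition can be negative — predictions worse than the observed mean —
and negative values propagate unclipped through the curve, the smoother
and the report. Pearson's r is available as an alternative reporting
metric (`metric="r"`); note R² equals r² only for unconstrained linear
fits, not for forest predictions.

## Step schedule

Counts advance by regime: step 1 until 100, 5 until 500, 10 until 1000,
then 50 until 5 000, 100 until 10 000, 500 until 50 000, 1 000 until
100 000 and 5 000 thereafter, always appending p so the sweep ends at the
full model. The regimes beyond 1000 are a package default chosen to keep
roughly geometric spacing; any regime list can be supplied (CLI
`--schedule bound:step,...`). A documented coarse variant
(`COARSE_BREAKPOINTS`, ~25 points up to a few thousand SNPs) trades curve
resolution for speed and is what the test profile and the bundled
acceptance script use.

## Super smoother

The variable-span smoother runs running local-linear fits at three spans —
0.05 (tweeter), 0.2 (midrange), 0.5 (woofer) of the series length — over
symmetric nearest-neighbour windows truncated at the boundaries, which
makes the smoother exact on affine data. For each span the exact
leave-one-out (deleted) residual is computed from the hat diagonal; the
absolute residuals are themselves smoothed at the midrange span to
estimate each span's local cross-validated error. Each point takes the
span with the smallest estimated error; a `bass` parameter in [0, 10]
(default 0) biases the choice toward the woofer by
span + (0.5 − span)·r^(10−bass) with r the residual ratio. The chosen span
sequence is smoothed at the midrange span, the final value at each point
is interpolated between the two bracketing span smooths, and a last
tweeter-span pass removes interpolation artefacts.

Inputs shorter than 5 points fall back to a single running-line smooth
whose window is chosen by leave-one-out absolute error; one-point inputs
pass through. Window sizes are never below 2; a guard of 1e−10 on
1 − h_ii protects the deleted residual against degenerate windows.

The accuracy curve is smoothed against log10(SNP count) by default
(`smooth_x="linear"` is available): the schedule is geometrically spaced
at the high end, and smoothing on the log axis weights the low-count
region where the optimum usually lives. The implementation tracks R's
`stats::supsmu` closely (correlation > 0.99 on a noisy-sine benchmark);
small boundary differences remain because truncation details are not
specified uniquely by the algorithm.

## Synthetic data generator

The generator produces the study conditions for every test: per-SNP
dosages drawn Binomial(2, f) with f ~ Uniform(0.05, 0.5), independent
across markers; a chosen number of causal SNPs with Gaussian (or Laplace)
effects on centred dosages; optional pairwise epistatic terms as products
of centred dosages (random forests are motivated precisely by such
interactions); Gaussian environmental noise. The genetic score is rescaled
so its variance is h² and the noise variance 1 − h², targeting the
heritability in expectation; the realized ratio var(score)/var(phenotype)
is recorded, not assumed. The stored effect sizes are the rescaled ones,
so the additive score is exactly reconstructable from the truth sidecar.
Missing dosages can be injected at a configurable rate. An optional block
mode thresholds AR(1) latent Gaussians to create LD-like correlation
between neighbouring markers for ranking experiments.

What the generator does **not** emulate: coalescent haplotype structure,
realistic LD decay, population stratification or kinship, genotyping
error, non-Gaussian trait distributions. Tests passing on this generator
therefore demonstrate correctness of the machinery and recoverability of
sparse additive architectures, not performance on any particular real
population.

Default problem sizes used by the test profile and acceptance runs —
chosen as the smallest sizes at which a 20-SNP architecture at h² = 0.7 is
reliably separable from noise — are n = 400 individuals × p = 2000 SNPs
(selection runs), n = 200 × 300 for null-trait checks, with 100 trees,
5 folds × 3 repetitions and the coarse schedule. The full profile (500
trees, 10 repetitions, dense schedule) is the default for real use.

## Known limitations

- The Ψ evaluation uses a single seeded 80/20 split; with small cohorts
  the hold-out R² carries substantial split-to-split variance. Repeated
  outer splits were deliberately not averaged into one report, because the
  selected SNP count differs per split and an averaged report would blur
  what was actually selected.
- Binary traits (logistic association) and covariate/mixed-model
  adjustment are out of scope; the scan assumes an unstructured sample.
- When the accuracy curve rises monotonically toward the full-model
  asymptote, the smoothed maximum is conservative and can suggest more
  SNPs than necessary; manual inspection of the curve may justify a
  smaller set.
- PLINK 2 formats (.pgen), VCF import and dosage formats are not read;
  inputs are PLINK 1.x binary triplets or the built-in generator.
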