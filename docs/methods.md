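# Methods

This note documents the models implemented in `metac`, the parameters that
matter, the design choices made where the procedure was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Signature construction

Markers are selected one subtype vs. the rest on log2-scale expression. For
each gene, a two-sided Mann-Whitney U test compares the subtype's samples
against all others, and the median fold change is computed on the log2 scale
as FC = 2^(median_subtype − median_rest). Genes with FC ≥ `min_fc` (default
1.5, i.e. Δlog2 ≥ log2 1.5 — up-regulation only) are ranked by ascending p
and truncated to `top_n` (default 60) per subtype. A gene qualifying for two
subtypes goes to the one with the smaller p (ties: larger FC). Marker
selection is invariant to sample order and to adding a constant to all log2
values (both the rank test and the median difference are shift-invariant).

The cross-cohort consistency filter retains a marker iff, in every supplied
cohort, its Spearman correlation with the mean expression of its own
subtype's marker set (i) strictly exceeds its correlation with either other
subtype's set mean and (ii) is at least `min_own_corr` (default 0.3). The
floor exists because a gene carrying no signal has all three correlations
near zero and would win the three-way comparison by chance about a third of
the time; requiring a positive own-set correlation makes the filter decisive.
This filter is this package's concrete operationalization of a
PCA-consistency step whose original criterion is not fully specified; it
should not be expected to reproduce any particular published gene list.

The reference (signature) matrix takes, per subtype, the
`replicates_per_subtype` (default 3) samples nearest their subtype centroid
in Euclidean distance over the signature genes, and averages them per gene.
Centroid proximity was chosen because it is deterministic and order-free;
any reasonable "representative sample" rule would serve.

## Fraction deconvolution

Each bulk profile *m* (linear scale; log2 inputs are unlogged) is modeled as
*m ≈ S f* with *f ≥ 0, Σ f = 1*, where *S* is the signature matrix. The
primary solver fits a linear ν-support-vector regression of the standardized
mixture on the standardized signature columns for each ν in {0.25, 0.5,
0.75} and keeps the fit with the smallest reconstruction RMSE (ties favor
the smaller ν); negative coefficients are clipped and the rest renormalized.
Quantile normalization of the mixture matrix (tie values receive the average
of their tied target quantiles) is on by default and should be disabled for
RNA-seq-scale cohorts.

Standardization is per gene, using the signature's own row mean and standard
deviation. This weights every signature gene equally in the fit; without it
the least-squares objective is dominated by the few highest-expressed genes
(expression spans orders of magnitude), which measurably degrades accuracy
under multiplicative noise. Per-gene centering has one consequence handled
explicitly: the three centered signature columns sum to zero in every row,
so the coefficient vector is identified only up to an additive constant.
The constant is pinned by the biological sum-to-one constraint — the raw SVR
coefficients are shifted by (1 − Σw)/3 before clipping. On noiseless
mixtures this recovers the exact fractions (the shifted solution coincides
with the true one). Signature rows with zero across-subtype variance carry
no fraction information and are dropped from the basis.

The ν-SVR uses C = 1, tolerance 1e−6, and an iteration cap of 10^5; the cap
is a safety net against rare solver cycling and never binds on ordinary
instances (typical iteration counts are single digits). A deterministic
nonnegative-least-squares solver (`solve_fractions_nnls`) provides a convex
reference: on exact mixtures it is accurate to ~1e−15 and the SVR solution
must agree with it within 0.05 per fraction.

Replicate samples of one patient/timepoint are averaged (arithmetic mean of
fractions, renormalized); distinct timepoints remain separate entries. The
dominant subtype is the argmax fraction, with exact ties broken in the fixed
order MetA < MetB < MetC and flagged.

## Phenotype scores

A phenotype score is the first-principal-component sample score (t1) of the
gene-set submatrix, with genes mean-centered across samples and *not*
variance-scaled (the inputs are already log2 "relative transcript levels";
scaling is a config choice). Since a principal component is defined up to
sign, scores are oriented to correlate positively with the per-sample mean
expression of the gene set (fallback for an exactly zero correlation: the
sign of the first gene's loading). A zero-variance submatrix yields all-zero
scores with a flag. The AR / proliferation / NEPC gene lists are external
inputs; the tests use the generator's planted marker sets as stand-ins.

## Enrichment

Genes are ranked by a moderated two-group t-statistic: per-gene pooled
variances s² (df d = n1+n2−2) are shrunk toward a prior, s̃² = (d0·s0² +
d·s²)/(d0 + d), with s0² and d0 estimated by moment matching on the log
variances (mean/variance of log s² matched to the scaled-F sampling model
via digamma/trigamma; no excess dispersion ⇒ d0 = ∞). The limits d0 → 0 and
d0 → ∞ reproduce the ordinary pooled t and the fully-shrunk statistic, and
both are exposed as overrides.

Preranked GSEA uses the weighted Kolmogorov-Smirnov running statistic (hit
increments ∝ |stat|^weight, default weight 1; uniform miss decrements); ES
is the running-sum extremum (largest absolute value, first occurrence). The
null is gene-label permutation — random hit positions at fixed set size —
as required for preranked lists. NES divides ES by the mean magnitude of
same-sign permutation ESs; the nominal p is the same-sign tail probability
(r+1)/(m+1), so "no same-sign permutation" reports the upper bound 1/(m+1)
with a flag; FDR q follows the standard positive/negative-pool procedure
across all sets of a run. Ranking-statistic ties are broken by gene id for
determinism. "Consistent" enrichment of a hallmark for a subtype means
NES > 0 and q < 0.05 (configurable) in every cohort.

## Genomic aberrations and OPLS

Variant retention keeps frameshift/nonframeshift indels, start-loss,
stop-gain, stop-loss and splice variants unconditionally; nonsynonymous SNVs
require damaging calls from *both* SIFT and PolyPhen (the stricter reading;
an OR mode is provided). Mutated genes are kept at frequency ≥ 0.02 of the
full sample universe (boundary included). Copy-number calls: loss at CN ≤ 1,
gain at CN ≥ 4. CNV genes enter association testing only if expressed
(nonzero) in strictly more than 97% of samples and CNV-altered in at least
3%. Lesion-fraction association is a two-sided Mann-Whitney test of the
subtype fraction between carriers and non-carriers; CNV genes are selected
when *both* the fraction and the gene's own expression differ at unadjusted
p < 0.05 (losses and gains tested separately by default, poolable), with BH
q-values reported alongside for transparency.

The selected transcripts (columns centered and unit-variance scaled) feed a
single-response OPLS model of the MetB fraction: `n_orth` y-orthogonal
components are extracted by NIPALS and deflated, then one predictive PLS
component is fitted. Predictive and orthogonal score vectors are orthogonal
by construction, and the fitted values coincide with an (n_orth+1)-component
PLS1 model — checked numerically against scikit-learn at 1e−6. R²Y is
computed on the training data; Q² by 7-fold venetian-blinds cross-validation
(deterministic fold assignment by sample index modulo 7). Q² of a permuted
response is negative in expectation; individual shuffles fluctuate, so the
permutation check averages 20 shuffles. A continuous response is the
default (the fraction itself); a binary "discriminant" use is just a 0/1
response.

## Survival

Kaplan-Meier curves use the product-limit estimator; the median is the first
event time where S(t) ≤ 0.5 and is reported as "not reached" (never
extrapolated) otherwise; groups without events are flagged. The log-rank
test is the multi-group chi-square with hypergeometric variance. Cox models
maximize the Efron-tied partial likelihood (Breslow available) by
Newton-Raphson with step-halving, to gradient norm < 1e−8 or until the step
size hits the rounding floor of the likelihood sums; non-convergence within
100 iterations is an error. Monotone likelihood (perfect separation) is
flagged when |β| exceeds 15. Wald CIs and p-values are reported; the score
test at β = 0 for a binary covariate reproduces the log-rank statistic on
untied data, which the tests verify to 1e−6. Zero-variance covariates are
reported with HR = 1 and p = 1.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, at
sizes chosen for fast, repeated simulation (defaults: 2000 genes, 100
samples, 60 markers per subtype):

* **Profiles** — baseline linear expression 2^N(7, 1.5²) per gene (shared
  across subtypes); each subtype's markers multiplied by 2^marker_log2fc
  (default 2, i.e. FC 4) in that subtype only.
* **Mixing** — per-sample fractions ~ Dirichlet(2, 1, 1) (MetA-skewed, as in
  the cohorts the analysis targets); bulk = fraction-weighted profile sum;
  multiplicative lognormal noise with σ = 0.5 on the log2 scale, the
  error structure of array/RNA-seq data. Optional replicates share their
  patient's true fractions with fresh noise.
* **Lesions** — one planted deleterious-SNV gene and a 21-gene deletion
  block (copy number 1, expression × 2^−1.5 in carriers), carrier
  probability logistic in the true MetB fraction with slope 5 and intercept
  −2.5: carrier probability ≈ 0.08 at MetB 0, ≈ 0.62 at MetB 0.6, matching
  the reported aberration rates in MetB-dominant tumors. Passenger SNVs
  mutate independently at rate 0.01 across 30 background genes.
* **Survival** — exponential event times with hazard 0.1·exp(2.77·MetB
  fraction) per year (slope = ln 16, the reported univariate hazard ratio
  per unit MetB fraction; baseline gives a MetA-like median near 5 years),
  censored by an independent uniform time whose horizon is calibrated by
  bisection to the target censoring rate (default 0.2).

Everything is reproducible bit-exactly from the config seed.

### What the synthetic experiments show — and what they do not

The generator's mixtures satisfy the deconvolution model by construction
(linear mixing, correct signature, lognormal noise). Passing recovery tests
therefore demonstrates the solver chain's correctness and noise robustness,
*not* that real metastasis cohorts satisfy linear mixing, nor that the
published signature transfers across platforms. Real-data features the
generator omits: batch/platform effects, tumor-purity confounding,
correlated gene-gene noise, non-exponential hazards, and informative
censoring. Headline clinical numbers (subtype distribution, published
survival medians, published correlation tables) derive from patient cohorts
and are deliberately not targets of the synthetic experiments; the
integration test instead checks the *structural* findings: planted markers
recovered exactly, MetB-dominant group with the lowest median survival,
the full deletion block (and nothing else) selected by dual association,
and uniformly negative OPLS predictive loadings for the knocked-down block.

## Numerical choices and edge cases

* Mann-Whitney: U counts pairs x > y plus half-ties; exact enumeration when
  both n ≤ 8 without ties, else normal approximation with tie and continuity
  correction; a fully tied comparison reports p = 1. Spearman p uses the
  t approximation; constant vectors yield a flagged result, not NaN.
* Deconvolution: an all-nonpositive coefficient vector (mixture outside the
  reference span) yields uniform fractions with a degenerate flag.
* Problem sizes in tests and the acceptance script (e.g. 300-gene cohorts in
  the repeated lesion-detection runs) keep repeated simulation fast; the
  sample-level conditions (n = 100 samples, logistic lesion models, noise
  σ = 0.5) are the ones that govern power and are kept at their defaults.
* Acceptance-script seeds all derive from `--seed`; detection rates use 100
  independent cohorts per condition.

## Known limitations

* The consistency filter and representative-sample rule are documented
  stand-ins for incompletely specified published procedures.
* The SVR deconvolution reports reconstruction RMSE/correlation but no
  permutation-null p-value for deconvolution quality.
* Cox models support right censoring only (no time-varying covariates or
  competing risks); the multivariate covariate list is caller-specified.
* GSEA FDR uses the classic pooled-permutation procedure, which is known to
  be conservative for very small collections of sets.
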