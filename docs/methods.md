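# Methods

This note documents the models, conventions and numerical choices behind
`lrnet`, and what the synthetic-data tests do and do not establish about
behavior on real cohorts.

## Input model

One biopsy's interactome is a list of directed ligand→receptor records:
sender cell type, receiver cell type, ligand complex, receptor complex,
one integer rank per inference method (1 = strongest), and an aggregate
rank in (0, 1] treated as a p-value proxy.  The **mean rank** is the
arithmetic mean over the method ranks that are present; when a method did
not score an interaction it simply does not contribute (averaging the
present methods is the least destructive convention for method-level
dropout, which the input format permits).  A feature is the full directed
key — the same ligand–receptor pair between two different cell-type pairs
is two features.  Complex subunits are serialized underscore-joined in
sorted order so keys are stable across files.

## Interaction frequencies

Records are filtered to aggregate rank ≤ 0.1 (boundary inclusive) before
any counting; the per-pair proportion divides by the *filtered* total, so
each biopsy's frequencies sum to 1 (a configuration switch on the calling
side can pass unfiltered records if the alternative denominator is
wanted).  Self-pairs (A→A) are ordinary directed pairs.  Absent pairs
score 0, and a biopsy with no passing interactions keeps an all-zero row
rather than being dropped.  Group contrasts use
`log2((median_A + 0.001) / (median_B + 0.001))` — the pseudocount makes
the statistic exactly 0 for equal medians including the all-zero case —
and a two-sided Wilcoxon rank-sum test per pair.

## Wilcoxon and Kruskal–Dunn conventions

The rank-sum test is exact for two tie-free groups smaller than 8, exact
by full permutation enumeration for small tied groups, and tie-corrected
normal otherwise; when every observation is tied the test is
uninformative and p = 1 by convention.  Dunn's post hoc z-statistics use
the pooled tie-corrected rank variance; the multiplicity adjustment
defaults to Holm (FWER control without Bonferroni's conservatism —
Bonferroni and unadjusted are options) because no particular correction is
canonical for this test.

## Imputation and threshold tuning

Columns observed in fewer than a fraction τ of samples are dropped
(τ = 0.7 is the conventional starting point; ≥ is boundary-inclusive).
Imputer quality is scored by masking cells of the fully observed
submatrix — uniformly at random, at the same rate as the thresholded
matrix's overall missingness — imputing them back, and computing
NRMSE = RMSE / sd(truth) with the population (n-denominator) sd, which
makes "impute the mean of the masked truth" score exactly 1.  The τ sweep
is coarse (0 to 1, step 0.1) then fine (±0.05 around the best coarse
point, step 0.01, clipped to [0, 1]); the minimum-NRMSE (imputer, τ) wins,
ties resolved toward the smaller τ to retain more features.  Grid points
where masking is impossible (no complete columns, nothing to mimic, or a
mask that strips a whole sample) are recorded as not evaluable and
excluded from the argmin.

Three imputers are registered.  `mean` fills column means.  `knn` fills a
missing cell with the distance-weighted mean of the k = 5 nearest rows by
Euclidean distance over mutually observed columns.  `random_forest` is
the iterative scheme: initialize missing cells at column means, revisit
columns in ascending-missingness order fitting a random-forest regression
of each on all others (500 trees, mtry = ⌊√p⌋, defaults seed 123), and
stop when the summed squared change of the imputed cells increases —
returning the last non-worsening state — or after 20 passes.  All
imputation runs on the transposed matrix (interactions as rows, samples
as variables); observed cells are never altered.  This is the standard
iterative forest-imputation scheme, not a claimed exact reproduction of
any particular implementation's stopping rule.

## Stability selection

The selector repeats a penalized fit `n_repeats` times (default 500;
tests use 100) and retains features with nonzero coefficients in ≥ 90% of
repeats.  The default fit is penalized least squares on a ±1-coded
response — the classic `lasso`/glmnet elastic-net with mixing parameter
α (default 1, pure lasso) — because selected-feature *identities*, not
class probabilities, are what feed downstream; a penalized logistic
variant is available.  Features are standardized to unit variance so the
penalty treats them comparably; constant columns are inert rather than
fatal.

What varies across repeats is the internal cross-validation partition
(5 stratified folds, re-randomized each repeat) used to choose the
penalty from a fixed grid of 30 log-spaced values spanning two decades
below the smallest all-zero penalty.  The chosen penalty is the strongest
one within one standard error of the minimum held-out deviance ("1se").
This choice matters: because the full-data refit at a given penalty does
not depend on the partition, the minimum-deviance rule concentrates the
repeats on weak penalties whose refit contains spuriously correlated
noise features in essentially every repeat, giving them selection
frequencies near 1 and defeating the stability filter; the 1-SE rule
restores false-positive control.  The minimum rule remains an option.

Biologically infeasible features are removed by an explicit, expert-curated
exclusion list (reason codes: single-cell complex subunit, intracellular
localization, refuted interaction); selection reruns after each removal
until the retained set is clean.  The loop terminates because the feature
set strictly shrinks.

## OPLS-DA, VIP and the permutation test

The discriminant model standardizes X, encodes classes ±1 (centered), and
extracts `n_orthogonal` components (default 1, giving the usual
two-dimensional score plot) of X-variation orthogonal to the
class-correlated weight vector, deflating each before a single predictive
PLS component is fit.  Orthogonal scores are exactly uncorrelated with
the class labels by construction.  Prediction thresholds a new sample's
predictive score at the midpoint of the training class means.  If the
orthogonal residual vanishes (e.g. one feature), fewer components are
extracted rather than failing.

With one predictive component, `VIP_j = sqrt(p)·|w_j|/‖w‖`, so mean
VIP² = 1 identically and a single-feature model has VIP exactly 1.  The
two-stage fit keeps VIP > 1 features (strict inequality; if none exceeds
1 — e.g. all features identical — the library errors with the VIP
distribution, and the pipeline orchestration falls back to a single-stage
model).  Accuracy is measured by stratified k-fold CV (default k = 5,
seed-controlled shuffling; stratification because the motivating cohorts
are small and unbalanced).  Significance is the empirical p-value against
`N` label-permuted null models, each re-cross-validated on its own folds:
`p = max(#{null ≥ observed}, 1) / N`.  Ties count against the model
(conservative), and the floor at 1/N is the convention consistent with
reporting p = 0.011 for 11-of-1000 exceedances and p = 0.001 for none.

## Co-correlate network

Correlations are computed on the *unimputed* matrix over pairwise-complete
samples — deliberately including interactions the missingness filter
excluded, since Pearson correlation tolerates holes — with a minimum
overlap of 5 samples per edge (Pearson on fewer points is unstable).
Each center keeps its 5 largest-|r| partners; ties break toward the
lexicographically smaller partner label; partners that are themselves
centers stay eligible, and undirected center–center edges are kept once.
Functional category labels are user-supplied annotations, never computed.

## Survival analysis

The LR score of a pair for a patient is the plain mean of the z-scored
expression of all its ligand and receptor genes; cell-type context is
dropped because bulk data has none.  Gene matching is exact after
uppercasing; absent genes are dropped from the mean with a warning and
only a pair with no measurable gene is fatal.  Ward clustering (Euclidean
distance) cuts at k clusters relabeled 1..k by descending mean score, so
"cluster 1 vs cluster k" is always high- vs low-expression regardless of
dendrogram order; with k = 3 the middle cluster is reported but excluded
from the headline two-group comparison.  The "5-year hazard ratio" is
implemented as administrative censoring at 60 months before a single
binary-covariate Cox fit (Wald 95% CI); reporting the full-follow-up HR
instead is a caller-side option.

## Synthetic data

The generator emulates the statistical shape of consensus LR inference
output, not its biology.  Latent base ranks are drawn per feature from a
right-skewed Beta(0.7, 2) over [1, n]; per sample the latent rank adds
Gaussian noise (`sample_noise_sd`, default 25 ranks — between-biopsy
variability without which averaging five method ranks would make groups
implausibly separable); each method rank adds independent Gaussian jitter
(`method_noise_sd`, default 25) and is clipped to [1, n]; the aggregate
rank is latent/n with multiplicative lognormal noise clipped to (0, 1] —
only its monotonicity in the latent rank matters.  Planted discriminative
features are displaced by ±shift/2 between groups, with their bases drawn
from the sub-interval of [1, n] where the displacement (plus a 3σ noise
margin when the range allows) fits, so the realized effect equals the
nominal shift instead of a boundary-clipped fraction of it.  Dropout
removes whole interaction rows at the configured rate (optionally
group-dependent).  Cell-type pairs are assigned round-robin over all
directed pairs including self-pairs.

The survival generator plants two equal clusters with gene-program means
±separation/2 (default 2 z-units), standardizes per gene, draws
exponential event times whose cluster hazards are in the requested ratio
(baseline 1/40 per month), and censors with an independent Uniform(0, c)
time where c is solved numerically so the expected censoring fraction
equals the requested rate.

What passing tests show — and what they do not: the generator's features
are conditionally independent given the group, its noise is Gaussian, and
its missingness is uniform at random.  Real interactomes have correlated
features, heavy-tailed rank noise, and informative missingness, so
synthetic recovery rates bound what the pipeline can do under its own
assumptions, not its field performance.  One consequence observed in
testing deserves note: equally shifted planted features are statistically
near-exchangeable, and on such data an l1 path often never contains more
than ~7 of 10 planted features at any penalty — lasso keeps redundant
features at zero — so "recover every planted feature" is not attainable
even by an oracle penalty choice in a sizable fraction of simulated
datasets at n = 40.

## Problem sizes and determinism

Test and example problem sizes (hundreds of interaction features, tens of
samples, 100 selection repeats, 200-permutation tests, 50-tree forests in
sweeps) are chosen so the full suite runs on a laptop-class single core in
minutes; defaults in `PipelineConfig` keep the published settings (500
repeats, 1000 permutations, 500 trees).  Every stochastic step takes an
explicit seed; the pipeline derives per-stage seeds from one global seed
by hashing, and rerunning any stage chain with the same config and seed
reproduces byte-identical numeric artifacts.
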