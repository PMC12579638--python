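# lrnet

Statistics for per-sample ligand–receptor (LR) interactome inferences from
tumor single-cell RNA-seq.

Cell–cell communication in a tumor biopsy can be summarized as a directed
network: cell types are nodes, and an edge from a sender to a receiver is
supported by expression of a ligand on one and its receptor on the other.
Consensus inference frameworks score every candidate interaction per biopsy
with a rank from each of several methods (1 = strongest evidence), an
aggregate rank in (0, 1] that behaves like a p-value, and the **mean rank**
— the average of the per-method ranks.  `lrnet` turns tables of these
ranked interactions, one per biopsy, into three analysis products:

1. **Interaction frequencies** — per biopsy, the fraction of robustly
   detected interactions (aggregate rank ≤ 0.1) attributed to each directed
   cell-type pair; groups are contrasted by the median log2 fold change
   (pseudocount 0.001) and Wilcoxon rank-sum tests.
2. **Multivariate interaction signatures** — the sample × interaction
   mean-rank matrix is completed by NRMSE-tuned imputation, log10
   transformed, and fed to stability selection (features with nonzero lasso
   coefficients in ≥ 90% of 500 CV-tuned repeated fits), then a two-stage
   orthogonalized PLS-DA: features with VIP > 1 in the first model are
   refit, and the second model is validated by fivefold cross-validation
   and an empirical permutation test
   `p = max(#{null ≥ observed}, 1) / N` against `N` label-shuffled null
   models.  A Pearson co-correlate network (top 5 partners per selected
   feature, by |r| on pairwise-complete samples) puts the signature in
   context.
3. **Survival stratification** — per patient, each selected LR pair is
   scored as the mean z-scored bulk expression of its ligand and receptor
   genes; Ward clustering on these scores defines high/low-expression
   groups compared by Kaplan–Meier/log-rank and a Cox model
   administratively censored at 5 years.

Key quantities, in the field's notation: VIP for a one-component PLS model
is `VIP_j = sqrt(p) · |w_j| / ‖w‖` (so mean VIP² = 1 and VIP > 1 means
above-average contribution); NRMSE is `RMSE(masked) / sd(truth)` with 1 ≈
"no better than predicting the mean"; the univariate display score for an
interaction is `1 / ln(mean rank)`, strictly increasing with evidence.

A first-class synthetic-data module generates ranked interaction cohorts
with planted group effects and two-cluster survival cohorts with a known
hazard ratio, so every stage is testable with ground truth and no
downloads.

## Worked example

`examples/` contains one short script per capability.  The discriminant
pipeline on a synthetic cohort with 8 planted features
(`examples/04_discriminant_signature.py`) prints:

```
retained 7 features (6 of 8 planted, 1 false)
stage 2 keeps 5 features with VIP > 1
cross-validated accuracy: 100%
permutation p (vs 200 null models): 0.005
```

i.e. stability selection recovered most of the planted signature with one
false positive, and the refit discriminant model separates the groups far
better than any of 200 chance relabelings (p at the 1/N floor).  The
survival stage (`examples/06_survival.py`) on a 400-patient cohort
simulated with a true hazard ratio of 2.0 prints:

```
cluster sizes (1 = high expression): {1: 198, 2: 202}
log-rank chi2=51.7, p=6.59e-13
5-year hazard ratio (low vs high expression): 2.32 (95% CI 1.83-2.95); simulated truth = 2.0
```

so Ward clustering on the LR scores recovers the planted split and the Cox
estimate brackets the simulated hazard ratio.

## Command line

The same stages run as subcommands over a single YAML config:

```sh
lrnet simulate    --config config.yaml
lrnet run-all     --config config.yaml --seed 5
```

`run-all` chains frequencies → impute → select → oplsda → network (and
survival when a cohort is configured), writing TSV/JSON/GraphML artifacts
plus a manifest with input checksums and per-stage seeds.  Identical
config and seed reproduce byte-identical numeric artifacts.

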