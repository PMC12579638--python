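"""Survival stratification from ligand-receptor expression scores.

Per patient, each selected LR pair is scored as the mean z-scored
expression of its ligand and receptor genes; Ward clustering on these
scores splits the cohort into high- and low-expression groups, compared by
Kaplan-Meier/log-rank and a Cox model censored at five years.
"""

from lrnet.survival import cox_hr_5yr, km_logrank, lr_scores, ward_cluster
from lrnet.synthetic import simulate_survival_cohort

genes = [f"LG{i:02d}" for i in range(5)] + [f"RC{i:02d}" for i in range(5)]
pairs = [([f"LG{i:02d}"], [f"RC{i:02d}"]) for i in range(5)]

cohort, truth = simulate_survival_cohort(
    n_patients=400, genes=genes, hazard_ratio=2.0, censor_rate=0.2, seed=6
)
scores = lr_scores(cohort, pairs)
cohort.cluster = ward_cluster(scores, k=2)
sizes = cohort.cluster.value_counts().sort_index()
print(f"cluster sizes (1 = high expression): {sizes.to_dict()}")

curves, chi2, p = km_logrank(cohort, (1, 2))
hr, (lo, hi) = cox_hr_5yr(cohort, reference=1, comparison=2)
print(f"log-rank chi2={chi2:.1f}, p={p:.2e}")
print(f"5-year hazard ratio (low vs high expression): {hr:.2f} "
      f"(95% CI {lo:.2f}-{hi:.2f}); simulated truth = {truth.true_hazard_ratio}")
# A hazard ratio near the planted 2.0 with a CI excluding 1 means patients
# with low expression of the signature genes die at about twice the rate.
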