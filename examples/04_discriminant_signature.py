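"""Multivariate interaction signature: stability LASSO then two-stage OPLS-DA.

Selection frequencies come from 100 repeated CV-tuned lasso fits; features
stable in >= 90% of repeats feed a discriminant model, which is refit on its
VIP > 1 features and validated by fivefold CV and a label-permutation test.
"""

from lrnet.imputation import impute
from lrnet.io import build_rank_matrix, key_to_label
from lrnet.oplsda import two_stage_fit
from lrnet.stability import log10_transform, stability_lasso
from lrnet.synthetic import SimulationConfig, simulate_interaction_cohort

config = SimulationConfig(
    n_samples_per_group=15, n_cell_types=4, n_lr_pairs=200,
    n_discriminative=8, rank_shift=120.0, missing_rate=0.2, seed=4,
)
records, annotations, truth = simulate_interaction_cohort(config)
matrix = build_rank_matrix(records, annotations)
X = log10_transform(impute(matrix, "knn"))
y = [truth.group_of_sample[s] for s in X.index]

selection = stability_lasso(X, y, n_repeats=100, seed=4)
planted = {key_to_label(k) for k in truth.discriminative_keys}
print(f"retained {len(selection.retained)} features "
      f"({len(selection.retained & planted)} of {len(planted)} planted, "
      f"{len(selection.retained - planted)} false)")

stage1, stage2, kept = two_stage_fit(
    X[sorted(selection.retained)], y, k=5, n_permutations=200, seed=4
)
print(f"stage 2 keeps {len(kept)} features with VIP > 1")
print(f"cross-validated accuracy: {stage2.cv_accuracy:.0%}")
print(f"permutation p (vs {stage2.permutation.n_permutations} null models): "
      f"{stage2.permutation.p_value:.3f}")
# An accuracy far above 50% with a permutation p at the 1/N floor says the
# signature separates the groups far better than chance relabelings do.
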