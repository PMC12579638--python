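"""Pipeline configuration: one flat key-value file drives every stage.

Defaults reproduce the published analysis settings: aggregate-rank cutoff
0.1, 500 LASSO repeats with 90% retention at alpha = 1, VIP cutoff 1,
fivefold CV, 1000 permutations, top-5 co-correlates, 3 survival clusters.
One global seed deterministically derives per-stage seeds, so a run is
reproducible without per-stage seed bookkeeping.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    # paths
    interactions: str | None = None
    metadata: str | None = None
    exclusion_list: str | None = None
    survival_cohort: str | None = None
    output_dir: str = "lrnet_out"
    # grouping: metadata column used as the two-class label
    group_by: str = "response"
    # frequency stage
    aggregate_rank_cutoff: float = 0.1
    fc_pseudocount: float = 0.001
    # imputation stage
    imputer: str = "random_forest"
    rf_trees: int = 500
    rf_max_iter: int = 20
    knn_k: int = 5
    imputation_seed: int = 123
    # selection stage
    alpha: float = 1.0
    n_repeats: int = 500
    retention: float = 0.9
    # discriminant stage
    vip_cutoff: float = 1.0
    cv_folds: int = 5
    n_permutations: int = 1000
    n_orthogonal: int = 1
    # network stage
    top_k_correlates: int = 5
    min_overlap: int = 5
    # survival stage
    clusters_k: int = 3
    # simulation stage (used by the `simulate` subcommand)
    sim_samples_per_group: int = 10
    sim_cell_types: int = 4
    sim_lr_pairs: int = 300
    sim_discriminative: int = 10
    sim_rank_shift: float = 150.0
    sim_missing_rate: float = 0.2
    sim_survival_patients: int = 400
    sim_hazard_ratio: float = 2.0
    sim_censor_rate: float = 0.2
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 < self.aggregate_rank_cutoff <= 1, "aggregate_rank_cutoff in (0, 1]"),
            (0 < self.alpha <= 1, "alpha in (0, 1]"),
            (self.n_repeats >= 1, "n_repeats >= 1"),
            (0 < self.retention <= 1, "retention in (0, 1]"),
            (self.vip_cutoff >= 0, "vip_cutoff >= 0"),
            (self.cv_folds >= 2, "cv_folds >= 2"),
            (self.n_permutations >= 1, "n_permutations >= 1"),
            (self.top_k_correlates >= 1, "top_k_correlates >= 1"),
            (self.clusters_k >= 1, "clusters_k >= 1"),
            (self.imputer in ("mean", "knn", "random_forest"), "imputer name"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"invalid config: {what}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config field(s) {unknown}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.seed, stage)
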