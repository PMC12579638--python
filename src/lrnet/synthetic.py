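"""Synthetic cohorts with known ground truth.

The generator emulates the shape of consensus ligand-receptor inference
output: per biopsy, one row per detected interaction carrying five
per-method ranks (1 = strongest), an aggregate rank in (0, 1] that behaves
like a p-value, and the per-sample mean rank that downstream modelling
consumes.  Group structure is planted by displacing the latent rank of a
chosen set of "discriminative" interactions toward better (smaller) values
in one group; sparsity is produced by dropping whole interaction rows.

Nothing here simulates raw single-cell expression or any inference method;
the target is the *statistical* structure the analysis pipeline sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    CANONICAL_METHODS,
    InteractionKey,
    RankedInteraction,
    SampleAnnotation,
)
from .survival import SurvivalCohort

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_interaction_cohort",
    "simulate_survival_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the interaction-cohort generator.

    ``rank_shift`` is the displacement of planted features' mean ranks
    between the two groups, on the rank scale [1, n_lr_pairs].
    ``method_noise_sd`` jitters each method's rank around the sample's
    latent rank; ``sample_noise_sd`` jitters the latent rank itself between
    samples, so that group separation is a signal-to-noise question rather
    than an artifact of averaging five method replicates.
    """

    n_samples_per_group: int = 10
    n_cell_types: int = 4
    n_lr_pairs: int = 4701
    n_discriminative: int = 10
    rank_shift: float = 0.0
    method_noise_sd: float = 25.0
    sample_noise_sd: float = 25.0
    missing_rate: float = 0.0
    group_missing_delta: float = 0.0
    seed: int = 0
    group_labels: tuple[str, str] = ("R", "NR")

    def __post_init__(self) -> None:
        for name in ("n_samples_per_group", "n_cell_types", "n_lr_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_discriminative < 0 or self.n_discriminative > self.n_lr_pairs:
            raise ValueError("n_discriminative must lie in [0, n_lr_pairs]")
        if self.rank_shift < 0 or self.method_noise_sd <= 0 or self.sample_noise_sd < 0:
            raise ValueError("rank_shift >= 0 and noise sds > 0 required")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.missing_rate + abs(self.group_missing_delta) >= 1:
            raise ValueError("missing_rate + |group_missing_delta| must be < 1")


@dataclass
class GroundTruth:
    """What the generator planted, for checking recovery downstream."""

    discriminative_keys: set[InteractionKey] = field(default_factory=set)
    group_of_sample: dict[str, str] = field(default_factory=dict)
    survival_cluster_of_patient: dict[str, int] = field(default_factory=dict)
    true_hazard_ratio: float = float("nan")


def _feature_keys(config: SimulationConfig) -> list[InteractionKey]:
    cell_types = [f"CT{i + 1:02d}" for i in range(config.n_cell_types)]
    pairs = [(s, r) for s in cell_types for r in cell_types]  # self-pairs included
    keys = []
    for f in range(config.n_lr_pairs):
        sender, receiver = pairs[f % len(pairs)]
        keys.append(InteractionKey(sender, receiver, (f"LG{f:05d}",), (f"RC{f:05d}",)))
    return keys


def simulate_interaction_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, list[RankedInteraction]], dict[str, SampleAnnotation], GroundTruth]:
    """Generate per-sample interaction tables, metadata and ground truth.

    Latent base ranks are drawn once per feature from a right-skewed Beta
    over [1, n_lr_pairs] (many strong, a long tail of weak interactions).
    Per sample: latent = base + N(0, sample_noise_sd), with the planted
    features displaced by -rank_shift/2 in the first group and
    +rank_shift/2 in the second; each of the five method ranks adds
    independent N(0, method_noise_sd) and is clipped into [1, n_lr_pairs];
    the aggregate rank is latent / n_lr_pairs with multiplicative lognormal
    noise clipped into (0, 1] -- only its monotonicity in the latent rank
    matters downstream.  Dropout removes whole rows at missing_rate -/+
    group_missing_delta/2 per group.
    """
    rng = np.random.default_rng(config.seed)
    keys = _feature_keys(config)
    n = config.n_lr_pairs
    base = 1.0 + (n - 1) * rng.beta(0.7, 2.0, size=n)
    disc = rng.choice(n, size=config.n_discriminative, replace=False) if config.n_discriminative else np.array([], dtype=int)
    disc_mask = np.zeros(n, dtype=bool)
    disc_mask[disc] = True
    if config.n_discriminative and config.rank_shift > 0:
        # planted bases live where the full +/- shift (plus a 3-sigma noise
        # margin when the rank range allows it) fits inside [1, n], so the
        # between-group displacement is rank_shift rather than a
        # boundary-clipped fraction of it
        half = config.rank_shift / 2.0
        lo = 1.0 + half + 3.0 * config.sample_noise_sd
        hi = n - half - 3.0 * config.sample_noise_sd
        if hi - lo < 0.2 * (n - 1):  # margin too greedy for this range
            lo, hi = 1.0 + half, n - half
        if hi <= lo:  # shift comparable to the whole range
            lo, hi = 1.0, float(n)
        base[disc] = rng.uniform(lo, hi, size=disc.size)

    g_first, g_second = config.group_labels
    miss = {
        g_first: min(max(config.missing_rate - config.group_missing_delta / 2, 0.0), 0.999),
        g_second: min(max(config.missing_rate + config.group_missing_delta / 2, 0.0), 0.999),
    }

    records: dict[str, list[RankedInteraction]] = {}
    annotations: dict[str, SampleAnnotation] = {}
    truth = GroundTruth(discriminative_keys={keys[f] for f in disc})

    for group, sign in ((g_first, -0.5), (g_second, +0.5)):
        for s in range(config.n_samples_per_group):
            sample_id = f"{group}_{s + 1:03d}"
            latent = base + rng.normal(0.0, config.sample_noise_sd, size=n)
            latent = latent + np.where(disc_mask, sign * config.rank_shift, 0.0)
            latent = np.clip(latent, 1.0, n)
            method_ranks = np.clip(
                latent[:, None] + rng.normal(0.0, config.method_noise_sd, size=(n, len(CANONICAL_METHODS))),
                1.0,
                n,
            )
            aggregate = np.clip(
                (latent / n) * np.exp(rng.normal(0.0, 0.2, size=n)), 1e-9, 1.0
            )
            if config.missing_rate > 0 or config.group_missing_delta != 0:
                keep = rng.random(n) >= miss[group]
            else:
                keep = np.ones(n, dtype=bool)
            recs = [
                RankedInteraction(
                    keys[f],
                    {m: round(float(method_ranks[f, j]), 2) for j, m in enumerate(CANONICAL_METHODS)},
                    float(aggregate[f]),
                )
                for f in range(n)
                if keep[f]
            ]
            records[sample_id] = recs
            annotations[sample_id] = SampleAnnotation(
                sample_id=sample_id,
                patient_id=f"P_{sample_id}",
                timepoint="pre",
                response=group if group in ("R", "NR") else "unknown",
            )
            truth.group_of_sample[sample_id] = group
    return records, annotations, truth


def _uniform_censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Horizon c of Uniform(0, c) censoring giving the target censor rate.

    For T ~ Exp(h) and C ~ U(0, c), P(C < T) = (1 - exp(-h c)) / (h c);
    averaged over the cohort's hazards this is monotone decreasing in c, so
    the target rate pins down a unique horizon.
    """

    def rate(c: float) -> float:
        hc = hazards * c
        return float(np.mean((1.0 - np.exp(-hc)) / hc))

    lo, hi = 1e-8, 1e8
    return float(brentq(lambda c: rate(c) - censor_rate, lo, hi, xtol=1e-10))


def simulate_survival_cohort(
    n_patients: int,
    genes: list[str],
    hazard_ratio: float,
    censor_rate: float = 0.2,
    seed: int = 0,
    cluster_separation: float = 2.0,
    baseline_hazard: float = 1.0 / 40.0,
) -> tuple[SurvivalCohort, GroundTruth]:
    """Two-cluster survival cohort with a known hazard ratio.

    Cluster 1 ("high expression") has gene means +separation/2, cluster 2
    has -separation/2, unit Gaussian noise, then per-gene standardization.
    Event times are exponential: cluster 1 at ``baseline_hazard`` (per
    month), cluster 2 at ``baseline_hazard * hazard_ratio``, so the true HR
    of cluster 2 vs cluster 1 equals ``hazard_ratio``.  Censoring is
    independent Uniform(0, c) with c solved for the requested rate.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if not genes:
        raise ValueError("gene list must be nonempty")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    patients = [f"PT{i + 1:04d}" for i in range(n_patients)]
    n_high = n_patients // 2
    cluster = np.array([1] * n_high + [2] * (n_patients - n_high))
    signs = np.where(cluster == 1, +0.5, -0.5) * cluster_separation
    z = signs[:, None] + rng.normal(0.0, 1.0, size=(n_patients, len(genes)))
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)

    hazards = np.where(cluster == 1, baseline_hazard, baseline_hazard * hazard_ratio)
    event_time = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        horizon = _uniform_censor_horizon(hazards, censor_rate)
        censor_time = rng.uniform(0.0, horizon, size=n_patients)
    else:
        censor_time = np.full(n_patients, np.inf)
    os_months = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    index = pd.Index(patients, name="patient_id")
    cohort = SurvivalCohort(
        z=pd.DataFrame(z, index=index, columns=[str(g) for g in genes]),
        os_months=pd.Series(os_months, index=index, name="os_months"),
        event=pd.Series(event, index=index, name="event"),
    )
    truth = GroundTruth(
        survival_cluster_of_patient=dict(zip(patients, cluster.tolist())),
        true_hazard_ratio=float(hazard_ratio),
    )
    return cohort, truth
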