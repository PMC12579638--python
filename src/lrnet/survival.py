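"""Survival stratification from ligand-receptor expression scores.

Given z-scored bulk expression for a patient cohort, each selected
ligand-receptor pair is summarised per patient as the mean z-score of all of
its ligand and receptor genes (cell-type context is deliberately ignored --
bulk data has none).  Patients are Ward-clustered on these scores, and the
resulting high- vs low-expression groups are compared by Kaplan-Meier /
log-rank and by a Cox proportional-hazards fit administratively censored at
five years (60 months).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCohort",
    "lr_scores",
    "ward_cluster",
    "km_logrank",
    "cox_hr_5yr",
    "read_survival_cohort",
    "write_survival_cohort",
]


@dataclass
class SurvivalCohort:
    """Patient-level z-scored expression with overall-survival follow-up.

    ``z`` is patients x genes with each gene column standardized (mean 0,
    sd 1) across patients; ``os_months`` is time to death or censoring,
    ``event`` is 1 if death was observed.  ``cluster`` is filled by
    :func:`ward_cluster`.
    """

    z: pd.DataFrame
    os_months: pd.Series
    event: pd.Series
    cluster: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.z.index.equals(self.os_months.index) or not self.z.index.equals(
            self.event.index
        ):
            raise ValueError("z, os_months and event must share the same patient index")
        if (self.os_months < 0).any():
            raise ValueError("os_months must be nonnegative")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event must be binary (0/1)")
        means = self.z.mean(axis=0)
        sds = self.z.std(axis=0, ddof=0)
        if (means.abs() > 0.05).any() or ((sds - 1).abs() > 0.05).any():
            raise ValueError("z columns must be standardized (mean 0, sd 1 within 0.05)")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.z.index)


def read_survival_cohort(path) -> SurvivalCohort:
    """Read a cohort TSV: patient_id, OS_months, event, then z-scored gene columns."""
    frame = pd.read_csv(path, sep="\t")
    required = ("patient_id", "OS_months", "event")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    frame = frame.set_index("patient_id")
    genes = [c for c in frame.columns if c not in ("OS_months", "event")]
    if not genes:
        raise ValueError(f"{path}: no gene columns")
    return SurvivalCohort(
        z=frame[genes].astype(float),
        os_months=frame["OS_months"].astype(float),
        event=frame["event"].astype(int),
    )


def write_survival_cohort(cohort: SurvivalCohort, path) -> None:
    frame = pd.concat(
        [cohort.os_months.rename("OS_months"), cohort.event.rename("event"), cohort.z],
        axis=1,
    )
    frame.index.name = "patient_id"
    frame.reset_index().to_csv(path, sep="\t", index=False)


def lr_scores(
    cohort: SurvivalCohort,
    pairs: Sequence[tuple[Sequence[str], Sequence[str]]],
) -> pd.DataFrame:
    """Per-patient LR score for each (ligand genes, receptor genes) pair.

    The score is the plain arithmetic mean of the z-scores of every ligand
    and receptor gene of the pair.  Genes absent from the expression table
    are dropped from the mean with a warning; a pair with no measurable gene
    at all is an error.  Matching is exact after uppercasing.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    colmap = {str(c).upper(): c for c in cohort.z.columns}
    out: dict[str, pd.Series] = {}
    for lig, rec in pairs:
        genes = [str(g) for g in list(lig) + list(rec)]
        if not genes:
            raise ValueError("a pair must name at least one gene")
        present = [colmap[g.upper()] for g in genes if g.upper() in colmap]
        absent = [g for g in genes if g.upper() not in colmap]
        pair_id = "_".join(str(g) for g in lig) + "^" + "_".join(str(g) for g in rec)
        if not present:
            raise ValueError(f"pair {pair_id}: no constituent gene in the expression table")
        if absent:
            logger.warning("pair %s: genes %s absent from table, omitted from mean", pair_id, absent)
        out[pair_id] = cohort.z[present].mean(axis=1)
    return pd.DataFrame(out, index=cohort.z.index)


def ward_cluster(scores: pd.DataFrame, k: int = 3) -> pd.Series:
    """Agglomerative Ward clustering of patients on their LR scores.

    Labels are renumbered 1..k by *descending* mean score, so cluster 1 is
    always the high-expression group regardless of dendrogram order.
    """
    if scores.isna().any().any():
        raise ValueError("scores must be complete (no missing values)")
    n = len(scores)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of patients ({n})")
    if k == 1:
        return pd.Series(1, index=scores.index, name="cluster")
    values = scores.to_numpy(float)
    if np.allclose(values, values[0]):
        logger.warning("all patients identical; clustering is degenerate")
    raw = fcluster(linkage(values, method="ward"), t=k, criterion="maxclust")
    means = {lab: values[raw == lab].mean() for lab in np.unique(raw)}
    # descending mean score; ties broken by the original dendrogram label
    order = sorted(means, key=lambda lab: (-means[lab], lab))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return pd.Series([remap[lab] for lab in raw], index=scores.index, name="cluster")


def _two_groups(cohort: SurvivalCohort, groups: tuple[int, int]):
    if cohort.cluster is None:
        raise ValueError("cohort has no cluster labels; run ward_cluster first")
    a, b = groups
    in_a = cohort.cluster == a
    in_b = cohort.cluster == b
    if not in_a.any() or not in_b.any():
        raise ValueError(f"empty cluster in comparison {groups}")
    return in_a, in_b


def km_logrank(
    cohort: SurvivalCohort, groups: tuple[int, int]
) -> tuple[dict[int, pd.DataFrame], float, float]:
    """Kaplan-Meier curves for two clusters plus the two-group log-rank test.

    Returns (curves, chi-square statistic, p).  Each curve is a DataFrame of
    step coordinates (timeline, survival probability).
    """
    in_a, in_b = _two_groups(cohort, groups)
    if cohort.event[in_a | in_b].sum() < 1:
        raise ValueError("no events in either group; log-rank undefined")
    curves: dict[int, pd.DataFrame] = {}
    for label, mask in zip(groups, (in_a, in_b)):
        km = KaplanMeierFitter()
        km.fit(cohort.os_months[mask], cohort.event[mask], label=str(label))
        est = km.survival_function_.reset_index()
        est.columns = ["time", "survival"]
        curves[label] = est
    res = logrank_test(
        cohort.os_months[in_a],
        cohort.os_months[in_b],
        event_observed_A=cohort.event[in_a],
        event_observed_B=cohort.event[in_b],
    )
    return curves, float(res.test_statistic), float(res.p_value)


def cox_hr_5yr(
    cohort: SurvivalCohort,
    reference: int,
    comparison: int,
    horizon_months: float = 60.0,
) -> tuple[float, tuple[float, float]]:
    """Five-year hazard ratio of ``comparison`` vs ``reference`` cluster.

    Follow-up is administratively censored at ``horizon_months`` before a
    single binary-covariate Cox fit; returns exp(coef) with its Wald 95% CI.
    """
    in_ref, in_cmp = _two_groups(cohort, (reference, comparison))
    mask = in_ref | in_cmp
    time = cohort.os_months[mask].clip(upper=horizon_months)
    event = cohort.event[mask].where(cohort.os_months[mask] <= horizon_months, 0)
    if event.sum() < 1:
        raise ValueError(f"no events within {horizon_months} months")
    frame = pd.DataFrame(
        {
            "time": time,
            "event": event.astype(int),
            "group": in_cmp[mask].astype(int),
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(frame, duration_col="time", event_col="event")
        except Exception as exc:  # convergence failure
            raise RuntimeError(
                f"Cox fit failed ({exc}); events={int(event.sum())}, n={len(frame)}"
            ) from exc
    hr = float(np.exp(cph.params_["group"]))
    lo = float(np.exp(cph.confidence_intervals_.iloc[0, 0]))
    hi = float(np.exp(cph.confidence_intervals_.iloc[0, 1]))
    return hr, (lo, hi)
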