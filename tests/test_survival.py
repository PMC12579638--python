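import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lrnet.survival import (
    SurvivalCohort,
    cox_hr_5yr,
    km_logrank,
    lr_scores,
    read_survival_cohort,
    ward_cluster,
    write_survival_cohort,
)
from lrnet.synthetic import simulate_survival_cohort


def _cohort(z, os_months=None, event=None):
    n = len(z)
    idx = z.index
    return SurvivalCohort(
        z=z,
        os_months=pd.Series(os_months if os_months is not None else np.arange(1.0, n + 1), index=idx),
        event=pd.Series(event if event is not None else np.ones(n, int), index=idx),
    )


def _zframe(values, columns):
    arr = np.asarray(values, float)
    arr = (arr - arr.mean(axis=0)) / arr.std(axis=0, ddof=0)
    return pd.DataFrame(arr, columns=columns,
                        index=pd.Index([f"p{i}" for i in range(len(arr))], name="patient_id"))


class TestLrScores:
    def test_two_gene_mean(self):
        rng = np.random.default_rng(0)
        z = _zframe(rng.normal(0, 1, (10, 2)), ["G1", "G2"])
        cohort = _cohort(z)
        scores = lr_scores(cohort, [(["G1"], ["G2"])])
        assert np.allclose(scores.iloc[:, 0], z[["G1", "G2"]].mean(axis=1))

    def test_complex_pair_arithmetic(self):
        z = _zframe(np.array([[1.0, 2.0, 6.0], [-1.0, -2.0, -6.0]] * 3), ["a", "b", "c"])
        cohort = _cohort(z)
        scores = lr_scores(cohort, [(["a", "b"], ["c"])])
        assert np.allclose(scores.iloc[:, 0], z[["a", "b", "c"]].mean(axis=1))

    def test_absent_genes_omitted_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        z = _zframe(rng.normal(0, 1, (8, 1)), ["G1"])
        cohort = _cohort(z)
        with caplog.at_level("WARNING"):
            scores = lr_scores(cohort, [(["G1"], ["MISSING"])])
        assert np.allclose(scores.iloc[:, 0], z["G1"])
        assert any("omitted" in r.message for r in caplog.records)

    def test_pair_without_measurable_genes_rejected(self):
        rng = np.random.default_rng(2)
        cohort = _cohort(_zframe(rng.normal(0, 1, (8, 1)), ["G1"]))
        with pytest.raises(ValueError, match="no constituent gene"):
            lr_scores(cohort, [(["NOPE"], ["NADA"])])

    def test_matching_is_case_insensitive(self):
        rng = np.random.default_rng(3)
        z = _zframe(rng.normal(0, 1, (8, 2)), ["TnfSF9", "TNFRSF9"])
        cohort = _cohort(z)
        scores = lr_scores(cohort, [(["tnfsf9"], ["tnfrsf9"])])
        assert scores.shape == (8, 1)

    def test_linear_in_z_table(self):
        rng = np.random.default_rng(4)
        z = _zframe(rng.normal(0, 1, (10, 4)), list("abcd"))
        pairs = [(["a"], ["b"]), (["c"], ["d"])]
        scores = lr_scores(_cohort(z), pairs)
        manual = np.column_stack([z[["a", "b"]].mean(axis=1), z[["c", "d"]].mean(axis=1)])
        assert np.allclose(scores.to_numpy(), manual)


class TestWardCluster:
    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(5)
        blobs = np.vstack(
            [rng.normal(c, 0.2, (15, 3)) for c in (-5.0, 0.0, 5.0)]
        )
        scores = pd.DataFrame(blobs, index=[f"p{i}" for i in range(45)])
        labels = ward_cluster(scores, k=3)
        truth = [0] * 15 + [1] * 15 + [2] * 15
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_labels_ordered_by_descending_mean(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(
            np.r_[rng.normal(3, 0.1, (10, 2)), rng.normal(-3, 0.1, (10, 2))],
            index=[f"p{i}" for i in range(20)],
        )
        labels = ward_cluster(scores, k=2)
        assert scores[labels == 1].mean().mean() > scores[labels == 2].mean().mean()

    def test_degenerate_identical_patients_no_crash(self):
        scores = pd.DataFrame(np.ones((6, 2)), index=[f"p{i}" for i in range(6)])
        labels = ward_cluster(scores, k=2)
        assert set(labels.unique()) <= {1, 2}

    def test_k_one_single_cluster_and_k_too_large(self):
        scores = pd.DataFrame(np.eye(3), index=list("abc"))
        assert (ward_cluster(scores, k=1) == 1).all()
        with pytest.raises(ValueError):
            ward_cluster(scores, k=5)

    def test_row_permutation_invariance_up_to_names(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(
            np.r_[rng.normal(2, 0.3, (8, 2)), rng.normal(-2, 0.3, (8, 2))],
            index=[f"p{i}" for i in range(16)],
        )
        l1 = ward_cluster(scores, k=2)
        perm = scores.sample(frac=1.0, random_state=1)
        l2 = ward_cluster(perm, k=2)
        assert (l2.reindex(l1.index) == l1).all()


class TestKmLogrank:
    def test_identical_groups_p_near_one(self):
        times = np.r_[np.arange(1.0, 11), np.arange(1.0, 11)]
        z = _zframe(np.random.default_rng(8).normal(0, 1, (20, 1)), ["g"])
        cohort = _cohort(z, os_months=times, event=np.ones(20, int))
        cohort.cluster = pd.Series([1] * 10 + [2] * 10, index=z.index)
        _, _, p = km_logrank(cohort, (1, 2))
        assert p > 0.9

    def test_fully_separated_event_times_significant(self):
        times = np.r_[np.arange(1.0, 13), np.arange(50.0, 62)]
        z = _zframe(np.random.default_rng(9).normal(0, 1, (24, 1)), ["g"])
        cohort = _cohort(z, os_months=times, event=np.ones(24, int))
        cohort.cluster = pd.Series([1] * 12 + [2] * 12, index=z.index)
        curves, chi2, p = km_logrank(cohort, (1, 2))
        assert p < 0.01
        for curve in curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] <= 1.0 + 1e-12
            assert (np.diff(surv) <= 1e-12).all()  # nonincreasing step function

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(10)
        z = _zframe(rng.normal(0, 1, (30, 1)), ["g"])
        cohort = _cohort(z, os_months=rng.exponential(20, 30), event=rng.integers(0, 2, 30))
        cohort.event.iloc[0] = 1  # ensure at least one event
        cohort.cluster = pd.Series([1] * 15 + [2] * 15, index=z.index)
        _, _, p12 = km_logrank(cohort, (1, 2))
        _, _, p21 = km_logrank(cohort, (2, 1))
        assert p12 == pytest.approx(p21)


class TestCox:
    def test_reciprocity_under_group_swap(self):
        cohort, truth = simulate_survival_cohort(200, ["g1", "g2"], 2.0, 0.2, seed=3)
        cohort.cluster = pd.Series(
            [truth.survival_cluster_of_patient[p] for p in cohort.patient_ids],
            index=cohort.z.index,
        )
        hr_fwd, _ = cox_hr_5yr(cohort, reference=1, comparison=2)
        hr_rev, _ = cox_hr_5yr(cohort, reference=2, comparison=1)
        assert hr_fwd == pytest.approx(1.0 / hr_rev, rel=1e-6)

    def test_null_ci_contains_one(self):
        contains = 0
        for rep in range(10):
            cohort, truth = simulate_survival_cohort(300, ["g"], 1.0, 0.2, seed=rep)
            cohort.cluster = pd.Series(
                [truth.survival_cluster_of_patient[p] for p in cohort.patient_ids],
                index=cohort.z.index,
            )
            _, (lo, hi) = cox_hr_5yr(cohort, 1, 2)
            contains += lo <= 1.0 <= hi
        assert contains >= 8

    def test_no_events_in_window_rejected(self):
        z = _zframe(np.random.default_rng(11).normal(0, 1, (10, 1)), ["g"])
        cohort = _cohort(z, os_months=np.full(10, 100.0), event=np.ones(10, int))
        cohort.cluster = pd.Series([1] * 5 + [2] * 5, index=z.index)
        with pytest.raises(ValueError, match="60"):
            cox_hr_5yr(cohort, 1, 2)


class TestCohortIO:
    def test_round_trip(self, tmp_path):
        cohort, _ = simulate_survival_cohort(30, ["g1", "g2", "g3"], 1.5, 0.2, seed=12)
        path = tmp_path / "cohort.tsv"
        write_survival_cohort(cohort, path)
        back = read_survival_cohort(path)
        assert np.allclose(back.z, cohort.z)
        assert np.allclose(back.os_months, cohort.os_months)
        assert (back.event == cohort.event).all()

    def test_standardization_validated(self):
        idx = pd.Index(["a", "b", "c"], name="patient_id")
        with pytest.raises(ValueError, match="standardized"):
            SurvivalCohort(
                z=pd.DataFrame({"g": [10.0, 20.0, 30.0]}, index=idx),
                os_months=pd.Series([1.0, 2.0, 3.0], index=idx),
                event=pd.Series([1, 0, 1], index=idx),
            )
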