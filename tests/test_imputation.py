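import numpy as np
import pandas as pd
import pytest

from lrnet.imputation import (
    impute,
    impute_columns,
    mask_complete_subset,
    missingness_filter,
    nrmse,
    threshold_sweep,
)


def _frame(values):
    arr = np.asarray(values, float)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"f{j}" for j in range(arr.shape[1])],
    )


@pytest.fixture()
def structured_matrix():
    """Low-rank samples x interactions matrix with strong inter-column
    correlation (each interaction is a scaled version of a sample profile)."""
    rng = np.random.default_rng(0)
    u = rng.uniform(1.0, 3.0, 12)
    v = rng.uniform(10.0, 100.0, 60)
    return _frame(np.outer(u, v) + rng.normal(0, 1.0, (12, 60)))


class TestMissingnessFilter:
    def test_boundary_inclusive_at_seventy_percent(self):
        arr = np.ones((10, 2))
        arr[:3, 0] = np.nan  # column 0 present in 7/10
        arr[:4, 1] = np.nan  # column 1 present in 6/10
        out = missingness_filter(_frame(arr), 0.7)
        assert list(out.columns) == ["f0"]

    def test_tau_zero_identity_and_tau_one_complete_only(self):
        arr = np.ones((4, 3))
        arr[0, 2] = np.nan
        frame = _frame(arr)
        assert missingness_filter(frame, 0.0).shape == (4, 3)
        assert list(missingness_filter(frame, 1.0).columns) == ["f0", "f1"]


class TestMasking:
    def test_exact_mask_count(self):
        masked, truth = mask_complete_subset(_frame(np.ones((10, 10)) * 5), 0.2, seed=1)
        assert len(truth) == 20
        assert int(masked.isna().sum().sum()) == 20

    def test_identical_seed_identical_mask(self):
        frame = _frame(np.arange(100.0).reshape(10, 10))
        m1, t1 = mask_complete_subset(frame, 0.3, seed=9)
        m2, t2 = mask_complete_subset(frame, 0.3, seed=9)
        assert t1.index.equals(t2.index)
        assert m1.equals(m2)

    def test_zero_cell_mask_rejected(self):
        with pytest.raises(ValueError, match="zero cells|proportion"):
            mask_complete_subset(_frame(np.ones((2, 2))), 0.01, seed=0)

    def test_no_complete_columns_instructs_lower_tau(self):
        arr = np.ones((3, 2))
        arr[0, 0] = np.nan
        arr[1, 1] = np.nan
        with pytest.raises(ValueError, match="tau"):
            mask_complete_subset(_frame(arr), 0.5, seed=0)


class TestImpute:
    @pytest.mark.parametrize("method", ["mean", "knn", "random_forest"])
    def test_complete_matrix_returned_unchanged(self, method):
        frame = _frame(np.arange(12.0).reshape(3, 4) + 1)
        out = impute(frame, method, n_trees=10)
        assert out.equals(frame)

    def test_mean_fills_column_mean(self):
        arr = np.array([[2.0, 1.0], [4.0, 1.0], [np.nan, 1.0]])
        out = impute_columns(_frame(arr), "mean")
        assert out.iloc[2, 0] == pytest.approx(3.0)

    @pytest.mark.parametrize("method", ["mean", "knn", "random_forest"])
    def test_observed_cells_never_altered(self, structured_matrix, method):
        masked, truth = mask_complete_subset(structured_matrix, 0.1, seed=3)
        out = impute(masked, method, n_trees=20)
        observed = ~masked.isna()
        assert np.allclose(out.values[observed.values], masked.values[observed.values])
        assert not out.isna().any().any()

    def test_collinear_columns_recovered_better_than_mean(self, structured_matrix):
        masked, truth = mask_complete_subset(structured_matrix, 0.15, seed=1)
        errs = {
            m: nrmse(impute(masked, m, n_trees=60), truth)
            for m in ("mean", "knn", "random_forest")
        }
        assert errs["random_forest"] < errs["mean"]
        assert errs["knn"] < errs["mean"]

    def test_empty_column_rejected(self):
        arr = np.ones((3, 2))
        arr[:, 1] = np.nan
        with pytest.raises(ValueError, match="zero observed"):
            impute_columns(_frame(arr), "mean")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown imputer"):
            impute(_frame(np.ones((2, 2))), "mice")


class TestNrmse:
    def test_perfect_imputation_is_zero(self):
        frame = _frame(np.arange(9.0).reshape(3, 3))
        truth = pd.Series(
            [frame.iat[0, 0], frame.iat[2, 2]],
            index=pd.MultiIndex.from_tuples([("s0", "f0"), ("s2", "f2")]),
        )
        assert nrmse(frame, truth) == 0.0

    def test_arithmetic_identity(self):
        # truth {0, 2} imputed {1, 1}: RMSE 1, population sd 1
        frame = _frame(np.ones((1, 2)))
        truth = pd.Series(
            [0.0, 2.0], index=pd.MultiIndex.from_tuples([("s0", "f0"), ("s0", "f1")])
        )
        assert nrmse(frame, truth) == pytest.approx(1.0)

    def test_constant_truth_rejected(self):
        frame = _frame(np.ones((1, 2)))
        truth = pd.Series(
            [2.0, 2.0], index=pd.MultiIndex.from_tuples([("s0", "f0"), ("s0", "f1")])
        )
        with pytest.raises(ValueError, match="constant"):
            nrmse(frame, truth)

    def test_masked_truth_mean_imputer_scores_one(self):
        rng = np.random.default_rng(5)
        frame = _frame(rng.normal(50, 10, (40, 40)))
        masked, truth = mask_complete_subset(frame, 0.4, seed=2)  # 640 cells
        filled = masked.copy()
        for s, f in truth.index:
            filled.at[s, f] = truth.mean()
        assert nrmse(filled, truth) == pytest.approx(1.0, abs=1e-12)


class TestThresholdSweep:
    def _sparse_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        u = rng.uniform(1, 3, 14)
        v = rng.uniform(10, 100, 50)
        arr = np.outer(u, v) + rng.normal(0, 1, (14, 50))
        # heterogeneous missingness so different taus keep different columns
        for j in range(50):
            rate = rng.uniform(0, 0.45)
            holes = rng.random(14) < rate
            arr[holes, j] = np.nan
        return _frame(arr)

    def test_fine_grid_brackets_best_coarse(self):
        report = threshold_sweep(self._sparse_matrix(), "mean", seed=11)
        taus = sorted({t for _, t in report.nrmse_table})
        coarse_best = min(
            (v, t) for (imp, t), v in report.nrmse_table.items() if round(t * 10, 6) % 1 == 0
        )[1]
        fine = [t for t in taus if round(t * 10, 6) % 1 != 0]
        if fine:  # fine grid points other than the coarse ones were evaluable
            assert min(fine) >= round(coarse_best - 0.05, 2) - 1e-9
            assert max(fine) <= round(coarse_best + 0.05, 2) + 1e-9

    def test_chosen_pair_minimizes_table(self):
        report = threshold_sweep(self._sparse_matrix(1), "mean", seed=5)
        best = min(report.nrmse_table.values())
        assert report.nrmse_table[(report.chosen_imputer, report.chosen_threshold)] == best

    def test_complete_matrix_not_tunable(self):
        with pytest.raises(ValueError, match="no threshold"):
            threshold_sweep(_frame(np.ones((4, 4)) + np.arange(4)), "mean", seed=0)

    def test_report_serializes(self, tmp_path):
        report = threshold_sweep(self._sparse_matrix(2), "mean", seed=7)
        path = tmp_path / "report.json"
        report.to_json(path)
        assert path.exists() and path.stat().st_size > 0
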