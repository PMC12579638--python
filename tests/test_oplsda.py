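import numpy as np
import pandas as pd
import pytest

from lrnet.oplsda import (
    PermutationRecord,
    cross_validate,
    empirical_p,
    fit_oplsda,
    permutation_test,
    two_stage_fit,
    vip,
)


class TestFit:
    def test_separable_classes_fit_perfectly(self, separable_data):
        X, y = separable_data
        model = fit_oplsda(X, y)
        assert (model.predict(X) == y).all()
        scores_a = model.predictive_scores[y == "A"]
        scores_b = model.predictive_scores[y == "B"]
        assert np.sign(scores_a.mean()) != np.sign(scores_b.mean())

    def test_label_swap_negates_scores_keeps_vip(self, separable_data):
        X, y = separable_data
        m1 = fit_oplsda(X, y)
        swapped = np.where(y == "A", "B", "A")
        m2 = fit_oplsda(X, swapped)
        assert np.allclose(m1.predictive_scores, -m2.predictive_scores)
        assert np.allclose(m1.vip, m2.vip)
        relabel = {"A": "B", "B": "A"}
        assert (m2.predict(X) == [relabel[c] for c in m1.predict(X)]).all()

    def test_orthogonal_scores_uncorrelated_with_labels(self, separable_data):
        X, y = separable_data
        model = fit_oplsda(X, y, n_orthogonal=2)
        y_pm = np.where(y == "B", 1.0, -1.0)
        for a in range(model.orthogonal_scores.shape[1]):
            assert abs(np.corrcoef(model.orthogonal_scores[:, a], y_pm)[0, 1]) < 1e-8

    def test_scale_invariance(self, separable_data):
        X, y = separable_data
        m1 = fit_oplsda(X, y)
        X2 = X.copy()
        X2.iloc[:, 0] *= 375.0
        m2 = fit_oplsda(X2, y)
        assert (m1.predict(X) == m2.predict(X2)).all()
        assert np.allclose(m1.vip, m2.vip)

    def test_single_feature_univariate_threshold(self):
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(0, 1, 15), rng.normal(8, 1, 15)]
        y = np.array(["A"] * 15 + ["B"] * 15)
        model = fit_oplsda(pd.DataFrame({"f": x}), y, n_orthogonal=0)
        assert model.vip["f"] == pytest.approx(1.0)
        assert (model.predict(pd.DataFrame({"f": x})) == y).mean() == 1.0

    def test_constant_feature_named_in_error(self, separable_data):
        X, y = separable_data
        X = X.copy()
        X["flat"] = 2.5
        with pytest.raises(ValueError, match="flat"):
            fit_oplsda(X, y)

    def test_single_class_rejected(self, separable_data):
        X, _ = separable_data
        with pytest.raises(ValueError):
            fit_oplsda(X, ["A"] * len(X))


class TestVip:
    def test_mean_squared_vip_is_one(self, separable_data):
        X, y = separable_data
        for n_orth in (0, 1, 2):
            model = fit_oplsda(X, y, n_orthogonal=n_orth)
            assert float((model.vip**2).mean()) == pytest.approx(1.0, abs=1e-8)

    def test_identical_features_all_vip_one(self):
        rng = np.random.default_rng(1)
        base = np.r_[rng.normal(0, 1, 10), rng.normal(3, 1, 10)]
        X = pd.DataFrame({f"c{j}": base for j in range(4)})
        y = ["A"] * 10 + ["B"] * 10
        model = fit_oplsda(X, y, n_orthogonal=0)
        assert np.allclose(vip(model), 1.0)

    def test_planted_feature_has_max_vip_above_one(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(0, 1, (40, 8)), columns=[f"f{j}" for j in range(8)])
        y = np.array(["A"] * 20 + ["B"] * 20)
        X.loc[y == "B", "f3"] += 3.0
        model = fit_oplsda(X, y)
        assert model.vip.idxmax() == "f3"
        assert model.vip["f3"] > 1.0


class TestCrossValidate:
    def test_separable_accuracy_high(self, separable_data):
        X, y = separable_data
        assert cross_validate(X, y, k=5, seed=0) >= 0.95

    def test_null_accuracy_near_chance(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(0, 1, (40, 10)))
        y = np.array(["A"] * 20 + ["B"] * 20)
        acc = cross_validate(X, y, k=5, seed=1)
        assert 0.3 <= acc <= 0.7

    def test_deterministic_given_seed(self, separable_data):
        X, y = separable_data
        assert cross_validate(X, y, seed=7) == cross_validate(X, y, seed=7)

    def test_class_smaller_than_k_rejected(self, separable_data):
        X, y = separable_data
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(X.iloc[:24], y[:24], k=10)


class TestPermutation:
    def test_empirical_p_conventions(self):
        assert empirical_p(11, 1000) == 0.011
        assert empirical_p(0, 1000) == 0.001
        assert empirical_p(1000, 1000) == 1.0

    def test_record_counts_at_least_as_good(self):
        rec = PermutationRecord(
            n_permutations=10,
            observed_metric=0.8,
            null_metrics=[0.5] * 7 + [0.8, 0.9, 1.0],
        )
        assert rec.k_at_least == 3
        assert rec.p_value == 0.3

    def test_permutation_test_significant_on_signal(self, separable_data):
        X, y = separable_data
        rec = permutation_test(X, y, k=5, n_permutations=50, seed=0)
        assert rec.p_value == pytest.approx(1 / 50)
        assert len(rec.null_metrics) == 50

    def test_invalid_permutation_count(self, separable_data):
        X, y = separable_data
        with pytest.raises(ValueError):
            permutation_test(X, y, n_permutations=0, seed=0)


class TestTwoStage:
    def test_planted_features_survive_to_stage_two(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(
            rng.normal(0, 1, (40, 10)), columns=[f"f{j}" for j in range(10)]
        )
        y = np.array(["A"] * 20 + ["B"] * 20)
        for planted in ("f0", "f1", "f2"):
            X.loc[y == "B", planted] += 2.5
        stage1, stage2, kept = two_stage_fit(X, y, k=5, n_permutations=25, seed=0)
        assert set(kept) <= set(stage1.feature_ids)
        assert {"f0", "f1", "f2"} <= set(kept)
        assert stage2.cv_accuracy >= 0.9
        assert stage2.permutation is not None

    def test_identical_copies_yield_no_vip_above_one(self):
        rng = np.random.default_rng(6)
        base = np.r_[rng.normal(0, 1, 10), rng.normal(3, 1, 10)]
        X = pd.DataFrame({f"c{j}": base for j in range(3)})
        y = ["A"] * 10 + ["B"] * 10
        with pytest.raises(ValueError, match="VIP"):
            two_stage_fit(X, y, k=5, n_permutations=5, seed=0, n_orthogonal=0)
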