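import numpy as np
import pandas as pd
import pytest

from lrnet.stability import (
    PruningRecord,
    log10_transform,
    prune_and_rerun,
    read_exclusion_list,
    stability_lasso,
)


def _planted_data(seed=0, n_per_group=10, n_noise=299, margin=4.0):
    """One strongly separating feature among pure noise."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    y = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    X = rng.normal(0, 1, (n, n_noise + 1))
    X[y == "B", 0] += margin
    cols = ["planted"] + [f"noise{j}" for j in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestLog10:
    def test_known_values(self):
        frame = pd.DataFrame({"a": [1.0, 1000.0, 4701.0]})
        out = log10_transform(frame)
        assert out["a"].tolist() == pytest.approx([0.0, 3.0, 3.6722], abs=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log10_transform(pd.DataFrame({"a": [1.0, 0.0]}))
        with pytest.raises(ValueError, match="complete"):
            log10_transform(pd.DataFrame({"a": [1.0, np.nan]}))


class TestStabilityLasso:
    def test_planted_separator_always_selected(self):
        X, y = _planted_data()
        sel = stability_lasso(X, y, n_repeats=50, seed=1)
        assert sel.selection_frequency["planted"] == 1.0
        assert "planted" in sel.retained

    def test_null_labels_retain_nothing(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(0, 1, (20, 150)))
        X.columns = [f"f{j}" for j in range(150)]
        y = rng.permutation(["A"] * 10 + ["B"] * 10)
        sel = stability_lasso(X, y, n_repeats=50, seed=2)
        assert sel.retained == set()

    def test_duplicated_column_no_crash_combined_frequency(self):
        X, y = _planted_data(n_noise=50)
        X["planted_copy"] = X["planted"]
        sel = stability_lasso(X, y, n_repeats=30, seed=3)
        combined = (
            sel.selection_frequency["planted"] + sel.selection_frequency["planted_copy"]
        )
        assert combined >= sel.selection_frequency["planted"]
        assert combined >= 0.9  # the pair carries the whole signal

    def test_seed_reproducibility(self):
        X, y = _planted_data(n_noise=30)
        a = stability_lasso(X, y, n_repeats=25, seed=11).selection_frequency
        b = stability_lasso(X, y, n_repeats=25, seed=11).selection_frequency
        assert a.equals(b)

    def test_logistic_loss_variant_agrees_on_strong_signal(self):
        X, y = _planted_data(n_noise=30)
        sel = stability_lasso(X, y, n_repeats=20, seed=4, loss="logistic")
        assert sel.selection_frequency["planted"] >= 0.9

    def test_single_class_rejected(self):
        X, _ = _planted_data(n_noise=5)
        with pytest.raises(ValueError):
            stability_lasso(X, ["A"] * len(X), n_repeats=5, seed=0)

    def test_monotone_selection_in_effect_size(self):
        freqs = []
        for margin in (0.3, 1.5, 4.0):
            X, y = _planted_data(seed=7, n_noise=80, margin=margin)
            sel = stability_lasso(X, y, n_repeats=30, seed=7)
            freqs.append(sel.selection_frequency["planted"])
        assert freqs[0] <= freqs[1] <= freqs[2]
        assert freqs[2] == 1.0


class TestPruneAndRerun:
    def test_empty_exclusion_single_iteration(self):
        X, y = _planted_data(n_noise=30)
        sel, records = prune_and_rerun(X, y, {}, n_repeats=20, seed=1)
        assert len(records) == 1
        assert records[0].excluded_features == []
        direct = stability_lasso(X, y, n_repeats=20, seed=1)
        assert sel.retained == direct.retained

    def test_excluded_retained_feature_forces_second_pass(self):
        X, y = _planted_data(n_noise=30)
        X["planted2"] = X["planted"] * 0.5 + np.random.default_rng(9).normal(
            0, 0.3, len(X)
        )
        sel, records = prune_and_rerun(
            X, y, {"planted": "refuted_interaction"}, n_repeats=20, seed=1
        )
        assert len(records) >= 2
        assert ("planted", "refuted_interaction") in records[0].excluded_features
        assert "planted" not in sel.retained
        assert "planted2" in sel.retained  # the surviving planted signal

    def test_all_features_excluded_rejected(self):
        X, y = _planted_data(n_noise=2)
        exclusion = {c: "refuted_interaction" for c in X.columns}
        with pytest.raises(ValueError, match="all features excluded"):
            # the planted feature is retained, excluded, retained again ...
            # until nothing is left
            prune_and_rerun(X[["planted"]], y, exclusion, n_repeats=10, seed=0)

    def test_unknown_exclusions_warned_not_fatal(self, caplog):
        X, y = _planted_data(n_noise=10)
        with caplog.at_level("WARNING"):
            prune_and_rerun(X, y, {"missing_feature": "refuted_interaction"},
                            n_repeats=10, seed=0)
        assert any("ignored" in r.message for r in caplog.records)


class TestExclusionListIO:
    def test_read_maps_keys_to_reasons(self, tmp_path):
        path = tmp_path / "exclusions.tsv"
        path.write_text(
            "sender\treceiver\tligand_complex\treceptor_complex\treason\trationale\n"
            "Treg\tCD8 T\tLGALS3\tLAG3\trefuted_interaction\tfree text\n"
            "NK\tNK\tGNB1_GNG2\tADRB2\tsingle_cell_complex_subunit\tG protein\n"
        )
        out = read_exclusion_list(path)
        assert out == {
            "Treg|CD8 T|LGALS3|LAG3": "refuted_interaction",
            "NK|NK|GNB1_GNG2|ADRB2": "single_cell_complex_subunit",
        }

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sender\treceiver\n")
        with pytest.raises(ValueError):
            read_exclusion_list(path)
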