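"""Balanced vote forest, cell splitting, and score contracts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from nucrisk.nrs import (
    BalancedVoteForest,
    RFConfig,
    score_cells,
    split_cells,
    tune_and_train,
)
from nucrisk.synthetic import CohortSpec, generate_feature_cohort


def _cells(seed=0, effect=None, n_patients=12, cells=(60, 60), patient_sigma=0.25,
           heterogeneity=0.9):
    spec = CohortSpec(seed=seed, n_patients=n_patients, rois_per_patient=(2, 2),
                      cells_per_roi=cells, effect=effect, patient_sigma=patient_sigma,
                      heterogeneity=heterogeneity)
    table, truth = generate_feature_cohort(spec)
    return table[table.grade.isin(["G1", "G2"])].reset_index(drop=True), truth


FEATURES = None


def _features(cells):
    from nucrisk.registry import default_registry

    return [n for n in default_registry().names if n in cells.columns]


class TestSplit:
    def test_floor_rounding(self):
        cells = pd.DataFrame({"patient_id": ["p"] * 10})
        split = split_cells(cells, 0.8, seed=0)
        assert split.train.sum() == 8
        assert (~split.train).sum() == 2

    def test_seed_reproducible(self):
        cells = pd.DataFrame({"patient_id": ["p"] * 100})
        s1 = split_cells(cells, 0.8, seed=5)
        s2 = split_cells(cells, 0.8, seed=5)
        assert (s1.train == s2.train).all()

    def test_grouped_mode_never_shares_patients(self):
        cells = pd.DataFrame({"patient_id": np.repeat([f"p{i}" for i in range(10)], 20)})
        split = split_cells(cells, 0.8, seed=1, mode="grouped")
        train_p = set(cells.loc[split.train, "patient_id"])
        test_p = set(cells.loc[~split.train, "patient_id"])
        assert not train_p & test_p

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_cells(pd.DataFrame({"patient_id": ["p"]}), 1.0)


class TestBalancedForest:
    def test_bootstrap_class_counts_equal_under_imbalance(self, rng):
        x = rng.standard_normal((200, 5))
        y = np.array(["LN+"] * 180 + ["LN0"] * 20)
        forest = BalancedVoteForest(n_trees=10, seed=0).fit(x, y, compute_oob=False)
        for counts in forest.bootstrap_class_counts(y):
            assert counts["LN+"] == counts["LN0"] == 20

    def test_scores_are_vote_fractions(self, rng):
        x = rng.standard_normal((100, 4))
        y = np.where(x[:, 0] > 0, "LN+", "LN0")
        forest = BalancedVoteForest(n_trees=33, seed=1).fit(x, y)
        s = forest.score_samples(x)
        assert ((s >= 0) & (s <= 1)).all()
        np.testing.assert_allclose(s * 33, np.round(s * 33), atol=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            BalancedVoteForest(n_trees=5).fit(rng.standard_normal((10, 2)), np.full(10, "LN+"))

    def test_nonfinite_features_rejected(self, rng):
        x = rng.standard_normal((20, 3))
        x[0, 1] = np.nan
        y = np.array(["LN+"] * 10 + ["LN0"] * 10)
        with pytest.raises(ValueError, match="non-finite"):
            BalancedVoteForest(n_trees=5).fit(x, y)


class TestTuneAndTrain:
    def test_strong_effect_recovers_high_auc(self):
        """2-SD shift on 5 features: held-out cell AUC >= 0.9."""
        cells, _ = _cells(seed=21)
        split = split_cells(cells, 0.8, seed=0)
        model = tune_and_train(cells[split.train.to_numpy()], _features(cells),
                               RFConfig(n_trees_grid=(50,), mtry_grid=("sqrt",), seed=0))
        test = cells[~split.train.to_numpy()]
        s = score_cells(model, test)
        auc = roc_auc_score(test["ln_status"] == "LN+", s["nrs"])
        assert auc >= 0.9

    def test_null_effect_grouped_split_at_chance(self):
        """effect=0: patient-grouped held-out AUC ~ 0.5 (median over seeds)."""
        aucs = []
        for seed in range(5):
            cells, _ = _cells(seed=100 + seed, effect={}, heterogeneity=0.0,
                              n_patients=14, cells=(40, 40))
            split = split_cells(cells, 0.8, seed=seed, mode="grouped")
            tr, te = cells[split.train.to_numpy()], cells[~split.train.to_numpy()]
            if te["ln_status"].nunique() < 2 or tr["ln_status"].nunique() < 2:
                continue
            model = tune_and_train(tr, _features(cells),
                                   RFConfig(n_trees_grid=(30,), mtry_grid=("sqrt",), seed=seed))
            s = score_cells(model, te)
            aucs.append(roc_auc_score(te["ln_status"] == "LN+", s["nrs"]))
        assert np.median(aucs) == pytest.approx(0.5, abs=0.07)

    def test_cell_split_leaks_patient_identity_on_null_data(self):
        """With patient-level random effects and zero class effect, the
        cell-level split (patients shared across partitions) scores above the
        leakage-free grouped split."""
        diffs = []
        for seed in range(3):
            cells, _ = _cells(seed=200 + seed, effect={}, heterogeneity=0.0,
                              patient_sigma=1.0, n_patients=14, cells=(50, 50))
            aucs = {}
            for mode in ("cell", "grouped"):
                split = split_cells(cells, 0.8, seed=seed, mode=mode)
                tr, te = cells[split.train.to_numpy()], cells[~split.train.to_numpy()]
                if te["ln_status"].nunique() < 2 or tr["ln_status"].nunique() < 2:
                    break
                model = tune_and_train(tr, _features(cells),
                                       RFConfig(n_trees_grid=(30,), mtry_grid=("sqrt",), seed=seed))
                s = score_cells(model, te)
                aucs[mode] = roc_auc_score(te["ln_status"] == "LN+", s["nrs"])
            if len(aucs) == 2:
                diffs.append(aucs["cell"] - aucs["grouped"])
        assert np.median(diffs) > 0.05

    def test_cv_selects_from_grid(self):
        cells, _ = _cells(seed=22, n_patients=8, cells=(30, 30))
        model = tune_and_train(cells, _features(cells),
                               RFConfig(n_trees_grid=(20, 40), mtry_grid=("sqrt",),
                                        cv_folds=3, seed=0))
        assert model.n_trees in (20, 40)
        assert len(model.cv_results) == 2
        assert np.isfinite(model.oob_error)

    def test_single_class_error(self):
        cells, _ = _cells(seed=23, n_patients=6)
        cells = cells[cells.ln_status == cells.ln_status.iloc[0]]
        with pytest.raises(ValueError, match="both LN classes"):
            tune_and_train(cells, _features(cells), RFConfig(n_trees_grid=(10,), mtry_grid=("sqrt",)))


@pytest.fixture(scope="module")
def trained():
    cells, _ = _cells(seed=24, n_patients=10, cells=(40, 40))
    model = tune_and_train(cells, _features(cells),
                           RFConfig(n_trees_grid=(40,), mtry_grid=("sqrt",), seed=0),
                           registry_hash="abc123")
    return model, cells


class TestScoreCells:
    def test_deterministic_scoring(self, trained):
        model, cells = trained
        s1 = score_cells(model, cells)
        s2 = score_cells(model, cells)
        pd.testing.assert_frame_equal(s1, s2)

    def test_scores_bounded_and_flag_consistent(self, trained):
        model, cells = trained
        s = score_cells(model, cells)
        assert s["nrs"].between(0, 1).all()
        assert (s["positive"] == (s["nrs"] >= 0.5)).all()

    def test_lnpos_cells_score_higher_on_strong_effect(self, trained):
        model, cells = trained
        s = score_cells(model, cells).assign(ln=cells["ln_status"].to_numpy())
        assert s.loc[s.ln == "LN+", "nrs"].mean() > s.loc[s.ln == "LN0", "nrs"].mean()

    def test_registry_hash_mismatch_rejected(self, trained):
        model, cells = trained
        with pytest.raises(ValueError, match="registry mismatch"):
            score_cells(model, cells, registry_hash="other")

    def test_missing_feature_rejected(self, trained):
        model, cells = trained
        with pytest.raises(ValueError, match="lack model features"):
            score_cells(model, cells.drop(columns=["iod"]))

    def test_exported_forest_rescores_identically(self, trained):
        """Scores are re-derivable from the implementation-neutral tree
        export."""
        from nucrisk.nrs import export_forest, score_from_export
        from nucrisk.registry import default_registry

        model, cells = trained
        x = cells[model.feature_names].to_numpy(float)[:50]
        expected = model.forest.score_samples(x)
        rederived = score_from_export(export_forest(model.forest), x)
        np.testing.assert_allclose(rederived, expected, atol=1e-12)
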