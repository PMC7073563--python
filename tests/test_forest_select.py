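"""Ensemble-of-forests selection: splits, tuning, importance, Mood's test."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from lvtool import forest_select as fs
from lvtool.containers import ForestEnsembleResult, ParameterError


def _meta(counts):
    rows = []
    for cls, n in counts.items():
        for i in range(n):
            rows.append({"sample_id": f"{cls}_{i}", "tumor_type": cls, "study_id": "x"})
    return pd.DataFrame(rows)


class TestSplit:
    def test_counts_four_by_ten(self):
        meta = _meta({"cNF": 10, "pNF": 10, "NF": 10, "MPNST": 10})
        model_ids, test_ids = fs.split_model_test(meta, 0.8, seed=0)
        assert len(model_ids) == 32 and len(test_ids) == 8
        test_types = meta.set_index("sample_id").loc[test_ids, "tumor_type"]
        assert test_types.value_counts().eq(2).all()

    def test_partition(self):
        meta = _meta({"cNF": 7, "MPNST": 5})
        model_ids, test_ids = fs.split_model_test(meta, 0.8, seed=1)
        assert set(model_ids) | set(test_ids) == set(meta["sample_id"])
        assert set(model_ids) & set(test_ids) == set()

    def test_stratification_across_seeds(self):
        meta = _meta({"cNF": 9, "pNF": 6, "NF": 12, "MPNST": 5})
        by_class = meta.groupby("tumor_type").size()
        for seed in range(50):
            model_ids, _ = fs.split_model_test(meta, 0.8, seed=seed)
            got = meta.set_index("sample_id").loc[model_ids, "tumor_type"].value_counts()
            for cls, n in by_class.items():
                assert abs(got.get(cls, 0) - 0.8 * n) <= 1

    def test_singleton_class_rejected(self):
        with pytest.raises(ParameterError):
            fs.split_model_test(_meta({"cNF": 5, "MPNST": 1}), 0.8, seed=0)


def _separable_data(n_per_class=10, n_features=6, seed=0):
    """Feature 0 perfectly separates the two classes."""
    rng = np.random.default_rng(seed)
    labels, cols = [], []
    for cls, base in (("cNF", 0.0), ("MPNST", 5.0)):
        for i in range(n_per_class):
            labels.append(cls)
            cols.append(f"{cls}_{i}")
    X = rng.standard_normal((n_features, 2 * n_per_class))
    X[0] = np.where(np.array(labels) == "MPNST", 5.0, 0.0) + 0.1 * X[0]
    B = pd.DataFrame(X, index=[f"LV{i}" for i in range(n_features)], columns=cols)
    return B, pd.Series(labels, index=cols)


class TestTune:
    def test_single_point_grid_returned(self):
        B, labels = _separable_data()
        cfg = fs.EnsembleConfig(mtry_grid=(2,), ntree_grid=(25,), cv_folds=3, seed=4)
        mtry, ntrees, table = fs.tune_hyperparams(B, labels, cfg)
        assert (mtry, ntrees) == (2, 25)
        assert len(table) == 1

    def test_tie_breaks_to_smallest_ntrees_then_mtry(self):
        B, labels = _separable_data()
        B.iloc[1] = B.iloc[0]  # duplicate separator: every grid point is perfect
        cfg = fs.EnsembleConfig(
            mtry_grid=(1, 2), ntree_grid=(25, 50), cv_folds=3, seed=4
        )
        mtry, ntrees, table = fs.tune_hyperparams(B, labels, cfg)
        assert table["cv_macro_f1"].max() == table["cv_macro_f1"].min() == 1.0
        assert (mtry, ntrees) == (1, 25)

    def test_oversized_mtry_skipped(self):
        B, labels = _separable_data(n_features=3)
        cfg = fs.EnsembleConfig(mtry_grid=(2, 10), ntree_grid=(25,), cv_folds=3, seed=4)
        _, _, table = fs.tune_hyperparams(B, labels, cfg)
        assert set(table["mtry"]) == {2}

    def test_cv_scores_match_manual_refit(self):
        B, labels = _separable_data(seed=3)
        cfg = fs.EnsembleConfig(mtry_grid=(2,), ntree_grid=(30,), cv_folds=3, seed=9)
        _, _, table = fs.tune_hyperparams(B, labels, cfg)
        X = B.T.loc[labels.index].to_numpy()
        y = labels.to_numpy()
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=9)
        scores = []
        for tr, te in skf.split(X, y):
            clf = RandomForestClassifier(
                n_estimators=30, max_features=2, random_state=9, n_jobs=1
            )
            clf.fit(X[tr], y[tr])
            scores.append(
                f1_score(y[te], clf.predict(X[te]), average="macro", zero_division=0)
            )
        assert table["cv_macro_f1"].iloc[0] == pytest.approx(np.mean(scores))


class TestEnsemble:
    @staticmethod
    def _four_class_planted(seed=0):
        """Feature 0 separates class cNF from the rest; others are noise."""
        rng = np.random.default_rng(seed)
        labels, cols = [], []
        for cls in ("cNF", "pNF", "NF", "MPNST"):
            for i in range(8):
                labels.append(cls)
                cols.append(f"{cls}_{i}")
        X = rng.standard_normal((20, 32))
        X[0] = np.where(np.array(labels) == "cNF", 4.0, 0.0) + 0.2 * X[0]
        B = pd.DataFrame(X, index=[f"LV{i}" for i in range(20)], columns=cols)
        return B, pd.Series(labels, index=cols)

    def test_planted_separator_found(self):
        B, labels = self._four_class_planted()
        cfg = fs.EnsembleConfig(n_iterations=30, seed=5)
        res = fs.run_ensemble(B, labels, cfg, mtry=4, ntrees=100)
        assert res.f1_scores["cNF"].median() >= 0.95
        med_imp = np.median(res.perm_importance[:, res.classes.index("cNF"), :], axis=0)
        assert res.features[int(np.argmax(med_imp))] == "LV0"

    def test_reproducible_given_seed(self):
        B, labels = self._four_class_planted()
        cfg = fs.EnsembleConfig(n_iterations=5, seed=11)
        a = fs.run_ensemble(B, labels, cfg, mtry=4, ntrees=50)
        b = fs.run_ensemble(B, labels, cfg, mtry=4, ntrees=50)
        assert np.array_equal(a.f1_scores.to_numpy(), b.f1_scores.to_numpy())
        assert np.array_equal(a.gini_importance, b.gini_importance)
        assert np.array_equal(a.perm_importance, b.perm_importance)

    def test_mtry_clipped_to_feature_count(self):
        B, labels = self._four_class_planted()
        cfg = fs.EnsembleConfig(n_iterations=2, seed=1, compute_permutation=False)
        res = fs.run_ensemble(B, labels, cfg, mtry=999, ntrees=20)
        assert res.mtry == 20


class TestSelectTop:
    @staticmethod
    def _result(perm, gini, classes, features):
        n_iter = perm.shape[0]
        return ForestEnsembleResult(
            f1_scores=pd.DataFrame(
                np.full((n_iter, len(classes)), 0.5), columns=classes
            ),
            gini_importance=gini,
            perm_importance=perm,
            classes=classes,
            features=features,
            mtry=1,
            ntrees=10,
        )

    def test_disjoint_per_class_rankings_union(self):
        classes = ["a", "b", "c", "d"]
        features = [f"LV{i}" for i in range(160)]
        perm = np.zeros((3, 4, 160))
        for ci in range(4):
            perm[:, ci, ci * 40 : (ci + 1) * 40] = 1.0  # class ci prefers its block
        gini = np.tile(np.linspace(1, 0, 160), (3, 1))
        res = self._result(perm, gini, classes, features)
        sel = fs.select_top_features(res, top_k=40, metric="permutation")
        assert len(sel.union) == 160
        sel_g = fs.select_top_features(res, top_k=40, metric="gini")
        assert len(sel_g.union) == 40

    def test_top_k_capped(self):
        res = self._result(
            np.zeros((2, 1, 5)), np.ones((2, 5)), ["a"], [f"LV{i}" for i in range(5)]
        )
        sel = fs.select_top_features(res, top_k=40)
        assert len(sel.union) == 5


class TestMoods:
    def test_identical_distributions(self):
        stat, p = fs.moods_median_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.5
        stat, p = fs.moods_median_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_hand_computed_table(self):
        stat, p = fs.moods_median_test([1, 1, 2, 2], [3, 3, 4, 4])
        assert stat == pytest.approx(8.0)
        assert p == pytest.approx(0.004677, abs=1e-5)

    def test_symmetric_in_samples(self):
        x = [0.1, 0.4, 0.3, 0.9, 0.2]
        y = [0.6, 0.8, 0.7, 0.5]
        assert fs.moods_median_test(x, y)[1] == pytest.approx(
            fs.moods_median_test(y, x)[1]
        )

    def test_compare_restricted_table(self):
        full = pd.DataFrame({"cNF": [0.1, 0.2, 0.1, 0.2], "MPNST": [0.5] * 4})
        restr = pd.DataFrame({"cNF": [0.8, 0.9, 0.8, 0.9], "MPNST": [0.5] * 4})
        out = fs.compare_restricted(full, restr).set_index("class")
        assert out.loc["cNF", "median_restricted"] > out.loc["cNF", "median_full"]
        assert out.loc["cNF", "p_value"] < 0.05
        assert out.loc["MPNST", "p_value"] == 1.0
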