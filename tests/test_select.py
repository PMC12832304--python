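"""LASSO, SVM-RFE and random-forest selection plus the Venn consensus."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

import priorshot as ps
from priorshot.select import SelectorResult

# the three published selector outputs for the JAK-axis candidate genes
LASSO_GENES = ["GZMA", "IL2RB", "IL2RG", "STAT4", "IL10RA", "EOMES"]
SVM_GENES = ["IL2RG", "IL10RA", "GZMA", "ITGAL", "CD3D", "STAT4", "EOMES",
             "IL2RB", "ITK"]
RF_GENES = ["IL2RG", "ITGAL", "STAT4", "IL2RB", "EOMES", "GZMA", "IL10RA"]


def planted(seed=0, n=100, p=10, informative=(0,), delta=2.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    for sign, j in zip((1, -1) * len(informative), informative):
        X[:, j] += sign * delta * y
    return pd.DataFrame(X, columns=[f"g{i}" for i in range(p)]), y


class TestLasso:
    def test_full_shrinkage_empties_the_selection(self):
        X, y = planted()
        res = ps.lasso_select(X, y, lambdas=[1e6], seed=0)
        assert res.selected == []

    def test_planted_signal_survives_at_lambda_min(self):
        X, y = planted(seed=1)
        res = ps.lasso_select(X, y, rule="lambda_min", seed=1)
        assert "g0" in res.selected

    def test_duplicated_rows_leave_selection_unchanged(self):
        X, y = planted(seed=2)
        base = ps.lasso_select(X, y, seed=3)
        dup = ps.lasso_select(pd.concat([X, X], ignore_index=True),
                              np.concatenate([y, y]), seed=3)
        assert set(base.selected) == set(dup.selected)

    def test_1se_rule_is_sparser_or_equal(self):
        X, y = planted(seed=4, informative=(0, 1))
        lo = ps.lasso_select(X, y, rule="lambda_min", seed=0)
        hi = ps.lasso_select(X, y, rule="lambda_1se", seed=0)
        assert len(hi.selected) <= len(lo.selected)
        assert hi.diagnostics["lambda_chosen"] >= lo.diagnostics["lambda_chosen"]

    def test_degenerate_labels_rejected(self):
        X, _ = planted()
        with pytest.raises(ValueError, match="classes"):
            ps.lasso_select(X, np.zeros(len(X), dtype=int))


class TestSvmRfe:
    def test_ranking_equals_squared_weights_of_independent_refit(self):
        X, y = planted(seed=5, p=4)
        res = ps.svm_rfe(X, y, C=1.0, seed=0)
        first_round = res.diagnostics["rankings"][0]
        w = SVC(kernel="linear", C=1.0).fit(X.to_numpy(), y).coef_.ravel()
        for j, g in enumerate(X.columns):
            assert first_round[g] == pytest.approx(w[j] ** 2, rel=1e-10)

    def test_min_features_equal_to_count_means_ranking_only(self):
        X, y = planted(seed=6, p=5)
        res = ps.svm_rfe(X, y, min_features=5, seed=0)
        assert res.diagnostics["elimination_order"] == []
        assert len(res.diagnostics["path"]) == 1

    def test_two_planted_features_survive_clear_separation(self):
        X, y = planted(seed=7, n=60, p=10, informative=(0, 1), delta=2.0)
        res = ps.svm_rfe(X, y, seed=0)
        assert {"g0", "g1"} <= set(res.selected)

    def test_elimination_order_reproducible(self):
        X, y = planted(seed=8, p=8)
        a = ps.svm_rfe(X, y, C=0.5, seed=2)
        b = ps.svm_rfe(X, y, C=0.5, seed=2)
        assert a.diagnostics["elimination_order"] == \
            b.diagnostics["elimination_order"]

    def test_ties_resolve_to_the_smaller_subset(self):
        X, y = planted(seed=9, informative=(0,), delta=5.0)
        res = ps.svm_rfe(X, y, seed=0)
        accs = [p["cv_accuracy"] for p in res.diagnostics["path"]]
        best = max(accs)
        sizes_at_best = [len(p["subset"]) for p in res.diagnostics["path"]
                         if p["cv_accuracy"] == best]
        assert len(res.selected) == min(sizes_at_best)


class TestRandomForest:
    def test_constant_feature_has_zero_importances(self):
        X, y = planted(seed=10, p=6)
        X["g5"] = 1.0
        res = ps.rf_importance(X, y, n_trees=60, seed=0)
        assert res.diagnostics["mdi"]["g5"] == 0.0
        assert res.diagnostics["permutation_importance"]["g5"] == 0.0

    def test_label_copy_feature_tops_the_mdi_ranking(self):
        X, y = planted(seed=11, p=6, delta=0.0)
        X["g0"] = y.astype(float)
        res = ps.rf_importance(X, y, n_trees=60, seed=0)
        mdg = res.diagnostics["mean_decrease_gini"]
        assert max(mdg, key=mdg.get) == "g0"
        assert res.selected[0] == "g0"

    def test_fraction_threshold_mode(self):
        X, y = planted(seed=12, p=6)
        res = ps.rf_importance(X, y, n_trees=60, seed=0,
                               threshold_mode="fraction")
        assert "g0" in res.selected

    def test_small_forest_still_reports_oob_error(self):
        X, y = planted(seed=13, n=8, p=3)
        res = ps.rf_importance(X, y, n_trees=5, seed=0)
        assert np.isfinite(res.diagnostics["oob_error"])

    def test_permutation_importance_zero_when_error_unchanged(self):
        # a constant feature never alters OOB predictions when permuted,
        # so the difference form e_perm - e_orig is exactly zero
        X, y = planted(seed=16, p=4)
        X["g3"] = 7.0
        res = ps.rf_importance(X, y, n_trees=40, seed=1)
        assert res.diagnostics["permutation_importance"]["g3"] == 0.0


class TestConsensus:
    def as_result(self, genes, method="m"):
        return SelectorResult(method=method, selected=list(genes))

    def test_published_lists_intersect_to_six_genes(self):
        consensus = ps.consensus_intersect(self.as_result(LASSO_GENES),
                                           self.as_result(SVM_GENES),
                                           self.as_result(RF_GENES))
        assert consensus == ["GZMA", "IL2RB", "IL2RG", "STAT4", "IL10RA",
                             "EOMES"]

    def test_idempotent_on_identical_lists(self):
        r = self.as_result(["a", "b"])
        assert ps.consensus_intersect(r, r, r) == ["a", "b"]

    def test_disjoint_lists_give_empty_consensus(self):
        assert ps.consensus_intersect(self.as_result(["a"]),
                                      self.as_result(["b"]),
                                      self.as_result(["c"])) == []

    def test_contained_in_each_input_and_order_free_as_set(self):
        a = self.as_result(["x", "y", "z"])
        b = self.as_result(["z", "x"])
        c = self.as_result(["y", "x", "z"])
        out = ps.consensus_intersect(a, b, c)
        for r in (a, b, c):
            assert set(out) <= set(r.selected)
        assert set(ps.consensus_intersect(c, a, b)) == set(out)


class TestAucScreen:
    def test_label_copy_gene_is_a_perfect_separator(self):
        y = np.repeat([0, 1], 10)
        X = pd.DataFrame({"g": y.astype(float)})
        out = ps.auc_screen(X, y)
        assert out.loc["g", "auc"] == 1.0 and bool(out.loc["g", "passed"])

    def test_permuted_gene_sits_at_chance(self):
        rng = np.random.default_rng(14)
        y = np.repeat([0, 1], 200)
        X = pd.DataFrame({"g": rng.permutation(np.arange(400, dtype=float))})
        out = ps.auc_screen(X, y)
        assert abs(out.loc["g", "auc"] - 0.5) <= 0.1
        assert not bool(out.loc["g", "passed"])

    def test_exact_threshold_fails_by_strict_inequality(self):
        # 10 negatives at 0..9 and 10 positives at 6.5: 70/100 winning pairs
        y = np.repeat([0, 1], 10)
        X = pd.DataFrame({"g": np.concatenate([np.arange(10.0),
                                               np.full(10, 6.5)])})
        out = ps.auc_screen(X, y, threshold=0.7)
        assert out.loc["g", "auc"] == pytest.approx(0.7)
        assert not bool(out.loc["g", "passed"])

    def test_down_regulated_gene_reported_with_direction(self):
        y = np.repeat([0, 1], 10)
        X = pd.DataFrame({"g": -y.astype(float)})
        out = ps.auc_screen(X, y)
        assert out.loc["g", "direction"] == "down"
        assert out.loc["g", "auc"] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ps.auc_screen(pd.DataFrame({"g": [1.0, 2.0]}), np.array([1, 1]))


def test_consensus_selector_estimator_combines_all_three():
    X, y = planted(seed=15, n=80, p=8, informative=(0, 1), delta=2.5)
    sel = ps.ConsensusSelector(n_trees=80, random_state=0).fit(X, y)
    assert set(sel.results_) == {"lasso", "svm_rfe", "random_forest"}
    assert {"g0", "g1"} <= set(sel.results_["lasso"].selected)
    assert sel.selected_ == ps.consensus_intersect(
        sel.results_["lasso"], sel.results_["svm_rfe"],
        sel.results_["random_forest"])
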