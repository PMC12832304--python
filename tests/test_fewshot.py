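"""Episodic sampling, the episode loss, training dynamics and inference."""

import numpy as np
import pandas as pd
import pytest

import priorshot as ps
from priorshot.relation import RelationNetwork

ln2 = np.log(2.0)


class TestSampleEpisode:
    y = np.repeat([0, 1], 10)

    def test_two_way_five_shot_layout(self):
        ep = ps.sample_episode(self.y, 5, 5, np.random.default_rng(0))
        assert all(len(ep.support[c]) == 5 for c in (0, 1))
        assert len(ep.query) == 10
        used = np.concatenate([ep.support[0], ep.support[1], ep.query])
        assert len(np.unique(used)) == 20

    def test_same_seed_same_episode(self):
        a = ps.sample_episode(self.y, 5, 5, np.random.default_rng(4))
        b = ps.sample_episode(self.y, 5, 5, np.random.default_rng(4))
        assert np.array_equal(a.query, b.query)
        assert all(np.array_equal(a.support[c], b.support[c]) for c in (0, 1))

    def test_insufficient_class_size_names_requirement(self):
        y = np.array([0] * 9 + [1] * 10)
        with pytest.raises(ValueError, match="class 0 has 9 .* needs 10"):
            ps.sample_episode(y, 5, 5, np.random.default_rng(0))


class TestEpisodeLoss:
    def test_uniform_scores_give_ln2(self):
        scores = np.zeros((7, 2)) + 3.3
        assert ps.episode_loss(scores, np.array([0, 1] * 3 + [0])) == \
            pytest.approx(ln2, abs=1e-12)

    @pytest.mark.parametrize("tau,expected", [
        (1.0, np.log(1 + np.exp(-1))),
        (0.5, np.log(1 + np.exp(-2))),
    ])
    def test_single_query_closed_form(self, tau, expected):
        loss = ps.episode_loss(np.array([[0.0, 1.0]]), np.array([1]), tau)
        assert loss == pytest.approx(expected, abs=1e-12)

    def test_one_hot_labels_accepted(self):
        scores = np.array([[0.0, 1.0], [2.0, 0.0]])
        onehot = np.array([[0, 1], [1, 0]])
        assert ps.episode_loss(scores, onehot) == \
            pytest.approx(ps.episode_loss(scores, np.array([1, 0])))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            ps.episode_loss(np.zeros((1, 2)), np.array([0]), 0.0)


def test_fresh_model_loss_sits_at_the_no_information_baseline():
    """An untrained comparator scores random balanced episodes at ~ln 2."""
    rng = np.random.default_rng(0)
    net = RelationNetwork(input_dim=12, seed=5)
    X = rng.normal(size=(40, 12))
    y = np.repeat([0, 1], 20)
    losses = []
    for _ in range(100):
        ep = ps.sample_episode(y, 5, 5, rng)
        h_q = net.encode(X[ep.query])
        sup = {c: net.encode(X[idx]) for c, idx in ep.support.items()}
        r = net.relation_scores_from_embeddings(h_q, sup)
        losses.append(ps.episode_loss(r, ep.query_labels))
    se = np.std(losses, ddof=1) / np.sqrt(len(losses))
    assert abs(np.mean(losses) - ln2) <= 3 * max(se, 1e-4)


@pytest.fixture(scope="module")
def small_features():
    ds = ps.make_dataset(ps.SyntheticConfig(
        n_genes=300, n_lvs=20, genes_per_lv=15, n_per_class=30, seed=11))
    Xs, _ = ps.standardize_genes(ds.expression)
    B = ps.project_to_latent(Xs, ds.loadings.loc[Xs.index], 1.0)
    gate = ps.compute_gate(ds.loadings, ds.true_hub_genes)
    return ps.apply_gate(B, gate).T, ds.labels.to_numpy()


class TestTrainingLoop:
    def test_training_loss_decreases_on_separable_data(self, small_features):
        F, y = small_features
        clf = ps.FewShotRelationClassifier(max_episodes=400, patience=100,
                                           random_state=0)
        clf.fit(F, y)
        ckpt_losses = [c["mean_loss"] for c in clf.train_log_]
        assert len(ckpt_losses) >= 20
        assert np.mean(ckpt_losses[-10:]) < np.mean(ckpt_losses[:10])

    def test_zero_learning_rate_stops_at_second_checkpoint(self, small_features):
        F, y = small_features
        clf = ps.FewShotRelationClassifier(learning_rate=0.0, patience=1,
                                           max_episodes=1000, random_state=0)
        clf.fit(F, y)
        assert len(clf.train_log_) == 2

    def test_log_length_bounded_by_checkpoint_count(self, small_features):
        F, y = small_features
        clf = ps.FewShotRelationClassifier(max_episodes=100, eval_every=10,
                                           random_state=0)
        clf.fit(F, y)
        assert len(clf.train_log_) <= 10

    def test_single_class_validation_rejected(self, small_features):
        F, y = small_features
        clf = ps.FewShotRelationClassifier(random_state=0)
        with pytest.raises(ValueError, match="single class"):
            clf.fit(F[:40], y[:40], X_val=F[:5], y_val=np.zeros(5, dtype=int))


class TestInference:
    def test_benchmark_validation_auc_is_high(self, bench_model):
        assert bench_model.classifier.best_val_auc_ >= 0.9

    def test_cases_score_above_controls_heldout(self, bench_heldout):
        pred, y = bench_heldout
        s = pred["score"].to_numpy()
        assert s[y == 1].mean() > s[y == 0].mean()

    def test_predict_is_deterministic_given_seed(self, bench_ds, bench_split,
                                                 bench_model):
        _, te = bench_split
        X = bench_ds.expression[te[:6]]
        a = ps.predict_diagnostic(bench_model, X, seed=5)
        b = ps.predict_diagnostic(bench_model, X, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_strategies_agree_on_hard_labels(self, bench_ds, bench_split,
                                             bench_model, bench_heldout):
        _, te = bench_split
        pred_ens, _ = bench_heldout
        pred_full = ps.predict_diagnostic(bench_model, bench_ds.expression[te],
                                          strategy="full_set")
        agree = (pred_ens["predicted_class"].to_numpy()
                 == pred_full["predicted_class"].to_numpy()).mean()
        assert agree >= 0.95

    def test_ensemble_of_one_on_exactly_k_references_matches_direct_call(
            self, bench_model):
        clf = bench_model.classifier
        rng = np.random.default_rng(8)
        # keep exactly K support samples per class: the single draw is forced
        ref_idx = np.concatenate([
            np.flatnonzero(clf.support_y_ == c)[:clf.k_shot] for c in (0, 1)])
        ref_X, ref_y = clf.support_X_[ref_idx], clf.support_y_[ref_idx]
        Xq = rng.normal(size=(3, clf.n_features_in_))
        clf.n_ensemble, saved = 1, clf.n_ensemble
        try:
            got = clf.relation_score_matrix(Xq, reference_X=ref_X,
                                            reference_y=ref_y,
                                            strategy="kshot_ensemble", seed=0)
        finally:
            clf.n_ensemble = saved
        h_q = clf.network_.encode(Xq)
        sup = {c: clf.network_.encode(ref_X[ref_y == c]) for c in (0, 1)}
        direct = clf.network_.relation_scores_from_embeddings(h_q, sup)
        np.testing.assert_allclose(got, direct, rtol=1e-12)

    def test_training_sample_scored_without_itself_in_support(
            self, bench_ds, bench_split, bench_model):
        tr, _ = bench_split
        sid = bench_model.classifier.support_ids_[0]
        pred = ps.predict_diagnostic(bench_model, bench_ds.expression[[sid]],
                                     strategy="full_set")
        assert np.isfinite(pred[["r_control", "r_case"]].to_numpy()).all()
        # removing that sample from the reference by hand gives the same score
        keep = bench_model.classifier.support_ids_ != sid
        manual = bench_model.classifier.relation_score_matrix(
            bench_model.transform_expression(bench_ds.expression[[sid]]),
            reference_X=bench_model.classifier.support_X_[keep],
            reference_y=bench_model.classifier.support_y_[keep],
            strategy="full_set")
        np.testing.assert_allclose(pred[["r_control", "r_case"]].to_numpy(),
                                   manual, rtol=1e-12)

    def test_reference_missing_a_class_rejected(self, bench_model):
        clf = bench_model.classifier
        only0 = clf.support_y_ == 0
        with pytest.raises(ValueError, match="class 1"):
            clf.relation_score_matrix(clf.support_X_[:2],
                                      reference_X=clf.support_X_[only0],
                                      reference_y=clf.support_y_[only0])


def test_model_archive_roundtrip(tmp_path, bench_ds, bench_split, bench_model):
    _, te = bench_split
    X = bench_ds.expression[te[:5]]
    before = ps.predict_diagnostic(bench_model, X, seed=3)
    path = tmp_path / "model.npz"
    ps.save_model(bench_model, path)
    reloaded = ps.load_model(path)
    after = ps.predict_diagnostic(reloaded, X, seed=3)
    pd.testing.assert_frame_equal(before, after)
    assert reloaded.hub_genes == bench_model.hub_genes
    np.testing.assert_array_equal(reloaded.gate.normalized.to_numpy(),
                                  bench_model.gate.normalized.to_numpy())
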