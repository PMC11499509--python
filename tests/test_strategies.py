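"""Classification strategies: reductions, hand oracles, rank aggregation."""

import numpy as np
import pandas as pd
import pytest

from mltlsmote import (
    BaseLearnerSpec,
    MultiLabelDataset,
    average_rank,
    fit_br,
    fit_cc,
    fit_clr,
    fit_lp,
    fit_mlknn,
    fit_rakel,
    run_experiment,
)
from mltlsmote.synthetic import frailty_like_preset, generate_mld


def blobs_mld(seed: int = 0, m: int = 200, q: int = 3):
    """Label-wise linearly separable blobs: label j active iff x_j > 0."""
    rng = np.random.default_rng(seed)
    features = rng.normal(size=(m, q)) * 2
    labels = (features > 0).astype(np.int8)
    # guarantee no degenerate label
    labels[0] = 1
    labels[1] = 0
    return MultiLabelDataset(features, labels,
                             tuple(f"L{j}" for j in range(q)),
                             tuple(f"x{j}" for j in range(q)))


RT = BaseLearnerSpec("random_tree")
DT = BaseLearnerSpec("decision_tree")


class TestBinaryRelevance:
    def test_separable_blobs_near_zero_hamming(self):
        train = blobs_mld(0)
        test = blobs_mld(1)
        model = fit_br(train, DT, random_state=0)
        from mltlsmote import hamming_loss
        assert hamming_loss(test.labels, model.predict(test.features)) < 0.1

    def test_q1_reduces_to_single_binary_classifier(self):
        mld = blobs_mld(2, q=1)
        br = fit_br(mld, DT, random_state=0)
        cc = fit_cc(mld, DT, random_state=0)
        x = blobs_mld(3, q=1).features
        np.testing.assert_array_equal(br.predict_scores(x),
                                      cc.predict_scores(x))

    def test_label_permutation_equivariance(self):
        mld = blobs_mld(4)
        perm = (2, 0, 1)
        permuted = MultiLabelDataset(
            mld.features, mld.labels[:, perm],
            tuple(mld.label_names[j] for j in perm), mld.feature_names)
        x = blobs_mld(5).features
        s1 = fit_br(mld, DT, random_state=0).predict_scores(x)
        s2 = fit_br(permuted, DT, random_state=0).predict_scores(x)
        np.testing.assert_allclose(s1[:, perm], s2)

    def test_degenerate_label_gets_constant_scorer(self):
        labels = np.ones((20, 2), dtype=np.int8)
        labels[:, 1] = 0
        labels[0, 1] = 1  # non-degenerate second label
        mld = MultiLabelDataset(np.random.default_rng(0).normal(size=(20, 2)),
                                labels, ("a", "b"), ("x", "y"))
        model = fit_br(mld, DT, random_state=0)
        scores = model.predict_scores(mld.features)
        assert (scores[:, 0] == 1.0).all()


class TestClassifierChain:
    def test_chain_order_validated(self):
        with pytest.raises(ValueError):
            fit_cc(blobs_mld(0), DT, chain_order=(0, 0, 2))

    def test_planted_label_dependency_improves_subset_agreement(self):
        rng = np.random.default_rng(6)
        features = rng.normal(size=(300, 2))
        first = (features[:, 0] + rng.normal(0, 0.6, 300) > 0).astype(np.int8)
        labels = np.column_stack([first, first])  # label 2 copies label 1
        labels[0] = [1, 1]
        labels[1] = [0, 0]
        mld = MultiLabelDataset(features, labels, ("a", "b"), ("x", "y"))
        test_x = rng.normal(size=(300, 2))
        br = fit_br(mld, DT, random_state=0).predict(test_x)
        cc = fit_cc(mld, DT, random_state=0).predict(test_x)
        agree_br = (br[:, 0] == br[:, 1]).mean()
        agree_cc = (cc[:, 0] == cc[:, 1]).mean()
        assert agree_cc >= agree_br
        assert agree_cc > 0.95


class TestLabelPowerset:
    def test_closed_world_predictions(self):
        rng = np.random.default_rng(7)
        labels = np.array([[0, 0], [1, 1]] * 30, dtype=np.int8)
        features = labels[:, :1] * 4 + rng.normal(size=(60, 1))
        mld = MultiLabelDataset(features, labels, ("a", "b"), ("x",))
        model = fit_lp(mld, DT, random_state=0)
        pred = model.predict(rng.normal(size=(50, 1)))
        for row in pred:
            assert list(row) in ([0, 0], [1, 1])

    def test_class_space_is_distinct_combinations(self, example_records):
        model = fit_lp(example_records, DT, random_state=0)
        assert model.labelsets.shape[0] == 5  # DC of the example records

    def test_scores_aggregate_class_confidences(self):
        mld = blobs_mld(8)
        model = fit_lp(mld, DT, random_state=0)
        x = mld.features[:5]
        conf = model.class_confidences(x)
        np.testing.assert_allclose(
            model.predict_scores(x), conf @ model.labelsets.astype(float))


class TestRakel:
    def test_reduces_to_lp_when_k_equals_q(self):
        mld = blobs_mld(9)
        lp = fit_lp(mld, DT, random_state=0)
        rakel = fit_rakel(mld, DT, labelset_size=3, n_models=1,
                          random_state=0)
        x = blobs_mld(10).features
        np.testing.assert_array_equal(lp.predict(x), rakel.predict(x))

    def test_k_larger_than_q_rejected(self):
        with pytest.raises(ValueError):
            fit_rakel(blobs_mld(0), DT, labelset_size=4)

    def test_default_ensemble_covers_all_labels(self):
        mld = generate_mld(frailty_like_preset(300, 11))
        model = fit_rakel(mld, DT, labelset_size=3, n_models=12,
                          random_state=1)
        assert (model.coverage > 0).all()
        scores = model.predict_scores(mld.features[:20])
        assert ((scores >= 0) & (scores <= 1)).all()


class TestClr:
    def test_component_counts(self):
        mld2 = blobs_mld(12, q=2)
        model2 = fit_clr(mld2, DT, random_state=0)
        assert len(model2.pairwise) == 1 and len(model2.calibration) == 2
        mld6 = generate_mld(frailty_like_preset(300, 13))
        model6 = fit_clr(mld6, DT, random_state=0)
        assert len(model6.pairwise) == 15 and len(model6.calibration) == 6

    def test_dominant_label_ranked_first(self):
        rng = np.random.default_rng(14)
        # instances with a single clearly indicated label
        labels = np.zeros((150, 3), dtype=np.int8)
        labels[np.arange(150), np.arange(150) % 3] = 1
        features = labels * 5.0 + rng.normal(size=(150, 3))
        mld = MultiLabelDataset(features, labels,
                                ("a", "b", "c"), ("x", "y", "z"))
        model = fit_clr(mld, DT, random_state=0)
        scores = model.predict_scores(features)
        assert (scores.argmax(axis=1) == labels.argmax(axis=1)).mean() > 0.9


class TestMlknn:
    def test_memorized_neighborhood_predicts_label(self):
        rng = np.random.default_rng(15)
        labels = np.array([[1, 0]] * 10 + [[0, 1]] * 10, dtype=np.int8)
        features = np.vstack([rng.normal(0, 0.2, size=(10, 2)),
                              rng.normal(8, 0.2, size=(10, 2))])
        mld = MultiLabelDataset(features, labels, ("a", "b"), ("x", "y"))
        model = fit_mlknn(mld, k_neighbors=3)
        pred = model.predict(features)
        np.testing.assert_array_equal(pred, labels)

    def test_priors_follow_smoothing_formula(self):
        mld = blobs_mld(16, m=50)
        model = fit_mlknn(mld, k_neighbors=5, smoothing=1.0)
        counts = mld.labels.sum(axis=0)
        np.testing.assert_allclose(model.prior_pos,
                                   (1 + counts) / (2 + 50))

    def test_hand_computed_bayes_table_four_points(self):
        # 4 training points on a line, k=1, s=1, one label
        features = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([[1], [1], [0], [0]], dtype=np.int8)
        mld = MultiLabelDataset(features, labels, ("a",), ("x",))
        model = fit_mlknn(mld, k_neighbors=1, smoothing=1.0)
        # priors: (1+2)/(2+4) = 1/2
        # LOO neighbour counts: points 0,1 see each other (count 1);
        # points 2,3 see each other (count 0)
        # lik_pos = (1 + [0,2])/(1*2 + 2) = [1/4, 3/4]
        # lik_neg = (1 + [2,0])/(1*2 + 2) = [3/4, 1/4]
        np.testing.assert_allclose(model.prior_pos, [0.5])
        np.testing.assert_allclose(model.lik_pos[0], [0.25, 0.75])
        np.testing.assert_allclose(model.lik_neg[0], [0.75, 0.25])
        # query near the positive pair: neighbour count 1
        # posterior = .5*.75 / (.5*.75 + .5*.25) = 0.75
        score = model.predict_scores(np.array([[0.5]]))
        assert score[0, 0] == pytest.approx(0.75)
        # query near the negative pair: count 0 -> posterior 0.25
        score = model.predict_scores(np.array([[10.5]]))
        assert score[0, 0] == pytest.approx(0.25)

    def test_k_must_be_less_than_m(self):
        with pytest.raises(ValueError):
            fit_mlknn(blobs_mld(0, m=5), k_neighbors=5)


class TestRunExperiment:
    def test_baseline_leaves_data_untouched_and_is_deterministic(self):
        mld = generate_mld(frailty_like_preset(400, 17))
        kw = dict(resampler="none", strategies=("br",), base=DT, folds=2,
                  seed=3)
        r1 = run_experiment(mld, **kw)
        r2 = run_experiment(mld, **kw)
        assert r1["config"]["n_train"] == r1["config"]["n_train_resampled"]
        assert r1["test"] == r2["test"] and r1["cv"] == r2["cv"]

    def test_resampling_applied_only_to_training(self):
        mld = generate_mld(frailty_like_preset(500, 18))
        r = run_experiment(mld, resampler="tlsmote", strategies=("br",),
                           base=DT, folds=2, seed=4, test_fraction=0.4)
        assert r["config"]["n_test"] == 200
        assert r["config"]["n_train_resampled"] != r["config"]["n_train"]

    def test_report_carries_std_across_strategies(self):
        mld = generate_mld(frailty_like_preset(400, 19))
        r = run_experiment(mld, strategies=("br", "mlknn"), base=DT,
                           folds=2, seed=5)
        for split in ("cv", "test"):
            assert set(r[f"{split}_std"]) == {"auroc", "ap", "f1", "hl", "rl"}


class TestAverageRank:
    # Published multi-model AP table: four datasets x six models
    AP = pd.DataFrame(
        {
            "hybrid": [0.79, 0.62, 0.79, 0.75, 0.83, 0.72],
            "oversampled": [0.73, 0.64, 0.70, 0.67, 0.75, 0.70],
            "undersampled": [0.58, 0.65, 0.50, 0.50, 0.53, 0.62],
            "base": [0.62, 0.51, 0.43, 0.57, 0.55, 0.64],
        },
        index=["BR", "CC", "LP", "RAkEL", "CLR", "MLkNN"],
    )

    def test_reproduces_published_rank_cells(self):
        ranks = {
            col: pd.Series(
                np.asarray(
                    __import__("scipy.stats", fromlist=["rankdata"])
                    .rankdata(-self.AP[col])),
                index=self.AP.index)
            for col in self.AP
        }
        expected = {
            "base": [2, 5, 6, 3, 4, 1],
            "undersampled": [3, 1, 5.5, 5.5, 4, 2],
            "oversampled": [2, 6, 3.5, 5, 1, 3.5],
            "hybrid": [2.5, 6, 2.5, 4, 1, 5],
        }
        for col, cells in expected.items():
            assert list(ranks[col]) == cells

    def test_reproduces_published_average_ranks(self):
        r = average_rank(self.AP)
        assert r["BR"] == pytest.approx(2.375)
        assert r["CC"] == pytest.approx(4.5)
        assert r["LP"] == pytest.approx(4.375)
        assert r["RAkEL"] == pytest.approx(4.375)
        assert r["CLR"] == pytest.approx(2.5)
        assert r["MLkNN"] == pytest.approx(2.875)

    def test_full_tie_gives_midrank(self):
        table = pd.DataFrame({"d1": [0.5, 0.5, 0.5], "d2": [0.2, 0.2, 0.2]},
                             index=list("abc"))
        assert (average_rank(table) == 2.0).all()

    def test_empty_or_incomplete_table_rejected(self):
        with pytest.raises(ValueError):
            average_rank(pd.DataFrame())
        with pytest.raises(ValueError):
            average_rank(pd.DataFrame({"d": [1.0, np.nan]}))
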