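import numpy as np
import pandas as pd
import pytest

from conftest import random_sequence
from thermoprot._lstm import LSTMClassifier
from thermoprot.modeling import (
    ModelSpec,
    SequenceFeaturizer,
    ThermophilicityClassifier,
    TrainedModel,
    build_default_pipeline,
    cross_validate,
    make_classifier,
    predict_table,
    train,
)
from thermoprot.sequence_io import SequenceRecord, SequenceSet, write_fasta
from thermoprot.synthetic_data import GeneratorConfig, effect_from_size, generate
from thermoprot.tabular_prep import FeatureMatrix


def separable_matrix(rng, n=40, d=6):
    """Two well-separated Gaussian clusters as a FeatureMatrix."""
    X = np.vstack([rng.normal(0, 0.3, (n // 2, d)), rng.normal(4, 0.3, (n // 2, d))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    ids = [f"r{i}" for i in range(n)]
    return FeatureMatrix(
        pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(d)]),
        {"all": (0, d)},
        pd.Series(y, index=ids),
    )


@pytest.fixture
def labelled_set(rng):
    cfg = GeneratorConfig(
        n_pos=40, n_neg=40, length_range=(40, 80), effect=effect_from_size(0.15), seed=3
    )
    s, _ = generate(cfg)
    return s


# a cheap estimator configuration for unit tests (full recipe is
# exercised in the acceptance tests)
FAST = dict(
    descriptors=("AAC", "GAAC", "DPC"),
    string_dim=64,
    hyperparameters={"n_estimators": 30},
)


class TestModelFamilies:
    @pytest.mark.parametrize("family", ["bagging", "random_forest", "gradient_boosting"])
    def test_tree_families_fit_separable_data(self, rng, family):
        M = separable_matrix(rng)
        model = make_classifier(ModelSpec(family=family, seed=0))
        model.fit(M.values, M.labels)
        assert (model.predict(M.values) == M.labels).all()

    def test_determinism_same_seed(self, rng):
        M = separable_matrix(rng, n=60)
        a = make_classifier(ModelSpec("gradient_boosting", seed=4)).fit(M.values, M.labels)
        b = make_classifier(ModelSpec("gradient_boosting", seed=4)).fit(M.values, M.labels)
        np.testing.assert_array_equal(
            a.predict_proba(M.values), b.predict_proba(M.values)
        )

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown model family"):
            make_classifier(ModelSpec("svm"))


class TestLSTM:
    def test_fits_separable_tabular_data(self, rng):
        M = separable_matrix(rng, n=30, d=4)
        clf = LSTMClassifier(hidden=8, epochs=40, batch_size=8, lr=0.02, seed=0)
        clf.fit(M.values, M.labels)
        assert (clf.predict(M.values) == M.labels).mean() >= 0.9
        proba = clf.predict_proba(M.values)
        assert proba.min() >= 0 and proba.max() <= 1
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_deterministic_given_seed(self, rng):
        M = separable_matrix(rng, n=20, d=3)
        a = LSTMClassifier(hidden=6, epochs=5, seed=9).fit(M.values, M.labels)
        b = LSTMClassifier(hidden=6, epochs=5, seed=9).fit(M.values, M.labels)
        np.testing.assert_array_equal(a._scores(M.values), b._scores(M.values))

    def test_sequence_mode_one_hot(self):
        seqs = ["ACDEF" * 8, "KLMNP" * 8] * 6
        y = [0, 1] * 6
        clf = LSTMClassifier(hidden=6, epochs=8, max_len=20, mode="sequence", seed=1)
        clf.fit(seqs, y)
        assert clf.predict_proba(seqs).shape == (12, 2)

    def test_single_class_raises(self, rng):
        M = separable_matrix(rng, n=10)
        with pytest.raises(ValueError, match="both classes"):
            LSTMClassifier(epochs=1).fit(M.values, np.zeros(10))


class TestFeaturizer:
    def test_block_layout(self, labelled_set):
        feat = SequenceFeaturizer(descriptors=("AAC", "GAAC"), seed=0)
        M = feat.fit(labelled_set).transform(labelled_set)
        assert list(M.blocks) == ["AAC", "GAAC"]
        assert M.shape == (80, 25)
        assert M.labels is not None

    def test_string_block_appended(self, labelled_set):
        from thermoprot.string_features import StringScheme

        feat = SequenceFeaturizer(
            descriptors=("AAC",),
            string_scheme=StringScheme(kind="hashed_ngrams", dim=32),
            seed=0,
        )
        M = feat.fit(labelled_set).transform(labelled_set)
        assert list(M.blocks) == ["AAC", "str_feature"]
        assert M.columns[-1] == "str_feature.feature_31"


class TestPipelineEstimator:
    def test_fit_predict_on_sequences(self, labelled_set):
        est = ThermophilicityClassifier(seed=0, **FAST)
        est.fit(labelled_set)
        p = est.decision_scores(labelled_set)
        assert p.shape == (80,)
        assert ((p >= 0) & (p <= 1)).all()
        assert (est.predict(labelled_set) == (p >= 0.5).astype(int)).all()

    def test_full_determinism(self, labelled_set):
        a = ThermophilicityClassifier(seed=1, **FAST).fit(labelled_set)
        b = ThermophilicityClassifier(seed=1, **FAST).fit(labelled_set)
        np.testing.assert_array_equal(
            a.decision_scores(labelled_set), b.decision_scores(labelled_set)
        )

    def test_no_leakage_from_test_labels(self, rng, labelled_set):
        est = ThermophilicityClassifier(seed=0, **FAST).fit(labelled_set)
        test = SequenceSet(
            [SequenceRecord(f"q{i}", random_sequence(rng, 50), label=int(i % 2)) for i in range(10)]
        )
        p1 = est.decision_scores(test)
        shuffled = SequenceSet(
            [SequenceRecord(r.id, r.sequence, label=1 - r.label) for r in test]
        )
        p2 = est.decision_scores(shuffled)
        np.testing.assert_array_equal(p1, p2)

    def test_selection_budget_applied(self, labelled_set):
        est = ThermophilicityClassifier(
            seed=0, select_method="f_classif", select_param=50, **FAST
        )
        est.fit(labelled_set)
        assert len(est.feature_columns_) == 50

    def test_single_class_rejected(self, rng):
        recs = [SequenceRecord(f"s{i}", random_sequence(rng, 30), label=1) for i in range(10)]
        with pytest.raises(ValueError, match="both classes"):
            ThermophilicityClassifier(seed=0, **FAST).fit(SequenceSet(recs))


class TestCrossValidate:
    def test_fold_partition_and_sizes(self, rng):
        M = separable_matrix(rng, n=100)
        est = ThermophilicityClassifier(smote=False, seed=0, hyperparameters={"n_estimators": 10})
        res = cross_validate(est, M, n_folds=10, seed=0)
        folds = pd.Series(res.fold_assignment)
        assert sorted(folds.index) == sorted(M.ids)
        assert (folds.value_counts() == 10).all()

    def test_stratification_within_one(self, rng):
        M = separable_matrix(rng, n=60)
        est = ThermophilicityClassifier(smote=False, seed=0, hyperparameters={"n_estimators": 10})
        res = cross_validate(est, M, n_folds=5, seed=1)
        y = pd.Series(M.labels, index=M.ids)
        for f in range(5):
            ids = [i for i, v in res.fold_assignment.items() if v == f]
            assert abs(y.loc[ids].sum() - 6) <= 1

    def test_different_fold_counts_same_coverage(self, rng):
        M = separable_matrix(rng, n=40)
        est = ThermophilicityClassifier(smote=False, seed=0, hyperparameters={"n_estimators": 5})
        r2 = cross_validate(est, M, n_folds=2, seed=3)
        r5 = cross_validate(est, M, n_folds=5, seed=3)
        assert sorted(r2.fold_assignment) == sorted(r5.fold_assignment)
        assert r2.fold_assignment != r5.fold_assignment

    def test_too_many_folds_raises(self, rng):
        M = separable_matrix(rng, n=10)
        est = ThermophilicityClassifier(seed=0)
        with pytest.raises(ValueError, match="minority"):
            cross_validate(est, M, n_folds=6, seed=0)

    def test_aggregate_statistics(self, rng):
        M = separable_matrix(rng, n=60)
        est = ThermophilicityClassifier(smote=False, seed=0, hyperparameters={"n_estimators": 10})
        res = cross_validate(est, M, n_folds=5, seed=0)
        assert res.mean["AUROC"] == pytest.approx(
            np.mean([r.AUROC for r in res.reports])
        )


class TestDefaultRecipe:
    def test_recipe_contract(self):
        cfg = build_default_pipeline(seed=7)
        assert len(cfg["feature_blocks"]) == 15
        assert cfg["feature_blocks"][-1] == "str_feature"
        assert cfg["scaler"] == "minmax"
        assert cfg["cv_folds"] == 5
        assert cfg["family"] == "gradient_boosting"
        assert cfg["smote"] is True


class TestTrainPredictSurface:
    def test_train_wrapper_and_bundle_roundtrip(self, rng, tmp_path, labelled_set):
        feat = SequenceFeaturizer(descriptors=("AAC", "GAAC"), seed=0)
        M = feat.fit(labelled_set).transform(labelled_set)
        bundle = train(ModelSpec("random_forest", {"n_estimators": 20}, seed=0), M)
        bundle.estimator.featurizer_ = feat
        bundle.save(tmp_path / "model")
        loaded = TrainedModel.load(tmp_path / "model")
        np.testing.assert_array_equal(
            bundle.estimator.decision_scores(M), loaded.estimator.decision_scores(M)
        )
        assert loaded.manifest["family"] == "random_forest"

    def test_predict_table_rejects_invalid_rows(self, rng, tmp_path, labelled_set):
        est = ThermophilicityClassifier(seed=0, **FAST).fit(labelled_set)
        query = SequenceSet(
            [
                SequenceRecord("good", random_sequence(rng, 40)),
                SequenceRecord("short", "MKV"),
                SequenceRecord("bad", "X" * 30),
            ]
        )
        fasta = tmp_path / "query.fasta"
        write_fasta(query, fasta)
        table = predict_table(est, fasta)
        assert len(table) == 3
        assert list(table["status"]) == ["OK", "REJECTED", "REJECTED"]
        assert table.loc[0, "predicted"] in ("TP", "NTP")
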