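"""Classifier construction, training, prediction, persistence, grid search."""

import numpy as np
import pytest

from ednacnn.augment import AugmentConfig
from ednacnn.model import (
    ConvSpec,
    ModelConfig,
    build,
    grid_search,
    train,
)
from ednacnn.refdb import ReferenceDB, ReferenceRecord


class TestModelConfig:
    def test_published_optima_build(self):
        # split-evaluation optimum: 1 conv x 4 filters (7x4), 3 dense x 128, C=156
        a = ModelConfig(n_classes=156, conv_layers=[ConvSpec(4)],
                        dense_layers=[128, 128, 128])
        # full-data optimum: 1 conv x 4 filters, 2 dense x 384, C=368
        b = ModelConfig(n_classes=368, conv_layers=[ConvSpec(4)],
                        dense_layers=[384, 384])
        for cfg in (a, b):
            clf = build(cfg, seed=0)
            assert clf.net.n_parameters() > 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(conv_layers=[]),
            dict(conv_layers=[ConvSpec(4)] * 4),
            dict(conv_layers=[ConvSpec(3)]),
            dict(conv_layers=[ConvSpec(17)]),
            dict(dense_layers=[]),
            dict(dense_layers=[10, 10, 10, 10]),
            dict(dropout_rate=1.0),
            dict(n_classes=0),
        ],
    )
    def test_out_of_range_configs_rejected(self, kwargs):
        base = dict(n_classes=5)
        base.update(kwargs)
        if "n_classes" in kwargs:
            base["n_classes"] = kwargs["n_classes"]
        with pytest.raises(ValueError):
            ModelConfig(**base)

    def test_dict_roundtrip(self):
        cfg = ModelConfig(n_classes=7, conv_layers=[ConvSpec(8), ConvSpec(4, (7, 1), True)])
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestPredictProba:
    def test_untrained_outputs_probability_rows(self, toy_db):
        clf = build(ModelConfig(n_classes=toy_db.n_classes), seed=0)
        seqs = [r.sequence for r in toy_db.records[:5]]
        probs = clf.predict_proba(seqs)
        assert probs.shape == (5, toy_db.n_classes)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_duplicate_inputs_identical_rows(self, toy_classifier, toy_db):
        s = toy_db.records[0].sequence
        probs = toy_classifier.predict_proba([s, s])
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_invalid_read_skipped_as_nan_row(self, toy_classifier):
        probs = toy_classifier.predict_proba(["ACGT" * 15, "ACXT" * 15])
        assert not np.isnan(probs[0]).any()
        assert np.isnan(probs[1]).all()


class TestTraining:
    def test_separable_classes_learned(self, toy_classifier, toy_db):
        seqs = [r.sequence for r in toy_db.records]
        truth = np.array([toy_db.label_index[r.species] for r in toy_db.records])
        probs = toy_classifier.predict_proba(seqs)
        assert (probs.argmax(axis=1) == truth).mean() >= 0.95

    def test_zero_epochs_leaves_weights_unchanged(self, toy_db):
        clf = build(ModelConfig(n_classes=toy_db.n_classes), seed=1)
        before = clf.net.get_weights()
        train(clf, toy_db, AugmentConfig.none(), epochs=0, seed=1)
        for b, a in zip(before, clf.net.get_weights()):
            np.testing.assert_array_equal(b, a)

    def test_single_species_degenerate_but_defined(self):
        db = ReferenceDB([ReferenceRecord("r", "only", "ACGTACGTACGT")])
        cfg = ModelConfig(n_classes=1, dense_layers=[8], input_width=16)
        clf = build(cfg, dict(db.label_index), seed=0)
        train(clf, db, AugmentConfig.none(target_width=16), epochs=2, seed=0)
        probs = clf.predict_proba(["ACGTACGTACGT"])
        assert probs.argmax(axis=1)[0] == 0
        np.testing.assert_allclose(probs.sum(), 1.0)

    def test_training_deterministic_given_seed(self, toy_db):
        res = []
        for _ in range(2):
            clf = build(ModelConfig(n_classes=toy_db.n_classes, dense_layers=[32]),
                        dict(toy_db.label_index), seed=5)
            train(clf, toy_db, AugmentConfig.training(), epochs=3, seed=5)
            res.append(clf.predict_proba([toy_db.records[0].sequence]))
        np.testing.assert_array_equal(res[0], res[1])

    def test_empty_db_rejected(self):
        clf = build(ModelConfig(n_classes=2), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(clf, ReferenceDB([]), AugmentConfig.none(), epochs=1)


class TestPersistence:
    def test_roundtrip_bit_identical_predictions(self, toy_classifier, toy_db, tmp_path):
        toy_classifier.save(tmp_path / "ckpt")
        from ednacnn.model import TrainedClassifier

        back = TrainedClassifier.load(tmp_path / "ckpt")
        seqs = [r.sequence for r in toy_db.records[:8]]
        np.testing.assert_array_equal(
            toy_classifier.predict_proba(seqs), back.predict_proba(seqs)
        )
        assert back.label_index == toy_classifier.label_index


class TestGridSearch:
    def test_single_config_returned_with_report(self, toy_db):
        from ednacnn.refdb import split_train_holdout

        tr, ho = split_train_holdout(toy_db, seed=0)
        cfg = ModelConfig(n_classes=tr.n_classes, dense_layers=[32])
        best, report = grid_search([cfg], tr, ho, AugmentConfig.none(), seed=0, epochs=5)
        assert best is cfg
        assert len(report) == 1

    def test_separable_architectures_ranked_by_holdout(self, toy_db):
        from ednacnn.refdb import split_train_holdout

        tr, ho = split_train_holdout(toy_db, seed=0)
        good = ModelConfig(n_classes=tr.n_classes, dense_layers=[64])
        tiny = ModelConfig(n_classes=tr.n_classes, dense_layers=[1])
        best, report = grid_search(
            [tiny, good], tr, ho, AugmentConfig.none(), seed=0, epochs=15
        )
        assert len(report) == 2
        assert best is good
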