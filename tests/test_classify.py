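"""Split protocol, model training, evaluation and selection."""

import numpy as np
import pytest

from chloromotion.dataset import CLASSES, LabeledSpectraSet
from chloromotion.classify import (
    ModelSpec,
    SplitPlan,
    avoidance_vs_rest_accuracy,
    cross_species_eval,
    evaluate,
    make_splits,
    model_select,
    train_model,
)
from chloromotion.errors import ProtocolError
from chloromotion.synthsim import generate_class_spectra


@pytest.fixture(scope="module")
def small_ds():
    return LabeledSpectraSet.concat(
        [
            generate_class_spectra("nicotiana", cls, 12, seed=50 + i, blocks_per_leaf=3)
            for i, cls in enumerate(CLASSES)
        ]
    )


class TestModelSpec:
    def test_rejects_unknown_family_and_kernel(self):
        with pytest.raises(ValueError):
            ModelSpec(family="forest")
        with pytest.raises(ValueError):
            ModelSpec(family="svm", svm_kernel="cubic")

    def test_rejects_nonmonotone_cnn_shapes(self):
        from chloromotion._nn import build_cnn

        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="decreasing"):
            build_cnn(160, (5, 7), (8, 16), (16, 3), rng)
        with pytest.raises(ValueError, match="increasing"):
            build_cnn(160, (7, 5), (16, 8), (16, 3), rng)

    def test_default_cnn_parameter_budget(self):
        assert ModelSpec(family="cnn").n_parameters(160) < 100_000


class TestMakeSplits:
    def test_counts_and_leaf_grouping(self, small_ds):
        plan = SplitPlan(seed=1)
        splits = make_splits(small_ds, plan)
        leaf_ids = small_ds.leaf_ids()
        test_leaves = set(leaf_ids[splits.test_idx])
        assert len(test_leaves) == 9  # 25% of 12 leaves per class, 3 classes
        # no test leaf appears anywhere in the CV folds
        for repeat in splits.folds:
            for train_idx, val_idx in repeat:
                assert not (set(leaf_ids[train_idx]) & test_leaves)
                assert not (set(leaf_ids[val_idx]) & test_leaves)
                assert not (set(leaf_ids[train_idx]) & set(leaf_ids[val_idx]))

    def test_folds_cover_all_training_leaves(self, small_ds):
        splits = make_splits(small_ds, SplitPlan(seed=1))
        leaf_ids = small_ds.leaf_ids()
        all_leaves = set(leaf_ids) - set(leaf_ids[splits.test_idx])
        covered = set()
        for train_idx, val_idx in splits.folds[0]:
            covered |= set(leaf_ids[val_idx])
        assert covered == all_leaves

    def test_deterministic_for_seed(self, small_ds):
        a = make_splits(small_ds, SplitPlan(seed=7))
        b = make_splits(small_ds, SplitPlan(seed=7))
        np.testing.assert_array_equal(a.test_idx, b.test_idx)
        np.testing.assert_array_equal(a.folds[3][2][1], b.folds[3][2][1])

    def test_too_few_leaves_raises(self):
        tiny = LabeledSpectraSet.concat(
            [generate_class_spectra("nicotiana", cls, 3, seed=5) for cls in CLASSES]
        )
        with pytest.raises(ValueError, match="fewer than k"):
            make_splits(tiny, SplitPlan())


class TestTrainModel:
    def test_linear_svm_separates_separable_toy(self, rng):
        # two linearly separable synthetic shape classes
        X = np.vstack(
            [
                rng.normal(0.0, 0.05, size=(10, 8)) + [1, 1, 1, 1, 0, 0, 0, 0],
                rng.normal(0.0, 0.05, size=(10, 8)) + [0, 0, 0, 0, 1, 1, 1, 1],
            ]
        )
        y = np.array(["dark"] * 10 + ["avoidance"] * 10)
        model = train_model(ModelSpec(family="svm"), (X, y), seed=0)
        assert (model.predict(X) == y).mean() == 1.0

    def test_single_class_training_raises(self):
        ds = generate_class_spectra("nicotiana", "dark", 4, seed=1)
        with pytest.raises(ValueError, match="2 classes"):
            train_model(ModelSpec(family="svm"), ds)

    def test_svm_deterministic_for_seed(self, small_ds):
        a = train_model(ModelSpec(family="svm"), small_ds, seed=3)
        b = train_model(ModelSpec(family="svm"), small_ds, seed=3)
        X = small_ds.features()
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_mlp_deterministic_and_learns(self, small_ds):
        spec = ModelSpec(family="mlp", epochs=60)
        a = train_model(spec, small_ds, seed=3)
        b = train_model(spec, small_ds, seed=3)
        X = small_ds.features()
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        assert (a.predict(X) == small_ds.y()).mean() > 0.7

    def test_probabilities_sum_to_one(self, small_ds):
        model = train_model(ModelSpec(family="mlp", epochs=20), small_ds, seed=0)
        p = model.predict_proba(small_ds.features())
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


class TestEvaluate:
    def test_perfect_classifier_identity_matrix(self, small_ds):
        model = train_model(ModelSpec(family="svm"), small_ds, seed=0)
        # evaluate on training data: linearly separable classes, near-identity
        cm = evaluate(model, small_ds)
        assert cm.recall("avoidance") == 1.0
        np.testing.assert_allclose(cm.mean.sum(axis=1), 1.0, atol=1e-9)

    def test_label_permutation_recall_near_chance(self, small_ds):
        """Shuffled-label training shows no real avoidance skill on fresh data."""
        fresh = LabeledSpectraSet.concat(
            [
                generate_class_spectra("nicotiana", cls, 10, seed=900 + i, blocks_per_leaf=2)
                for i, cls in enumerate(CLASSES)
            ]
        )
        y = list(small_ds.labels)
        recalls = []
        for rep in range(5):
            perm = np.random.default_rng(rep).permutation(len(y))
            shuffled = LabeledSpectraSet(
                small_ds.spectra, [y[i] for i in perm], small_ds.meta.copy()
            )
            model = train_model(ModelSpec(family="svm"), shuffled, seed=rep)
            recalls.append(evaluate(model, fresh).recall("avoidance"))
        # mean over permutations hovers near the 1/3 chance level
        assert 0.05 <= float(np.mean(recalls)) <= 0.65

    def test_repeat_training_reports_spread(self, small_ds):
        spec = ModelSpec(family="mlp", epochs=15)
        cm = evaluate(spec, small_ds, train=small_ds, n_repeats=3, seed=0)
        assert cm.n_repeats == 3
        assert cm.sd.shape == (3, 3)
        rows = cm.counts.sum(axis=1)
        assert rows.sum() == 3 * len(small_ds)

    def test_missing_class_row_is_nan(self, small_ds):
        two = small_ds.subset(np.asarray(small_ds.labels) != "dark")
        model = train_model(ModelSpec(family="svm"), small_ds, seed=0)
        cm = evaluate(model, two)
        assert np.isnan(cm.mean[CLASSES.index("dark")]).all()


class TestCrossSpecies:
    def test_species_overlap_raises(self, small_ds):
        with pytest.raises(ProtocolError, match="overlap"):
            cross_species_eval(ModelSpec(family="svm"), small_ds, small_ds)

    def test_cross_species_transfer(self, small_ds):
        arab = LabeledSpectraSet.concat(
            [
                generate_class_spectra("arabidopsis", cls, 8, seed=60 + i, blocks_per_leaf=2)
                for i, cls in enumerate(CLASSES)
            ]
        )
        cm = cross_species_eval(ModelSpec(family="svm"), small_ds, arab, seed=0)
        # desk-scale sanity on a 12-leaf training set; the full-protocol
        # bound is asserted in the end-to-end suite
        assert cm.recall("avoidance") >= 0.8
        assert cm.recall("avoidance") >= cm.recall("accumulation")


class TestModelSelect:
    def test_strictly_better_spec_wins(self):
        a, b = ModelSpec(family="svm"), ModelSpec(family="svm", svm_kernel="rbf")
        assert model_select([(a, 0.9), (b, 0.95)]) is b

    def test_tie_breaks_toward_fewer_parameters(self):
        small = ModelSpec(family="mlp", mlp_layers=(8, 3))
        big = ModelSpec(family="mlp", mlp_layers=(30, 20, 3))
        assert model_select([(big, 0.9), (small, 0.9)]) is small

    def test_empty_search_space_raises(self):
        with pytest.raises(ValueError):
            model_select([])

    def test_svm_kernel_ranking_has_five_rows(self, small_ds):
        from chloromotion.classify import SVM_KERNELS

        results = []
        X, y = small_ds.features(), small_ds.y()
        for kernel in SVM_KERNELS:
            model = train_model(ModelSpec(family="svm", svm_kernel=kernel), small_ds, seed=0)
            results.append((model.spec, (model.predict(X) == y).mean()))
        assert len(results) == 5
        assert model_select(results).family == "svm"
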