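"""Spectral classifiers for chloroplast positioning.

Three model families classify L2-normalised reflectance spectra
(400-750 nm) into dark / accumulation / avoidance: a support vector
machine (five kernel choices), a small multilayer perceptron (21-10-3,
batch-norm + ReLU between layers) and a four-block 1-D convolutional
network (decreasing kernel widths, increasing feature maps, max-pool of
width 5 and stride 2 per block, then a 64/32/16/3 dense head). Neural
families minimise the multinomial negative log-likelihood with Adam at
batch size 64.

Splitting is always grouped by leaf: block spectra augment within a leaf,
so pooling a leaf's blocks across partitions would leak. The protocol is a
fixed stratified 25% leaf-level test set, then repeated balanced k-fold
cross-validation of the remainder for hyperparameter selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.svm import SVC

from . import _nn
from .dataset import CLASSES, LabeledSpectraSet
from .errors import ProtocolError

logger = logging.getLogger(__name__)

SVM_KERNELS = ("linear", "poly3", "poly4", "sigmoid", "rbf")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one classifier."""

    family: str = "svm"  # svm | mlp | cnn
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    mlp_layers: tuple[int, ...] = (21, 10, 3)
    conv_widths: tuple[int, ...] = (11, 9, 7, 5)
    feature_maps: tuple[int, ...] = (8, 16, 32, 64)
    dense_sizes: tuple[int, ...] = (64, 32, 16, 3)
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.family not in ("svm", "mlp", "cnn"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "svm" and self.svm_kernel not in SVM_KERNELS:
            raise ValueError(f"unknown SVM kernel {self.svm_kernel!r}")
        if self.family == "mlp" and self.mlp_layers[-1] != 3:
            raise ValueError("final MLP layer width must be 3")
        if self.family == "cnn":
            if self.dense_sizes[-1] != 3:
                raise ValueError("final dense layer width must be 3")
            if len(self.conv_widths) != len(self.feature_maps):
                raise ValueError("conv widths and feature maps must pair up")

    def n_parameters(self, n_in: int) -> int:
        """Trainable parameter count for an ``n_in``-band input."""
        if self.family == "svm":
            return n_in  # proxy: one weight per feature
        rng = np.random.default_rng(0)
        net = _build_net(self, n_in, rng)
        return sum(p.size for layer in net.layers for p in layer.params())


def _build_net(spec: ModelSpec, n_in: int, rng: np.random.Generator) -> _nn.SequentialNet:
    if spec.family == "mlp":
        return _nn.build_mlp(n_in, spec.mlp_layers, rng)
    return _nn.build_cnn(n_in, spec.conv_widths, spec.feature_maps, spec.dense_sizes, rng)


def _net_input(X: np.ndarray, family: str) -> np.ndarray:
    """Condition features for the neural families.

    L2-normalised spectra have per-band magnitude ~1/sqrt(n_bands);
    rescaling by sqrt(n_bands) keeps activations (and hence batch-norm
    statistics) at unit order, which the shape of the features does not
    change.
    """
    Xs = X * np.sqrt(X.shape[1])
    return Xs[:, None, :] if family == "cnn" else Xs


class TrainedClassifier:
    """Uniform prediction surface over the three families.

    ``classes_`` lists the class labels in the canonical order restricted
    to those present in training; ``predict_proba`` returns calibrated
    probabilities (Platt scaling for the SVM, softmax for the networks).
    """

    def __init__(self, spec: ModelSpec, classes: tuple[str, ...], impl):
        self.spec = spec
        self.classes_ = classes
        self._impl = impl

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.spec.family == "svm":
            proba = self._impl.predict_proba(X)
            order = [list(self._impl.classes_).index(c) for c in self.classes_]
            return proba[:, order]
        return self._impl.predict_proba(_net_input(X, self.spec.family))

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.spec.family == "svm":
            # decision-function prediction; Platt-scaled probabilities can
            # disagree with the margin on small training sets
            return self._impl.predict(X)
        idx = self.predict_proba(X).argmax(axis=1)
        return np.asarray(self.classes_)[idx]


def train_model(
    spec: ModelSpec,
    train: LabeledSpectraSet | tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    epochs: int | None = None,
) -> TrainedClassifier:
    """Fit one classifier; reproducible for a fixed seed.

    ``train`` is either a labeled spectra set (features are L2-normalised
    truncated spectra) or a precomputed ``(X, y)`` pair. ``epochs``
    overrides the spec for the neural families (the full protocol uses
    2000; the default spec uses 200, which these synthetic classes
    saturate well before).
    """
    if isinstance(train, LabeledSpectraSet):
        X, y = train.features(), train.y()
    else:
        X, y = train
        y = np.asarray(y)
    present = tuple(c for c in CLASSES if c in set(y))
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 classes")

    if spec.family == "svm":
        kernel_kwargs = {
            "linear": {"kernel": "linear"},
            "poly3": {"kernel": "poly", "degree": 3},
            "poly4": {"kernel": "poly", "degree": 4},
            "sigmoid": {"kernel": "sigmoid"},
            "rbf": {"kernel": "rbf"},
        }[spec.svm_kernel]
        impl = SVC(C=spec.svm_c, probability=True, random_state=seed, **kernel_kwargs)
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=FutureWarning)
            impl.fit(X, y)
        return TrainedClassifier(spec, present, impl)

    rng = np.random.default_rng(seed)
    net = _build_net(spec, X.shape[1], rng)
    # the net head is width 3; with 2 classes present only 2 outputs get mass
    y_index = np.array([CLASSES.index(c) for c in y])
    Xn = _net_input(X, spec.family)
    net.fit(
        Xn,
        y_index,
        n_classes=3,
        epochs=epochs if epochs is not None else spec.epochs,
        batch_size=spec.batch_size,
        lr=spec.learning_rate,
        rng=rng,
    )
    return TrainedClassifier(spec, CLASSES, net)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Test fraction + repeated k-fold protocol, grouped by leaf."""

    test_fraction: float = 0.25
    k_folds: int = 5
    repeats: int = 10
    seed: int = 0


@dataclass
class SplitResult:
    test_idx: np.ndarray  # spectrum indices
    folds: list[list[tuple[np.ndarray, np.ndarray]]]  # [repeat][fold] -> (train, val)


def make_splits(ds: LabeledSpectraSet, plan: SplitPlan) -> SplitResult:
    """Stratified leaf-level test split, then repeated balanced k-folds.

    All spectra of one leaf always land in the same partition. Each class
    must contribute at least ``k_folds`` leaves.
    """
    leaf_ids = ds.leaf_ids()
    y = ds.y()
    leaves = {}
    for lid, cls in zip(leaf_ids, y):
        if leaves.setdefault(lid, cls) != cls:
            raise ValueError(f"leaf {lid!r} carries more than one class label")
    leaf_arr = np.array(list(leaves))
    cls_arr = np.array([leaves[l] for l in leaf_arr])
    for cls in np.unique(cls_arr):
        if (cls_arr == cls).sum() < plan.k_folds:
            raise ValueError(f"class {cls!r} has fewer than k={plan.k_folds} leaves")

    rng = np.random.default_rng(plan.seed)
    test_leaves = []
    for cls in np.unique(cls_arr):
        members = leaf_arr[cls_arr == cls]
        n_test = max(1, round(plan.test_fraction * members.size))
        test_leaves.extend(rng.choice(members, size=n_test, replace=False))
    test_leaves = set(test_leaves)
    rest_leaves = np.array([l for l in leaf_arr if l not in test_leaves])
    rest_cls = np.array([leaves[l] for l in rest_leaves])

    folds_all = []
    for _ in range(plan.repeats):
        # balanced folds: assign each class's shuffled leaves round-robin
        fold_of = {}
        for cls in np.unique(rest_cls):
            members = rest_leaves[rest_cls == cls]
            members = members[rng.permutation(members.size)]
            for pos, leaf in enumerate(members):
                fold_of[leaf] = pos % plan.k_folds
        repeat_folds = []
        for f in range(plan.k_folds):
            val_leaves = {l for l, ff in fold_of.items() if ff == f}
            train_leaves = {l for l in fold_of if l not in val_leaves}
            train_idx = np.nonzero([l in train_leaves for l in leaf_ids])[0]
            val_idx = np.nonzero([l in val_leaves for l in leaf_ids])[0]
            repeat_folds.append((train_idx, val_idx))
        folds_all.append(repeat_folds)

    test_idx = np.nonzero([l in test_leaves for l in leaf_ids])[0]
    return SplitResult(test_idx=test_idx, folds=folds_all)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Row-normalised 3x3 confusion (rows = true class) with repeat spread."""

    classes: tuple[str, ...]
    counts: np.ndarray  # summed over repeats
    mean: np.ndarray  # mean row-normalised proportions
    sd: np.ndarray
    n_repeats: int

    def recall(self, cls: str) -> float:
        i = self.classes.index(cls)
        return float(self.mean[i, i])

    def off_diagonal_mass(self, cls: str) -> float:
        """Mean probability of misclassifying a true ``cls`` spectrum."""
        i = self.classes.index(cls)
        return float(self.mean[i].sum() - self.mean[i, i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.mean, index=list(self.classes), columns=list(self.classes))


def _confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    counts = np.zeros((len(CLASSES), len(CLASSES)))
    for t, p in zip(y_true, y_pred):
        counts[CLASSES.index(t), CLASSES.index(p)] += 1
    return counts


def _row_normalise(counts: np.ndarray) -> np.ndarray:
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, counts / sums, np.nan)


def evaluate(
    model_or_spec: TrainedClassifier | ModelSpec,
    test: LabeledSpectraSet,
    train: LabeledSpectraSet | None = None,
    n_repeats: int = 20,
    seed: int = 0,
    epochs: int | None = None,
) -> ConfusionMatrix:
    """Confusion matrix on a test set; retrains per repeat if given a spec.

    With a :class:`ModelSpec`, the model is retrained ``n_repeats`` times
    with different seeds on ``train`` and the per-cell mean ± SD of the
    row-normalised confusion is reported. A missing true class in the test
    set leaves its row as NaN with a warning.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    X_test, y_test = test.features(), test.y()
    missing = set(CLASSES) - set(y_test)
    if missing:
        logger.warning("test set lacks class(es) %s; rows undefined", sorted(missing))

    if isinstance(model_or_spec, TrainedClassifier):
        counts = _confusion_counts(y_test, model_or_spec.predict(X_test))
        props = _row_normalise(counts)
        return ConfusionMatrix(CLASSES, counts, props, np.zeros_like(props), 1)

    if train is None:
        raise ValueError("evaluating a ModelSpec requires a training set")
    all_props, total = [], np.zeros((3, 3))
    for rep in range(n_repeats):
        model = train_model(model_or_spec, train, seed=seed + rep, epochs=epochs)
        counts = _confusion_counts(y_test, model.predict(X_test))
        total += counts
        all_props.append(_row_normalise(counts))
    stack = np.stack(all_props)
    return ConfusionMatrix(CLASSES, total, stack.mean(axis=0), stack.std(axis=0), n_repeats)


def cross_species_eval(
    spec: ModelSpec,
    train_species: LabeledSpectraSet,
    test_species: LabeledSpectraSet,
    n_repeats: int = 1,
    seed: int = 0,
    epochs: int | None = None,
) -> ConfusionMatrix:
    """Train on one species' spectra and evaluate on another's.

    The species sets must be disjoint — the point is generalisation across
    species, so any overlap is a protocol violation.
    """
    sp_train = set(train_species.meta.get("species", []))
    sp_test = set(test_species.meta.get("species", []))
    if not sp_train or not sp_test:
        raise ProtocolError("both sets must carry species provenance")
    if sp_train & sp_test:
        raise ProtocolError(f"species overlap between train and test: {sp_train & sp_test}")
    return evaluate(spec, test_species, train=train_species, n_repeats=n_repeats,
                    seed=seed, epochs=epochs)


def avoidance_vs_rest_accuracy(
    model: TrainedClassifier, test: LabeledSpectraSet, positive: str = "avoidance"
) -> float:
    """Binary accuracy of the one-vs-rest reduction of the 3-class output."""
    pred = model.predict(test.features())
    truth = test.y()
    return float(np.mean((pred == positive) == (truth == positive)))


def model_select(cv_results: list[tuple[ModelSpec, float]], n_in: int = 160) -> ModelSpec:
    """Pick the spec with the best mean validation accuracy.

    Ties (within 1e-12) break toward the model with fewer parameters.
    """
    if not cv_results:
        raise ValueError("empty search space")
    best_acc = max(acc for _, acc in cv_results)
    tied = [spec for spec, acc in cv_results if abs(acc - best_acc) < 1e-12]
    return min(tied, key=lambda s: s.n_parameters(n_in))
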