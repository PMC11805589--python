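"""Classify chloroplast positioning from leaf spectra.

Trains a linear SVM and the 21-10-3 multilayer perceptron on L2-normalised
400-750 nm spectra (60 leaves per class, 10 block spectra per leaf, split
25% of leaves into a held-out test set) and evaluates both on the same
species and on the other species preset. The 1-D CNN follows the same API
(family="cnn") but trains for a few minutes on a laptop CPU, so this
example sticks to the two fast families.
"""

import numpy as np

from chloromotion.dataset import CLASSES, LabeledSpectraSet
from chloromotion.classify import (
    ModelSpec,
    SplitPlan,
    avoidance_vs_rest_accuracy,
    evaluate,
    make_splits,
    train_model,
)
from chloromotion.synthsim import generate_class_spectra


def build(species, seed, n_leaves, blocks):
    return LabeledSpectraSet.concat(
        [
            generate_class_spectra(species, cls, n_leaves, seed=seed + 97 * i, blocks_per_leaf=blocks)
            for i, cls in enumerate(CLASSES)
        ]
    )


full = build("nicotiana", 7, 60, 10)
splits = make_splits(full, SplitPlan(seed=7))
train = full.subset(np.setdiff1d(np.arange(len(full)), splits.test_idx))
test = full.subset(splits.test_idx)
arabidopsis = build("arabidopsis", 1007, 20, 6)
print(f"train {len(train)} / test {len(test)} spectra; cross-species test {len(arabidopsis)}")

for family in ("svm", "mlp"):
    model = train_model(ModelSpec(family=family), train, seed=7)
    same = avoidance_vs_rest_accuracy(model, test)
    cross = avoidance_vs_rest_accuracy(model, arabidopsis)
    cm = evaluate(model, test)
    print(f"\n{family.upper()}: avoidance-vs-rest accuracy {100*same:.1f}% (same species), "
          f"{100*cross:.1f}% (cross-species)")
    print("row-normalised confusion (rows = true class):")
    print(cm.to_frame().round(2))
print("\navoidance is recognised almost perfectly; dark vs accumulation overlap")
print("(leaves differ in their resting chloroplast arrangement) keeps those")
print("two classes harder apart, as in real measurements.")
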