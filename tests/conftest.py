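import numpy as np
import pytest

from chloromotion.dataset import CLASSES, LabeledSpectraSet
from chloromotion.hypercube_io import default_grid
from chloromotion.spectra import ReflectanceSpectrum
from chloromotion.synthsim import GeneratorConfig, generate_class_spectra, generate_scene_cube


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_spectrum(grid, rng, lo=0.01, hi=0.6):
    return ReflectanceSpectrum(grid, rng.uniform(lo, hi, size=len(grid)))


@pytest.fixture(scope="session")
def scene_cube():
    """Raw-DN whole-leaf scene (WT, high light) plus ground truth."""
    cfg = GeneratorConfig(species="nicotiana", genotype="WT", condition="high", seed=42)
    return generate_scene_cube(cfg)


@pytest.fixture(scope="session")
def three_class_sets():
    """Small per-class spectra sets (both species) shared across tests."""
    out = {}
    for species in ("nicotiana", "arabidopsis"):
        for cls in CLASSES:
            out[(species, cls)] = generate_class_spectra(
                species, cls, n_leaves=15, seed=100 + 13 * CLASSES.index(cls)
            )
    return out


def combined(sets, species="nicotiana"):
    return LabeledSpectraSet.concat([sets[(species, c)] for c in CLASSES])
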