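"""Region spectra, block augmentation, normalisation, differential curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chloromotion.hypercube_io import SpectralCube, WavelengthGrid, default_grid
from chloromotion.spectra import (
    DifferentialSpectrum,
    ReflectanceSpectrum,
    differential_spectrum,
    find_spectral_features,
    mean_spectrum,
    normalize_truncate,
    sample_blocks,
)
from chloromotion.synthsim import differential_template


@pytest.fixture
def refl_cube(rng):
    grid = WavelengthGrid(np.linspace(400, 900, 8))
    data = rng.uniform(0.05, 0.5, size=(20, 24, 8))
    return SpectralCube(data, grid, kind="reflectance")


class TestMeanSpectrum:
    def test_single_pixel_mask(self, refl_cube):
        mask = np.zeros((20, 24), dtype=bool)
        mask[3, 5] = True
        s = mean_spectrum(refl_cube, mask)
        np.testing.assert_array_equal(s.values, refl_cube.data[3, 5])

    def test_uniform_cube(self, refl_cube):
        cube = SpectralCube(
            np.full_like(refl_cube.data, 0.2), refl_cube.grid, kind="reflectance"
        )
        s = mean_spectrum(cube, np.ones((20, 24), dtype=bool))
        np.testing.assert_allclose(s.values, 0.2)

    def test_empty_mask_raises(self, refl_cube):
        with pytest.raises(ValueError, match="empty"):
            mean_spectrum(refl_cube, np.zeros((20, 24), dtype=bool))


class TestSampleBlocks:
    def test_contract_and_determinism(self, refl_cube):
        mask = np.ones((20, 24), dtype=bool)
        a = sample_blocks(refl_cube, mask, n_blocks=10, block_px=5, seed=3)
        b = sample_blocks(refl_cube, mask, n_blocks=10, block_px=5, seed=3)
        assert len(a) == 10
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.values, sb.values)
            assert sa.provenance["block_row"] == sb.provenance["block_row"]

    def test_block_mean_matches_manual(self, refl_cube):
        mask = np.ones((20, 24), dtype=bool)
        (s,) = sample_blocks(refl_cube, mask, n_blocks=1, block_px=4, seed=0)
        r, c = s.provenance["block_row"], s.provenance["block_col"]
        manual = refl_cube.data[r : r + 4, c : c + 4].reshape(-1, 8).mean(axis=0)
        np.testing.assert_allclose(s.values, manual)

    def test_blocks_lie_in_pixel_hull(self, refl_cube):
        """Block means stay inside the componentwise min/max of masked pixels."""
        mask = np.ones((20, 24), dtype=bool)
        lo = refl_cube.data.reshape(-1, 8).min(axis=0)
        hi = refl_cube.data.reshape(-1, 8).max(axis=0)
        for s in sample_blocks(refl_cube, mask, n_blocks=20, block_px=6, seed=1):
            assert np.all(s.values >= lo - 1e-12) and np.all(s.values <= hi + 1e-12)

    def test_blocks_fully_inside_irregular_mask(self, refl_cube):
        mask = np.zeros((20, 24), dtype=bool)
        mask[2:12, 3:13] = True
        for s in sample_blocks(refl_cube, mask, n_blocks=15, block_px=5, seed=2):
            r, c = s.provenance["block_row"], s.provenance["block_col"]
            assert mask[r : r + 5, c : c + 5].all()

    def test_oversized_block_raises(self, refl_cube):
        mask = np.zeros((20, 24), dtype=bool)
        mask[:10, :10] = True
        with pytest.raises(ValueError, match="smaller block_px"):
            sample_blocks(refl_cube, mask, n_blocks=1, block_px=60, seed=0)


class TestNormalizeTruncate:
    def test_scale_invariance_and_unit_norm(self, grid, rng):
        v = rng.uniform(0.01, 0.5, size=len(grid))
        a = normalize_truncate(ReflectanceSpectrum(grid, v))
        b = normalize_truncate(ReflectanceSpectrum(grid, 2.0 * v))
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert abs(np.linalg.norm(a) - 1.0) < 1e-12

    def test_default_band_count(self, grid, rng):
        v = rng.uniform(0.01, 0.5, size=len(grid))
        # bands with centers in [400, 750] on the 2.2 nm grid: 400.0 .. 749.8
        assert normalize_truncate(ReflectanceSpectrum(grid, v)).size == 160

    def test_idempotence(self, grid, rng):
        v = rng.uniform(0.01, 0.5, size=len(grid))
        once = normalize_truncate(ReflectanceSpectrum(grid, v))
        sub = WavelengthGrid(grid.wavelengths[grid.band_slice(400, 750)])
        twice = normalize_truncate(ReflectanceSpectrum(sub, once))
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_zero_norm_raises(self, grid):
        with pytest.raises(ValueError, match="zero"):
            normalize_truncate(ReflectanceSpectrum(grid, np.zeros(len(grid))))


class TestDifferentialSpectrum:
    def _pairs(self, grid, rng, n):
        pairs = []
        for _ in range(n):
            dk = ReflectanceSpectrum(grid, rng.uniform(0.05, 0.2, size=len(grid)))
            ir = ReflectanceSpectrum(grid, rng.uniform(0.05, 0.2, size=len(grid)))
            pairs.append((dk, ir))
        return pairs

    def test_identical_halves_zero_curve(self, grid, rng):
        s = ReflectanceSpectrum(grid, rng.uniform(0.05, 0.2, size=len(grid)))
        ds = differential_spectrum([(s, s)] * 5)
        np.testing.assert_allclose(ds.mean_diff, 0.0)
        np.testing.assert_allclose(ds.sd, 0.0)

    def test_antisymmetry(self, grid, rng):
        pairs = self._pairs(grid, rng, 6)
        fwd = differential_spectrum(pairs)
        rev = differential_spectrum([(ir, dk) for dk, ir in pairs])
        np.testing.assert_array_equal(fwd.mean_diff, -rev.mean_diff)

    def test_se_definition_and_n(self, grid, rng):
        pairs = self._pairs(grid, rng, 8)
        ds = differential_spectrum(pairs)
        assert ds.n == 8
        np.testing.assert_allclose(ds.se, ds.sd / np.sqrt(8))

    def test_single_leaf_convention(self, grid, rng):
        pairs = self._pairs(grid, rng, 1)
        ds = differential_spectrum(pairs)
        np.testing.assert_allclose(ds.sd, 0.0)
        np.testing.assert_allclose(ds.se, 0.0)

    def test_mismatched_grids_raise(self, grid, rng):
        other = WavelengthGrid(grid.wavelengths + 1.0)
        a = ReflectanceSpectrum(grid, np.full(len(grid), 0.1))
        b = ReflectanceSpectrum(other, np.full(len(other), 0.1))
        with pytest.raises(ValueError, match="grid"):
            differential_spectrum([(a, b)])


class TestSpectralFeatures:
    def test_monotone_curve_has_no_extrema(self, grid):
        ds = DifferentialSpectrum(grid, np.linspace(0, 1, len(grid)), np.zeros(len(grid)), 1)
        assert find_spectral_features(ds) == []

    def test_avoidance_template_fluorescence_features(self):
        """High-light differential curve: trough near 684 nm, peak near 695 nm."""
        for species in ("nicotiana", "arabidopsis"):
            feats = find_spectral_features(differential_template(species, "avoidance"))
            troughs = [w for w, t in feats if t == "trough" and 675 <= w <= 692]
            peaks = [w for w, t in feats if t == "peak" and 690 <= w <= 700]
            assert troughs and abs(troughs[0] - 684.0) <= 2.2
            assert peaks and abs(peaks[0] - 695.0) <= 2.2

    def test_accumulation_template_green_yellow_minimum(self):
        """Low-light differential curve dips in 500-600 nm, never above zero."""
        for species in ("nicotiana", "arabidopsis"):
            ds = differential_template(species, "accumulation")
            w_min = ds.grid.wavelengths[np.argmin(ds.mean_diff)]
            assert 500 <= w_min <= 600
            assert ds.mean_diff.max() <= 0.0

    def test_features_sorted_by_wavelength(self):
        feats = find_spectral_features(differential_template("nicotiana", "avoidance"))
        ws = [w for w, _ in feats]
        assert ws == sorted(ws)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_normalize_truncate_scale_invariance_property(seed):
    grid = default_grid()
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.01, 0.8, size=len(grid))
    c = rng.uniform(0.1, 10.0)
    a = normalize_truncate(ReflectanceSpectrum(grid, v))
    b = normalize_truncate(ReflectanceSpectrum(grid, c * v))
    np.testing.assert_allclose(a, b, atol=1e-10)
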