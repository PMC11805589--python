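"""Synthetic generator: genotype map, calibration targets, scenes."""

import numpy as np
import pytest

from chloromotion.hypercube_io import calibrate_reflectance, default_grid
from chloromotion.indices import cmi, vegetation_index
from chloromotion.leafscene import exclude_veins, segment_leaf, split_halves
from chloromotion.spectra import ReflectanceSpectrum, mean_spectrum
from chloromotion.synthsim import (
    CONDITIONS,
    GENOTYPES,
    PRESETS,
    GeneratorConfig,
    differential_template,
    generate_class_spectra,
    generate_spectra,
    positioning_for,
)


class TestPositioningMap:
    @pytest.mark.parametrize(
        "genotype,condition,expected",
        [
            ("WT", "dark", "dark"),
            ("WT", "low", "accumulation"),
            ("WT", "high", "avoidance"),
            ("phot1", "low", "accumulation"),
            ("phot1", "high", "avoidance"),
            ("phot2", "low", "accumulation"),
            ("phot2", "high", "accumulation"),
            ("phot1phot2", "low", "dark"),
            ("phot1phot2", "high", "dark"),
            ("jac1", "low", "avoidance"),
            ("jac1", "high", "avoidance"),
            ("jac1", "dark", "dark"),
        ],
    )
    def test_genotype_response(self, genotype, condition, expected):
        assert positioning_for(genotype, condition) == expected

    def test_unknown_genotype_raises(self):
        with pytest.raises(KeyError):
            positioning_for("phot3", "low")

    def test_all_combinations_resolve(self):
        for g in GENOTYPES:
            for c in CONDITIONS:
                assert positioning_for(g, c) in ("dark", "accumulation", "avoidance")


class TestTemplates:
    def test_base_positive_and_class_sums_positive(self, grid):
        for preset in PRESETS.values():
            base = preset.base(grid)
            assert base.min() > 0
            for cls in ("accumulation", "avoidance"):
                assert (base + preset.class_effect(cls, grid)).min() > 0

    def test_visible_mean_near_eleven_percent(self, grid):
        vis = grid.window_indices(400, 700)
        for preset in PRESETS.values():
            assert 0.08 <= preset.base(grid)[vis].mean() <= 0.14

    def test_avoidance_minus_accumulation_offset(self, grid):
        vis = grid.window_indices(400, 700)
        for preset in PRESETS.values():
            diff = (preset.avoidance_effect(grid) - preset.accumulation_effect(grid))[vis]
            assert 0.015 <= diff.mean() <= 0.03

    def test_template_cmi_calibration(self, grid):
        """Dark CMI in the reported band; avoidance raises it, accumulation not."""
        for preset in PRESETS.values():
            base = ReflectanceSpectrum(grid, preset.base(grid))
            c_dark = cmi(base)
            assert -0.45 <= c_dark <= -0.1
            c_av = cmi(ReflectanceSpectrum(grid, preset.base(grid) + preset.avoidance_effect(grid)))
            c_acc = cmi(
                ReflectanceSpectrum(grid, preset.base(grid) + preset.accumulation_effect(grid))
            )
            assert c_av > c_dark
            assert c_acc <= c_dark + 5e-3  # lowers or preserves

    def test_dark_template_is_zero(self):
        ds = differential_template("nicotiana", "dark")
        np.testing.assert_array_equal(ds.mean_diff, 0.0)

    def test_index_effect_directions(self, grid):
        """Avoidance lowers NDVI and raises SG/VOG2/VOG3 (as between halves)."""
        for preset in PRESETS.values():
            dark = ReflectanceSpectrum(grid, preset.base(grid))
            av = ReflectanceSpectrum(grid, preset.base(grid) + preset.avoidance_effect(grid))
            assert vegetation_index(av, "NDVI") < vegetation_index(dark, "NDVI")
            for name in ("SG", "VOG2", "VOG3"):
                assert vegetation_index(av, name) > vegetation_index(dark, name)


class TestGenerateSpectra:
    def test_seed_reproducibility(self):
        cfg = GeneratorConfig(seed=5, condition="high")
        a = generate_spectra(cfg, 4, blocks_per_leaf=3)
        b = generate_spectra(cfg, 4, blocks_per_leaf=3)
        for sa, sb in zip(a.spectra, b.spectra):
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_labels_follow_genotype_map(self):
        ds = generate_spectra(GeneratorConfig(genotype="jac1", condition="low", seed=1), 3)
        assert set(ds.labels) == {"avoidance"}

    def test_law_of_large_numbers_on_dark_mean(self, grid):
        """Mean of N dark spectra converges to the base template ~ 1/sqrt(N)."""
        base = PRESETS["nicotiana"].base(grid)
        errs = []
        for n in (10, 100, 1000):
            # average over replicates: a single draw's error is itself noisy
            reps = []
            for rep in range(5):
                ds = generate_class_spectra("nicotiana", "dark", n, seed=31 + 1000 * rep)
                mean = np.stack([s.values for s in ds.spectra]).mean(axis=0)
                reps.append(np.abs(mean - base).mean())
            errs.append(np.mean(reps))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < errs[0] / 3

    def test_blocks_share_leaf_level_draws(self):
        ds = generate_spectra(GeneratorConfig(seed=2), 2, blocks_per_leaf=4)
        leaf_ids = ds.meta["leaf_id"]
        assert leaf_ids.nunique() == 2
        within = ds.spectra[0].values - ds.spectra[1].values
        across = ds.spectra[0].values - ds.spectra[4].values
        assert np.abs(within).mean() < np.abs(across).mean()

    def test_generated_cmi_within_reported_band(self):
        for species in PRESETS:
            for cls in ("dark", "accumulation", "avoidance"):
                ds = generate_class_spectra(species, cls, 20, seed=9)
                vals = [cmi(s) for s in ds.spectra]
                assert min(vals) >= -0.45 and max(vals) <= -0.1


class TestSceneCube:
    def test_calibration_recovers_half_spectra(self, scene_cube):
        cube, truth = scene_cube
        refl = calibrate_reflectance(cube, truth["references"])
        for half, key in (("darkened", "dark_spectrum"), ("irradiated", "irradiated_spectrum")):
            rec = mean_spectrum(refl, truth[half]).values
            assert np.abs(rec - truth[key]).max() < 0.01

    def test_white_disk_calibrates_to_one(self, scene_cube):
        cube, truth = scene_cube
        refl = calibrate_reflectance(cube, truth["references"])
        assert abs(refl.data[truth["white"]].mean() - 1.0) < 0.01

    def test_segmentation_recovers_leaf(self, scene_cube):
        cube, truth = scene_cube
        refl = calibrate_reflectance(cube, truth["references"])
        mask = segment_leaf(refl)
        recovered = (mask & truth["leaf"]).sum() / truth["leaf"].sum()
        assert recovered >= 0.99

    def test_vein_mostly_excluded_at_default_threshold(self, scene_cube):
        cube, truth = scene_cube
        refl = calibrate_reflectance(cube, truth["references"])
        mask = segment_leaf(refl)
        _, excluded = exclude_veins(refl, mask)
        frac = (excluded & truth["vein"]).sum() / truth["vein"].sum()
        assert frac >= 0.9

    def test_auto_split_balanced_on_symmetric_leaf(self, scene_cube):
        cube, truth = scene_cube
        refl = calibrate_reflectance(cube, truth["references"])
        mask = segment_leaf(refl)
        a, b = split_halves(mask, "auto")
        assert abs(a.sum() - b.sum()) / mask.sum() < 0.02
        assert not (a & b).any()
        assert ((a | b) ^ mask).sum() / mask.sum() < 0.02  # only the line pixels differ
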