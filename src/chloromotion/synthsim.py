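"""Synthetic leaf reflectance spectra and whole-leaf scenes.

No hyperspectral data ship with the package, so this module generates
spectra and scenes with the statistical structure reported for blue-light
chloroplast-movement experiments:

* dark-adapted leaves reflect ~11% in the visible (400-700 nm);
* the avoidance (high-light) arrangement brightens leaves broadly, with a
  green-yellow "saddle" (500-600 nm), a fluorescence-quenching trough near
  684 nm, a peak near 695 nm and a steep decline over 700-745 nm;
* the accumulation (low-light) arrangement darkens the green-yellow region;
* the avoidance minus accumulation visible-mean difference is ~2.3%.

The class-effect curves are additive in reflectance. Their lobe amplitudes
were fitted once, by numerical search, so that the visible-mean offset and
the NDVI / RGRI between-half differences reproduce the magnitudes above,
and then frozen as the preset constants below; they are not tuned per run.

Leaf-to-leaf variability uses a small hierarchy: a multiplicative
brightness factor, a response-amplitude jitter, a resting-arrangement
jitter along the accumulation-effect direction (dark-adapted leaves differ
in how accumulated their chloroplasts rest, which is what makes the dark
vs accumulation classes genuinely overlap), smooth pigment noise, and
per-band sensor noise shrinking with the pixel count averaged per spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import CLASSES, LabeledSpectraSet
from .hypercube_io import ReferenceRegions, SpectralCube, WavelengthGrid, default_grid
from .spectra import DifferentialSpectrum, ReflectanceSpectrum

GENOTYPES = ("WT", "phot1", "phot2", "phot1phot2", "jac1")
CONDITIONS = ("dark", "low", "high")  # dark-adapted, 1.6 and 120 umol m-2 s-1 blue


def _gauss(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SpeciesPreset:
    """Frozen spectral-template constants for one species.

    The base curve is a diffuse green-leaf spectrum: visible baseline, a
    green bump near 550 nm, a blue absorption well, and a sigmoid red edge
    rising to the NIR plateau. Avoidance is modelled as blue and red
    brightening humps over a low pedestal (the gap between the humps is the
    green-yellow saddle), cut off by a steep decline past 700 nm, plus the
    two narrow fluorescence-quenching features. Accumulation is a
    proportional darkening of the green-yellow window.
    """

    name: str
    # base curve
    baseline: float
    green_amp: float
    green_center: float
    green_sigma: float
    bluewell_amp: float
    bluewell_center: float
    bluewell_sigma: float
    nir_plateau: float
    red_edge_center: float
    red_edge_width: float
    # avoidance effect (fitted once against the target magnitudes, then frozen)
    av_pedestal: float
    av_blue_amp: float
    av_blue_center: float
    av_blue_sigma: float
    av_red_amp: float
    av_red_center: float
    av_red_sigma: float
    av_rise_center: float
    av_rise_width: float
    av_decline_center: float
    av_decline_width: float
    fluor_trough_amp: float
    fluor_trough_nm: float
    fluor_peak_amp: float
    fluor_peak_nm: float
    # accumulation effect
    acc_depth: float
    acc_window_lo: float
    acc_window_hi: float
    acc_window_width: float

    def base(self, grid: WavelengthGrid) -> np.ndarray:
        lam = grid.wavelengths
        return (
            self.baseline
            + self.green_amp * _gauss(lam, self.green_center, self.green_sigma)
            - self.bluewell_amp * _gauss(lam, self.bluewell_center, self.bluewell_sigma)
            + self.nir_plateau
            * _logistic((lam - self.red_edge_center) / self.red_edge_width)
        )

    def avoidance_effect(self, grid: WavelengthGrid) -> np.ndarray:
        lam = grid.wavelengths
        envelope = _logistic((lam - self.av_rise_center) / self.av_rise_width) * _logistic(
            (self.av_decline_center - lam) / self.av_decline_width
        )
        smooth = envelope * (
            self.av_pedestal
            + self.av_blue_amp * _gauss(lam, self.av_blue_center, self.av_blue_sigma)
            + self.av_red_amp * _gauss(lam, self.av_red_center, self.av_red_sigma)
        )
        fluor = -self.fluor_trough_amp * _gauss(lam, self.fluor_trough_nm, 3.2) + (
            self.fluor_peak_amp * _gauss(lam, self.fluor_peak_nm, 3.3)
        )
        return smooth + fluor

    def accumulation_effect(self, grid: WavelengthGrid) -> np.ndarray:
        lam = grid.wavelengths
        window = _logistic((lam - self.acc_window_lo) / self.acc_window_width) * _logistic(
            (self.acc_window_hi - lam) / self.acc_window_width
        )
        return -self.acc_depth * self.base(grid) * window

    def class_effect(self, positioning: str, grid: WavelengthGrid) -> np.ndarray:
        if positioning == "dark":
            return np.zeros(len(grid))
        if positioning == "accumulation":
            return self.accumulation_effect(grid)
        if positioning == "avoidance":
            return self.avoidance_effect(grid)
        raise KeyError(f"unknown positioning class {positioning!r}")


# Frozen preset constants. Base-curve green amplitudes put the dark-adapted
# visible (400-700 nm) mean at 0.11; avoidance/accumulation lobe amplitudes
# come from the one-off numerical fit described in the module docstring.
NICOTIANA = SpeciesPreset(
    name="nicotiana",
    baseline=0.075,
    green_amp=0.115134,
    green_center=550.0,
    green_sigma=42.0,
    bluewell_amp=0.030,
    bluewell_center=460.0,
    bluewell_sigma=30.0,
    nir_plateau=0.40,
    red_edge_center=715.0,
    red_edge_width=9.0,
    av_pedestal=0.009137,
    av_blue_amp=0.011696,
    av_blue_center=455.000000,
    av_blue_sigma=34.000000,
    av_red_amp=0.027706,
    av_red_center=632.000000,
    av_red_sigma=24.0,
    av_rise_center=412.0,
    av_rise_width=10.0,
    av_decline_center=722.0,
    av_decline_width=9.0,
    fluor_trough_amp=0.0040,
    fluor_trough_nm=684.0,
    fluor_peak_amp=0.0035,
    fluor_peak_nm=695.0,
    acc_depth=0.069767,
    acc_window_lo=490.0,
    acc_window_hi=720.0,
    acc_window_width=18.0,
)

ARABIDOPSIS = SpeciesPreset(
    name="arabidopsis",
    baseline=0.074000,
    green_amp=0.114083,
    green_center=552.0,
    green_sigma=42.000000,
    bluewell_amp=0.028,
    bluewell_center=455.0,
    bluewell_sigma=28.0,
    nir_plateau=0.380000,
    red_edge_center=714.000000,
    red_edge_width=9.500000,
    av_pedestal=0.009137,
    av_blue_amp=0.011696,
    av_blue_center=455.000000,
    av_blue_sigma=34.000000,
    av_red_amp=0.027707,
    av_red_center=632.000000,
    av_red_sigma=24.000000,
    av_rise_center=412.0,
    av_rise_width=10.0,
    av_decline_center=721.0,
    av_decline_width=9.0,
    fluor_trough_amp=0.0038,
    fluor_trough_nm=684.0,
    fluor_peak_amp=0.0034,
    fluor_peak_nm=695.0,
    acc_depth=0.069640,
    acc_window_lo=490.0,
    acc_window_hi=720.0,
    acc_window_width=18.0,
)

PRESETS = {"nicotiana": NICOTIANA, "arabidopsis": ARABIDOPSIS}


def positioning_for(genotype: str, condition: str) -> str:
    """Chloroplast positioning class for a genotype x irradiance combination.

    WT and *phot1* respond normally (low light -> accumulation, high ->
    avoidance); *phot2* accumulates regardless of irradiance; *phot1phot2*
    moves nothing; *jac1* avoids at both irradiances. Dark-adapted leaves
    stay in the dark arrangement for every genotype.
    """
    if genotype not in GENOTYPES:
        raise KeyError(f"unknown genotype {genotype!r}; known: {GENOTYPES}")
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; known: {CONDITIONS}")
    if condition == "dark":
        return "dark"
    table = {
        "WT": {"low": "accumulation", "high": "avoidance"},
        "phot1": {"low": "accumulation", "high": "avoidance"},
        "phot2": {"low": "accumulation", "high": "accumulation"},
        "phot1phot2": {"low": "dark", "high": "dark"},
        "jac1": {"low": "avoidance", "high": "avoidance"},
    }
    return table[genotype][condition]


@dataclass
class GeneratorConfig:
    """Study conditions for the spectrum generator.

    ``leaf_brightness_sd`` is the SD of the per-leaf multiplicative
    brightness factor; ``pixel_noise_sd`` the per-band SD of single-pixel
    sensor noise (averaged spectra see it shrunk by 1/sqrt(pixel count));
    ``response_jitter_sd`` scales how strongly an individual leaf expresses
    its class response; ``arrangement_jitter_sd`` is the SD (in units of
    the accumulation effect) of the resting chloroplast arrangement, the
    source of dark/accumulation overlap; ``pigment_noise_sd`` drives two
    smooth per-leaf pigment-variation lobes.
    """

    species: str = "nicotiana"
    genotype: str = "WT"
    condition: str = "dark"
    leaf_brightness_sd: float = 0.05
    pixel_noise_sd: float = 0.005
    response_jitter_sd: float = 0.2
    arrangement_jitter_sd: float = 0.45
    pigment_noise_sd: float = 0.002
    fine_structure_sd: float = 0.004
    fine_structure_scale_nm: float = 18.0
    seed: int = 0
    grid: WavelengthGrid = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        if self.species not in PRESETS:
            raise KeyError(f"unknown species preset {self.species!r}")
        positioning_for(self.genotype, self.condition)  # validate enums
        for name in (
            "leaf_brightness_sd",
            "pixel_noise_sd",
            "response_jitter_sd",
            "arrangement_jitter_sd",
            "pigment_noise_sd",
            "fine_structure_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def preset(self) -> SpeciesPreset:
        return PRESETS[self.species]

    @property
    def positioning(self) -> str:
        return positioning_for(self.genotype, self.condition)


def _fine_structure_factor(cfg: GeneratorConfig) -> np.ndarray | None:
    """Cholesky factor of the squared-exponential fine-structure covariance.

    Each leaf carries a smooth random deviation with correlation length
    ``fine_structure_scale_nm`` — the fine pigment/structure texture that
    makes even neighbouring narrow bands differ between leaves.
    """
    if cfg.fine_structure_sd == 0.0:
        return None
    lam = cfg.grid.wavelengths
    d = lam[:, None] - lam[None, :]
    cov = cfg.fine_structure_sd**2 * np.exp(-0.5 * (d / cfg.fine_structure_scale_nm) ** 2)
    cov[np.diag_indices_from(cov)] += 1e-12
    return np.linalg.cholesky(cov)


def _leaf_spectrum(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    base: np.ndarray,
    acc_eff: np.ndarray,
    effect: np.ndarray,
    fine_chol: np.ndarray | None = None,
) -> np.ndarray:
    """Noiseless per-leaf spectrum: leaf-level draws only, no band noise."""
    lam = cfg.grid.wavelengths
    factor = rng.normal(1.0, cfg.leaf_brightness_sd)
    amp = rng.normal(1.0, cfg.response_jitter_sd)
    resting = rng.normal(0.0, cfg.arrangement_jitter_sd)
    c1, c2 = rng.normal(0.0, cfg.pigment_noise_sd, size=2)
    pigment = c1 * _gauss(lam, 470.0, 55.0) + c2 * _gauss(lam, 610.0, 55.0)
    fine = fine_chol @ rng.standard_normal(len(lam)) if fine_chol is not None else 0.0
    return factor * (base + amp * effect + resting * acc_eff) + pigment + fine


def generate_spectra(
    cfg: GeneratorConfig,
    n_leaves: int,
    blocks_per_leaf: int = 1,
    block_px: int = 60,
) -> LabeledSpectraSet:
    """Generate ``n_leaves`` x ``blocks_per_leaf`` labeled spectra.

    Each leaf gets its own brightness/response/arrangement/pigment draws;
    block spectra within a leaf differ only by sensor noise with per-band
    SD ``pixel_noise_sd / block_px`` (the mean over ``block_px**2``
    pixels). Fully reproducible from ``cfg.seed``.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    preset = cfg.preset
    base = preset.base(cfg.grid)
    acc_eff = preset.accumulation_effect(cfg.grid)
    effect = preset.class_effect(cfg.positioning, cfg.grid)
    fine_chol = _fine_structure_factor(cfg)
    noise_sd = cfg.pixel_noise_sd / block_px  # mean over block_px**2 pixels

    spectra, labels = [], []
    n_clipped = 0
    for leaf in range(n_leaves):
        clean = _leaf_spectrum(cfg, rng, base, acc_eff, effect, fine_chol)
        for block in range(blocks_per_leaf):
            values = clean + rng.normal(0.0, noise_sd, size=len(cfg.grid))
            n_clipped += int((values < 0).sum())
            values = np.clip(values, 0.0, None)
            spectra.append(
                ReflectanceSpectrum(
                    cfg.grid,
                    values,
                    provenance={
                        "leaf_id": f"{cfg.species}-{cfg.genotype}-{cfg.condition}-{cfg.seed}-{leaf}",
                        "species": cfg.species,
                        "genotype": cfg.genotype,
                        "condition": cfg.condition,
                        "block": block,
                    },
                )
            )
            labels.append(cfg.positioning)
    ds = LabeledSpectraSet(spectra, labels)
    ds.meta.attrs["n_clipped_values"] = n_clipped
    return ds


def generate_class_spectra(
    species: str,
    positioning: str,
    n_leaves: int,
    seed: int,
    blocks_per_leaf: int = 1,
    **cfg_kwargs,
) -> LabeledSpectraSet:
    """Convenience wrapper: spectra of one positioning class directly.

    Maps the class to a (genotype, condition) pair that produces it in the
    wild type or, for class-by-construction sampling, uses *jac1* low light
    for avoidance.
    """
    pair = {
        "dark": ("WT", "dark"),
        "accumulation": ("WT", "low"),
        "avoidance": ("WT", "high"),
    }[positioning]
    cfg = GeneratorConfig(
        species=species, genotype=pair[0], condition=pair[1], seed=seed, **cfg_kwargs
    )
    return generate_spectra(cfg, n_leaves, blocks_per_leaf)


def differential_template(
    species: str, positioning: str, grid: WavelengthGrid | None = None
) -> DifferentialSpectrum:
    """Exact noiseless (irradiated − darkened) curve for one class."""
    grid = grid or default_grid()
    effect = PRESETS[species].class_effect(positioning, grid)
    return DifferentialSpectrum(grid, effect, np.zeros(len(grid)), n=1)


# ---------------------------------------------------------------------------
# Whole-leaf scenes
# ---------------------------------------------------------------------------

@dataclass
class LeafScene:
    """Geometry of a synthetic whole-leaf acquisition.

    An elliptical leaf with a single-pixel-wide main vein along its major
    (row) axis on a black-velvet background, plus a white-reference disk.
    """

    rows: int = 180
    cols: int = 180
    leaf_center: tuple[float, float] = (95.0, 88.0)
    leaf_semi_axes: tuple[float, float] = (75.0, 58.0)
    vein_half_width: float = 0.5
    white_center: tuple[float, float] = (18.0, 160.0)
    white_radius: float = 11.0
    background_reflectance: float = 0.012
    dn_white_peak: float = 3000.0
    dn_dark_level: float = 60.0
    dn_noise_sd: float = 8.0

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")

    def leaf_mask(self) -> np.ndarray:
        rr, cc = self.coordinate_grids()
        r0, c0 = self.leaf_center
        ar, ac = self.leaf_semi_axes
        return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0

    def vein_mask(self) -> np.ndarray:
        rr, cc = self.coordinate_grids()
        return self.leaf_mask() & (np.abs(cc - self.leaf_center[1]) <= self.vein_half_width)

    def white_mask(self) -> np.ndarray:
        rr, cc = self.coordinate_grids()
        r0, c0 = self.white_center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.white_radius**2

    def half_masks(self, irradiated_side: str = "right") -> tuple[np.ndarray, np.ndarray]:
        """(darkened, irradiated) masks split along the main vein, vein excluded."""
        if irradiated_side not in ("left", "right"):
            raise ValueError("irradiated_side must be 'left' or 'right'")
        rr, cc = self.coordinate_grids()
        leaf = self.leaf_mask() & ~self.vein_mask()
        right = leaf & (cc > self.leaf_center[1])
        left = leaf & (cc < self.leaf_center[1])
        return (left, right) if irradiated_side == "right" else (right, left)


def generate_scene_cube(
    cfg: GeneratorConfig,
    scene: LeafScene | None = None,
    irradiated_side: str = "right",
) -> tuple[SpectralCube, dict]:
    """Render a raw-DN cube of a half-darkened leaf plus ground-truth masks.

    The darkened half carries the dark arrangement; the irradiated half
    carries ``positioning_for(cfg.genotype, cfg.condition)``. The vein gets
    a red-reflectance boost (high CMI), the background is near-black, and a
    white disk is rendered at the calibration level. DN = dark level +
    reflectance x (white level − dark level) + Gaussian sensor noise.

    Returns ``(raw_cube, truth)`` where ``truth`` has the masks, the
    reference regions and the two noiseless half spectra.
    """
    scene = scene or LeafScene()
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    lam = grid.wavelengths
    preset = cfg.preset
    base = preset.base(grid)
    acc_eff = preset.accumulation_effect(grid)

    fine_chol = _fine_structure_factor(cfg)
    dark_spec = _leaf_spectrum(cfg, rng, base, acc_eff, np.zeros(len(grid)), fine_chol)
    irr_spec = _leaf_spectrum(
        cfg, rng, base, acc_eff, preset.class_effect(cfg.positioning, grid), fine_chol
    )
    vein_boost = 0.12 * _gauss(lam, 640.0, 50.0)

    darkened, irradiated = scene.half_masks(irradiated_side)
    vein = scene.vein_mask()
    leaf = scene.leaf_mask()
    white = scene.white_mask()

    refl = np.empty((scene.rows, scene.cols, len(grid)))
    refl[:] = scene.background_reflectance + 0.01 * _logistic((lam - 750.0) / 40.0)
    refl[darkened] = dark_spec
    refl[irradiated] = irr_spec
    refl[vein] = 0.5 * (dark_spec + irr_spec) + vein_boost
    refl[white] = 1.0

    white_level = scene.dn_white_peak * (0.55 + 0.45 * _gauss(lam, 620.0, 260.0))
    dn = scene.dn_dark_level + refl * (white_level - scene.dn_dark_level)
    dn = dn + rng.normal(0.0, scene.dn_noise_sd, size=dn.shape)
    dn = np.clip(np.round(dn), 0, 65535).astype(np.uint16)

    cube = SpectralCube(
        dn,
        grid,
        kind="raw_dn",
        metadata={"species": cfg.species, "genotype": cfg.genotype, "condition": cfg.condition},
    )
    truth = {
        "leaf": leaf,
        "vein": vein,
        "white": white,
        "darkened": darkened,
        "irradiated": irradiated,
        "references": ReferenceRegions(white, dark_level=scene.dn_dark_level),
        "dark_spectrum": dark_spec,
        "irradiated_spectrum": irr_spec,
    }
    return cube, truth
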