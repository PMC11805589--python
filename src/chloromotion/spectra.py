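"""Region spectra, block augmentation, feature normalisation and
differential reflectance curves.

The central objects are single reflectance spectra (one per pixel, block or
leaf half) and the per-leaf differential curve: the band-wise mean across
leaves of (irradiated − darkened) reflectance, whose shape carries the
chloroplast-positioning signature (a 500-600 nm dip under accumulation; a
broad brightening with a 500-600 nm saddle, a ~684 nm trough and a ~695 nm
peak under avoidance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hypercube_io import SpectralCube, WavelengthGrid

logger = logging.getLogger(__name__)


@dataclass
class ReflectanceSpectrum:
    """One relative-reflectance spectrum on a wavelength grid."""

    grid: WavelengthGrid
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.grid):
            raise ValueError("spectrum length must match grid length")
        if self.values.size and self.values.min() < 0:
            raise ValueError("reflectance values must be non-negative")

    def at(self, target_nm: float) -> float:
        """Reflectance at the nearest band to ``target_nm``."""
        return float(self.values[self.grid.nearest_band(target_nm)])

    def window_mean(self, lo_nm: float, hi_nm: float) -> float:
        """Mean reflectance over all bands with centers in [lo_nm, hi_nm]."""
        idx = self.grid.window_indices(lo_nm, hi_nm)
        if idx.size == 0:
            raise ValueError(f"no bands inside [{lo_nm}, {hi_nm}] nm")
        return float(self.values[idx].mean())


@dataclass
class DifferentialSpectrum:
    """Band-wise mean ± spread of (irradiated − darkened) across n leaves."""

    grid: WavelengthGrid
    mean_diff: np.ndarray
    sd: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.mean_diff = np.asarray(self.mean_diff, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean_diff.size != len(self.grid) or self.sd.size != len(self.grid):
            raise ValueError("differential curve length must match grid")
        if self.n < 1:
            raise ValueError("need at least one leaf")

    @property
    def se(self) -> np.ndarray:
        return self.sd / np.sqrt(self.n)


def mean_spectrum(cube: SpectralCube, mask: np.ndarray, **provenance) -> ReflectanceSpectrum:
    """Arithmetic mean spectrum over the masked pixels of a reflectance cube."""
    if cube.kind != "reflectance":
        raise ValueError("mean_spectrum expects a reflectance cube")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if not mask.any():
        raise ValueError("mask is empty")
    return ReflectanceSpectrum(cube.grid, cube.data[mask].mean(axis=0), provenance)


def sample_blocks(
    cube: SpectralCube,
    mask: np.ndarray,
    n_blocks: int,
    block_px: int = 60,
    seed: int | np.random.Generator = 0,
    **provenance,
) -> list[ReflectanceSpectrum]:
    """Draw ``n_blocks`` square blocks fully inside ``mask`` and average each.

    Block top-left corners are drawn uniformly at random, with replacement,
    from the positions whose entire ``block_px`` × ``block_px`` footprint
    lies inside the mask; each returned spectrum is the mean over the
    block's pixels. Reproducible for a fixed seed.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    valid = _interior_block_positions(mask, block_px)
    if valid[0].size == 0:
        raise ValueError(
            f"no {block_px}x{block_px} block fits inside the mask; "
            "use a smaller block_px"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picks = rng.integers(0, valid[0].size, size=n_blocks)
    out = []
    for k, p in enumerate(picks):
        r, c = int(valid[0][p]), int(valid[1][p])
        block = cube.data[r : r + block_px, c : c + block_px, :]
        prov = dict(provenance)
        prov.update(block_row=r, block_col=c, block_px=block_px, block_index=k)
        out.append(
            ReflectanceSpectrum(cube.grid, block.reshape(-1, block.shape[2]).mean(axis=0), prov)
        )
    return out


def _interior_block_positions(mask: np.ndarray, block_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-left corners whose block_px x block_px footprint is all-True."""
    h, w = mask.shape
    if h < block_px or w < block_px:
        return np.array([], dtype=int), np.array([], dtype=int)
    # 2-D summed-area table: a block is interior iff its sum equals block_px^2
    integral = np.pad(mask.astype(np.int64).cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    b = block_px
    sums = (
        integral[b:, b:]
        - integral[:-b, b:]
        - integral[b:, :-b]
        + integral[:-b, :-b]
    )
    return np.nonzero(sums == b * b)


def normalize_truncate(
    spectrum: ReflectanceSpectrum, lo_nm: float = 400.0, hi_nm: float = 750.0,
    mode: str = "l2",
) -> np.ndarray:
    """Restrict to [lo_nm, hi_nm] (nearest-band endpoints) and normalise.

    L2 normalisation (default) makes classifier features invariant to
    overall brightness, so classifiers see spectral shape only; ``mode`` =
    ``"mean"`` divides by the mean instead.
    """
    sl = spectrum.grid.band_slice(lo_nm, hi_nm)
    v = spectrum.values[sl]
    if mode == "l2":
        norm = float(np.linalg.norm(v))
    elif mode == "mean":
        norm = float(v.mean())
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if norm == 0.0:
        raise ValueError("cannot normalise an all-zero spectrum")
    return v / norm


def differential_spectrum(
    pairs: list[tuple[ReflectanceSpectrum, ReflectanceSpectrum]],
) -> DifferentialSpectrum:
    """Mean/SD/SE across leaves of (irradiated − darkened) reflectance.

    ``pairs`` is a list of (darkened, irradiated) spectra, one pair per
    leaf, all on one grid. With a single leaf the SD (and SE) are zero by
    convention.
    """
    if not pairs:
        raise ValueError("need at least one (darkened, irradiated) pair")
    grid = pairs[0][0].grid
    for dk, ir in pairs:
        if dk.grid != grid or ir.grid != grid:
            raise ValueError("all spectra must share one wavelength grid")
    diffs = np.stack([ir.values - dk.values for dk, ir in pairs])
    n = diffs.shape[0]
    if n == 1:
        logger.warning("differential_spectrum with n=1: SD and SE are 0 by convention")
        sd = np.zeros(diffs.shape[1])
    else:
        sd = diffs.std(axis=0, ddof=1)
    return DifferentialSpectrum(grid, diffs.mean(axis=0), sd, n)


def find_spectral_features(
    ds: DifferentialSpectrum, window_bands: int = 3
) -> list[tuple[float, str]]:
    """Locate strict local extrema of the mean differential curve.

    A band is a peak (trough) if its value is strictly greater (smaller)
    than every band within ±``window_bands``. Returns
    ``[(wavelength_nm, "peak" | "trough"), ...]`` sorted by wavelength;
    endpoints are not eligible.
    """
    y = ds.mean_diff
    w = ds.grid.wavelengths
    if y.size < 2 * window_bands + 1:
        raise ValueError("curve shorter than the extremum window")
    features = []
    for i in range(window_bands, y.size - window_bands):
        neigh = np.concatenate([y[i - window_bands : i], y[i + 1 : i + 1 + window_bands]])
        if np.all(y[i] > neigh):
            features.append((float(w[i]), "peak"))
        elif np.all(y[i] < neigh):
            features.append((float(w[i]), "trough"))
    return features
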