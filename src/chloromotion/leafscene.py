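"""Leaf segmentation, half splitting, vein exclusion and index maps.

Whole-leaf acquisitions show the leaf on black velvet with half of the
blade darkened by foil. Analysis needs four masks: leaf vs background
(NDVI thresholding), the two blade halves (split along the main vein,
which the operator supplies or the principal axis approximates), and a
vein/petiole exclusion (vein tissue has anomalously high CMI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, SegmentationError
from .hypercube_io import SpectralCube
from .indices import INDEX_REGISTRY, evaluate_with_resolvers

logger = logging.getLogger(__name__)


@dataclass
class DividingLine:
    """A line through the blade, as two distinct (row, col) endpoints."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise GeometryError("dividing line endpoints must be distinct")

    def signed_side(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Signed cross-product side of each pixel relative to the line."""
        (r0, c0), (r1, c1) = self.p0, self.p1
        return (r1 - r0) * (cols - c0) - (c1 - c0) * (rows - r0)


def _cube_band_resolvers(cube: SpectralCube):
    """(at, window) resolvers returning per-pixel 2-D arrays."""
    def at(nm: float) -> np.ndarray:
        return cube.data[:, :, cube.grid.nearest_band(nm)].astype(float)

    def window(lo: float, hi: float) -> np.ndarray:
        idx = cube.grid.window_indices(lo, hi)
        if idx.size == 0:
            raise ValueError(f"no bands inside [{lo}, {hi}] nm")
        return cube.data[:, :, idx].astype(float).mean(axis=2)

    return at, window


def ndvi_image(cube: SpectralCube) -> np.ndarray:
    """Per-pixel NDVI from the nearest bands to 800 and 670 nm."""
    at, _ = _cube_band_resolvers(cube)
    nir, red = at(800.0), at(670.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir - red) / (nir + red)
    return np.where(np.isfinite(ndvi), ndvi, 0.0)


def segment_leaf(cube: SpectralCube, ndvi_threshold: float = 0.4) -> np.ndarray:
    """Boolean leaf mask: NDVI above threshold, largest connected component.

    The red/NIR contrast separates the blade cleanly from black velvet and
    from the white standard (both have NDVI near zero).
    """
    if cube.kind != "reflectance":
        raise SegmentationError("segment_leaf expects a calibrated reflectance cube")
    candidate = ndvi_image(cube) > ndvi_threshold
    if not candidate.any():
        raise SegmentationError(
            f"no pixels exceed NDVI threshold {ndvi_threshold}; empty leaf mask"
        )
    labels, n = ndimage.label(candidate)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def principal_axis_line(mask: np.ndarray) -> DividingLine:
    """Dividing line through the mask centroid along its principal axis."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise SegmentationError("cannot fit a principal axis to an empty mask")
    centroid = np.array([rows.mean(), cols.mean()])
    coords = np.stack([rows - centroid[0], cols - centroid[1]])
    cov = coords @ coords.T / rows.size
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, int(np.argmax(eigvals))]  # largest-variance direction
    p0 = tuple(centroid - axis)
    p1 = tuple(centroid + axis)
    return DividingLine(p0, p1)


def split_halves(
    mask: np.ndarray,
    line: DividingLine | str = "auto",
    irradiated_side: str = "positive",
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the leaf mask into (darkened, irradiated) half masks.

    ``line="auto"`` uses the principal axis of the mask (the main vein of
    an elongated blade). Because no image metadata records which side the
    foil covered, the caller states it: ``irradiated_side`` selects whether
    the positive or negative signed side of the line was the lit one.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("leaf mask is empty")
    if isinstance(line, str):
        if line != "auto":
            raise GeometryError(f"unknown line specification {line!r}")
        line = principal_axis_line(mask)
    else:
        rows, cols = np.nonzero(mask)
        r_lo, r_hi = rows.min(), rows.max()
        c_lo, c_hi = cols.min(), cols.max()
        pts = np.array([line.p0, line.p1])
        if (
            pts[:, 0].max() < r_lo or pts[:, 0].min() > r_hi
            or pts[:, 1].max() < c_lo or pts[:, 1].min() > c_hi
        ):
            raise GeometryError("dividing line lies outside the leaf bounding box")
    if irradiated_side not in ("positive", "negative"):
        raise ValueError("irradiated_side must be 'positive' or 'negative'")

    rr, cc = np.meshgrid(np.arange(mask.shape[0]), np.arange(mask.shape[1]), indexing="ij")
    side = line.signed_side(rr, cc)
    positive = mask & (side > 0)
    negative = mask & (side < 0)
    if irradiated_side == "positive":
        return negative, positive
    return positive, negative


def exclude_veins(
    cube: SpectralCube,
    mask: np.ndarray,
    cmi_threshold: float | None = None,
    quantile: float = 98.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag high-CMI leaf pixels (vein/petiole tissue) for exclusion.

    Returns ``(analysis_mask, excluded_mask)``. With ``cmi_threshold=None``
    the threshold is the ``quantile``-th percentile of CMI over the leaf
    mask, which adapts across species; an absolute threshold can be passed
    instead.
    """
    mask = np.asarray(mask, dtype=bool)
    cmi_map = index_map(cube, mask, "CMI")
    values = cmi_map[mask]
    if cmi_threshold is None:
        cmi_threshold = float(np.nanpercentile(values, quantile))
    excluded = mask & (np.nan_to_num(cmi_map, nan=-np.inf) > cmi_threshold)
    analysis = mask & ~excluded
    if not analysis.any():
        logger.warning("vein exclusion removed every leaf pixel (threshold %.3f)", cmi_threshold)
    return analysis, excluded


def index_map(cube: SpectralCube, mask: np.ndarray, index_name: str) -> np.ndarray:
    """Per-pixel map of a registered index; NaN outside the mask.

    Note the map mean over the mask is a different estimator from the
    index of the masked mean spectrum (indices are nonlinear in
    reflectance); both are legitimate and they agree only approximately.
    """
    if index_name not in INDEX_REGISTRY:
        raise KeyError(
            f"unknown index {index_name!r}; registered: {sorted(INDEX_REGISTRY)}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    at, window = _cube_band_resolvers(cube)
    values = evaluate_with_resolvers(INDEX_REGISTRY[index_name], at, window)
    values = np.asarray(values, dtype=float)
    out = np.full(mask.shape, np.nan)
    out[mask] = values[mask]
    return out
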