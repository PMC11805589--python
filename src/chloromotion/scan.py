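"""Wavelength-pair scan: point-biserial correlation of ND(λ1, λ2) with
binary chloroplast positioning.

For every ordered band pair (λ1, λ2) in 400-750 nm the normalized
difference ND = (R_λ1 − R_λ2)/(R_λ1 + R_λ2) is computed per spectrum and
correlated with a 0/1 positioning label (avoidance coded 1, so positive r
marks indices that rise under avoidance). Point-biserial correlation is
Pearson correlation with the dichotomous variable dummy-coded:

    r = (M1 − M0) / s * sqrt(n1 n0 / n^2)

with M0, M1 the group means of ND and s its population SD over all
spectra. Candidate index pairs are strict local maxima of r inside a
search window (550-670 nm by default), excluding the 500-550 nm region
where blue-light-driven non-movement responses bias reflectance.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import LabeledSpectraSet
from .errors import DegenerateLabelError
from .hypercube_io import WavelengthGrid

logger = logging.getLogger(__name__)


@dataclass
class CorrelationSurface:
    """λ1 × λ2 matrix of point-biserial correlations.

    ``r[i, j]`` correlates ND(λ_i, λ_j) with the label; the diagonal
    (ND ≡ 0) and zero-variance cells hold NaN. Antisymmetric:
    ``r[i, j] = −r[j, i]``.
    """

    grid: WavelengthGrid
    r: np.ndarray
    n0: int
    n1: int
    label_name: str = "avoidance"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of off-diagonal cells."""
        w = self.grid.wavelengths
        i, j = np.meshgrid(np.arange(w.size), np.arange(w.size), indexing="ij")
        keep = i != j
        return pd.DataFrame(
            {
                "lambda1_nm": w[i[keep]],
                "lambda2_nm": w[j[keep]],
                "r": self.r[keep],
            }
        )


@dataclass
class ScanConstraints:
    """Search window, exclusion window and local-maximum neighborhood."""

    search_lo_nm: float = 550.0
    search_hi_nm: float = 670.0
    exclude_lo_nm: float = 500.0
    exclude_hi_nm: float = 550.0  # half-open: [lo, hi)
    radius_bands: int = 2

    def admissible(self, w: np.ndarray) -> np.ndarray:
        inside = (w >= self.search_lo_nm) & (w <= self.search_hi_nm)
        excluded = (w >= self.exclude_lo_nm) & (w < self.exclude_hi_nm)
        return inside & ~excluded


def biserial_surface(
    spectra: LabeledSpectraSet,
    positive_class: str = "avoidance",
    lo_nm: float = 400.0,
    hi_nm: float = 750.0,
) -> CorrelationSurface:
    """Point-biserial correlation of ND with the binary label at all pairs.

    ``positive_class`` is coded 1, every other label 0. ND is computed
    from raw (unnormalized) reflectance — it is scale-free by itself.
    """
    if len(spectra) < 3:
        raise ValueError("need at least 3 spectra for a correlation surface")
    y = (spectra.y() == positive_class).astype(float)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n0 == 0 or n1 == 0:
        raise DegenerateLabelError(
            f"both label groups must be non-empty (coded {positive_class!r} vs rest)"
        )

    sl = spectra.grid.band_slice(lo_nm, hi_nm)
    R = spectra.reflectance_matrix()[:, sl]  # (n, B)
    w = spectra.grid.wavelengths[sl]
    n, B = R.shape

    X = R[:, :, None]
    Y = R[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        nd = (X - Y) / (X + Y)  # (n, B, B)

    mean_all = nd.mean(axis=0)
    sd_all = nd.std(axis=0)  # population SD
    mean1 = nd[y == 1].mean(axis=0)
    mean0 = nd[y == 0].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mean1 - mean0) / sd_all * np.sqrt(n1 * n0 / n**2)
    r[~np.isfinite(r)] = np.nan
    np.fill_diagonal(r, np.nan)
    return CorrelationSurface(WavelengthGrid(w), r, n0=n0, n1=n1, label_name=positive_class)


def find_candidate_pairs(
    surface: CorrelationSurface,
    constraints: ScanConstraints | None = None,
) -> list[tuple[float, float, float]]:
    """Strict local maxima of positive r inside the constrained window.

    A cell qualifies when its r exceeds every other admissible finite cell
    in its (2·radius+1)² neighborhood, r > 0, and both of its wavelengths
    are admissible (inside the search window, outside the half-open
    exclusion window). The comparison is restricted to admissible cells —
    the search is defined within the window, so a ridge that keeps rising
    beyond it still yields the best within-window candidate. Returned as
    (λ1, λ2, r) ranked by r descending; ties break toward lower λ1.
    """
    constraints = constraints or ScanConstraints()
    w = surface.grid.wavelengths
    r = surface.r
    ok = constraints.admissible(w)
    rad = constraints.radius_bands

    filled = np.nan_to_num(r, nan=-np.inf)
    filled[~ok, :] = -np.inf
    filled[:, ~ok] = -np.inf
    candidates = []
    for i in np.nonzero(ok)[0]:
        for j in np.nonzero(ok)[0]:
            if i == j or not np.isfinite(r[i, j]) or r[i, j] <= 0:
                continue
            neigh = filled[
                max(0, i - rad) : i + rad + 1, max(0, j - rad) : j + rad + 1
            ].copy()
            neigh[min(i, rad), min(j, rad)] = -np.inf  # drop the center
            if r[i, j] > neigh.max():
                candidates.append((float(w[i]), float(w[j]), float(r[i, j])))
    if not candidates:
        logger.warning("no candidate pairs found inside the scan constraints")
    candidates.sort(key=lambda t: (-t[2], t[0]))
    return candidates


def scan_report(
    surface: CorrelationSurface,
    candidates: list[tuple[float, float, float]],
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write surface.csv (long format), candidates.csv and surface.png.

    The contour plot puts λ1 on the x axis and λ2 on the y axis, with the
    top candidate marked by a cross.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "surface": os.path.join(out_dir, "surface.csv"),
        "candidates": os.path.join(out_dir, "candidates.csv"),
        "plot": os.path.join(out_dir, "surface.png"),
    }
    surface.to_frame().to_csv(paths["surface"], index=False)
    pd.DataFrame(candidates, columns=["lambda1_nm", "lambda2_nm", "r"]).to_csv(
        paths["candidates"], index=False
    )

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = surface.grid.wavelengths
    fig, ax = plt.subplots(figsize=(6, 5))
    # rows of r are lambda1 -> transpose so lambda1 runs along x
    mesh = ax.contourf(w, w, surface.r.T, levels=21, cmap="RdBu_r", vmin=-1, vmax=1)
    fig.colorbar(mesh, ax=ax, label="point-biserial r")
    if candidates:
        l1, l2, _ = candidates[0]
        ax.plot(l1, l2, marker="x", color="black", markersize=10, mew=2)
    ax.set_xlabel("$\\lambda_1$ (nm)")
    ax.set_ylabel("$\\lambda_2$ (nm)")
    ax.set_title(f"ND({{$\\lambda_1$}},{{$\\lambda_2$}}) vs {surface.label_name} (n={surface.n0 + surface.n1})")
    fig.tight_layout()
    fig.savefig(paths["plot"], dpi=120)
    plt.close(fig)
    return paths
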