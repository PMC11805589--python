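"""ENVI hypercube I/O and white-standard reflectance calibration.

A VNIR line-scan camera records raw digital numbers (DN) in a few hundred
narrow bands between 400 and 1000 nm. Relative reflectance is obtained by
dividing, band by band, the dark-corrected DN of each pixel by the
dark-corrected mean DN of a white diffuse standard placed in the scene:

    R(x, y, b) = (DN(x, y, b) - dark_b) / (W_b - dark_b)

Cubes are held in memory as ``(rows, cols, bands)`` float or integer arrays
regardless of the on-disk interleave (BIL, BIP or BSQ).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import BandRangeError, CalibrationError, FormatError, TruncationError

logger = logging.getLogger(__name__)

#: ENVI "data type" codes -> numpy dtypes (subset in common camera use).
ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in ENVI_DTYPES.items()}

#: Default reflectance ceiling; diffuse leaves sit near 0.1 in the visible,
#: so values beyond 1.5 indicate specular glint or a saturated standard.
DEFAULT_CLIP_MAX = 1.5


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band centers in nanometres (VNIR: 300-1100 nm)."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("wavelength grid needs at least 2 band centers")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if w[0] < 300.0 or w[-1] > 1100.0:
            raise ValueError("band centers must lie within [300, 1100] nm")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def __hash__(self) -> int:
        return hash(self.wavelengths.tobytes())

    def nearest_band(self, target_nm: float) -> int:
        """0-based index of the band center closest to ``target_nm``.

        Ties break toward the lower wavelength. Targets further than one
        band spacing beyond either end of the grid raise
        :class:`BandRangeError`.
        """
        w = self.wavelengths
        lo_tol = w[1] - w[0]
        hi_tol = w[-1] - w[-2]
        if target_nm < w[0] - lo_tol or target_nm > w[-1] + hi_tol:
            raise BandRangeError(
                f"target {target_nm} nm outside grid span "
                f"[{w[0]}, {w[-1]}] nm (tolerance one band spacing)"
            )
        # argmin returns the first (= lower-wavelength) index on exact ties
        return int(np.argmin(np.abs(w - target_nm)))

    def band_slice(self, lo_nm: float, hi_nm: float) -> slice:
        """Slice covering the closed interval [lo_nm, hi_nm] by nearest bands."""
        i = self.nearest_band(lo_nm)
        j = self.nearest_band(hi_nm)
        if i > j:
            raise ValueError("lo_nm must not exceed hi_nm")
        return slice(i, j + 1)

    def window_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of all bands whose centers fall inside [lo_nm, hi_nm]."""
        w = self.wavelengths
        return np.nonzero((w >= lo_nm) & (w <= hi_nm))[0]


def default_grid(lo_nm: float = 400.0, spacing_nm: float = 2.2, n_bands: int = 273) -> WavelengthGrid:
    """The package's default VNIR grid: 400-998.4 nm at 2.2 nm (273 bands)."""
    return WavelengthGrid(lo_nm + spacing_nm * np.arange(n_bands))


@dataclass
class SpectralCube:
    """A hyperspectral image: ``data`` is (rows, cols, bands)."""

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw_dn"  # "raw_dn" | "reflectance"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"bands dimension {self.data.shape[2]} != grid length {len(self.grid)}"
            )
        if self.kind not in ("raw_dn", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("cube values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferenceRegions:
    """White-standard region plus an optional dark level.

    ``white_region`` is either a boolean (rows, cols) mask or a rectangle
    ``(row0, row1, col0, col1)`` with half-open bounds. ``dark_level`` is a
    scalar or per-band vector of shutter-closed DN.
    """

    white_region: np.ndarray | tuple[int, int, int, int]
    dark_level: float | np.ndarray = 0.0

    def white_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if isinstance(self.white_region, tuple):
            r0, r1, c0, c1 = self.white_region
            mask = np.zeros(shape, dtype=bool)
            mask[r0:r1, c0:c1] = True
        else:
            mask = np.asarray(self.white_region, dtype=bool)
            if mask.shape != shape:
                raise ValueError("white-region mask shape does not match cube")
        if not mask.any():
            raise ValueError("white region is empty")
        return mask


# ---------------------------------------------------------------------------
# ENVI format
# ---------------------------------------------------------------------------

_REQUIRED_HDR = ("samples", "lines", "bands", "data type", "interleave", "wavelength")


def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI ASCII header into a flat {field: value} dict."""
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict = {}
    body = text.lstrip()[4:]
    pos = 0
    while pos < len(body):
        eq = body.find("=", pos)
        if eq < 0:
            break
        key = body[pos:eq].strip().lower()
        rest = body[eq + 1 :].lstrip()
        if rest.startswith("{"):
            close = rest.find("}")
            if close < 0:
                raise FormatError(f"unterminated '{{' value for header field {key!r}")
            value = rest[1:close].strip()
            consumed = (eq + 1) + (len(body[eq + 1 :]) - len(rest)) + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl < 0 else nl
            value = rest[:nl].strip()
            consumed = (eq + 1) + (len(body[eq + 1 :]) - len(rest)) + nl
        if key:
            fields[key] = value
        pos = consumed
    return fields


def read_envi(header_path: str | os.PathLike) -> SpectralCube:
    """Read an ENVI header/binary pair into a (rows, cols, bands) cube.

    The sibling binary file is located by dropping the ``.hdr`` suffix or,
    failing that, by appending ``.img``/``.dat``/``.bin`` / ``.raw``.
    """
    header_path = os.fspath(header_path)
    with open(header_path, "r") as fh:
        fields = _parse_envi_header(fh.read())

    missing = [k for k in _REQUIRED_HDR if k not in fields]
    if missing:
        raise FormatError(f"ENVI header missing required field(s): {missing}")

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except ValueError as exc:
        raise FormatError(f"non-numeric dimension field in ENVI header: {exc}") from exc
    interleave = fields["interleave"].lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unknown interleave {interleave!r}")
    if dtype_code not in ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(ENVI_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")

    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    binary_path = _sibling_binary(header_path)
    raw = np.fromfile(binary_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size < expected:
        raise TruncationError(
            f"{binary_path}: expected {expected} samples, found {raw.size}"
        )
    raw = raw[:expected]

    if interleave == "bip":  # (lines, samples, bands)
        data = raw.reshape(lines, samples, bands)
    elif interleave == "bil":  # (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq: (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    kind = fields.get("cube kind", "raw_dn")
    if kind not in ("raw_dn", "reflectance"):
        kind = "reflectance" if np.issubdtype(dtype, np.floating) else "raw_dn"
    metadata = {
        k: v for k, v in fields.items() if k not in _REQUIRED_HDR + ("byte order", "cube kind")
    }
    metadata["interleave"] = interleave
    return SpectralCube(
        np.ascontiguousarray(data), WavelengthGrid(wavelengths), kind=kind, metadata=metadata
    )


def _sibling_binary(header_path: str) -> str:
    stem, ext = os.path.splitext(header_path)
    candidates = [stem] + [stem + e for e in (".img", ".dat", ".bin", ".raw")]
    for cand in candidates:
        if os.path.isfile(cand):
            return cand
    raise FormatError(f"no binary file found next to header {header_path}")


def write_envi(
    cube: SpectralCube, path: str | os.PathLike, interleave: str = "bil"
) -> tuple[str, str]:
    """Write ``cube`` as an ENVI header + flat binary pair.

    ``path`` may end in ``.hdr`` or be a bare stem; returns
    ``(header_path, binary_path)``. Default interleave is BIL,
    little-endian.
    """
    if len(cube.grid) == 0 or cube.data.shape[2] == 0:
        raise ValueError("cannot write a cube with zero bands")
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}")

    path = os.fspath(path)
    stem = path[:-4] if path.endswith(".hdr") else path
    header_path, binary_path = stem + ".hdr", stem + ".img"

    data = cube.data
    dtype = data.dtype
    if dtype not in _DTYPE_CODES:
        data = data.astype(np.float64)
        dtype = data.dtype
    rows, cols, bands = data.shape

    if interleave == "bip":
        ondisk = data
    elif interleave == "bil":
        ondisk = data.transpose(0, 2, 1)  # (lines, bands, samples)
    else:
        ondisk = data.transpose(2, 0, 1)  # (bands, lines, samples)
    ondisk = np.ascontiguousarray(ondisk, dtype=dtype.newbyteorder("<"))

    # shortest decimal repr round-trips float64 band centers exactly
    wl = ", ".join(repr(float(w)) for w in cube.grid.wavelengths)
    lines_out = [
        "ENVI",
        "description = {chloromotion hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"cube kind = {cube.kind}",
        "wavelength = {" + wl + "}",
    ]
    try:
        with open(header_path, "w") as fh:
            fh.write("\n".join(lines_out) + "\n")
        ondisk.tofile(binary_path)
    except OSError as exc:
        raise OSError(f"cannot write ENVI pair at {stem!r}: {exc}") from exc
    return header_path, binary_path


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_reflectance(
    raw: SpectralCube,
    refs: ReferenceRegions,
    clip_max: float = DEFAULT_CLIP_MAX,
) -> SpectralCube:
    """Convert raw DN to relative reflectance against the white standard.

    Per band ``b``: ``R = (DN - dark_b) / (W_b - dark_b)`` with ``W_b`` the
    mean DN over the white region. Negative results clip to 0; values above
    ``clip_max`` clip down with a logged warning.
    """
    if raw.kind != "raw_dn":
        raise CalibrationError("calibrate_reflectance expects a raw-DN cube")
    mask = refs.white_mask(raw.data.shape[:2])
    dark = np.asarray(refs.dark_level, dtype=float)
    if dark.ndim == 1 and dark.size != len(raw.grid):
        raise CalibrationError("per-band dark level length does not match grid")
    if np.any(dark < 0):
        raise CalibrationError("dark level must be non-negative")

    white = raw.data[mask].astype(float).mean(axis=0)  # per-band W_b
    denom = white - dark
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        w_nm = raw.grid.wavelengths[bad[0]]
        raise CalibrationError(
            f"white minus dark is non-positive in band {bad[0]} ({w_nm:.1f} nm)"
        )

    refl = (raw.data.astype(float) - dark) / denom
    n_neg = int((refl < 0).sum())
    n_high = int((refl > clip_max).sum())
    if n_high:
        logger.warning(
            "calibration clipped %d pixel-band values above %.2f (specular glint?)",
            n_high,
            clip_max,
        )
    if n_neg:
        logger.debug("calibration clipped %d negative pixel-band values to 0", n_neg)
    refl = np.clip(refl, 0.0, clip_max)
    meta = dict(raw.metadata)
    meta["calibration"] = "white-standard flat field"
    return SpectralCube(refl, raw.grid, kind="reflectance", metadata=meta)


def nearest_band(grid: WavelengthGrid, target_nm: float) -> int:
    """Module-level alias for :meth:`WavelengthGrid.nearest_band`."""
    return grid.nearest_band(target_nm)


def white_noise_sd(raw: SpectralCube, refs: ReferenceRegions) -> np.ndarray:
    """Per-band SD of DN over the white region (simple sensor-noise estimate)."""
    mask = refs.white_mask(raw.data.shape[:2])
    return raw.data[mask].astype(float).std(axis=0)
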