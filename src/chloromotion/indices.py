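"""Narrow-band vegetation indices, the generic ND index and the CMI.

The chloroplast movement index is a normalized-difference index over the
red/green band pair selected by the wavelength-pair scan:

    CMI = (R635 − R555) / (R635 + R555)

It is negative for leaves (green reflectance exceeds red) and rises as
chloroplasts move into the avoidance position. The remaining registry
covers 17 published narrow-band indices sensitive to pigments and cell
structure. Single-wavelength terms use nearest-band reflectance (no
interpolation); windowed terms (SG, RGRI) average every band whose center
falls in the closed window.

Index formulas are registered as expression strings over ``R<nm>`` tokens
(e.g. ``"(R800-R670)/(R800+R670)"``) and ``mean(R<lo>:R<hi>)`` windows, so
a formula can be corrected or added without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedValueError
from .spectra import ReflectanceSpectrum

#: name -> expression over R<nm> tokens. Standard published narrow-band forms.
INDEX_REGISTRY: dict[str, str] = {
    "CMI": "(R635 - R555) / (R635 + R555)",
    "NDVI": "(R800 - R670) / (R800 + R670)",
    "SR": "R800 / R670",
    "EVI": "2.5 * (R800 - R670) / (R800 + 6*R670 - 7.5*R475 + 1)",
    "ARVI": "(R800 - (2*R670 - R450)) / (R800 + (2*R670 - R450))",
    "RENDVI": "(R750 - R705) / (R750 + R705)",
    "mRENDVI": "(R750 - R705) / (R750 + R705 - 2*R445)",
    "mRESR": "(R750 - R445) / (R705 - R445)",
    "SG": "mean(R500:R600)",
    "VOG1": "R740 / R720",
    "VOG2": "(R734 - R747) / (R715 + R726)",
    "VOG3": "(R734 - R747) / (R715 + R720)",
    "PRI": "(R531 - R570) / (R531 + R570)",
    "SIPI": "(R800 - R445) / (R800 - R680)",
    "RGRI": "mean(R600:R699) / mean(R500:R599)",
    "PSRI": "(R680 - R500) / R750",
    "CAR1": "1/R510 - 1/R550",
    "CAR2": "1/R510 - 1/R700",
}

_WINDOW_RE = re.compile(r"mean\(\s*R(\d+(?:\.\d+)?)\s*:\s*R(\d+(?:\.\d+)?)\s*\)")
_BAND_RE = re.compile(r"R(\d+(?:\.\d+)?)")


@dataclass
class IndexDelta:
    """Per-leaf difference of one index between leaf halves (darkened − irradiated)."""

    leaf_id: object
    index_name: str
    value_darkened: float
    value_irradiated: float
    condition: str | None = None
    genotype: str | None = None
    species: str | None = None

    @property
    def delta(self) -> float:
        return self.value_darkened - self.value_irradiated


def nd_index(s: ReflectanceSpectrum, l1_nm: float, l2_nm: float) -> float:
    """Normalized difference (R_λ1 − R_λ2)/(R_λ1 + R_λ2) with nearest bands."""
    r1, r2 = s.at(l1_nm), s.at(l2_nm)
    denom = r1 + r2
    if denom == 0.0:
        raise UndefinedValueError(f"ND({l1_nm}, {l2_nm}): zero total reflectance")
    return (r1 - r2) / denom


def cmi(s: ReflectanceSpectrum) -> float:
    """Chloroplast movement index: ND over the (635 nm, 555 nm) pair."""
    return nd_index(s, 635.0, 555.0)


def evaluate_with_resolvers(expr: str, at, window):
    """Evaluate a registry expression with caller-supplied band resolvers.

    ``at(nm)`` returns the reflectance term for a single wavelength and
    ``window(lo, hi)`` the windowed mean; either may return scalars or
    numpy arrays (e.g. per-pixel images), which is how whole-cube index
    maps are computed from the same registry.
    """
    namespace: dict = {}

    def sub_window(match: re.Match) -> str:
        name = f"_w{len(namespace)}"
        namespace[name] = window(float(match.group(1)), float(match.group(2)))
        return name

    def sub_band(match: re.Match) -> str:
        name = f"_b{len(namespace)}"
        namespace[name] = at(float(match.group(1)))
        return name

    substituted = _BAND_RE.sub(sub_band, _WINDOW_RE.sub(sub_window, expr))
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            value = eval(substituted, {"__builtins__": {}}, namespace)
    except ZeroDivisionError as exc:
        raise UndefinedValueError(f"index expression {expr!r}: {exc}") from exc
    return value


def evaluate_expression(expr: str, s: ReflectanceSpectrum) -> float:
    """Evaluate a registry expression against one spectrum."""
    value = float(evaluate_with_resolvers(expr, s.at, s.window_mean))
    if not np.isfinite(value):
        raise UndefinedValueError(f"index expression {expr!r} is non-finite")
    return value


def vegetation_index(s: ReflectanceSpectrum, name: str) -> float:
    """Compute a registered index by name (case-sensitive registry keys)."""
    try:
        expr = INDEX_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown index {name!r}; registered: {sorted(INDEX_REGISTRY)}"
        ) from None
    return evaluate_expression(expr, s)


def index_deltas(
    pairs: list[tuple[ReflectanceSpectrum, ReflectanceSpectrum]],
    names: list[str],
) -> list[IndexDelta]:
    """One record per leaf per index; sign convention darkened − irradiated."""
    if not pairs:
        raise ValueError("need at least one (darkened, irradiated) pair")
    out = []
    for k, (dk, ir) in enumerate(pairs):
        prov = dk.provenance
        for name in names:
            out.append(
                IndexDelta(
                    leaf_id=prov.get("leaf_id", k),
                    index_name=name,
                    value_darkened=vegetation_index(dk, name),
                    value_irradiated=vegetation_index(ir, name),
                    condition=prov.get("condition"),
                    genotype=prov.get("genotype"),
                    species=prov.get("species"),
                )
            )
    return out


def deltas_to_frame(deltas: list[IndexDelta]):
    """Tidy pandas DataFrame of IndexDelta records."""
    import pandas as pd

    return pd.DataFrame(
        {
            "leaf_id": [d.leaf_id for d in deltas],
            "index_name": [d.index_name for d in deltas],
            "value_darkened": [d.value_darkened for d in deltas],
            "value_irradiated": [d.value_irradiated for d in deltas],
            "delta": [d.delta for d in deltas],
            "condition": [d.condition for d in deltas],
            "genotype": [d.genotype for d in deltas],
            "species": [d.species for d in deltas],
        }
    )
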