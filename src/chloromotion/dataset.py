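"""Labeled collections of reflectance spectra for scans and classification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import ReflectanceSpectrum, normalize_truncate

#: Canonical chloroplast-positioning classes, in fixed order.
CLASSES = ("dark", "accumulation", "avoidance")


@dataclass
class LabeledSpectraSet:
    """Spectra tagged with positioning class and provenance.

    ``labels`` are positioning classes (one of :data:`CLASSES`);
    ``meta`` carries one row per spectrum (species, genotype, leaf_id,
    half, condition, ...).
    """

    spectra: list[ReflectanceSpectrum]
    labels: list[str]
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.labels):
            raise ValueError("labels and spectra length mismatch")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown positioning class(es): {sorted(bad)}")
        if self.meta.empty:
            self.meta = pd.DataFrame(
                [s.provenance for s in self.spectra]
            ).reset_index(drop=True)
        if len(self.meta) != len(self.spectra):
            raise ValueError("meta must have one row per spectrum")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def grid(self):
        return self.spectra[0].grid

    def reflectance_matrix(self) -> np.ndarray:
        """(n_spectra, n_bands) raw reflectance matrix."""
        return np.stack([s.values for s in self.spectra])

    def features(self, lo_nm: float = 400.0, hi_nm: float = 750.0, mode: str = "l2") -> np.ndarray:
        """(n_spectra, n_features) matrix of normalised truncated spectra."""
        return np.stack([normalize_truncate(s, lo_nm, hi_nm, mode) for s in self.spectra])

    def y(self) -> np.ndarray:
        return np.asarray(self.labels)

    def leaf_ids(self) -> np.ndarray:
        if "leaf_id" in self.meta.columns:
            return self.meta["leaf_id"].to_numpy()
        return np.arange(len(self))

    def subset(self, idx) -> "LabeledSpectraSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return LabeledSpectraSet(
            [self.spectra[i] for i in idx],
            [self.labels[i] for i in idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )

    @staticmethod
    def concat(sets: list["LabeledSpectraSet"]) -> "LabeledSpectraSet":
        spectra = [s for ds in sets for s in ds.spectra]
        labels = [l for ds in sets for l in ds.labels]
        meta = pd.concat([ds.meta for ds in sets], ignore_index=True)
        return LabeledSpectraSet(spectra, labels, meta)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per spectrum per band)."""
        rows = []
        w = self.grid.wavelengths
        for i, (s, lab) in enumerate(zip(self.spectra, self.labels)):
            base = {"spectrum_index": i, "positioning": lab}
            base.update({k: v for k, v in self.meta.iloc[i].items()})
            for wl, r in zip(w, s.values):
                rows.append({**base, "wavelength_nm": wl, "reflectance": r})
        return pd.DataFrame(rows)
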