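"""Bulk-culture absorption-spectrum utilities.

Whole-culture absorption spectra (400-750 nm) are the classical way to
monitor the pigmentation state of a cyanobacterial culture: phycocyanin
absorbs near 620 nm and chlorophyll a near 680 nm, so the 620/680
absorbance ratio (PC/Chl) tracks the producer-typical phycocyanin
down-regulation at culture level.  Spectra are normalized to a relative
absorbance of 0.45 at the 680 nm chlorophyll peak so overlays of different
cultures are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "normalize_spectrum", "pc_chl_ratio", "read_spectrum"]

CHL_PEAK_NM = 680.0
PC_PEAK_NM = 620.0
NORMALIZED_A680 = 0.45


@dataclass(frozen=True)
class Spectrum:
    """Absorption spectrum: strictly increasing wavelengths (nm) with
    nonnegative absorbances."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        ab = np.asarray(self.absorbance, float)
        if wl.ndim != 1 or wl.shape != ab.shape:
            raise ValueError("wavelengths and absorbance must be equal-length 1-D")
        if wl.size < 2:
            raise ValueError("spectrum needs at least two points")
        if not (np.diff(wl) > 0).all():
            raise ValueError("wavelengths must be strictly increasing")
        if (ab < 0).any():
            raise ValueError("absorbance must be nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)

    def at(self, nm: float) -> float:
        """Absorbance at ``nm``, linearly interpolated; errors outside range."""
        wl = self.wavelengths
        if not wl[0] <= nm <= wl[-1]:
            raise ValueError(
                f"{nm} nm outside the recorded range [{wl[0]}, {wl[-1]}] nm"
            )
        return float(np.interp(nm, wl, self.absorbance))


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Scale so the absorbance at the 680 nm chlorophyll peak is exactly 0.45.

    Idempotent, and commutes with :func:`pc_chl_ratio` (the ratio is
    scale-invariant).
    """
    a680 = s.at(CHL_PEAK_NM)
    if a680 <= 0:
        raise ValueError(f"absorbance at {CHL_PEAK_NM:g} nm must be > 0 to normalize")
    return Spectrum(s.wavelengths, s.absorbance * (NORMALIZED_A680 / a680))


def pc_chl_ratio(s: Spectrum) -> float:
    """Phycocyanin/chlorophyll indicator: A(620 nm) / A(680 nm)."""
    a680 = s.at(CHL_PEAK_NM)
    if a680 <= 0:
        raise ValueError(f"absorbance at {CHL_PEAK_NM:g} nm must be > 0")
    return s.at(PC_PEAK_NM) / a680


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column CSV (wavelength_nm, absorbance)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, absorbance)")
    return Spectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))
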