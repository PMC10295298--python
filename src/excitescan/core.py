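"""Core containers shared across the package.

The central objects are :class:`SpectralStack` (one excitation-scanning
image cube, band axis first) and :class:`SpectralLibrary` (peak-normalized
pure endmember excitation spectra).  Detector outputs are wrapped in
:class:`DetectionMap`, which records whether larger or smaller values mean
"more target" so thresholding code never has to special-case the spectral
angle mapper.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ExcitescanError",
    "FormatError",
    "DegenerateSpectrumError",
    "DegenerateInputError",
    "ConditioningError",
    "SpectralStack",
    "SpectralLibrary",
    "DetectionMap",
    "UnmixResult",
]


class ExcitescanError(Exception):
    """Base class for package-specific failures."""


class FormatError(ExcitescanError):
    """A file on disk does not have the expected layout or metadata."""


class DegenerateSpectrumError(ExcitescanError):
    """An extracted spectrum is identically zero and cannot be normalized."""


class DegenerateInputError(ExcitescanError):
    """An input has no variation where variation is required (e.g. Otsu)."""


class ConditioningError(ExcitescanError):
    """A matrix inversion required by a detector is numerically singular."""


def _as_wavelengths(wavelengths) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise ValueError("wavelengths must be a nonempty 1-D sequence")
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    return wl


@dataclass
class SpectralStack:
    """One spectral image cube, indexed (band, row, col).

    Parameters
    ----------
    data
        3-D array of intensities (arbitrary units). Bands are ordered with
        ascending excitation wavelength.
    wavelengths
        Excitation band centers in nm, one per band, strictly increasing.
    time_s
        Acquisition time stamp (seconds) for time-lapse series, or None.
    saturation_value
        Detector full-scale value, or None if unknown.
    corrected
        True once background subtraction and flat spectral-response
        correction have been applied (or the data are ideal/simulated).
    saturated_mask
        Optional per-pixel boolean image marking pixels that hit
        ``saturation_value`` in any band *before* correction.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    time_s: float | None = None
    saturation_value: float | None = None
    corrected: bool = False
    saturated_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (band, row, col)")
        self.wavelengths = _as_wavelengths(self.wavelengths)
        if self.wavelengths.size != self.data.shape[0]:
            raise ValueError(
                f"{self.wavelengths.size} wavelengths for "
                f"{self.data.shape[0]} bands"
            )
        if self.saturated_mask is not None:
            self.saturated_mask = np.asarray(self.saturated_mask, dtype=bool)
            if self.saturated_mask.shape != self.image_shape:
                raise ValueError("saturated_mask shape must match image shape")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def pixel_spectra(self) -> np.ndarray:
        """Return pixels as an (n_pixels, n_bands) float matrix."""
        return self.data.reshape(self.n_bands, -1).T.astype(float)

    def with_data(self, data: np.ndarray) -> "SpectralStack":
        """Copy of this stack with ``data`` replaced, metadata kept."""
        return replace(self, data=data)


@dataclass
class SpectralLibrary:
    """Matrix of peak-normalized endmember excitation spectra.

    ``spectra`` has one row per endmember, one column per band; every row is
    nonnegative with maximum exactly 1 (peak normalization).
    """

    names: list[str]
    spectra: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths = _as_wavelengths(self.wavelengths)
        if len(self.names) != self.spectra.shape[0]:
            raise ValueError("one name per spectrum row required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate endmember names")
        if self.spectra.shape[1] != self.wavelengths.size:
            raise ValueError("spectra columns must match wavelength count")
        if np.any(self.spectra < 0):
            raise ValueError("library spectra must be nonnegative")
        maxima = self.spectra.max(axis=1)
        if not np.allclose(maxima, 1.0, atol=1e-9):
            raise ValueError("library rows must be peak-normalized to 1")

    @property
    def n_endmembers(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"endmember {name!r} not in library") from None

    def spectrum(self, name: str) -> np.ndarray:
        return self.spectra[self.index(name)]

    def without(self, name: str) -> tuple[list[str], np.ndarray]:
        """Names and spectra of every endmember except ``name``."""
        i = self.index(name)
        keep = [j for j in range(self.n_endmembers) if j != i]
        return [self.names[j] for j in keep], self.spectra[keep]


@dataclass
class DetectionMap:
    """Scalar per-pixel output of one detector for one endmember.

    ``kind`` is ``"abundance"`` (larger = more target; LU, CEM, MF) or
    ``"angle"`` (smaller = more target; SAM).  ``positive_direction``
    encodes that convention for thresholding code.
    """

    values: np.ndarray
    endmember: str
    kind: str
    algorithm: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("detection map must be a 2-D image")
        if self.kind not in ("abundance", "angle"):
            raise ValueError("kind must be 'abundance' or 'angle'")

    @property
    def positive_direction(self) -> str:
        return "less" if self.kind == "angle" else "greater"


@dataclass
class UnmixResult:
    """Full linear-unmixing output: one abundance map per endmember plus
    the per-pixel residual RMS over bands."""

    maps: dict[str, DetectionMap]
    rms_error: np.ndarray

    def __post_init__(self) -> None:
        self.rms_error = np.asarray(self.rms_error, dtype=float)
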