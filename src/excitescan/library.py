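"""Reference-spectrum extraction and spectral-library assembly.

A reference (pure endmember) spectrum is measured from a single-label
control stack by averaging the pixel spectra over a user-drawn region of
high — but unsaturated — signal and normalizing the average to a peak of
unity. Named references are assembled into a :class:`SpectralLibrary`
stored as CSV with header ``wavelength_nm,<name1>,<name2>,...``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DegenerateSpectrumError, FormatError, SpectralLibrary, SpectralStack

__all__ = [
    "extract_reference",
    "assemble_library",
    "write_library",
    "read_library",
]


def extract_reference(stack: SpectralStack, roi: np.ndarray) -> np.ndarray:
    """Pixel-averaged, peak-normalized spectrum over an ROI.

    Pixels that hit the detector saturation value in any band are excluded
    before averaging (they would distort the spectral shape). The stack
    must already be spectrally corrected.
    """
    if not stack.corrected:
        raise ValueError("reference extraction requires a corrected stack")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.image_shape:
        raise ValueError("roi shape must match image shape")
    if not roi.any():
        raise ValueError("empty roi")

    keep = roi.copy()
    if stack.saturated_mask is not None:
        keep &= ~stack.saturated_mask
    elif stack.saturation_value is not None:
        keep &= ~(stack.data >= stack.saturation_value).any(axis=0)
    if not keep.any():
        raise ValueError("all roi pixels are saturated")

    mean = stack.data[:, keep].astype(float).mean(axis=1)
    peak = mean.max()
    if peak <= 0:
        raise DegenerateSpectrumError("roi-averaged spectrum is all zero")
    return mean / peak


def assemble_library(names, spectra, wavelengths,
                     normalize: bool = True) -> SpectralLibrary:
    """Stack named spectra (equal band counts) into a library.

    With ``normalize=True`` (default) each row is divided by its maximum
    so the library invariant (row peak exactly 1) holds; rows that are
    already peak-normalized pass through unchanged.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    names = list(names)
    if len(names) != spectra.shape[0]:
        raise ValueError("one name per spectrum required")
    if normalize:
        peaks = spectra.max(axis=1)
        if np.any(peaks <= 0):
            raise DegenerateSpectrumError("cannot normalize an all-zero spectrum")
        spectra = spectra / peaks[:, None]
    return SpectralLibrary(names=names, spectra=spectra,
                           wavelengths=wavelengths)


def write_library(library: SpectralLibrary, path) -> None:
    """Write a library CSV: one row per band, one column per endmember."""
    df = pd.DataFrame({"wavelength_nm": library.wavelengths})
    for name in library.names:
        df[name] = library.spectrum(name)
    df.to_csv(path, index=False)


def read_library(path) -> SpectralLibrary:
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise FormatError(f"{path}: first column must be 'wavelength_nm'")
    names = list(df.columns[1:])
    if not names:
        raise FormatError(f"{path}: no endmember columns")
    spectra = df[names].to_numpy(dtype=float).T
    return SpectralLibrary(names=names, spectra=spectra,
                           wavelengths=df["wavelength_nm"].to_numpy(dtype=float))
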