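"""Reading, writing and flat spectral-response correction of stacks.

Spectral stacks travel as multi-page TIFF, one page per excitation band in
ascending wavelength order. Plain TIFF has no wavelength axis, so stacks
are accompanied by either an embedded JSON description (written by this
package) or a sidecar CSV ``band,wavelength_nm``. Illumination power
tables are CSV ``wavelength_nm,power``; masks are single-page PNG/TIFF
images where nonzero means inside.

The correction model: measure illumination power per excitation band
(``power``), take its reciprocal, and normalize that to a peak of unity to
obtain per-band correction coefficients. A raw stack is corrected by
background subtraction followed by multiplication with the coefficient,
which flattens the system's wavelength-dependent excitation response.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import FormatError, SpectralStack

__all__ = [
    "CorrectionProfile",
    "read_stack",
    "write_stack",
    "read_wavelengths_csv",
    "write_wavelengths_csv",
    "read_power_table",
    "build_correction",
    "correct_stack",
    "read_mask",
    "write_mask",
]


@dataclass
class CorrectionProfile:
    """Per-band flat spectral-response correction.

    ``coefficients`` is the reciprocal of the measured illumination power,
    peak-normalized so the weakest band gets coefficient exactly 1.
    """

    wavelengths: np.ndarray
    power: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)


def build_correction(power_table) -> CorrectionProfile:
    """Build a correction profile from (wavelength, power) rows.

    Accepts a DataFrame with columns ``wavelength_nm, power``, an (N, 2)
    array, or a ``(wavelengths, powers)`` pair. All powers must be
    strictly positive.
    """
    if isinstance(power_table, pd.DataFrame):
        wl = power_table["wavelength_nm"].to_numpy(dtype=float)
        power = power_table["power"].to_numpy(dtype=float)
    elif isinstance(power_table, (tuple, list)) and len(power_table) == 2 \
            and np.ndim(power_table[0]) == 1:
        wl = np.asarray(power_table[0], dtype=float)
        power = np.asarray(power_table[1], dtype=float)
        if wl.shape != power.shape:
            raise ValueError("wavelength and power lengths differ")
    else:
        arr = np.asarray(power_table, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 2:
            wl, power = arr[:, 0], arr[:, 1]
        else:
            raise ValueError("power table must be (wavelength, power) rows")
    if power.size == 0:
        raise ValueError("empty power table")
    if np.any(power <= 0):
        raise ValueError("illumination powers must be strictly positive")
    inverse = 1.0 / power
    coefficients = inverse / inverse.max()
    return CorrectionProfile(wavelengths=wl, power=power,
                             coefficients=coefficients)


def correct_stack(stack: SpectralStack, profile: CorrectionProfile | None,
                  background=0.0) -> SpectralStack:
    """Background-subtract then flatten the spectral response.

    ``background`` may be a scalar, a per-band vector, a (band, row, col)
    dark stack, or a :class:`SpectralStack`. Subtraction happens first,
    negatives are clipped to zero (abundances are physical), then each
    band is scaled by its correction coefficient. The output is flagged
    ``corrected``; pixels that sat at the detector's saturation value in
    the raw data are recorded in ``saturated_mask``.
    """
    data = stack.data.astype(float)
    if isinstance(background, SpectralStack):
        background = background.data
    bg = np.asarray(background, dtype=float)
    if bg.ndim == 1:
        if bg.size != stack.n_bands:
            raise ValueError("per-band background length mismatch")
        bg = bg[:, None, None]
    elif bg.ndim == 3 and bg.shape != data.shape:
        raise ValueError("dark-stack background shape mismatch")
    elif bg.ndim not in (0, 3):
        raise ValueError("background must be scalar, per-band, or a stack")

    if profile is None:
        coeff = np.ones(stack.n_bands)
    else:
        if (profile.wavelengths.size != stack.wavelengths.size
                or not np.allclose(profile.wavelengths, stack.wavelengths)):
            raise ValueError("correction profile wavelengths do not match stack")
        coeff = profile.coefficients

    out = np.clip(data - bg, 0.0, None) * coeff[:, None, None]
    saturated = None
    if stack.saturation_value is not None:
        saturated = (stack.data >= stack.saturation_value).any(axis=0)
    return SpectralStack(data=out, wavelengths=stack.wavelengths,
                         time_s=stack.time_s, saturation_value=None,
                         corrected=True, saturated_mask=saturated)


# ---------------------------------------------------------------------------
# TIFF stacks

def write_stack(stack: SpectralStack, path, sidecar: Path | None = None) -> None:
    """Write a stack as multi-page TIFF, one page per band ascending.

    Wavelengths (and time stamp / corrected flag) are embedded as a JSON
    image description; pass ``sidecar`` to additionally write a
    ``band,wavelength_nm`` CSV next to the TIFF.
    """
    meta = {
        "wavelength_nm": [float(w) for w in stack.wavelengths],
        "time_s": stack.time_s,
        "corrected": stack.corrected,
    }
    tifffile.imwrite(path, stack.data, photometric="minisblack",
                     description=json.dumps(meta))
    if sidecar is not None:
        write_wavelengths_csv(stack.wavelengths, sidecar)


def read_stack(path, wavelengths=None) -> SpectralStack:
    """Read a multi-page TIFF stack; band order equals page order.

    ``wavelengths`` may be an array or the path of a sidecar CSV; if
    omitted, the embedded JSON description written by :func:`write_stack`
    is used. A stack without any wavelength metadata is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise FormatError(f"{path}: pages have mismatched shapes {shapes}")
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[None]
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}

    if wavelengths is not None:
        if isinstance(wavelengths, (str, Path)):
            wl = read_wavelengths_csv(wavelengths)
        else:
            wl = np.asarray(wavelengths, dtype=float)
    elif "wavelength_nm" in meta:
        wl = np.asarray(meta["wavelength_nm"], dtype=float)
    else:
        raise FormatError(
            f"{path}: no wavelength metadata; provide a sidecar CSV")
    if wl.size != data.shape[0]:
        raise FormatError(
            f"{path}: {wl.size} wavelengths for {data.shape[0]} pages")
    return SpectralStack(data=data, wavelengths=wl,
                         time_s=meta.get("time_s"),
                         corrected=bool(meta.get("corrected", False)))


def write_wavelengths_csv(wavelengths, path) -> None:
    wl = np.asarray(wavelengths, dtype=float)
    pd.DataFrame({"band": np.arange(wl.size), "wavelength_nm": wl}).to_csv(
        path, index=False)


def read_wavelengths_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise FormatError(f"{path}: missing 'wavelength_nm' column")
    if "band" in df.columns:
        df = df.sort_values("band")
    return df["wavelength_nm"].to_numpy(dtype=float)


def read_power_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"wavelength_nm", "power"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Masks

def read_mask(path) -> np.ndarray:
    """Read a single-page image as a boolean mask (nonzero = inside)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse any color channels
        img = img.max(axis=-1)
    if img.ndim != 2:
        raise FormatError(f"{path}: mask must be a single-page 2-D image")
    return img != 0


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
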