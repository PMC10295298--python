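"""Pixel-wise spectral detection algorithms: LU, SAM, CEM and MF.

All four map a corrected spectral stack to per-endmember scalar images.

* Linear unmixing (LU) models each pixel spectrum x as a nonnegative
  combination of library spectra, x = sum_i a_i r_i + w, and solves for
  the abundances a by nonnegative least squares per pixel; the residual
  RMS over bands is reported alongside.
* Spectral angle mapper (SAM) scores each pixel by the angle
  theta = arccos(r.x / (|r||x|)) between its spectrum and the target
  reference — smaller is more target-like, and the score is invariant to
  pixel brightness.
* Constrained energy minimization (CEM) builds the linear filter
  L = R^-1 r / (r^T R^-1 r) from the image's own sample correlation
  matrix R = sum_j x_j x_j^T / N; L has unity gain on the target while
  minimizing the filter's output energy over the observed scene.
* Matched filter (MF, orthogonal-subspace-projection form) projects out
  the span of the non-target library spectra U via P = I - U U# with
  U# = (U^T U)^-1 U^T, then scores pixels with q = r^T P, i.e. a = q.x.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .core import (
    ConditioningError,
    DetectionMap,
    SpectralLibrary,
    SpectralStack,
    UnmixResult,
)

__all__ = [
    "unmix_lu",
    "sam_angle",
    "CEMFilter",
    "cem_build",
    "cem_apply",
    "MFOperator",
    "mf_build",
    "mf_apply",
]

_COND_LIMIT = 1e12


def unmix_lu(stack: SpectralStack, library: SpectralLibrary) -> UnmixResult:
    """Nonnegatively constrained linear unmixing of every pixel.

    Solves min ||x - R^T a||_2 s.t. a >= 0 per pixel (Lawson-Hanson NNLS)
    and returns one abundance map per endmember plus the per-pixel
    root-mean-square residual over bands.
    """
    if library.n_bands != stack.n_bands:
        raise ValueError("library band count does not match stack")
    if np.linalg.matrix_rank(library.spectra) < 1:
        raise ValueError("library has rank zero")
    A = library.spectra.T  # (bands, endmembers)
    X = stack.data.reshape(stack.n_bands, -1).astype(float)
    n_pix = X.shape[1]
    coeffs = np.zeros((library.n_endmembers, n_pix))
    # all-zero pixels have the trivial solution a = 0; skip them
    for j in np.flatnonzero(X.any(axis=0)):
        coeffs[:, j], _ = nnls(A, X[:, j])
    resid = X - A @ coeffs
    rms = np.sqrt(np.mean(resid ** 2, axis=0)).reshape(stack.image_shape)
    maps = {
        name: DetectionMap(values=coeffs[i].reshape(stack.image_shape),
                           endmember=name, kind="abundance", algorithm="LU")
        for i, name in enumerate(library.names)
    }
    return UnmixResult(maps=maps, rms_error=rms)


def sam_angle(stack: SpectralStack, target_spectrum: np.ndarray,
              endmember: str = "target") -> DetectionMap:
    """Spectral angle (radians) between each pixel and the target.

    Zero-norm pixels get the convention theta = pi/2 (maximally
    non-target) so thresholding remains defined everywhere.
    """
    r = np.asarray(target_spectrum, dtype=float)
    r_norm = np.linalg.norm(r)
    if r_norm == 0:
        raise ValueError("target spectrum must be nonzero")
    if r.size != stack.n_bands:
        raise ValueError("target band count does not match stack")
    X = stack.data.reshape(stack.n_bands, -1).astype(float)
    x_norm = np.linalg.norm(X, axis=0)
    dots = r @ X
    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = dots / (r_norm * x_norm)
    angles = np.arccos(np.clip(cosines, -1.0, 1.0))
    angles[x_norm == 0] = np.pi / 2
    return DetectionMap(values=angles.reshape(stack.image_shape),
                        endmember=endmember, kind="angle", algorithm="SAM")


@dataclass
class CEMFilter:
    """A built CEM operator: the filter vector, the sample correlation
    matrix it was derived from, and the target's name."""

    operator: np.ndarray
    correlation: np.ndarray
    target: str


def cem_build(stack: SpectralStack, target_spectrum: np.ndarray,
              target: str = "target", ridge: float = 1e-9) -> CEMFilter:
    """Derive the CEM filter from the stack's sample correlation matrix.

    R is the average outer product of all pixel spectra; when R is
    ill-conditioned a ridge ``ridge * trace(R)/B`` is added to the
    diagonal before inversion.  The built filter satisfies L.r = 1.
    """
    r = np.asarray(target_spectrum, dtype=float)
    if r.size != stack.n_bands:
        raise ValueError("target band count does not match stack")
    X = stack.pixel_spectra()  # (N, B)
    R = (X.T @ X) / X.shape[0]
    if np.linalg.cond(R) > _COND_LIMIT:
        R = R + ridge * (np.trace(R) / R.shape[0]) * np.eye(R.shape[0])
    try:
        rinv_r = np.linalg.solve(R, r)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError("sample correlation matrix is singular") from exc
    denom = float(r @ rinv_r)
    if not np.isfinite(denom) or denom == 0 or np.linalg.cond(R) > 1 / np.finfo(float).eps:
        raise ConditioningError("sample correlation matrix is singular "
                                "even after ridge regularization")
    return CEMFilter(operator=rinv_r / denom, correlation=R, target=target)


def cem_apply(cem: CEMFilter, stack: SpectralStack) -> DetectionMap:
    """Apply a CEM filter: map value is L.x per pixel."""
    if cem.operator.size != stack.n_bands:
        raise ValueError("filter band count does not match stack")
    values = np.einsum("b,brc->rc", cem.operator, stack.data.astype(float))
    return DetectionMap(values=values, endmember=cem.target,
                        kind="abundance", algorithm="CEM")


@dataclass
class MFOperator:
    """A built matched-filter operator.

    ``rejection`` is the symmetric idempotent projector P = I - U U# that
    annihilates the non-target library spectra (columns of ``background``);
    ``filter_vector`` is q = r^T P.  With ``normalized`` the applied score
    is divided by q.r so a pure target pixel scores 1.
    """

    rejection: np.ndarray
    pseudo_inverse: np.ndarray
    filter_vector: np.ndarray
    background: np.ndarray
    target: str
    normalized: bool = False


def mf_build(library: SpectralLibrary, target: str,
             normalized: bool = False) -> MFOperator:
    """Build the matched-filter rejection operator for one endmember.

    The background matrix U collects every library spectrum except the
    target; its columns must be linearly independent.
    """
    r = library.spectrum(target)
    _, others = library.without(target)
    if others.size == 0:
        # no background to reject: P is the identity
        U = np.zeros((library.n_bands, 0))
        U_pinv = np.zeros((0, library.n_bands))
        P = np.eye(library.n_bands)
    else:
        U = others.T  # (bands, m-1)
        G = U.T @ U
        if np.linalg.cond(G) > _COND_LIMIT:
            raise ConditioningError(
                "non-target spectra are linearly dependent (U^T U singular)")
        U_pinv = np.linalg.solve(G, U.T)
        P = np.eye(library.n_bands) - U @ U_pinv
    q = r @ P
    return MFOperator(rejection=P, pseudo_inverse=U_pinv, filter_vector=q,
                      background=U, target=target, normalized=normalized)


def mf_apply(op: MFOperator, stack: SpectralStack) -> DetectionMap:
    """Apply a matched filter: map value is q.x per pixel (optionally
    divided by q.r when the operator was built ``normalized``)."""
    if op.filter_vector.size != stack.n_bands:
        raise ValueError("operator band count does not match stack")
    values = np.einsum("b,brc->rc", op.filter_vector,
                       stack.data.astype(float))
    if op.normalized:
        # q.r equals q.q because P is symmetric and idempotent
        qr = float(op.filter_vector @ op.filter_vector)
        if qr == 0:
            raise ConditioningError("target lies in the background subspace")
        values = values / qr
    return DetectionMap(values=values, endmember=op.target,
                        kind="abundance", algorithm="MF")
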