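"""Theoretical sensitivity analysis (TSA) for spectral detectors.

Ground truth is created *in silico*: the target endmember spectrum r,
scaled by a, is added to every pixel of a chosen region of a real (or
simulated) control image, x' = x + a r. Running a detector over the
injected images yields three diagnostic curves:

* TSC  — the detector output over the injection region versus a, with a
  linear fit quantifying response linearity;
* TPPC — the whole-image count of pixels called positive at a fixed
  detection threshold, versus a;
* ROC  — true-positive versus false-positive rate as the threshold sweeps
  at one fixed injection level, summarized by the area under the curve.

A minimum detectable limit (MDL) is derived as the most permissive
threshold whose false-positive fraction on the un-injected image stays
within tolerance; it feeds the pixel filtering in :mod:`excitescan.kinetics`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DetectionMap, SpectralLibrary, SpectralStack
from .detectors import cem_apply, cem_build, mf_apply, mf_build, sam_angle, unmix_lu

__all__ = [
    "TSAConfig",
    "TSCResult",
    "TPPCResult",
    "ROCResult",
    "TSAResult",
    "default_config",
    "inject_target",
    "detect",
    "run_tsc",
    "run_tppc",
    "run_roc",
    "roc_curve",
    "estimate_mdl",
    "run_tsa",
    "plot_tsa",
]

DETECTORS = ("LU", "SAM", "CEM", "MF")


@dataclass
class TSAConfig:
    """Parameters of one sensitivity analysis run.

    ``a_grid`` must be ascending, nonnegative and contain 0 (the
    no-injection point that anchors the false-positive measurements);
    ``roc_scale`` is the single injection level at which the ROC threshold
    sweep runs.
    """

    roi: np.ndarray
    target: str
    detector: str
    a_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 31.0))
    roc_scale: float = 5.0
    tppc_threshold: float = 15.0
    threshold_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 51.0))
    fp_tolerance: float = 0.0

    def __post_init__(self) -> None:
        self.roi = np.asarray(self.roi, dtype=bool)
        self.a_grid = np.asarray(self.a_grid, dtype=float)
        self.threshold_grid = np.asarray(self.threshold_grid, dtype=float)
        if self.detector not in DETECTORS:
            raise ValueError(f"unknown detector {self.detector!r}")
        if self.a_grid.size == 0 or np.any(self.a_grid < 0):
            raise ValueError("a_grid must be nonnegative")
        if not np.all(np.diff(self.a_grid) > 0):
            raise ValueError("a_grid must be strictly ascending")
        if self.a_grid[0] != 0:
            raise ValueError("a_grid must contain 0")
        if self.roc_scale < 0:
            raise ValueError("roc_scale must be nonnegative")
        if self.threshold_grid.size == 0:
            raise ValueError("threshold_grid must be nonempty")
        if not 0 <= self.fp_tolerance < 1:
            raise ValueError("fp_tolerance must lie in [0, 1)")


def default_config(roi, target: str, detector: str) -> TSAConfig:
    """Detector-appropriate defaults: injections a = 0..30 in steps of 1,
    ROC at a = 5; thresholds 15 (abundance detectors) / 0.98 rad (SAM);
    ROC sweep 0..50 (abundance) / 0..1.8 rad (SAM)."""
    if detector == "SAM":
        return TSAConfig(roi=roi, target=target, detector=detector,
                         tppc_threshold=0.98,
                         threshold_grid=np.linspace(0.0, 1.8, 37))
    return TSAConfig(roi=roi, target=target, detector=detector)


def inject_target(stack: SpectralStack, roi: np.ndarray,
                  target_spectrum: np.ndarray, a: float) -> SpectralStack:
    """Add ``a`` times the target spectrum to every pixel inside ``roi``."""
    if a < 0:
        raise ValueError("injection scalar a must be nonnegative")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.image_shape:
        raise ValueError("roi shape must match image shape")
    r = np.asarray(target_spectrum, dtype=float)
    if r.size != stack.n_bands:
        raise ValueError("target band count does not match stack")
    data = stack.data.astype(float).copy()
    data[:, roi] += a * r[:, None]
    return stack.with_data(data)


def detect(stack: SpectralStack, detector: str, target: str,
           library: SpectralLibrary) -> DetectionMap:
    """Run one named detector and return the target's detection map.

    CEM rebuilds its filter from each stack's own correlation matrix, as
    the algorithm prescribes; MF and SAM use only the library.
    """
    r = library.spectrum(target)
    if detector == "LU":
        return unmix_lu(stack, library).maps[target]
    if detector == "SAM":
        return sam_angle(stack, r, endmember=target)
    if detector == "CEM":
        return cem_apply(cem_build(stack, r, target=target), stack)
    if detector == "MF":
        return mf_apply(mf_build(library, target), stack)
    raise ValueError(f"unknown detector {detector!r}")


def _positive(dmap: DetectionMap, threshold: float) -> np.ndarray:
    if dmap.positive_direction == "less":
        return dmap.values < threshold
    return dmap.values > threshold


@dataclass
class TSCResult:
    """Theoretical sensitivity curve: ROI output distribution per a."""

    a: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    distributions: list[np.ndarray]
    slope: float
    intercept: float
    r_squared: float


@dataclass
class TPPCResult:
    """Thresholded positive pixel curve: whole-image positives per a."""

    a: np.ndarray
    counts: np.ndarray
    threshold: float


@dataclass
class ROCResult:
    """ROC points (sorted by FPR, (0,0)/(1,1) appended) and trapezoid AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    roc_scale: float


@dataclass
class TSAResult:
    tsc: TSCResult
    tppc: TPPCResult
    roc: ROCResult
    auc: float
    mdl: float


def _maps_over_grid(stack, config, library, a_values):
    r = library.spectrum(config.target)
    for a in a_values:
        injected = inject_target(stack, config.roi, r, float(a))
        yield float(a), detect(injected, config.detector, config.target,
                               library)


def _tsc_from_maps(config, a_values, maps) -> TSCResult:
    distributions = [m.values[config.roi] for m in maps]
    means = np.array([d.mean() for d in distributions])
    sds = np.array([d.std(ddof=1) if d.size > 1 else 0.0
                    for d in distributions])
    fit = stats.linregress(a_values, means)
    return TSCResult(a=np.asarray(a_values), mean=means, sd=sds,
                     distributions=distributions, slope=float(fit.slope),
                     intercept=float(fit.intercept),
                     r_squared=float(fit.rvalue ** 2))


def run_tsc(stack: SpectralStack, config: TSAConfig,
            library: SpectralLibrary) -> TSCResult:
    """Detector output over the ROI versus injected amount, with an
    ordinary-least-squares linear fit of mean output against a."""
    if not config.roi.any():
        raise ValueError("empty roi")
    pairs = list(_maps_over_grid(stack, config, library, config.a_grid))
    return _tsc_from_maps(config, [a for a, _ in pairs],
                          [m for _, m in pairs])


def _tppc_from_maps(config, a_values, maps) -> TPPCResult:
    counts = np.array([int(_positive(m, config.tppc_threshold).sum())
                       for m in maps])
    return TPPCResult(a=np.asarray(a_values), counts=counts,
                      threshold=config.tppc_threshold)


def run_tppc(stack: SpectralStack, config: TSAConfig,
             library: SpectralLibrary) -> TPPCResult:
    """Whole-image positive-pixel count at the fixed detection threshold,
    versus injected amount."""
    pairs = list(_maps_over_grid(stack, config, library, config.a_grid))
    return _tppc_from_maps(config, [a for a, _ in pairs],
                           [m for _, m in pairs])


def roc_curve(dmap: DetectionMap, roi: np.ndarray, threshold_grid,
              roc_scale: float = float("nan")) -> ROCResult:
    """Threshold-sweep ROC of one detection map against an ROI.

    TPR is the positive fraction inside the ROI, FPR outside; the point
    set is sorted by FPR with (0,0) and (1,1) appended and the AUC is the
    trapezoid-rule area.
    """
    roi = np.asarray(roi, dtype=bool)
    threshold_grid = np.asarray(threshold_grid, dtype=float)
    n_roi = int(roi.sum())
    n_bg = roi.size - n_roi
    if n_roi == 0 or n_bg == 0:
        raise ValueError("roi must be neither empty nor the whole image")
    fpr = np.empty(threshold_grid.size)
    tpr = np.empty(threshold_grid.size)
    for i, t in enumerate(threshold_grid):
        pos = _positive(dmap, float(t))
        tpr[i] = pos[roi].sum() / n_roi
        fpr[i] = pos[~roi].sum() / n_bg
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=threshold_grid, fpr=fpr, tpr=tpr,
                     auc=auc, roc_scale=roc_scale)


def _roc_from_map(config, dmap: DetectionMap) -> ROCResult:
    return roc_curve(dmap, config.roi, config.threshold_grid,
                     roc_scale=config.roc_scale)


def run_roc(stack: SpectralStack, config: TSAConfig,
            library: SpectralLibrary):
    """Threshold-sweep ROC at the fixed injection level ``roc_scale``.

    Returns ``(ROCResult, auc)``. The ROI must be neither empty nor the
    whole image, otherwise one of the rates is undefined.
    """
    n_roi = int(config.roi.sum())
    if n_roi == 0 or n_roi == config.roi.size:
        raise ValueError("roi must be neither empty nor the whole image")
    r = library.spectrum(config.target)
    injected = inject_target(stack, config.roi, r, config.roc_scale)
    dmap = detect(injected, config.detector, config.target, library)
    roc = _roc_from_map(config, dmap)
    return roc, roc.auc


def _mdl_from_map(config, dmap: DetectionMap) -> float:
    grid = config.threshold_grid
    if dmap.positive_direction == "greater":
        # threshold 0 means "no filtering" in the pixel-filter convention,
        # so only positive thresholds are MDL candidates
        grid = grid[grid > 0]
    if grid.size == 0:
        raise ValueError("threshold grid has no admissible MDL candidates")
    fractions = np.array([_positive(dmap, float(t)).mean() for t in grid])
    ok = fractions <= config.fp_tolerance
    if not ok.any():
        raise ValueError("no threshold on the grid meets the "
                         "false-positive tolerance")
    if dmap.positive_direction == "less":
        # positives grow with the threshold: take the largest compliant one
        return float(grid[np.flatnonzero(ok)[-1]])
    return float(grid[np.flatnonzero(ok)[0]])


def estimate_mdl(stack: SpectralStack, config: TSAConfig,
                 library: SpectralLibrary,
                 fp_tolerance: float | None = None) -> float:
    """Minimum detectable limit from the un-injected image.

    The MDL is the most permissive threshold on the grid whose whole-image
    false-positive fraction at a = 0 stays within ``fp_tolerance``
    (default 0: no false positives at all).
    """
    if fp_tolerance is not None:
        if not 0 <= fp_tolerance < 1:
            raise ValueError("fp_tolerance must lie in [0, 1)")
        config = TSAConfig(roi=config.roi, target=config.target,
                           detector=config.detector, a_grid=config.a_grid,
                           roc_scale=config.roc_scale,
                           tppc_threshold=config.tppc_threshold,
                           threshold_grid=config.threshold_grid,
                           fp_tolerance=fp_tolerance)
    dmap = detect(stack, config.detector, config.target, library)
    return _mdl_from_map(config, dmap)


def run_tsa(stack: SpectralStack, config: TSAConfig,
            library: SpectralLibrary) -> TSAResult:
    """Full sensitivity analysis: TSC, TPPC, ROC/AUC and MDL in one pass.

    Detection maps are computed once per injection level and shared by the
    TSC and TPPC; the ROC reuses the map at ``roc_scale`` when that level
    is on the grid.
    """
    n_roi = int(config.roi.sum())
    if n_roi == 0 or n_roi == config.roi.size:
        raise ValueError("roi must be neither empty nor the whole image")
    pairs = list(_maps_over_grid(stack, config, library, config.a_grid))
    a_values = [a for a, _ in pairs]
    maps = [m for _, m in pairs]
    tsc = _tsc_from_maps(config, a_values, maps)
    tppc = _tppc_from_maps(config, a_values, maps)
    by_a = dict(zip(a_values, maps))
    if config.roc_scale in by_a:
        roc = _roc_from_map(config, by_a[config.roc_scale])
    else:
        roc, _ = run_roc(stack, config, library)
    try:
        mdl = _mdl_from_map(config, by_a[0.0])
    except ValueError:
        mdl = float("nan")  # no grid threshold meets the FP tolerance
    return TSAResult(tsc=tsc, tppc=tppc, roc=roc, auc=roc.auc, mdl=mdl)


def plot_tsa(result: TSAResult, path) -> None:
    """Write a three-panel TSC/TPPC/ROC figure as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].errorbar(result.tsc.a, result.tsc.mean, yerr=result.tsc.sd,
                     fmt="ks", ecolor="r", capsize=2)
    fit = result.tsc.intercept + result.tsc.slope * result.tsc.a
    axes[0].plot(result.tsc.a, fit, "k-", lw=1)
    axes[0].set(xlabel="added endmember signal a",
                ylabel="detector output (A.U.)", title="TSC")
    axes[1].plot(result.tppc.a, result.tppc.counts, "ko-")
    axes[1].set(xlabel="added endmember signal a",
                ylabel=f"positives @ t={result.tppc.threshold:g}",
                title="TPPC")
    axes[2].plot(result.roc.fpr, result.roc.tpr, "k-")
    axes[2].plot([0, 1], [0, 1], "k:", lw=0.5)
    axes[2].set(xlabel="false-positive rate", ylabel="true-positive rate",
                title=f"ROC (AUC = {result.auc:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
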