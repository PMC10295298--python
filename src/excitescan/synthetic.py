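"""Synthetic excitation-scanning scenes with known ground truth.

Emulates time-lapse acquisitions from a widefield microscope that scans a
narrow excitation band from 360 to 480 nm in 5 nm steps while a camera
integrates long-pass-filtered emission, one frame every 30 s for 15 min.
Scenes contain a near-confluent field of elliptical cells carrying three
spectral species: a bright 360 nm-peaked nuclear label, a Ca2+ indicator
whose excitation keeps rising past the end of the scan range (peak
~495 nm), and cellular autofluorescence. Optional agonist-triggered Ca2+
transients and shot noise complete the picture.

Autofluorescence is deliberately the hard part, as it is in real cells:
by default it is rendered as a per-pixel blend of two sub-components (a
blue-shifted NADH-like shape and a green-shifted FAD-like shape), with a
granular lognormal intensity texture inside each cell and a faint level
everywhere in the field. The analysis workflow only ever sees one
averaged "AF" endmember — exactly the model mismatch a measured spectral
library suffers from.

Every rendered pixel spectrum is, before noise, the exact
library-weighted sum of the ground-truth abundance maps (four maps when
the two AF sub-components are active), so detectors can be validated
quantitatively.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import SpectralLibrary, SpectralStack
from .library import assemble_library

__all__ = [
    "SpectrumModel",
    "CaTransient",
    "CellSpec",
    "SyntheticScene",
    "GroundTruth",
    "make_library",
    "render_scene",
    "analysis_library",
    "default_models",
    "af_submodels",
    "default_scene",
    "control_scene",
    "tsa_roi",
    "tiny_scene",
    "DEFAULT_WAVELENGTHS",
    "NUCLEAR_NAME",
    "CALCIUM_NAME",
    "AF_NAME",
]

#: Default excitation grid: 360-480 nm in 5 nm increments (25 bands).
DEFAULT_WAVELENGTHS = np.arange(360.0, 481.0, 5.0)

NUCLEAR_NAME = "NucBlue"
CALCIUM_NAME = "Cal-520"
AF_NAME = "AF"


@dataclass(frozen=True)
class SpectrumModel:
    """Parametric excitation spectrum: truncated Gaussian plus flat baseline.

    ``baseline`` is the fraction of a flat broad component mixed into the
    Gaussian peak; the evaluated spectrum is peak-normalized on the
    wavelength grid, so its maximum is exactly 1 and all values are >= 0.
    """

    name: str
    peak_nm: float
    width_nm: float
    baseline: float = 0.0

    def evaluate(self, wavelengths) -> np.ndarray:
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("baseline must lie in [0, 1]")
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")
        wl = np.asarray(wavelengths, dtype=float)
        if wl.size == 0:
            raise ValueError("empty wavelength grid")
        g = np.exp(-0.5 * ((wl - self.peak_nm) / self.width_nm) ** 2)
        s = (1.0 - self.baseline) * g + self.baseline
        peak = s.max()
        if peak <= 0:
            raise ValueError("spectrum evaluates to zero on this grid")
        return s / peak


@dataclass(frozen=True)
class CaTransient:
    """Agonist-triggered Ca2+ response: step onset, exponential decay,
    optional sinusoidal oscillation (period in seconds)."""

    onset_s: float
    amplitude: float
    decay_s: float
    period_s: float | None = None

    def value(self, t: float) -> float:
        if t < self.onset_s:
            return 0.0
        dt = t - self.onset_s
        v = self.amplitude * math.exp(-dt / self.decay_s)
        if self.period_s is not None:
            # raised cosine keeps the abundance nonnegative
            v *= 0.5 * (1.0 + math.cos(2.0 * math.pi * dt / self.period_s))
        return v


@dataclass(frozen=True)
class CellSpec:
    """An elliptical cell body with a concentric elliptical nucleus.

    Abundance levels are in the same arbitrary intensity units as rendered
    stacks (a level of ``a`` contributes ``a`` A.U. at the endmember's
    peak excitation band). The nuclear label lives in the nucleus, the
    Ca2+ indicator and autofluorescence fill the whole body; ``af_level``
    is the mean of the granular AF texture.
    """

    center: tuple[float, float]
    body_axes: tuple[float, float]
    nucleus_axes: tuple[float, float]
    ca_baseline: float = 0.0
    ca_transient: CaTransient | None = None
    nuc_level: float = 0.0
    af_level: float = 0.0

    def __post_init__(self) -> None:
        if min(self.ca_baseline, self.nuc_level, self.af_level) < 0:
            raise ValueError("abundance levels must be nonnegative")
        if (self.nucleus_axes[0] > self.body_axes[0]
                or self.nucleus_axes[1] > self.body_axes[1]):
            raise ValueError("nucleus ellipse must fit inside the body")

    def in_bounds(self, shape: tuple[int, int]) -> bool:
        r0, c0 = self.center
        ar, ac = self.body_axes
        return (r0 - ar >= 0 and r0 + ar <= shape[0] - 1
                and c0 - ac >= 0 and c0 + ac <= shape[1] - 1)

    def _ellipse(self, shape, axes) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        r0, c0 = self.center
        ar, ac = axes
        return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0

    def body_mask(self, shape) -> np.ndarray:
        return self._ellipse(shape, self.body_axes)

    def nucleus_mask(self, shape) -> np.ndarray:
        return self._ellipse(shape, self.nucleus_axes)

    def ca_level(self, t: float) -> float:
        v = self.ca_baseline
        if self.ca_transient is not None:
            v += self.ca_transient.value(t)
        return v


@dataclass(frozen=True)
class SyntheticScene:
    """Complete description of a synthetic acquisition.

    ``endmember_models`` holds exactly three models in role order
    (nuclear label, Ca2+ indicator, autofluorescence); cell abundance
    levels map onto those roles. When ``af_submodels`` is set, cellular
    autofluorescence is rendered as a per-pixel two-component blend (the
    green fraction drawn from Beta(b, b) with b = ``af_green_beta``)
    instead of the single nominal AF shape; ``af_texture_sigma`` is the
    lognormal sigma of the granular AF intensity texture inside cells and
    ``background_af`` a faint AF abundance present everywhere in the
    field. ``seed`` fully determines the output.
    """

    wavelengths: np.ndarray
    frame_interval_s: float
    n_frames: int
    image_shape: tuple[int, int]
    cells: tuple[CellSpec, ...]
    endmember_models: tuple[SpectrumModel, ...]
    noise_model: str = "none"
    noise_scale: float = 1.0
    seed: int = 0
    af_submodels: tuple[SpectrumModel, SpectrumModel] | None = None
    af_green_beta: float = 8.0
    af_texture_sigma: float = 0.0
    background_af: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths",
                           np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "endmember_models",
                           tuple(self.endmember_models))
        if (self.wavelengths.size > 1
                and not np.all(np.diff(self.wavelengths) > 0)):
            raise ValueError("wavelengths must be strictly increasing")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if len(self.endmember_models) != 3:
            raise ValueError("three endmember models required "
                             "(nuclear, calcium, autofluorescence)")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be nonnegative")
        if self.af_texture_sigma < 0 or self.background_af < 0:
            raise ValueError("AF texture sigma and background must be >= 0")
        for cell in self.cells:
            if not cell.in_bounds(self.image_shape):
                raise ValueError("cell extends outside the image")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * float(self.frame_interval_s)


@dataclass
class GroundTruth:
    """Noiseless per-endmember abundance maps (frame, row, col), per-cell
    body masks, and the library the renderer mixed with.

    When the scene uses two AF sub-components the library has four rows
    and the abundance maps four entries (the AF total splits into the
    blue and green sub-components)."""

    abundance_maps: dict[str, np.ndarray]
    masks: list[np.ndarray]
    library: SpectralLibrary


def make_library(models, wavelengths) -> SpectralLibrary:
    """Evaluate spectrum models on a wavelength grid into a library.

    Each row is peak-normalized to a maximum of exactly 1; model order is
    preserved.
    """
    models = list(models)
    wl = np.asarray(wavelengths, dtype=float)
    if not models:
        raise ValueError("at least one spectrum model required")
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    spectra = np.stack([m.evaluate(wl) for m in models])
    names = [m.name for m in models]
    return SpectralLibrary(names=names, spectra=spectra, wavelengths=wl)


def analysis_library(scene: SyntheticScene,
                     reference_green_fraction: float = 0.4) -> SpectralLibrary:
    """The three-endmember library an analyst would measure for a scene.

    For scenes with heterogeneous AF this carries a single AF row — the
    simplification a measured spectral library makes of variable cellular
    autofluorescence. ``reference_green_fraction`` sets the green
    sub-component weight of that row: the field-average composition is
    0.5, but a reference extracted from an intense AF region is
    mitochondria-rich and hence NADH-weighted, i.e. slightly blue-shifted
    of the average — the default 0.4 emulates that measured reference.
    Pass 0.5 for the ideal field-average reference.
    """
    nuc_m, ca_m, af_m = scene.endmember_models
    wl = scene.wavelengths
    if scene.af_submodels is None:
        return make_library(scene.endmember_models, wl)
    if not 0.0 <= reference_green_fraction <= 1.0:
        raise ValueError("reference_green_fraction must lie in [0, 1]")
    blue_m, green_m = scene.af_submodels
    s_af = ((1.0 - reference_green_fraction) * blue_m.evaluate(wl)
            + reference_green_fraction * green_m.evaluate(wl))
    rows = np.stack([nuc_m.evaluate(wl), ca_m.evaluate(wl), s_af])
    return assemble_library([nuc_m.name, ca_m.name, af_m.name], rows, wl)


def render_scene(scene: SyntheticScene):
    """Render a scene into spectral stacks plus ground truth.

    Returns ``(stacks, truth)`` where ``stacks`` is a list of ``n_frames``
    :class:`SpectralStack` objects of shape (bands, rows, cols). With
    ``noise_model='none'`` each pixel spectrum is exactly the
    ground-truth-library-weighted sum of the abundance maps; Poisson
    noise treats ``noise_scale`` as the camera gain g (A.U. per photon)
    and draws g * Poisson(I / g); Gaussian noise adds zero-mean noise of
    standard deviation ``noise_scale``, clipped at zero. The same scene
    (including seed) always renders bit-identical output.
    """
    nuc_m, ca_m, af_m = scene.endmember_models
    wl = scene.wavelengths
    rng = np.random.default_rng(scene.seed)
    shape = tuple(scene.image_shape)
    body_masks = [c.body_mask(shape) for c in scene.cells]
    nucleus_masks = [c.nucleus_mask(shape) for c in scene.cells]

    # static structure: nuclear map and textured cellular AF
    nuc_map = np.zeros(shape)
    af_map = np.full(shape, float(scene.background_af))
    for cell, body, nucleus in zip(scene.cells, body_masks, nucleus_masks):
        nuc_map[nucleus] += cell.nuc_level
        texture = rng.lognormal(0.0, scene.af_texture_sigma,
                                int(body.sum()))
        af_map[body] += cell.af_level * texture
    green_frac = rng.beta(scene.af_green_beta, scene.af_green_beta,
                          size=shape)

    if scene.af_submodels is None:
        names = [nuc_m.name, ca_m.name, af_m.name]
        truth_library = make_library(scene.endmember_models, wl)
        static_maps = {af_m.name: af_map}
    else:
        blue_m, green_m = scene.af_submodels
        names = [nuc_m.name, ca_m.name, blue_m.name, green_m.name]
        truth_library = make_library(
            [nuc_m, ca_m, blue_m, green_m], wl)
        static_maps = {blue_m.name: af_map * (1.0 - green_frac),
                       green_m.name: af_map * green_frac}

    n_frames = scene.n_frames
    abundance = {name: np.zeros((n_frames,) + shape) for name in names}
    stacks: list[SpectralStack] = []
    for f, t in enumerate(scene.times_s):
        abundance[nuc_m.name][f] = nuc_map
        ca_frame = np.zeros(shape)
        for cell, body in zip(scene.cells, body_masks):
            ca_frame[body] += cell.ca_level(float(t))
        abundance[ca_m.name][f] = ca_frame
        for name, amap in static_maps.items():
            abundance[name][f] = amap
        frame_maps = np.stack([abundance[name][f] for name in names])
        mixed = np.einsum("mb,mrc->brc", truth_library.spectra, frame_maps)
        if scene.noise_model == "gaussian":
            mixed = mixed + rng.normal(0.0, scene.noise_scale, mixed.shape)
            np.clip(mixed, 0.0, None, out=mixed)
        elif scene.noise_model == "poisson":
            gain = scene.noise_scale
            if gain > 0:
                mixed = gain * rng.poisson(mixed / gain).astype(float)
        stacks.append(SpectralStack(data=mixed, wavelengths=wl,
                                    time_s=float(t), corrected=True))

    truth = GroundTruth(abundance_maps=abundance, masks=body_masks,
                        library=truth_library)
    return stacks, truth


# ---------------------------------------------------------------------------
# Default study conditions

def default_models() -> tuple[SpectrumModel, SpectrumModel, SpectrumModel]:
    """Default endmember spectra on the 360-480 nm excitation scan.

    The nuclear label peaks at the first scanned band (360 nm) and decays;
    the Ca2+ indicator peaks at ~495 nm, beyond the scan range, so its
    measured spectrum rises monotonically toward 480 nm. The nominal AF
    model is a broad shape between the two sub-components; it is what
    homogeneous-AF scenes render with.
    """
    return (
        SpectrumModel(NUCLEAR_NAME, peak_nm=360.0, width_nm=35.0),
        SpectrumModel(CALCIUM_NAME, peak_nm=495.0, width_nm=45.0),
        SpectrumModel(AF_NAME, peak_nm=445.0, width_nm=80.0, baseline=0.15),
    )


def af_submodels() -> tuple[SpectrumModel, SpectrumModel]:
    """The two AF sub-components: an NADH-like blue-shifted shape and an
    FAD-like shape rising toward the green end of the scan."""
    return (
        SpectrumModel("AF-blue", peak_nm=420.0, width_nm=70.0, baseline=0.15),
        SpectrumModel("AF-green", peak_nm=465.0, width_nm=55.0, baseline=0.15),
    )


# Near-confluent field: 16 cells on a jittered 4x4 grid covering ~66% of
# a 96x96 frame (HASMCs imaged at 70-80% confluency).
_GRID = (12, 36, 60, 84)
_JITTER = [(0, 1), (2, -2), (-1, 0), (1, 2), (-2, 1), (0, -1), (2, 0),
           (-1, -2), (1, 1), (-2, 0), (0, 2), (2, -1), (-1, 1), (1, -2),
           (-2, -1), (0, 0)]
_BODY_AXES = [(11, 10), (12, 11), (10, 12), (12, 10), (11, 12), (12, 12),
              (10, 10), (11, 11), (12, 11), (10, 11), (11, 10), (12, 12),
              (10, 12), (11, 11), (12, 10), (11, 12)]
_AF_LEVELS = [25, 15, 35, 20, 30, 12, 28, 18, 22, 33, 14, 26, 19, 31, 16, 24]
_CA_BASE = [16, 12, 20, 14, 18, 10, 16, 12, 18, 14, 20, 12, 16, 10, 14, 18]
_CA_AMP = [36, 48, 30, 40, 24, 44, 32, 38, 28, 50, 34, 42, 26, 46, 30, 40]
_CA_DECAY = [150, 180, 120, 200, 150, 160, 140, 190, 170, 130, 180, 150,
             160, 140, 200, 170]
_CA_PERIOD = {0: 60.0, 9: 45.0}  # two cells show Ca2+ oscillations
#: Cells whose bodies form the default sensitivity-analysis ROI (~25%).
_TSA_CELLS = (0, 2, 4, 9, 12, 5)


def _confluent_cells(with_ca: bool, onset_s: float = 300.0
                     ) -> tuple[CellSpec, ...]:
    cells = []
    k = 0
    for i in _GRID:
        for j in _GRID:
            ar, ac = _BODY_AXES[k]
            r = min(max(i + _JITTER[k][0], ar), 95 - ar)
            c = min(max(j + _JITTER[k][1], ac), 95 - ac)
            transient = None
            ca_base = 0.0
            if with_ca:
                ca_base = float(_CA_BASE[k])
                transient = CaTransient(onset_s, float(_CA_AMP[k]),
                                        float(_CA_DECAY[k]),
                                        _CA_PERIOD.get(k))
            cells.append(CellSpec((float(r), float(c)), (float(ar), float(ac)),
                                  (6.0, 5.0), ca_baseline=ca_base,
                                  ca_transient=transient, nuc_level=400.0,
                                  af_level=float(_AF_LEVELS[k])))
            k += 1
    return tuple(cells)


def default_scene(seed: int = 0, noise_model: str = "poisson",
                  noise_scale: float = 0.25) -> SyntheticScene:
    """Default time-lapse scene: 25 bands (360-480 nm, 5 nm steps), one
    frame every 30 s for 15 min (31 frames), a near-confluent 16-cell
    field, agonist-triggered Ca2+ transients starting at 300 s,
    heterogeneous granular AF, shot noise at gain 0.25 A.U./photon."""
    return SyntheticScene(
        wavelengths=DEFAULT_WAVELENGTHS,
        frame_interval_s=30.0,
        n_frames=31,
        image_shape=(96, 96),
        cells=_confluent_cells(with_ca=True),
        endmember_models=default_models(),
        noise_model=noise_model,
        noise_scale=noise_scale,
        seed=seed,
        af_submodels=af_submodels(),
        af_texture_sigma=0.6,
        background_af=2.0,
    )


def control_scene(seed: int = 0, noise_model: str = "poisson",
                  noise_scale: float = 0.25) -> SyntheticScene:
    """Single-frame control acquisition for the sensitivity analysis:
    the same confluent field carrying every spectral component except the
    Ca2+ target (nuclear label + heterogeneous AF), so any target signal
    present afterwards is the artificially injected one."""
    return SyntheticScene(
        wavelengths=DEFAULT_WAVELENGTHS,
        frame_interval_s=30.0,
        n_frames=1,
        image_shape=(96, 96),
        cells=_confluent_cells(with_ca=False),
        endmember_models=default_models(),
        noise_model=noise_model,
        noise_scale=noise_scale,
        seed=seed,
        af_submodels=af_submodels(),
        af_texture_sigma=0.6,
        background_af=2.0,
    )


def tsa_roi(scene: SyntheticScene) -> np.ndarray:
    """Default injection region: the bodies of six designated cells
    (~25% of the field), i.e. a freehand-style region drawn over
    cell-covered area so every ROI pixel carries confounding signal."""
    if not scene.cells:
        raise ValueError("scene has no cells to place an ROI on")
    shape = tuple(scene.image_shape)
    indices = [i for i in _TSA_CELLS if i < len(scene.cells)] or [0]
    roi = np.zeros(shape, dtype=bool)
    for idx in indices:
        roi |= scene.cells[idx].body_mask(shape)
    return roi


def tiny_scene(seed: int = 0, noise_model: str = "none",
               noise_scale: float = 1.0, n_frames: int = 4) -> SyntheticScene:
    """Small fast scene (5 bands, 16x16, one cell, homogeneous AF) for
    quick exact-recovery style tests."""
    cell = CellSpec((8, 8), (5, 4), (2, 2), ca_baseline=5.0,
                    ca_transient=CaTransient(30.0, 10.0, 60.0),
                    nuc_level=50.0, af_level=8.0)
    return SyntheticScene(
        wavelengths=np.arange(400.0, 481.0, 20.0),
        frame_interval_s=30.0,
        n_frames=n_frames,
        image_shape=(16, 16),
        cells=(cell,),
        endmember_models=default_models(),
        noise_model=noise_model,
        noise_scale=noise_scale,
        seed=seed,
    )
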