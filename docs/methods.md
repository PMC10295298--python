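# Methods

This note records the models, conventions and numerical choices behind
`excitescan`, and what the synthetic scenes do and do not establish about
real data.

## Spectral correction

Illumination power `Φ(λ)` is measured per excitation band; the correction
coefficient is `cc = Φ⁻¹ / max(Φ⁻¹)`, so the weakest band gets coefficient
exactly 1 and every other band is scaled up relative to it. A raw stack is
corrected as `out = max(0, in − background) · cc`, in that order:
background subtraction first, then flattening. Negative differences are
clipped to zero because abundances are physical quantities and the
nonnegative unmixing assumes nonnegative data. The background may be a
scalar, a per-band vector (e.g. the mean over a dark region), or a full
dark stack. Correction rescales intensities, so equality with the
detector's saturation value is only meaningful on raw data;
`correct_stack` therefore records a per-pixel `saturated_mask` (any band
at or above the saturation value before correction) that reference
extraction uses to drop blown-out pixels.

## Spectral library

Reference spectra are pixel-averaged over a user-supplied region of a
corrected single-label stack, excluding saturated pixels, then
peak-normalized to a maximum of exactly 1. Libraries store normalized rows
and detectors consume them as such; CSV round trips preserve values to
full double precision (pandas writes shortest round-trip representations).

## Detectors

* **LU** solves per-pixel nonnegative least squares with SciPy's
  Lawson–Hanson implementation; all-zero pixels are skipped (their
  solution is identically zero). Per-pixel residual RMS over bands is
  reported. Active-set tie behavior follows the solver; an exhaustive
  subset-enumeration oracle in the test suite pins the solution to 1e-6.
* **SAM** returns the angle in radians, with zero-norm pixels assigned
  π/2 (maximally non-target) so that thresholding remains total. The
  angle is scale-invariant, so whether pixels are normalized first is
  immaterial.
* **CEM** forms the sample correlation matrix `R` as the average outer
  product of all pixel spectra of the analyzed image (the filter adapts
  to each frame), then `L = R⁻¹r/(rᵀR⁻¹r)`. If `cond(R) > 1e12` a ridge
  `1e-9·trace(R)/B·I` is added before inversion; a still-singular matrix
  raises a conditioning error.
* **MF** uses the rejection projector `P = I − U(UᵀU)⁻¹Uᵀ` over the
  non-target library spectra and scores `a = (rᵀP)·x`, unnormalized by
  default; a `normalized=True` build divides by `q·r` so a pure target
  pixel scores 1. With a single-endmember library `P` is the identity.

All detectors operate frame by frame on time-lapse data; no temporal
regularization is applied.

## Sensitivity analysis

Injection is performed on corrected stacks in corrected-intensity units,
with the peak-normalized library spectrum as the target, so one unit of
`a` equals one intensity unit at the target's peak band. Defaults follow
the standard protocol: `a = 0..30` in steps of 1, ROC at fixed `a = 5`,
positive-pixel threshold 15 (0.98 rad for SAM), ROC threshold sweep 0–50
(0–1.8 rad for SAM, where positivity is *below* threshold). The TSC linear
fit is unweighted ordinary least squares of mean output against `a`. ROC
rates are normalized to [0, 1] (an ideal detector has AUC 1); points are
sorted by FPR with (0,0) and (1,1) appended, and the AUC is the trapezoid
rule.

The MDL is the most permissive threshold on the grid whose whole-image
false-positive fraction at `a = 0` stays within `fp_tolerance` (default 0:
no false positives at all). For abundance maps that is the smallest
compliant threshold, excluding 0 because a zero threshold means "no
filtering" in the pixel-filter convention; for angle maps, where positives
grow with the threshold, it is the largest compliant one. With heavy-tailed
detector output (bright AF granules leaking into the target channel) the
zero-tolerance MDL can exceed the default grid; `estimate_mdl` raises in
that case while `run_tsa` records NaN so the remaining curves are still
produced.

## Pixel filtering and traces

Filters compare strictly (`> t` for abundance, `< t` for angle), so a
manual threshold of 0 excludes exact-zero background. Otsu's threshold is
computed on a 256-bin histogram between the image minimum and maximum,
returning the bin edge that maximizes between-class variance; splits
across empty bins leave the class partition unchanged and are collapsed to
their lowest edge, which also realizes the tie-break toward the lowest
threshold. Traces average detector output over a region's passing pixels
per frame; frames with no passing pixel carry NaN rather than zero (a zero
would fabricate a signal dip). The pass mask is recomputed per frame by
default (`per_frame`); `reference_frame` freezes it from a designated
frame when pixel identity should be stable across the series. Both are
recorded in run manifests.

## Synthetic scenes

The generator emulates the target acquisition protocol: 360–480 nm
excitation scan in 5 nm steps (25 bands), one frame every 30 s for 15 min
(31 frames), agonist added at t = 300 s. The default field is 96×96 pixels
with 16 elliptical cells on a jittered grid covering ~66% of the frame
(cultures imaged at 70–80% confluency). Endmember excitation spectra are
truncated Gaussians plus a flat baseline, peak-normalized on the grid: the
nuclear label peaks at the first scanned band (360 nm); the Ca²⁺ indicator
peaks at ~495 nm, beyond the scan range, so its measured spectrum rises
monotonically to 480 nm.

Autofluorescence is deliberately the hard part, as it is in real cells:

* it is a per-pixel blend of two sub-components — an NADH-like shape
  (peak 420 nm) and an FAD-like shape (peak 465 nm) — with the green
  fraction drawn per pixel from Beta(8, 8) around 0.5, because cellular AF
  composition varies with metabolic state and organelle content;
* its intensity inside each cell is granular (lognormal texture, σ = 0.6
  around the cell's mean level of 12–35 A.U./band), like punctate
  mitochondrial/lysosomal AF;
* a faint level (2 A.U.) is present everywhere in the field, as in any
  real widefield image.

The analysis workflow only ever sees a single "AF" endmember.
`analysis_library` models how that reference is obtained: a reference
extracted from an intense AF region is mitochondria-rich and hence
NADH-weighted, so its default composition (green fraction 0.4) is slightly
blue-shifted of the field average; passing 0.5 gives the ideal
field-average reference. This single-endmember simplification of variable
AF — not the noise — is what separates the detectors qualitatively: the
scale-invariant angle cannot see a fixed absolute injection on bright
heterogeneous AF, the adaptive CEM filter both absorbs the injected region
into its correlation matrix and mis-whitens signal-dependent shot noise,
while LU and MF respond linearly in absolute units.

Ca²⁺ levels are roughly twice the AF levels (baselines 10–20, transient
amplitudes 24–50 A.U.), matching the relative brightness of indicator and
AF in the target preparations; transients are step-onset with exponential
decay (120–200 s) and, in two cells, a raised-cosine oscillation (45–60 s
period). Nuclei carry the nuclear label at 400 A.U.

Noise: Gaussian (additive, clipped at zero) or Poisson. Poisson treats
`noise_scale` as the camera gain `g` in A.U. per photon and draws
`g · Poisson(I/g)`; the default `g = 0.25` (4 photons per A.U.) reflects a
back-illuminated sCMOS with binning, where corrected intensity units
understate photon counts. At `g = 1` the brightest (nuclear) pixels of the
default scene sit at peak SNR ≈ 20. One seed drives every draw (texture,
AF composition field, then per-frame noise), so identical scenes render
bit-identical stacks.

What the synthetic scenes do *not* contain: optical blur (no PSF),
photobleaching, cell motion, read noise or fixed-pattern noise, and any
AF variability beyond the two-component blend. Passing tests therefore
demonstrate algorithmic correctness and the qualitative detector
phenomenology under controlled conditions — not performance figures for
any particular instrument or preparation; quantitative AUCs and thresholds
depend on the acquisition.

## Numerical conventions

Pixel indexing is 0-based `(row, col)` with the band axis first;
multi-page TIFF pages are bands in ascending wavelength, with wavelengths
embedded as JSON metadata or carried in a `band,wavelength_nm` sidecar
CSV. Degenerate inputs fail loudly: empty ROIs, all-saturated ROIs,
all-zero spectra, constant images for Otsu, singular correlation or Gram
matrices. Problem sizes in the test suite and the acceptance script
(96×96 fields, 31 frames, 1000-pixel oracle comparisons) were chosen so
the full analysis runs in seconds while every oracle comparison remains
exhaustive.
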