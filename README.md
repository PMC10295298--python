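# excitescan

Spectral detection, sensitivity analysis and kinetic trace extraction for
**excitation-scanning hyperspectral fluorescence microscopy**.

## The problem

Excitation-scanning hyperspectral imaging (HSI) tunes a narrow excitation
band across many wavelengths (here 360–480 nm in 5 nm steps) while a camera
collects long-pass-filtered emission, so each pixel carries a sample of the
*excitation* spectrum of whatever fluoresces there. In live-cell Ca²⁺
imaging the signal of interest — a Ca²⁺ indicator whose excitation peak lies
just beyond the scan range — must be separated from a bright nuclear
counterstain and from broad, spatially heterogeneous cellular
autofluorescence (AF). This package implements and compares the four
standard pixel-wise detectors for that task, quantifies their sensitivity
with an injected-signal analysis, and uses the resulting detection limit to
filter pixels before extracting time-lapse signal traces. Everything is
exercisable on synthetic scenes with known ground truth; no external data
are needed.

## The detectors

Each pixel spectrum is modeled as a nonnegative mixture of library
endmember spectra `rᵢ` (peak-normalized excitation spectra):

    x = Σᵢ aᵢ rᵢ + w

* **LU** — nonnegatively constrained linear unmixing: per pixel solve
  `min ‖x − Rᵀa‖₂ s.t. a ≥ 0` (Lawson–Hanson NNLS), reporting abundance
  maps and the residual RMS.
* **SAM** — spectral angle mapper: `θ = arccos(r·x / ‖r‖‖x‖)`;
  brightness-invariant, smaller angle = more target-like.
* **CEM** — constrained energy minimization: `L = R⁻¹r / (rᵀR⁻¹r)` with
  `R = Σⱼ xⱼxⱼᵀ / N` the image's own sample correlation matrix; unity gain
  on the target, minimum output energy elsewhere.
* **MF** — matched filter in orthogonal-subspace-projection form:
  `P = I − U(UᵀU)⁻¹Uᵀ` rejects the non-target library spectra `U`, and the
  score is `a = (rᵀP)·x`.

The **theoretical sensitivity analysis** (TSA) adds `a·r` to every pixel of
a chosen region of a control image (`x′ = x + a·r`) and reports three
curves: the sensitivity curve (detector output in the region vs `a`, with a
linear fit), the thresholded positive-pixel curve (whole-image positives at
a fixed threshold vs `a`), and a threshold-sweep ROC at fixed `a` with its
AUC. A **minimum detectable limit** (MDL) — the most permissive threshold
with no false positives on the un-injected image — then drives **pixel
filtering**: time traces average only pixels whose detector output passes
the MDL (or an Otsu threshold), which prevents background and weakly
labeled pixels from washing out kinetic features.

## Worked example

Characterize all four detectors on the default synthetic control
acquisition (a near-confluent field of nuclei-labeled, autofluorescent
cells with shot noise, no Ca²⁺ label):

```python
import excitescan as ex
from excitescan.sensitivity import default_config, run_tsa

scene = ex.control_scene(seed=1)          # unlabeled-control acquisition
stacks, truth = ex.render_scene(scene)    # 25-band stack + ground truth
library = ex.analysis_library(scene)      # measured-style 3-endmember library
roi = ex.tsa_roi(scene)                   # injection region (~25% of field)

for detector in ("LU", "SAM", "CEM", "MF"):
    config = default_config(roi, "Cal-520", detector)
    result = run_tsa(stacks[0], config, library)
    print(f"{detector:>3}: AUC={result.auc:.3f}  "
          f"TSC slope={result.tsc.slope:+.3f}  R2={result.tsc.r_squared:.4f}  "
          f"MDL={result.mdl:g}")
```

prints

```
 LU: AUC=0.879  TSC slope=+0.988  R2=0.9998  MDL=nan
SAM: AUC=0.700  TSC slope=-0.007  R2=0.9769  MDL=0.4
CEM: AUC=0.828  TSC slope=+0.694  R2=1.0000  MDL=35
 MF: AUC=0.881  TSC slope=+0.933  R2=1.0000  MDL=50
```

Reading this: LU and MF respond linearly to injected Ca²⁺-indicator signal
(slope near 1 per unit injected, R² ≈ 1) and discriminate best (highest
AUC); CEM sits in between; SAM — a brightness-invariant angle — barely
moves for bright autofluorescent pixels and performs worst, its "slope"
being a small negative angle change. The MDL is in detector-output units;
`nan` for LU means no threshold on the default 0–50 grid eliminated every
false positive for that noise realization (the abundance leak of bright AF
granules is heavy-tailed).

The same workflow is available from the shell:

```sh
excitescan simulate --preset control --seed 1 --out sim/
excitescan tsa --stack sim/stack_t0000.tif --library sim/library.csv \
    --roi sim/tsa_roi.png --detector MF --target Cal-520 --out tsa/
excitescan simulate --preset default --seed 1 --out movie/
excitescan unmix --algorithm MF --target Cal-520 --library movie/library.csv \
    --out maps/ movie/stack_t*.tif
excitescan trace maps/Cal-520_t*.tif --region movie/cell_0.png \
    --filter manual --threshold 20 --out traces/cell0.csv
```

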