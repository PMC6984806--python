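# mpdepth

Tools for locating the depth limit of two-photon fluorescence microscopy
in scattering brain tissue, and for testing it against three-photon
reference recordings.

Two-photon excitation produces fluorescence not only in the focal volume
but — increasingly with depth — throughout the illuminated cone. Writing
F_i for the in-focus and F_oof for the out-of-focus fluorescence, the
useful signal fraction is the contrast ratio

    CR(z0) = F_i / (F_i + F_oof) = SBR / (1 + SBR),   SBR = F_i / F_oof,

and the **balance depth** is the focal depth z0 at which CR = 0.5, i.e.
where background equals signal — the postulated two-photon depth limit.
The package provides:

* **`mpdepth.optics`** — a numerical model of ballistic and scattered
  excitation in tissue (Gaussian beam with ray-cone attenuation
  exp(−a·s(z,ρ)); small-angle beam-spread function
  h ∝ exp(−3nρ²/az³⟨Θ²⟩), ⟨Θ²⟩ = 2(1−g)), the fluorescence budget
  F_i, F_oof = ∫(I_b + I_s)^m dV with its ballistic/scattered/cross
  decomposition for photon order m ∈ {2, 3}, CR-versus-depth curves,
  fluorescence-origin profiles, and the balance depth.
* **`mpdepth.contrast`** — the **empirical contrast ratio (ECR)**: from a
  paired 2P/3P movie of the same field, γ = (mean − min)/mean per
  32 × 32-pixel subregion of the time average, and
  ECR = γ_2P/γ_3P = F̄_i/(F̄_i + F̄_oof), the measured in-focus fraction
  (assuming three-photon excitation is background-free).
* **`mpdepth.tuning`** — direction tuning from 12-direction drifting
  gratings (neuropil subtraction with r = 1, per-trial ΔF/F, peak of the
  trial-averaged response, preferred direction) and cross-modality
  agreement (percent identical preferences, chance 1/12; Pearson trace
  correlation).
* **`mpdepth.synthetic`** — a generator of paired 2P/3P TIFF movies with
  known ground truth (in-focus fraction, ROI masks, tuning, schedule), so
  every stage of the analysis is testable without microscope data.

Intended users: microscopists planning deep two-photon/three-photon
experiments and analysts validating contrast-based background estimates.

## Worked example

```python
import numpy as np
from mpdepth import contrast, optics, synthetic

params = optics.OpticalParameters()  # 900 nm, NA 0.8, n 1.33, g 0.9, l 200 µm
budget = optics.contrast_ratio(params.replace(focal_depth_um=450.0))
print(f"CR(450 um) = {budget.contrast:.3f}  (SBR = {budget.sbr:.2f})")
for t in budget.terms:
    print(f"  term I_b^{t.ballistic_power} I_s^{t.scattered_power}: {t.value:.3e}")

# render a synthetic 2P/3P pair whose true in-focus fraction is CR(450),
# then re-measure that fraction with the ECR estimator
scene = synthetic.SceneSpec.random(seed=0, shape=(96, 128), n_rois=10,
                                   radius_px=(4, 6))
acq = synthetic.AcquisitionSpec(in_focus_fraction=budget.contrast, noise=True)
ds = synthetic.generate_dataset(scene, acq, seed=1, repeats=8)
pair = contrast.MoviePair(
    two_photon=contrast.preprocess(ds.pair.two_photon),
    three_photon=contrast.preprocess(ds.pair.three_photon),
)
res = contrast.empirical_contrast_ratio(pair)
print(f"rendered in-focus fraction f = {ds.in_focus_fraction:.3f}")
print(f"measured mean ECR            = {res.mean_ecr:.3f}  ({res.n_retained} subregions)")
```

prints

```
CR(450 um) = 0.835  (SBR = 5.06)
  term I_b^2 I_s^0: 9.333e-04
  term I_b^1 I_s^1: 1.719e-03
  term I_b^0 I_s^2: 2.473e-03
rendered in-focus fraction f = 0.835
measured mean ECR            = 0.824  (12 subregions)
```

At 450 µm focal depth, 83.5% of the modeled two-photon fluorescence still
originates from the focal plane; the scattered–scattered term already
dominates the background. The ECR estimator recovers the rendered
fraction to ~0.01 despite Poisson–Gaussian sensor noise.

The same computations are available from the shell:

```bash
mpdepth model curve --depths 100:800:25 --out profile.csv
mpdepth model balance-depth --out balance.json    # ≈ 660 µm at l = 200 µm
mpdepth ecr compute --movie-2p a.tif --movie-3p b.tif \
    --dark-2p d2.tif --dark-3p d3.tif --depth-um 450 --out ecr.json
mpdepth tuning compute --traces-2p t2.csv --traces-3p t3.csv \
    --schedule sched.csv --out tuning.json
mpdepth synth depth-series --depths 250,450,650 --out-dir data/
```

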