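# Methods

## The physical model

A Gaussian beam of vacuum wavelength λ enters a homogeneous scattering
medium (refractive index n, scattering length l = 1/a, anisotropy g) at
z = 0 and focuses at depth z0. Fluorescence of photon order m (2 or 3) is
generated in proportion to the m-th power of the local excitation
intensity, which is the sum of a ballistic and a scattered component.

**Ballistic light.** The unscattered beam is

    I_b(z, ρ) = (2 P0 / π w²(z)) · exp(−2ρ²/w²(z)) · exp(−a s(z, ρ)),

with 1/e² width w²(z) = c·((z0−z)² + zR²). Attenuation acts along the
ray-cone path s(z, ρ) = z·√(1 + ρ²/(z0−z)²): a ray observed at radius ρ
at depth z entered the surface at radius η = ρ·z0/(z0−z) and has travelled
z·√(1 + η²/z0²), which is the same expression. The implied ray slope
ρ/|z0−z| is capped at tan θ, θ = asin(NA/n), so the path is finite
everywhere, including at the focal plane.

**Width convention.** The Rayleigh length is taken as
zR = λ·n/(π tan²θ) and the width prefactor as c = λ/(π zR). Under this
convention the full-axis volume integral of the squared focal beam
carrying power P is exactly π P²/λ, which is also the closed form used
for the in-focus fluorescence — the two ingredients of the contrast ratio
are therefore mutually consistent. An alternative reading that divides
the width prefactor by a further factor n is available as
`width_convention="indexed"`; it rescales absolute yields but changes the
balance depth only modestly. Since neither the refractive index nor the
rendered width formula is unambiguous in this problem domain's usual
sources, the convention is a package choice, stated here once; n defaults
to 1.33 (aqueous tissue) and is configurable. The contrast ratio is
insensitive to common rescalings by construction (it is homogeneous of
degree zero in P0 and in the modality constant).

**Scattered light.** Small-angle scattering spreads an initially on-axis
ray into the normalized Gaussian

    h(z, ρ) = (3n / π a z³⟨Θ²⟩) · exp(−3n ρ² / a z³⟨Θ²⟩),   ⟨Θ²⟩ = 2(1−g),

whose total power grows as 1 − exp(−a·s). Integrating h over the surface
distribution of the incident beam gives the scattered intensity
I_s(z, ρ); the azimuthal part of that surface integral is evaluated in
closed form (it yields a modified Bessel function, computed with the
exponentially scaled `i0e`), leaving a single radial surface integral per
field point. Energy is conserved by construction: the ballistic and
scattered channels split the surface power according to exp(−a·s) per
ray, and the numerical transverse power sums stay within ~0.2% of P0.

**In-focus and out-of-focus fluorescence.** The in-focus term is the
full-axis volume integral of the unscattered focal beam carrying the
attenuated focal power P_z0, raised to the m-th power:

    F_i = π P_z0² / λ                 (m = 2)
    F_i = 2 P_z0³ / (3 π c² zR³)      (m = 3),

both validated against numerical volume quadrature. P_z0 is the limit of
the transverse ballistic power integral as z → z0. Evaluated pointwise
the integrand is singular there (the ray-slope factor diverges), but in
surface coordinates the singularity is removable:

    P_z0 = (4 P0 / w0′²) ∫ exp(−2η²/w0′²) · exp(−a z0 √(1+η²/z0²)) η dη,

i.e. a Gaussian-weighted average of per-ray cone attenuation, with
w0′ = √c·z0 the geometric surface radius of the focal cone. This choice
matters: regularizing instead by capping the slope at tan θ attenuates
every off-axis ray as if it were marginal and shifts the two-photon
balance depth ~100 µm shallower; the ray-weighted limit reproduces the
expected ≈3 scattering lengths.

The out-of-focus fluorescence integrates C·(I_b + I_s)^m over the tissue
volume outside an exclusion slab of half-depth δ (default l/5) around the
focus, from the surface (fluorophores exist only at z > 0) down to
z_max = z0 + 5l. The binomial expansion is retained term by term, giving
the pure-ballistic, pure-scattered, and cross contributions (three terms
for m = 2; four with weights 1, 3, 3, 1 for m = 3).

**Quadrature.** All integrals use composite Gauss–Legendre panels aligned
with the integrand's physical scales: the radial grid covers the
ballistic width and the scattered spread; the surface (η) grid uses
uniform panels whose width tracks the narrow Gaussian that appears near
the tissue surface (where the beam-spread width collapses as z^{3/2}),
capped between 8 and 160 panels of 16 nodes; the axial grid refines
toward the exclusion boundaries and is geometric below the focus, where
the density decays as 1/(z−z0)². Defaults reproduce 10×-refined grids to
<0.5% and can be scaled with `QuadratureSettings.refined`; a draft preset
(~1–2%) serves surveys. The balance depth — the root of CR(z0) = 0.5 —
is found by sampling CR on a user grid, verifying monotonicity (a
non-monotone sample indicates quadrature failure and raises), and
bracketed bisection to 1 µm. At the reference configuration (λ = 900 nm,
NA = 0.8, n = 1.33, g = 0.9, l = 200 µm, δ = 40 µm, m = 2) the model
yields a balance depth of ≈660 µm ≈ 3.3 scattering lengths; with
l = 150 µm it falls below 500 µm.

## The ECR estimator

The empirical contrast ratio estimates the in-focus fraction of
two-photon fluorescence from a paired, co-registered three-photon movie.
Both movies are dark-subtracted (pixel-wise mean of dark frames; negative
results clipped to zero and logged) and normalized to a common mean —
γ is scale-invariant, so normalization only guards against numeric
artifacts. The time-averaged images are tiled into 32 × 32-pixel
subregions; per subregion γ = (mean − min)/mean, and ECR_j = γ_2P/γ_3P.
Subregions with γ_3P < 0.05 (configurable) are excluded as
ratio-unstable, per-subregion values above 1 are clipped to 1 (the
unclipped mean is reported alongside), and the retained mean is the
per-depth estimate. Whole-image contrast uses 22 × 22-pixel blocks
(nearest integer tiling of the 22.5-pixel convention, trailing partial
blocks included) scoring 1 − min/max each.

The estimator is exact when the out-of-focus term is a per-subregion
additive constant and subregion means are spatially uniform; on such
noise-free synthetic pairs it recovers the rendered fraction to 1e−6.
Two bias mechanisms matter in practice and are reproduced by the
generator: (i) spatial heterogeneity of subregion means produces a small
concave (Jensen) bias; (ii) the subregion *minimum* is a noise order
statistic — if many pixels share the structural minimum, noise in the
time average drags the minimum down by ~3σ and inflates γ in both
channels, biasing ECR upward, most severely where the true 2P contrast is
small (deep focus). The bias shrinks with total collected photons per
pixel and with structural texture, which anchors the minimum; under the
generator's defaults (structural texture SD 25%, ~30–60 photons/px/frame,
2304-frame averages) the recovery error stays within ±0.02–0.05 over
f ∈ [0.2, 0.9]. Photon-starved or texture-free data will overestimate the
in-focus fraction.

## Direction tuning

Stimuli are gratings drifting in 12 directions (30° steps), 2 s on / 1 s
gray, 8 repeats each in random order. Traces are neuropil-subtracted
(F_soma − r·F_np, r = 1), converted to ΔF/F with a per-trial baseline
(the mean over the gray second preceding each presentation; a global
low-percentile baseline is available), trial-averaged per direction, and
scored by the peak of the trial-averaged trace in the stimulus window
relative to the pre-stimulus baseline ("peak of mean" — chosen over
mean-of-peaks, which is noise-inflated; both orders agree noise-free).
The preferred direction is the argmax, ties broken toward the smallest
angle and logged. ROIs with nonpositive baselines are flagged and
excluded. Cross-modality agreement: percent of ROIs with identical
preferred directions (chance 1/12 ≈ 8.3%) and Pearson correlation of the
neuropil-subtracted traces.

Known limitation: with slow-indicator kinetics (decay 1.5 s > the 1-s
gray period) calcium carryover between consecutive presentations biases
neighboring directions for broadly tuned cells, so recovery of the
generator's specified preferred direction is exact only when the decay
fits inside the gray period (verified in tests); at the slow-indicator
defaults recovery stays ≳90%. The cross-modality match statistic is
unaffected, because both channels share the same dynamics.

## The synthetic generator

The generator renders what the analysis assumes, nothing more: disk
somata (radius 6–9 px, i.e. ~9–13 µm at the 360-µm/512-px field of view;
50–90 per full field) over neuropil at ~1/9 somatic brightness, both
modulated by a static per-pixel texture (SD 25%) standing in for
structural variation; von Mises direction tuning (κ 2–5, peak ΔF/F
0.5–1.5, trial gain SD 0.15) convolved with a fast-rise (0.2 s)
slow-decay (1.5 s) indicator kernel; Poisson–Gaussian sensor noise
(2 photons per digitizer unit, read noise 0.5 DU, dark level 10 DU
estimated from 40 dark frames); 8-Hz acquisition of the full 96-trial
schedule. The two-photon channel mixes the scene S(t) with a spatially
uniform background at in-focus fraction f — constant, or tracking the
population-mean brightness ("activity-driven") — while the three-photon
channel is background-free by assumption. In both background modes the
*time-averaged* two-photon image equals f·S̄ + (1−f)·mean(S̄) exactly, so
f is the ground truth the ECR estimator should recover. f can be supplied
directly or taken from the model CR at a chosen depth to emulate a depth
series. All randomness flows from one recorded seed; identical manifests
reproduce byte-identical TIFFs.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: optical point-spread
rendering, motion, vascular shadows, segmentation errors (masks are
ground truth), non-uniform out-of-focus background, and depth-dependent
photon budgets. In particular, because a spatially uniform background
cancels exactly under r = 1 neuropil subtraction, tuning degradation in
the synthetic depth series is driven by shot-noise dilution of the
residual in-focus signal and reaches chance only at f ≈ 0.005; real
recordings degrade far earlier through segmentation and motion failures
that are upstream of this package.

## Problem sizes used in the shipped checks

Balance-depth runs sample CR at 11 depths (400–900 µm, full quadrature,
~1 s per depth) plus ~10 bisection steps. Synthetic end-to-end checks use
reduced fields (48×64 to 96×128 px, 10 ROIs) at the full frame count
where time-averaging statistics matter, and single-repeat schedules where
only geometry matters; the generator's defaults remain at study scale.
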