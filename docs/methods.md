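# Methods

This note documents the models, calibration anchors, numerical choices and
known limitations of the `thzbean` pipeline. It is written for a reader who
wants to know exactly what the code computes and what passing tests do and
do not demonstrate.

## Conventions

* Units at the API boundary: time in ps, frequency in THz, length in μm
  (mm where a field name says so). c = 299 792 458 m/s exactly
  (299.792458 μm/ps).
* Fourier convention: Ê(f) = Σ E(t) e^{+i2πft} Δt. Under this convention a
  positive delay produces a positive phase slope, absorbing media have
  Im ε ≥ 0 and κ = Im n ≥ 0, and propagation over d multiplies the field by
  e^{+i2πfnd/c}, whose magnitude e^{−2πfκd/c} decays. NumPy's FFT uses the
  opposite sign, so the implementation conjugates at the transform
  boundary.
* Transmission is referenced to an equal-length vacuum path (the
  empty-aperture reference); reflection to a perfect mirror at the front
  surface (the metal-paint reference), so the reported reflectivity is
  R̂ = |r|². The simulated mirror return is the sign-flipped incident
  field. Metal backings are modeled as r = −1 exactly.
* Penetration depth uses the **intensity** convention, δ = λ₀/(4πκ): the
  depth at which transmitted power (not field) has fallen to 1/e. The
  field-amplitude convention would give twice this value. The intensity
  convention is the one under which a water-like κ ≈ 0.318 at 0.5 THz
  corresponds to δ = 150 μm.

## Forward model

The dielectric function is a sum of Lorentz oscillators,
ε(f) = ε∞ + Σⱼ Δεⱼ f₀ⱼ²/(f₀ⱼ² − f² − iγⱼ f), with Δε ≥ 0, γ > 0. A heavily
damped oscillator with f₀ below the band plays the role of water's Debye
relaxation; its overdamped pole produces the 1/f-like absorption tail and a
small, bounded contribution to Re ε (an *underdamped* near-DC pole would
produce a large negative Re ε across the band, which is why the damping
ratio is kept above ~1.5 in the calibration).

n = √ε on the principal branch; for passive models (Im ε ≥ 0) this keeps
κ ≥ 0 and continuous. Slab transmission and reflection are computed with
2×2 characteristic matrices at normal incidence, with the Airy closed forms
documented as identities and verified against an explicit echo-summation
oracle to 10⁻⁸. The matrix cosines grow like e^{Im φ} for opaque slabs, so
Im φ is capped at 650 once the transmitted amplitude has underflowed to
zero — this affects only slabs with T below ~10⁻⁵⁰⁰.

Beam convergence, the metallic aperture, polarization and surface roughness
are not modeled: plane waves at normal incidence only. A beam that
straddles two regions of slightly different index is modeled as a coherent
area-weighted sum t = Σ wᵢ tᵢ, which reproduces interference dips at
frequencies where the partial beams are π out of phase.

## Phantom calibration (version 1)

The phantom dielectrics are implementation constants, derived once by
numerical optimization against a set of anchors and then frozen; they are
not fitted to any measured spectra.

Green (mature) beans — ε∞ = 1.0008, a relaxational oscillator
(Δε = 9.754, f₀ = 0.0781 THz, γ = 0.1188 THz, damping ratio 1.52) and a
broad high-frequency oscillator (Δε = 5.316, f₀ = 4 THz, γ = 9.401 THz).
Anchors:

* κ(0.5 THz) = 0.31809, so that δ(0.5 THz) = 150.000 μm with the exact
  value of c (the frequently quoted κ = λ₀/(4πδ) = 600/(4π·150) = 0.3183
  uses λ₀ ≈ 600 μm);
* the 1.5 mm slab transmission is dome-shaped with its maximum near
  0.22 THz and a sharp decrease toward lower frequencies;
* the 3.5 mm whole-bean transmission peaks at ≈ 7·10⁻⁵ — "well below
  0.5 %" with a wide margin, consistent with whole green beans sitting at
  the spectrometer's detection limit;
* Re n(0.5 THz) ≈ 2.44 and rising toward low frequency (the water
  relaxation), which also sets the front-surface reflectivity used by the
  bed-scan contrast.

Roasted beans — a drier matrix (ε∞ = 1.951) with the green oscillator
strengths scaled by 0.470 (relaxational) and 0.176 (high-frequency). The
two scales differ because roasting removes proportionally more of the
low-frequency (free-water) response than of the broad high-frequency
background; they were chosen so that Im n is strictly below the green
curve at every frequency, Re n(0.5) ≈ 1.65, and the roasted slab dome
peaks near 0.3 THz at ≈ 17 % transmission.

Quaker (immature) beans — the green dielectric with every oscillator
strength multiplied by the density factor ρ = 0.98209, calibrated by
bisection so that the 0.5 mm quaker slab's transmission excess over the
0.5 mm mature slab reaches 19 % at the edge of the reliable band
(T > 10⁻⁷ for both slabs, 0.1–2 THz). Because a 0.5 mm slab's
transmission depends exponentially on κd, a ~1.8 % density deficit is
enough for a ~19 % transmission excess; ρ is an *effective* optical
density factor, not a gravimetric one.

Whole beans are single effective slabs of 3.5 mm (green) / 3.8 mm
(roasted) by default; an optional two-layer variant (500 μm porous front
layer at 80 % oscillator strength) is available but off by default.

## Simulated instrument

* **Pulse** — two superposed Gaussian-derivative cycles: the main cycle
  (σ = 0.5 ps) peaks spectrally at 0.32 THz, and a 1 % fast component
  (σ/5) keeps the spectral amplitude above 10⁻³ of its peak up to 3 THz,
  as real photoconductive antennas do. Acquisition grid: 150 ps window at
  Δt = 0.05 ps (3000 samples; 6.7 GHz frequency step, 10 THz Nyquist).
* **Water vapor** — nine Lorentzian absorbance lines between 0.557 and
  1.919 THz scaled by a single relative-humidity knob (default 0.3),
  applied as a real multiplicative amplitude profile; the associated
  dispersion is neglected. The lines produce the characteristic post-pulse
  beating and divide out of transfer functions, as in the experiment.
* **Stray radiation** — a deterministic, configuration-only waveform: the
  reference pulse delayed by 10 ps, low-passed below 0.3 THz, scaled so
  its peak field is 10^{−2.5} of the reference peak. It is identical in
  every acquisition sharing a configuration ("highly stable over time")
  and is returned as the blocked-aperture record E_S(t).
* **Noise** — per trace: a delay jitter (σ = 2 fs), a single multiplicative
  amplitude factor (σ = 3·10⁻⁴), and additive white noise
  (σ = 2·10⁻⁷ of the peak field). These defaults are calibrated so that
  the amplitude ratio of two independent references deviates from unity by
  at most 0.2 % over 0.1–2 THz in ≥95 of 100 seed pairs — the instrument's
  printed reproducibility. All draws flow from named substreams of one
  top-level seed (reference-noise, sample-noise, raster-noise,
  orientation, bed-noise), so each stage is independently reproducible.
* **Scenes** — the default 32×32 bean map has an oval aperture, two side
  lobes (extinction ×0.88), a two-pixel vertical groove (×1.25) and a
  3-px embryo disc near the top (×1.55); extinction multipliers scale κ,
  thickness multipliers scale d. Bed scans draw a per-bean orientation
  factor from Beta(2, 5) rescaled to (0.02, 1] applied to the reflected
  amplitude — randomly oriented beans return an order of magnitude less
  power on average (E[o²] ≈ 0.11); plastic logo cells are flat (factor 1,
  n = 1.60); empty cells return noise.

## Processing and fitting

Default processing: Tukey window (α = 0.1) over the full trace, zero
padding ×4 (≈1.7 GHz frequency step), no echo windowing (Fabry–Pérot
echoes are modeled, not excised), no phase unwrapping anywhere. Division
guards: frequencies where the reference amplitude is below 10⁻¹² of its
peak carry 0 + 0i and a false mask; the default reliability mask
additionally requires T > 10⁻⁷ strictly.

The fit minimizes w_T‖log₁₀T_m − log₁₀T_d‖² + w_Re‖ΔRe t‖² + w_Im‖ΔIm t‖²
over masked-true frequencies in the fit band (default 0.1–2 THz), with
unit weights; the log-intensity block equalizes the dome's several-decade
dynamic range. Thickness is a fixed input, not a fit parameter. The
deterministic initializer estimates Re n from wrapped phase increments
(a local derivative, not an unwrap), Im n from the thin-slab absorbance
−ln|t|·c/(2πfd), places oscillators at 0.01 and 4 THz, and solves a small
linear system for the starting strengths. Optimization is trust-region
least squares (scipy) with bounds; an 8-start seeded multi-start runs when
the first attempt converges poorly. Oscillator centers remain free within
bounds — the calibrated green relaxator actually sits at 0.078 THz and is
recovered from the 0.01 THz start.

Windowing and pad-interpolation introduce absolute errors of order 10⁻⁵ in
t(ω), which matter only where |t| itself is ~10⁻⁴ (near the reliability
floor). The parameter-recovery oracle tests therefore process with
`window="none", pad_factor=1` — exact for circularly constructed synthetic
data — to isolate what they test (band truncation, not window leakage).
The headline penetration-depth chain uses the default processing and is
insensitive to this (150.01 vs 150.00 μm).

## Statistics

The green/roasted contrast statistic is the difference of group means of
band-integrated (0.2–0.8 THz) reflectivity; significance comes from a
two-sided label-permutation test with p = (1 + #{|s*| ≥ |s|})/(nperm + 1),
bounded below by 1/(nperm+1). A Mann–Whitney rank statistic is available
as an alternative. The type-I error of the default test is verified to be
5 % ± 2 % over 1000 null trials.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute of
CPU: 3000-sample traces, 100 seed pairs for the noise calibration, 100
random slabs for the oracle-equivalence property, 1000 null trials at 199
permutations for the test calibration, one 32×32 raster and one 14×14 bed
scene (60 green + 60 roasted + 24 plastic + 52 empty cells). The
acceptance script uses the same sizes.

## What the phantoms do and do not show

The generator reproduces the *structure* of real measurements — stray
contamination, vapor beating, dynamic-range masking, Fabry–Pérot echoes,
sample-orientation spread — with dielectrics that are smooth two-oscillator
surrogates. It does not emulate sample-to-sample biological variability,
diffraction at the aperture, beam-waist chromatism in transmission (only
imaging applies the spot-size blur), depolarization, or scattering from
surface roughness. Passing tests therefore demonstrate that the analysis
chain is correct and self-consistent (it recovers known ground truth under
realistic nuisance effects), not that the calibrated constants equal the
optical constants of any particular bean lot.

## Known limitations

* The Lorentz family cannot produce both κ(0.5) ≈ 0.32 and a slab
  transmission window extending to 2 THz with an interior dome maximum at
  0.3 THz; the calibration favors the penetration-depth and opacity
  anchors, so the green slab's reliable band ends near 0.65 THz (the real
  instrument's green-slab window is wider).
* Increasing an oscillator strength always increases Im ε pointwise and
  always lowers the band-integrated transmitted power, but can *raise*
  T(f) at isolated frequencies by shifting Fabry–Pérot fringes (and can
  locally lower κ where it raises Re ε faster than Im ε). The monotone
  "more strength, more absorption" property is asserted in those two
  forms, not pointwise in T.
* Reflection simulations support single-layer phantoms only; multilayer
  stacks are transmission-only.
* No uncertainty quantification beyond residual norms: the experimental
  error bars represent sample-to-sample spread, which lives in the phantom
  replication, not the fitter.
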