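# thzbean

Terahertz time-domain spectroscopy (THz-TDS) of coffee beans, end to end:
from simulated time-domain field traces to the complex refractive index
n(ω), penetration depth, predicted reflectivity, and frequency-binned
transmission/reflection imaging.

## The problem

Coffee-bean sorting today relies on visual inspection and near-infrared
spectroscopy, which probes only the outer tens of microns of a bean's skin.
THz radiation penetrates far deeper — the intensity penetration depth of a
green bean is about 150 μm at 0.5 THz — and the THz optical properties of a
bean are dominated by its internal moisture. That makes THz spectroscopy a
candidate for sorting beans by composition: green (moist) beans absorb and
reflect markedly more THz radiation than roasted (dry) ones, and
lower-density immature "quaker" beans transmit measurably more than mature
ones. This package implements the full analysis pipeline for such
measurements as a tested, reusable library, with a phantom-bean simulator
standing in for the spectrometer so every stage has known ground truth.

## The method

A THz-TDS instrument records the transmitted electric field E_T(t) of a
single-cycle pulse. The pipeline processes it as follows:

1. **Stray correction** — a blocked-aperture record E_S(t) captures the
   radiation that diffracts around the sample holder; it is subtracted
   from E_T(t) before any transform. Without it, spurious low-frequency
   transmission bands appear for opaque samples.
2. **Transfer function** — windowed, zero-padded Fourier transforms give
   the complex transmission t(ω) = Ê_T(ω)/Ê_0(ω) against an empty-aperture
   reference, with intensity T(ω) = |t(ω)|² and a reliability mask
   (T > 10⁻⁷, the instrument's dynamic-range floor).
3. **Dielectric fit** — the sample is modeled as a homogeneous slab with a
   two-oscillator Lorentz dielectric,
   ε(f) = ε∞ + Σⱼ Δεⱼ f₀ⱼ²/(f₀ⱼ² − f² − iγⱼ f),
   one heavily damped oscillator below the band (the relaxational response
   of water) and one broad oscillator near 4 THz. The slab transmission is
   computed by the transfer-matrix method (all Fabry–Pérot echoes), and
   log₁₀ T(ω), Re t(ω) and Im t(ω) are fitted simultaneously by
   trust-region least squares — amplitude and phase are pinned without any
   phase unwrapping.
4. **Derived optics** — from the fitted n(ω) = n′ + iκ: the intensity
   penetration depth δ = λ₀/(4πκ); the predicted mirror-referenced
   reflectivity R̂(ω) of a whole bean including its Fabry–Pérot structure;
   and a two-sample permutation test for the green-vs-roasted contrast of
   band-integrated (0.2–0.8 THz) reflectivity.
5. **Imaging** — raster scans are reduced to per-pixel band-integrated
   spectral power ∫|Ê(f)|² df in 0.2 THz bins between 0.2 and 1.2 THz,
   with the frequency-dependent beam spot (≈3 mm 1/e² diameter at 1 THz)
   applied as a Gaussian point-spread blur.

The `phantom` module generates all inputs with known ground truth:
calibrated green/roasted/quaker dielectrics, slab and whole-bean
measurements with stray radiation, water-vapor line beating and calibrated
noise, 32×32 bean maps (side lobes, groove, embryo), and reflection-mode
bed scans with random bean orientation.

## Worked example

```python
import numpy as np
import thzbean as tb

# simulate a noise-free measurement of a 1.5 mm green bean slab
cfg = tb.AcquisitionConfig(rng_seed=1).noise_free()
phantom = tb.make_bean_phantom("green_slab")
sample, reference, stray = tb.simulate_measurement(phantom, cfg)

# stray-correct, transform, divide
corrected = tb.subtract_stray(sample, stray)
tf = tb.transfer_function(tb.to_spectrum(corrected), tb.to_spectrum(reference))

# fit the two-oscillator Lorentz model through the transfer matrix
fit = tb.fit_dielectric(tf, 1500.0, tb.FitConfig(seed=1))
curve = tb.recovered_index(fit, np.linspace(0.4, 0.6, 41))
n05 = curve.at(0.5)
print(f"fit converged: {fit.converged}")
print(f"n(0.5 THz) = {n05.real:.3f} + {n05.imag:.4f}i")
print(f"penetration depth at 0.5 THz: {tb.penetration_depth(curve, 0.5):.1f} um")

# contrast between green and roasted beans in a simulated bed scan
scan = tb.simulate_bed_pattern(tb.default_bed_layout(),
                               tb.AcquisitionConfig(rng_seed=1))
_, groups = tb.integrated_reflect_map(scan, band=(0.2, 0.8))
report = tb.contrast_test(groups["green"], groups["roasted"],
                          nperm=9999, seed=1)
print(f"bed scan: green mean R = {groups['green'].mean():.4f}, "
      f"roasted mean R = {groups['roasted'].mean():.4f}, "
      f"p = {report.p_value:.4g}")
```

prints

```
fit converged: True
n(0.5 THz) = 2.415 + 0.3181i
penetration depth at 0.5 THz: 150.0 um
bed scan: green mean R = 0.0185, roasted mean R = 0.0059, p = 0.0001
```

The recovered index at 0.5 THz matches the phantom's ground truth
(κ = 0.3181, i.e. δ = 150 μm), and the permutation test on 60 green vs 60
roasted cells rejects at its resolution floor of 10⁻⁴: randomly oriented
green beans still reflect about three times more band-integrated THz power
than roasted ones.

A command-line interface mirrors the library
(`thzbean simulate | process | fit | reflect | image | bedscan | classify`);
every artifact is plain text (thz-tsv, CSV, JSON) and carries its
configuration and seed.

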