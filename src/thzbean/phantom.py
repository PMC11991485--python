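"""Synthetic coffee-bean phantoms and a simulated THz-TDS instrument.

Everything downstream of the spectrometer is testable against this module:
it generates single-cycle reference pulses, transmission/reflection
measurements of slab and whole-bean phantoms with known Lorentz dielectric
ground truth, 2D bean maps for raster imaging, and reflection-mode bed
scans of bean patterns.

Calibration constants
---------------------
The phantom dielectrics are implementation constants, derived once
(``CALIBRATION_VERSION`` 1) by matching a set of anchors and then frozen:

* green beans: Im n(0.5 THz) = 0.31809, so the intensity penetration depth
  at 0.5 THz is exactly 150 μm; a dome-shaped 1.5 mm slab transmission
  peaking near 0.22 THz with a sharp low-frequency decrease; a 3.5 mm
  whole-bean peak transmission of ≈ 7·10⁻⁵ (well below 0.5 %);
* roasted beans: strictly lower Im n at every frequency (less moisture),
  higher transmission, lower front-surface reflectivity;
* quaker (immature) beans: the green dielectric with all oscillator
  strengths scaled by the density factor ρ = 0.98209, calibrated so the
  0.5 mm quaker slab transmits at most 19 % more than the mature slab
  across the reliable band.

The near-DC oscillator is a heavily damped resonance below the band that
plays the role of water's dielectric relaxation; the 4 THz oscillator
accounts for the gradual high-frequency decline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import (
    C_UM_PS,
    DegeneratePhantomError,
    FieldTrace,
    RasterScan,
    ThzBeanError,
)
from .dielectric import (
    LorentzDielectric,
    LorentzOscillator,
    RefractiveIndexCurve,
    refractive_index,
    slab_reflectivity,
    slab_transmission,
    stack_transmission,
)

__all__ = [
    "CALIBRATION_VERSION",
    "GREEN_DIELECTRIC",
    "ROASTED_DIELECTRIC",
    "QUAKER_DENSITY_FACTOR",
    "AcquisitionConfig",
    "PhantomLayerStack",
    "BeanMap2D",
    "make_bean_phantom",
    "reference_pulse_waveform",
    "simulate_reference_pulse",
    "simulate_measurement",
    "make_bean_map",
    "simulate_raster",
    "default_bed_layout",
    "simulate_bed_pattern",
    "quaker_transmission_excess",
]

# --------------------------------------------------------------------------
# Frozen calibration constants (version 1)
# --------------------------------------------------------------------------

CALIBRATION_VERSION = 1

#: Green (mature, unroasted) bean dielectric.
GREEN_DIELECTRIC = LorentzDielectric(
    1.00083893,
    (
        LorentzOscillator(9.75378257, 0.07813007, 0.11876662),  # relaxational
        LorentzOscillator(5.31552870, 4.0, 9.40140120),  # broad high-THz
    ),
)

#: Roasted bean: reduced oscillator strengths (moisture loss) on a drier matrix.
_ROASTED_SCALE_RELAX = 0.46987726
_ROASTED_SCALE_HIGH = 0.17593257
ROASTED_DIELECTRIC = LorentzDielectric(
    1.95092457,
    (
        LorentzOscillator(
            GREEN_DIELECTRIC.oscillators[0].strength * _ROASTED_SCALE_RELAX,
            GREEN_DIELECTRIC.oscillators[0].center,
            GREEN_DIELECTRIC.oscillators[0].damping,
        ),
        LorentzOscillator(
            GREEN_DIELECTRIC.oscillators[1].strength * _ROASTED_SCALE_HIGH,
            GREEN_DIELECTRIC.oscillators[1].center,
            GREEN_DIELECTRIC.oscillators[1].damping,
        ),
    ),
)

#: Oscillator-strength scale of the lower-density quaker bean.
QUAKER_DENSITY_FACTOR = 0.98209398

SLAB_THICKNESS_UM = 1500.0
GREEN_WHOLE_THICKNESS_UM = 3500.0
ROASTED_WHOLE_THICKNESS_UM = 3800.0
THIN_SLAB_THICKNESS_UM = 500.0

#: Real refractive index of the 3D-printed plastic used in bed-scan logos.
PLASTIC_INDEX = 1.60

#: Strong ambient water-vapor lines (center THz, relative strength, HWHM THz).
WATER_VAPOR_LINES = (
    (0.557, 1.0, 0.006),
    (0.752, 1.6, 0.006),
    (0.988, 1.3, 0.006),
    (1.097, 2.6, 0.007),
    (1.163, 2.1, 0.007),
    (1.411, 1.5, 0.008),
    (1.603, 1.9, 0.008),
    (1.669, 3.4, 0.009),
    (1.919, 2.0, 0.009),
)

#: Named RNG substreams: every stochastic draw flows from
#: (rng_seed, stream id, realization) so stages are independently reproducible.
_STREAMS = {
    "reference-noise": 1,
    "sample-noise": 2,
    "raster-noise": 3,
    "orientation": 4,
    "bed-noise": 5,
}


def _rng(seed: int, stream: str, realization: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream], int(realization)])


# --------------------------------------------------------------------------
# Configuration and phantom types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition settings of the simulated time-domain spectrometer.

    Times in ps, frequencies in THz.  ``pulse_width`` is the Gaussian width
    σ of the main single-cycle component; the emitted spectrum peaks near
    1/(2πσ).  The default noise parameters are calibrated so that the
    amplitude ratio of two independently simulated references stays within
    ±0.2 % over 0.1–2 THz (the instrument's printed reproducibility).
    """

    time_window: float = 150.0
    dt: float = 0.05
    pulse_delay: float = 25.0
    pulse_width: float = 0.5
    relative_amplitude_noise: float = 3e-4
    additive_noise_sd: float = 2e-7
    delay_jitter_sd: float = 2e-3
    stray_fraction: float = 10.0**-2.5
    water_vapor: bool = True
    humidity: float = 0.3
    vapor_lines: tuple = WATER_VAPOR_LINES
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.time_window < 30.0 * self.pulse_width:
            raise ValueError("time_window must be >= 30 x pulse_width")
        for name in ("relative_amplitude_noise", "additive_noise_sd",
                     "delay_jitter_sd", "stray_fraction", "humidity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if 1.0 / self.time_window > 0.03:
            raise ValueError("frequency grid must resolve 0.03 THz "
                             "(time_window too short)")
        if 0.5 / self.dt < 3.0:
            raise ValueError("frequency grid must reach 3 THz (dt too coarse)")

    @property
    def n_samples(self) -> int:
        return int(round(self.time_window / self.dt))

    def time_axis(self) -> np.ndarray:
        return self.dt * np.arange(self.n_samples)

    def frequency_axis(self) -> np.ndarray:
        return np.fft.rfftfreq(self.n_samples, self.dt)

    def noise_free(self) -> "AcquisitionConfig":
        """Copy with every stochastic term switched off."""
        return replace(self, relative_amplitude_noise=0.0,
                       additive_noise_sd=0.0, delay_jitter_sd=0.0)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["vapor_lines"] = [list(line) for line in self.vapor_lines]
        return d


@dataclass(frozen=True)
class PhantomLayerStack:
    """Ordered dielectric layers with a backing, the fit's ground truth."""

    layers: tuple  # of (LorentzDielectric, thickness_um)
    backing: str = "air"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer required")
        for _, d in self.layers:
            if d <= 0:
                raise ValueError("layer thickness must be positive")
        if self.backing not in ("air", "metal"):
            raise ValueError(f"unknown backing {self.backing!r}")

    @property
    def total_thickness_um(self) -> float:
        return float(sum(d for _, d in self.layers))


_PHANTOM_VARIANTS = {
    "green_slab": (GREEN_DIELECTRIC, SLAB_THICKNESS_UM),
    "roasted_slab": (ROASTED_DIELECTRIC, SLAB_THICKNESS_UM),
    "green_whole": (GREEN_DIELECTRIC, GREEN_WHOLE_THICKNESS_UM),
    "roasted_whole": (ROASTED_DIELECTRIC, ROASTED_WHOLE_THICKNESS_UM),
    "mature_slab_0p5": (GREEN_DIELECTRIC, THIN_SLAB_THICKNESS_UM),
}


def make_bean_phantom(
    variant: str, two_layer: bool = False, density_factor: float | None = None
) -> PhantomLayerStack:
    """Default calibrated phantom for a named bean variant.

    ``quaker_slab`` equals ``mature_slab_0p5`` with all oscillator strengths
    scaled by ``density_factor`` (default :data:`QUAKER_DENSITY_FACTOR`).
    ``two_layer`` adds an optional more-porous front layer to whole-bean
    variants (off by default).
    """
    if variant == "quaker_slab":
        rho = QUAKER_DENSITY_FACTOR if density_factor is None else density_factor
        return PhantomLayerStack(
            ((GREEN_DIELECTRIC.scaled(rho), THIN_SLAB_THICKNESS_UM),),
            label="quaker_slab",
        )
    if variant not in _PHANTOM_VARIANTS:
        raise ValueError(f"unknown phantom variant {variant!r}")
    diel, d = _PHANTOM_VARIANTS[variant]
    if two_layer and variant in ("green_whole", "roasted_whole"):
        # porous flat side: 500 μm at 80 % oscillator strength
        return PhantomLayerStack(
            ((diel.scaled(0.8), 500.0), (diel, d - 500.0)), label=variant
        )
    return PhantomLayerStack(((diel, d),), label=variant)


# --------------------------------------------------------------------------
# Pulse, vapor, stray
# --------------------------------------------------------------------------


def reference_pulse_waveform(cfg: AcquisitionConfig, t: np.ndarray) -> np.ndarray:
    """Closed-form emitted field: two superposed Gaussian-derivative cycles.

    The main cycle (width σ = ``pulse_width``) peaks spectrally near
    1/(2πσ) ≈ 0.32 THz; a 1 % fast component of width σ/5 keeps the
    spectral amplitude above 10⁻³ of its peak up to 3 THz.
    """
    u = np.asarray(t, dtype=float) - cfg.pulse_delay
    out = np.zeros_like(u)
    for amp, sigma in ((1.0, cfg.pulse_width), (0.01, cfg.pulse_width / 5.0)):
        # derivative of a Gaussian, peak-normalized to `amp`
        out += -amp * (u / sigma) * np.exp(0.5 - u**2 / (2.0 * sigma**2))
    return out


def vapor_amplitude(cfg: AcquisitionConfig, f: np.ndarray) -> np.ndarray:
    """Multiplicative amplitude transmission of ambient water vapor.

    A sum of Lorentzian absorbance lines scaled by the single ``humidity``
    knob; purely real (the associated dispersion is neglected).
    """
    f = np.asarray(f, dtype=float)
    absorbance = np.zeros_like(f)
    for center, strength, hwhm in cfg.vapor_lines:
        absorbance += strength * hwhm**2 / ((f - center) ** 2 + hwhm**2)
    return np.exp(-cfg.humidity * absorbance)


def _clean_reference_field(cfg: AcquisitionConfig) -> np.ndarray:
    """Noise-free reference field on the acquisition grid (vapor included)."""
    t = cfg.time_axis()
    field = reference_pulse_waveform(cfg, t)
    if cfg.water_vapor:
        spec = np.fft.rfft(field)
        field = np.fft.irfft(spec * vapor_amplitude(cfg, cfg.frequency_axis()),
                             n=cfg.n_samples)
    return field


def _apply_noise(
    field: np.ndarray, cfg: AcquisitionConfig, rng: np.random.Generator
) -> np.ndarray:
    """Delay jitter, then a single amplitude factor, then additive noise."""
    n = field.size
    if cfg.delay_jitter_sd > 0:
        tau = rng.normal(0.0, cfg.delay_jitter_sd)
        freq = np.fft.rfftfreq(n, cfg.dt)
        field = np.fft.irfft(
            np.fft.rfft(field) * np.exp(-2j * np.pi * freq * tau), n=n
        )
    else:
        rng.normal(0.0, 1.0)  # keep the substream layout fixed
    if cfg.relative_amplitude_noise > 0:
        field = field * (1.0 + rng.normal(0.0, cfg.relative_amplitude_noise))
    else:
        rng.normal(0.0, 1.0)
    if cfg.additive_noise_sd > 0:
        field = field + rng.normal(0.0, cfg.additive_noise_sd, n)
    return field


def stray_waveform(cfg: AcquisitionConfig) -> np.ndarray:
    """Deterministic stray field: a delayed, low-passed replica of the pulse.

    The stray path (diffraction around the sample holder) arrives 10 ps
    late, carries only content below ≈ 0.3 THz, and is scaled so its peak
    field is ``stray_fraction`` of the reference peak.  It depends on the
    configuration only, never on the sample — the experimental stray was
    highly stable over time.
    """
    base = _clean_reference_field(cfg)
    freq = cfg.frequency_axis()
    lowpass = 1.0 / np.sqrt(1.0 + (freq / 0.3) ** 8)
    delayed = np.fft.irfft(
        np.fft.rfft(base) * lowpass * np.exp(-2j * np.pi * freq * 10.0),
        n=cfg.n_samples,
    )
    peak = np.max(np.abs(delayed))
    if peak == 0.0 or cfg.stray_fraction == 0.0:
        return np.zeros_like(delayed)
    return delayed * (cfg.stray_fraction * np.max(np.abs(base)) / peak)


# --------------------------------------------------------------------------
# Single-point simulations
# --------------------------------------------------------------------------


def simulate_reference_pulse(
    cfg: AcquisitionConfig, realization: int = 0
) -> FieldTrace:
    """A clear-aperture reference trace (vapor + noise per the config).

    ``realization`` selects an independent noise draw from the
    ``reference-noise`` substream; the trace is otherwise deterministic.
    """
    field = _clean_reference_field(cfg)
    field = _apply_noise(field, cfg, _rng(cfg.rng_seed, "reference-noise",
                                          realization))
    return FieldTrace(
        cfg.time_axis(), field, kind="reference",
        meta={"geometry": "transmission", "seed": cfg.rng_seed,
              "realization": realization, "config": cfg.as_dict(),
              "calibration_version": CALIBRATION_VERSION},
    )


def _stack_index_curves(
    phantom: PhantomLayerStack, f: np.ndarray
) -> list[tuple[RefractiveIndexCurve, float]]:
    return [(refractive_index(diel, f), d) for diel, d in phantom.layers]


def phantom_transfer(
    phantom: PhantomLayerStack, f: np.ndarray, geometry: str = "transmission"
):
    """Ground-truth transfer function of a phantom on a frequency grid."""
    layers = _stack_index_curves(phantom, f)
    if geometry == "transmission":
        if len(layers) == 1:
            return slab_transmission(layers[0][0], layers[0][1])
        return stack_transmission(layers)
    if geometry == "reflection":
        if len(layers) != 1:
            raise ThzBeanError("reflection supports single-layer phantoms only")
        n, d = layers[0]
        if phantom.backing == "air" and np.max(np.abs(n.n - 1.0)) < 1e-9:
            raise DegeneratePhantomError(
                "vacuum phantom with air backing reflects nothing"
            )
        return slab_reflectivity(n, d, backing=phantom.backing)
    raise ValueError(f"unknown geometry {geometry!r}")


def simulate_measurement(
    phantom: PhantomLayerStack,
    cfg: AcquisitionConfig,
    geometry: str = "transmission",
) -> tuple[FieldTrace, FieldTrace, FieldTrace]:
    """Simulate one (sample, reference, stray) acquisition of a phantom.

    Transmission: the sample trace is the reference propagated through the
    phantom (empty-aperture referencing) plus the stray field plus noise.
    Reflection: the reference is the perfect-mirror return at the front
    surface (field flipped in sign), the sample the phantom's reflection.
    The stray trace is the blocked-aperture record E_S(t) and is exactly
    identical across calls sharing a configuration.
    """
    t = cfg.time_axis()
    freq = cfg.frequency_axis()
    base = _clean_reference_field(cfg)
    tf = phantom_transfer(phantom, freq, geometry)
    # physical convention e^{+i2πft} <-> numpy's e^{-i2πft}: conjugate
    sample_clean = np.fft.irfft(np.fft.rfft(base) * np.conj(tf.values),
                                n=cfg.n_samples)
    ref_clean = base if geometry == "transmission" else -base
    stray_field = stray_waveform(cfg)

    sample_field = _apply_noise(sample_clean, cfg,
                                _rng(cfg.rng_seed, "sample-noise"))
    sample_field = sample_field + stray_field
    ref_field = _apply_noise(ref_clean, cfg, _rng(cfg.rng_seed,
                                                  "reference-noise"))
    meta = {
        "geometry": geometry,
        "phantom": phantom.label,
        "thickness_um": phantom.total_thickness_um,
        "seed": cfg.rng_seed,
        "config": cfg.as_dict(),
        "calibration_version": CALIBRATION_VERSION,
    }
    sample = FieldTrace(t, sample_field, kind="sample", meta=dict(meta))
    reference = FieldTrace(t, ref_field, kind="reference", meta=dict(meta))
    stray = FieldTrace(t, stray_field, kind="stray", meta=dict(meta))
    return sample, reference, stray


# --------------------------------------------------------------------------
# 2D bean maps and raster scans
# --------------------------------------------------------------------------


@dataclass
class BeanMap2D:
    """Per-pixel thickness/extinction multipliers with region labels."""

    thickness_mult: np.ndarray
    extinction_mult: np.ndarray
    region: np.ndarray  # str labels: outside/bulk/lobe/groove/embryo
    aperture: np.ndarray  # bool, True inside the elliptical aperture
    pitch_mm: float = 0.3
    label: str = ""

    REGIONS = ("outside", "bulk", "lobe", "groove", "embryo")

    def __post_init__(self) -> None:
        shape = self.thickness_mult.shape
        for name in ("extinction_mult", "region", "aperture"):
            if getattr(self, name).shape != shape:
                raise ValueError("map layers must share one shape")
        inside = self.aperture
        if np.any(self.thickness_mult[inside] <= 0) or np.any(
            self.extinction_mult[inside] <= 0
        ):
            raise ValueError("multipliers must be positive inside the aperture")
        if not set(np.unique(self.region)) <= set(self.REGIONS):
            raise ValueError("unknown region label")
        if np.any((self.region == "outside") != ~inside):
            raise ValueError("outside label must match the aperture mask")


def make_bean_map(variant: str = "roasted") -> BeanMap2D:
    """Default 32×32 bean map: oval aperture, side lobes, groove, embryo.

    The embryo is a small disc near the top of the aperture with the
    highest extinction; the vertical groove is a contiguous stripe of
    increased extinction; the two side lobes transmit slightly more than
    the bulk.
    """
    if variant not in ("green", "roasted"):
        raise ValueError(f"unknown bean map variant {variant!r}")
    ny = nx = 32
    y, x = np.mgrid[0:ny, 0:nx]
    cy = cx = (ny - 1) / 2.0
    aperture = ((x - cx) / 10.5) ** 2 + ((y - cy) / 13.5) ** 2 <= 1.0
    region = np.full((ny, nx), "outside", dtype=object)
    region[aperture] = "bulk"
    lobe = np.zeros_like(aperture)
    for lx in (cx - 5.5, cx + 5.5):
        lobe |= ((x - lx) / 3.5) ** 2 + ((y - cy) / 8.0) ** 2 <= 1.0
    region[aperture & lobe] = "lobe"
    groove = np.abs(x - cx) <= 1.0
    region[aperture & groove] = "groove"
    # small disc near the top of the aperture, beside the groove
    embryo = (x - (cx - 3.5)) ** 2 + (y - 6.0) ** 2 <= 1.4**2
    region[aperture & embryo] = "embryo"
    ext = np.ones((ny, nx))
    ext[region == "lobe"] = 0.88
    ext[region == "groove"] = 1.25
    ext[region == "embryo"] = 1.55
    thick = np.ones((ny, nx))
    region_str = region.astype(str)
    return BeanMap2D(thick, ext, region_str, aperture, pitch_mm=0.3,
                     label=variant)


def simulate_raster(
    bean_map: BeanMap2D, base_phantom: PhantomLayerStack, cfg: AcquisitionConfig
) -> RasterScan:
    """Transmission raster scan: one trace per map pixel.

    Each pixel propagates the reference through the base phantom with that
    pixel's thickness multiplier (on d) and extinction multiplier (on κ).
    Outside-aperture pixels transmit nothing (additive noise only).
    """
    if len(base_phantom.layers) != 1:
        raise ThzBeanError("raster simulation supports single-layer phantoms")
    diel, d0 = base_phantom.layers[0]
    freq = cfg.frequency_axis()
    n0 = refractive_index(diel, freq).n
    ny, nx = bean_map.aperture.shape
    inside = np.flatnonzero(bean_map.aperture.ravel())
    th = bean_map.thickness_mult.ravel()[inside, None]
    ex = bean_map.extinction_mult.ravel()[inside, None]
    n_px = n0.real[None, :] + 1j * ex * n0.imag[None, :]
    d_px = th * d0
    # vacuum-referenced Airy transmission, vectorized over pixels
    r1 = (n_px - 1.0) / (n_px + 1.0)
    t_px = (
        4.0 * n_px / (n_px + 1.0) ** 2
        * np.exp(2j * np.pi * freq[None, :] * (n_px - 1.0) * d_px / C_UM_PS)
        / (1.0 - r1**2 * np.exp(4j * np.pi * freq[None, :] * n_px * d_px
                                / C_UM_PS))
    )
    base = _clean_reference_field(cfg)
    base_spec = np.fft.rfft(base)
    fields = np.zeros((ny * nx, cfg.n_samples))
    fields[inside] = np.fft.irfft(base_spec[None, :] * np.conj(t_px),
                                  n=cfg.n_samples, axis=1)
    rng = _rng(cfg.rng_seed, "raster-noise")
    if cfg.relative_amplitude_noise > 0:
        fields[inside] *= 1.0 + rng.normal(
            0.0, cfg.relative_amplitude_noise, (inside.size, 1)
        )
    if cfg.additive_noise_sd > 0:
        fields += rng.normal(0.0, cfg.additive_noise_sd, fields.shape)
    reference = FieldTrace(cfg.time_axis(),
                           _apply_noise(base, cfg,
                                        _rng(cfg.rng_seed, "reference-noise")),
                           kind="reference")
    stray = FieldTrace(cfg.time_axis(), np.zeros(cfg.n_samples), kind="stray")
    return RasterScan(
        cfg.time_axis(),
        fields.reshape(ny, nx, cfg.n_samples),
        pitch_mm=bean_map.pitch_mm,
        geometry="transmission",
        reference=reference,
        stray=stray,
        labels=bean_map.region.copy(),
        meta={"phantom": base_phantom.label, "map": bean_map.label,
              "seed": cfg.rng_seed, "config": cfg.as_dict()},
    )


# --------------------------------------------------------------------------
# Reflection-mode bed scans
# --------------------------------------------------------------------------


def default_bed_layout(shape: tuple[int, int] = (14, 14)) -> np.ndarray:
    """Deterministic bed pattern: empty border, plastic logo rows, and an
    alternating green/roasted field (60 cells each for the default shape)."""
    ny, nx = shape
    if ny < 6 or nx < 6:
        raise ValueError("layout too small")
    layout = np.full((ny, nx), "empty", dtype=object)
    inner = layout[1:-1, 1:-1]
    inner[:2, :] = "plastic"
    beans = inner[2:, :]
    checker = (np.add.outer(np.arange(beans.shape[0]),
                            np.arange(beans.shape[1])) % 2) == 0
    beans[checker] = "green"
    beans[~checker] = "roasted"
    return layout.astype(str)


def simulate_bed_pattern(
    layout: np.ndarray,
    cfg: AcquisitionConfig,
    orientation_factors: np.ndarray | None = None,
) -> RasterScan:
    """Reflection-mode scan of a bed of beans (one trace per cell).

    Each bean cell reflects with its material's ideal front-surface
    coefficient times a random orientation factor in (0.02, 1] drawn from a
    rescaled Beta(2, 5) — randomly oriented beans return far less light
    than a well-aligned one (an order of magnitude on average, in
    intensity).  Plastic cells are flat and well aligned (factor 1, fixed
    real index); empty cells return noise only.  The per-cell reference is
    the perfect-mirror return.
    """
    layout = np.asarray(layout, dtype=str)
    if layout.ndim != 2 or layout.size == 0:
        raise ValueError("layout must be a nonempty 2D grid")
    known = {"green", "roasted", "plastic", "empty"}
    if not set(np.unique(layout)) <= known:
        raise ValueError("unknown cell label in layout")
    freq = cfg.frequency_axis()
    n_green = refractive_index(GREEN_DIELECTRIC, freq).n
    n_roast = refractive_index(ROASTED_DIELECTRIC, freq).n
    r_front = {
        "green": (1.0 - n_green) / (1.0 + n_green),
        "roasted": (1.0 - n_roast) / (1.0 + n_roast),
        "plastic": np.full(freq.size,
                           (1.0 - PLASTIC_INDEX) / (1.0 + PLASTIC_INDEX),
                           dtype=complex),
        "empty": np.zeros(freq.size, dtype=complex),
    }
    ny, nx = layout.shape
    flat = layout.ravel()
    rng_o = _rng(cfg.rng_seed, "orientation")
    if orientation_factors is None:
        orient = 0.02 + 0.98 * rng_o.beta(2.0, 5.0, flat.size)
    else:
        orient = np.asarray(orientation_factors, dtype=float).ravel()
        if orient.size != flat.size:
            raise ValueError("orientation_factors shape mismatch")
    orient = np.where(np.isin(flat, ("plastic", "empty")), 1.0, orient)
    base = _clean_reference_field(cfg)
    base_spec = np.fft.rfft(base)
    fields = np.empty((flat.size, cfg.n_samples))
    for i, label in enumerate(flat):
        rv = r_front[label] * orient[i]
        fields[i] = np.fft.irfft(base_spec * np.conj(rv), n=cfg.n_samples)
    rng = _rng(cfg.rng_seed, "bed-noise")
    if cfg.relative_amplitude_noise > 0:
        fields *= 1.0 + rng.normal(0.0, cfg.relative_amplitude_noise,
                                   (flat.size, 1))
    if cfg.additive_noise_sd > 0:
        fields += rng.normal(0.0, cfg.additive_noise_sd, fields.shape)
    reference = FieldTrace(cfg.time_axis(),
                           _apply_noise(-base, cfg,
                                        _rng(cfg.rng_seed, "reference-noise")),
                           kind="reference")
    return RasterScan(
        cfg.time_axis(),
        fields.reshape(ny, nx, cfg.n_samples),
        pitch_mm=10.0,
        geometry="reflection",
        reference=reference,
        labels=layout.copy(),
        meta={"seed": cfg.rng_seed, "config": cfg.as_dict(),
              "orientation_factors": orient.reshape(ny, nx).tolist()},
    )


# --------------------------------------------------------------------------
# Calibrated contrasts
# --------------------------------------------------------------------------


def quaker_transmission_excess(
    f: np.ndarray | None = None,
    density_factor: float | None = None,
    floor: float = 1e-7,
    band: tuple[float, float] = (0.1, 2.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative transmission excess of the quaker over the mature thin slab.

    Forward-models both 0.5 mm phantoms and returns (frequency grid,
    percent excess 100·(T_q/T_m − 1), reliable-band mask with both
    intensities above ``floor`` and inside ``band``).
    """
    if f is None:
        f = np.linspace(0.03, 3.0, 1000)
    f = np.asarray(f, dtype=float)
    t_m = phantom_transfer(make_bean_phantom("mature_slab_0p5"), f)
    t_q = phantom_transfer(
        make_bean_phantom("quaker_slab", density_factor=density_factor), f
    )
    T_m, T_q = t_m.intensity, t_q.intensity
    mask = (T_m > floor) & (T_q > floor) & (f >= band[0]) & (f <= band[1])
    excess = np.zeros_like(f)
    excess[mask] = 100.0 * (T_q[mask] / T_m[mask] - 1.0)
    return f, excess, mask
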