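"""Time-domain traces → corrected complex transfer functions.

The processing chain of a transmission THz-TDS measurement:

1. subtract the blocked-aperture stray record from the sample trace,
2. window, zero-pad and Fourier-transform both sample and reference,
3. divide to get the complex transfer function t(ω) = Ê_T(ω)/Ê_0(ω),
4. attach a reliability mask (dynamic-range floor on T = |t|²).

Transform convention: ``Ê(f) = Σ E(t) e^{+i2πft} Δt`` so that a positive
delay yields a positive phase slope and absorbing media carry Im n > 0.
No phase unwrapping is performed anywhere — downstream fitting works on
(T, Re t, Im t), which are unwrap-free.
"""

from __future__ import annotations

import numpy as np
from scipy.signal.windows import tukey

from .containers import (
    ComplexSpectrum,
    FieldTrace,
    GridMismatchError,
    TransferFunction,
)

__all__ = [
    "DEFAULT_RELIABILITY_FLOOR",
    "subtract_stray",
    "to_spectrum",
    "inverse_transform",
    "transfer_function",
    "noise_level",
    "reliability_mask",
]

#: Default intensity floor below which a transfer function is not trusted.
DEFAULT_RELIABILITY_FLOOR = 1e-7

#: Relative reference-amplitude level below which division is refused.
DIVISION_GUARD = 1e-12

#: Default Tukey taper fraction.
TUKEY_ALPHA = 0.1


def subtract_stray(sample: FieldTrace, stray: FieldTrace) -> FieldTrace:
    """Pointwise removal of the blocked-aperture stray record.

    The grids must be identical — stray correction is only meaningful on the
    acquisition grid itself, so no resampling is attempted.
    """
    if not sample.same_grid(stray):
        raise GridMismatchError(
            "sample and stray traces are on different time grids"
        )
    meta = dict(sample.meta)
    meta["stray_corrected"] = True
    return FieldTrace(sample.time.copy(), sample.field - stray.field,
                      kind=sample.kind, meta=meta)


def _window(n: int, window: str) -> np.ndarray:
    if window == "none":
        return np.ones(n)
    if window == "tukey":
        return tukey(n, alpha=TUKEY_ALPHA)
    raise ValueError(f"unknown window {window!r}")


def to_spectrum(
    trace: FieldTrace, window: str = "tukey", pad_factor: int = 4
) -> ComplexSpectrum:
    """Windowed, zero-padded one-sided spectrum of a trace.

    The frequency step is 1/(pad_factor × N × Δt).  The returned values
    follow the ``e^{+i2πft}`` forward convention and carry the physical
    Δt scaling, so Parseval holds against :meth:`FieldTrace.energy`.
    """
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise ValueError("pad_factor must be an integer >= 1")
    n = trace.field.size
    w = _window(n, window)
    n_pad = int(pad_factor) * n
    # numpy's rfft uses e^{-i2πft}; conjugating flips to our convention
    values = np.conj(np.fft.rfft(trace.field * w, n=n_pad)) * trace.dt
    # the physical phase is referenced to the trace's own time origin
    freq = np.fft.rfftfreq(n_pad, trace.dt)
    if trace.time[0] != 0.0:
        values = values * np.exp(2j * np.pi * freq * trace.time[0])
    return ComplexSpectrum(
        freq,
        values,
        meta={
            "window": window,
            "pad_factor": int(pad_factor),
            "n_time": n_pad,
            "dt_ps": trace.dt,
            "t0_ps": float(trace.time[0]),
            **{k: v for k, v in trace.meta.items() if k in ("kind", "geometry")},
        },
    )


def inverse_transform(spec: ComplexSpectrum) -> FieldTrace:
    """Inverse of :func:`to_spectrum` (window included in the payload).

    Recovers the windowed, zero-padded trace on its original time grid.
    """
    dt = spec.meta.get("dt_ps")
    n_time = spec.meta.get("n_time")
    t0 = spec.meta.get("t0_ps", 0.0)
    if dt is None or n_time is None:
        raise ValueError("spectrum lacks the transform record needed to invert")
    values = spec.values
    if t0 != 0.0:
        values = values * np.exp(-2j * np.pi * spec.frequency * t0)
    field = np.fft.irfft(np.conj(values) / dt, n=n_time)
    time = t0 + dt * np.arange(n_time)
    return FieldTrace(time, field, kind=spec.meta.get("kind", "sample"))


def transfer_function(
    sample_spec: ComplexSpectrum,
    ref_spec: ComplexSpectrum,
    geometry: str = "transmission",
    floor: float = DEFAULT_RELIABILITY_FLOOR,
) -> TransferFunction:
    """Pointwise complex ratio t(ω) = Ê_sample(ω)/Ê_ref(ω).

    Frequencies where the reference amplitude is below ``DIVISION_GUARD`` of
    its peak are never divided: they carry the value 0 + 0i and a False
    mask.  The default reliability mask additionally requires the intensity
    to exceed ``floor`` (strictly).
    """
    if sample_spec.frequency.size != ref_spec.frequency.size or not np.array_equal(
        sample_spec.frequency, ref_spec.frequency
    ):
        raise GridMismatchError("sample and reference spectra on different grids")
    ref_amp = np.abs(ref_spec.values)
    ok = ref_amp > DIVISION_GUARD * ref_amp.max()
    values = np.zeros(sample_spec.values.size, dtype=complex)
    values[ok] = sample_spec.values[ok] / ref_spec.values[ok]
    tf = TransferFunction(
        sample_spec.frequency.copy(),
        values,
        geometry=geometry,
        mask=ok,
        meta={"reliability_floor": floor},
    )
    return reliability_mask(tf, floor)


def noise_level(
    ref1: ComplexSpectrum,
    ref2: ComplexSpectrum,
    band: tuple[float, float] = (0.1, 2.0),
) -> tuple[np.ndarray, float]:
    """Amplitude reproducibility of two reference spectra.

    Returns the per-frequency deviation |Ê₁/Ê₂| − 1 and its maximum absolute
    value over ``band``.  Frequencies where the denominator is below the
    division guard are excluded from the band maximum (deviation set to 0).
    """
    if ref1.frequency.size != ref2.frequency.size or not np.array_equal(
        ref1.frequency, ref2.frequency
    ):
        raise GridMismatchError("reference spectra on different grids")
    amp2 = np.abs(ref2.values)
    ok = amp2 > DIVISION_GUARD * amp2.max()
    dev = np.zeros(ref1.values.size)
    dev[ok] = np.abs(ref1.values[ok]) / amp2[ok] - 1.0
    sel = (ref1.frequency >= band[0]) & (ref1.frequency <= band[1]) & ok
    band_max = float(np.max(np.abs(dev[sel]))) if np.any(sel) else 0.0
    return dev, band_max


def reliability_mask(
    tf: TransferFunction, floor: float = DEFAULT_RELIABILITY_FLOOR
) -> TransferFunction:
    """Mask true iff the intensity strictly exceeds ``floor``.

    Points already masked false (e.g. by the division guard, which zeroes
    their values) stay false.  Raising the floor can only shrink the mask.
    """
    if floor <= 0:
        raise ValueError("reliability floor must be > 0")
    mask = tf.mask & (tf.intensity > floor)
    meta = dict(tf.meta)
    meta["reliability_floor"] = floor
    return TransferFunction(
        tf.frequency.copy(), tf.values.copy(), geometry=tf.geometry,
        mask=mask, meta=meta
    )
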