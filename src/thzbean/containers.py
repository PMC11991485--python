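"""Shared data containers and exceptions for the THz bean-spectroscopy pipeline.

Unit conventions at the API boundary: time in picoseconds (ps), frequency in
terahertz (THz), lengths in micrometres (μm) unless a field name says ``mm``.
With these units the vacuum speed of light is ``C_UM_PS`` μm/ps, and products
like ``f * d / c`` are dimensionless as written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Speed of light in vacuum, μm/ps (≡ 299 792 458 m/s exactly).
C_UM_PS = 299.792458

#: Tolerance for "uniform time axis" checks, ps.
TIME_GRID_TOL = 1e-9


class ThzBeanError(Exception):
    """Base class for all errors raised by this package."""


class GridMismatchError(ThzBeanError):
    """Two records that must share an axis do not."""


class GeometryError(ThzBeanError):
    """An operation received data of the wrong measurement geometry."""


class DegeneratePhantomError(ThzBeanError):
    """A phantom that cannot produce the requested measurement."""


class ModelSignError(ThzBeanError):
    """A dielectric model violates the absorbing-medium sign convention."""


class FitError(ThzBeanError):
    """Spectral fitting could not be carried out."""


class ThzTsvError(ThzBeanError):
    """A thz-tsv file is malformed."""


def _as_1d_float(x: Any, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class FieldTrace:
    """A sampled time-domain electric field E(t).

    Parameters
    ----------
    time : array of float
        Uniform time axis, ps.  Strictly increasing; the step must be
        constant to within ``TIME_GRID_TOL``.
    field : array of float
        Field values in arbitrary (but consistent) units.
    kind : str
        One of ``sample``, ``reference``, ``stray``, ``blocked``.
    meta : dict
        Provenance record (geometry, aperture, seed, config hash, ...).
    """

    time: np.ndarray
    field: np.ndarray
    kind: str = "sample"
    meta: dict = field(default_factory=dict)

    KINDS = ("sample", "reference", "stray", "blocked")

    def __post_init__(self) -> None:
        self.time = _as_1d_float(self.time, "time")
        self.field = _as_1d_float(self.field, "field")
        if self.time.size != self.field.size:
            raise ValueError("time and field must have equal length")
        if self.time.size < 2:
            raise ValueError("a trace needs at least two samples")
        steps = np.diff(self.time)
        if steps[0] <= 0 or np.any(np.abs(steps - steps[0]) > TIME_GRID_TOL):
            raise ValueError("time axis must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("field values must be finite")
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def energy(self) -> float:
        """Time-domain energy, Σ E² Δt (arbitrary units² · ps)."""
        return float(np.sum(self.field**2) * self.dt)

    def same_grid(self, other: "FieldTrace") -> bool:
        return self.time.size == other.time.size and bool(
            np.array_equal(self.time, other.time)
        )


@dataclass
class ComplexSpectrum:
    """One-sided complex spectrum Ê(f) of a field trace.

    The forward-transform convention is ``Ê(f) = Σ E(t) e^{+i2πft} Δt``
    (see :mod:`thzbean.processing`): a positive time delay appears as a
    positive phase slope and absorbing media have Im n > 0.
    """

    frequency: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = _as_1d_float(self.frequency, "frequency")
        self.values = np.asarray(self.values, dtype=complex)
        if self.frequency.size != self.values.size:
            raise ValueError("frequency and values must have equal length")
        if self.frequency[0] < 0:
            raise ValueError("one-sided spectrum must start at f >= 0")

    @property
    def df(self) -> float:
        return float(self.frequency[1] - self.frequency[0])

    def energy(self) -> float:
        """Frequency-domain energy matching :meth:`FieldTrace.energy`.

        One-sided sum with the DC (and Nyquist, when the underlying number
        of time samples was even) bins counted once.
        """
        w = np.full(self.values.size, 2.0)
        w[0] = 1.0
        if self.meta.get("n_time", 0) % 2 == 0:
            w[-1] = 1.0
        return float(np.sum(w * np.abs(self.values) ** 2) * self.df)


@dataclass
class TransferFunction:
    """Complex transmission t(ω) or reflection r(ω) on a frequency grid.

    ``intensity`` is always |value|²; ``mask`` is True where the value is
    trusted (reference dynamic range and reliability floor).
    """

    frequency: np.ndarray
    values: np.ndarray
    geometry: str = "transmission"
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    GEOMETRIES = ("transmission", "reflection")

    def __post_init__(self) -> None:
        self.frequency = _as_1d_float(self.frequency, "frequency")
        self.values = np.asarray(self.values, dtype=complex)
        if self.frequency.size != self.values.size:
            raise ValueError("frequency and values must have equal length")
        if self.geometry not in self.GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.mask is None:
            self.mask = np.ones(self.values.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.size != self.values.size:
                raise ValueError("mask length mismatch")

    @property
    def intensity(self) -> np.ndarray:
        """|t(ω)|² (T) or |r(ω)|² (R)."""
        return np.abs(self.values) ** 2

    def band_slice(self, band: tuple[float, float]) -> np.ndarray:
        """Boolean selector for frequencies inside ``band`` (inclusive)."""
        lo, hi = band
        return (self.frequency >= lo) & (self.frequency <= hi)


@dataclass
class RefractiveIndexCurve:
    """Complex refractive index n(ω) = n′ + iκ on a frequency grid."""

    frequency: np.ndarray
    n: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = _as_1d_float(self.frequency, "frequency")
        self.n = np.asarray(self.n, dtype=complex)
        if self.frequency.size != self.n.size:
            raise ValueError("frequency and n must have equal length")
        if np.any(self.n.imag < -1e-12):
            raise ModelSignError("κ must be >= 0 for an absorbing medium")
        if np.any(self.n.real <= 0):
            raise ModelSignError("Re n must be positive")

    def at(self, f: float | np.ndarray) -> np.ndarray | complex:
        """Linear interpolation of n at frequency ``f`` (THz)."""
        fr = np.asarray(f, dtype=float)
        re = np.interp(fr, self.frequency, self.n.real)
        im = np.interp(fr, self.frequency, self.n.imag)
        out = re + 1j * im
        return complex(out) if np.isscalar(f) else out


@dataclass
class RasterScan:
    """A rectangular grid of time-domain traces sharing one time axis."""

    time: np.ndarray
    fields: np.ndarray  # (ny, nx, nt)
    pitch_mm: float
    geometry: str = "transmission"
    reference: FieldTrace | None = None
    stray: FieldTrace | None = None
    labels: np.ndarray | None = None  # (ny, nx) of str, optional
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_1d_float(self.time, "time")
        self.fields = np.asarray(self.fields, dtype=float)
        if self.fields.ndim != 3 or self.fields.shape[2] != self.time.size:
            raise ValueError("fields must be (ny, nx, nt) on the shared time axis")
        if self.geometry not in TransferFunction.GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fields.shape[0], self.fields.shape[1]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class BinnedImage:
    """Frequency-binned intensity images of a raster scan."""

    edges: np.ndarray  # (nbin + 1,) THz, strictly increasing
    images: np.ndarray  # (nbin, ny, nx), non-negative
    normalization: str = "per-bin"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = _as_1d_float(self.edges, "edges")
        self.images = np.asarray(self.images, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.images.ndim != 3 or self.images.shape[0] != self.edges.size - 1:
            raise ValueError("images must be (nbin, ny, nx)")
        if np.any(self.images < 0):
            raise ValueError("binned intensities must be non-negative")

    def normalized(self) -> np.ndarray:
        """Images scaled per the recorded normalization ('per-bin' or 'global')."""
        if self.normalization == "global":
            peak = self.images.max()
            return self.images / peak if peak > 0 else self.images.copy()
        out = np.empty_like(self.images)
        for i, img in enumerate(self.images):
            peak = img.max()
            out[i] = img / peak if peak > 0 else img
        return out
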