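"""Lorentz-oscillator dielectric models and single-slab transfer-matrix optics.

The physical forward model of the pipeline: a complex dielectric function
built from Lorentz oscillators, the complex refractive index n(ω) = √ε, and
the transmission/reflection of a plane-parallel slab at normal incidence
including all internal (Fabry–Pérot) echoes.

Sign conventions (matching the ``e^{+i2πft}`` transform convention used in
:mod:`thzbean.processing`): an absorbing medium has Im ε ≥ 0 and κ = Im n ≥ 0,
and forward propagation over a distance d multiplies the field by
``exp(+i 2πf n d / c)`` whose magnitude ``exp(−2πf κ d / c)`` decays.

Transmission is referenced to an equal-length vacuum path (the empty-aperture
reference of a transmission spectrometer); reflection is referenced to a
perfect mirror at the sample's front surface (the metal-paint reference).
The closed-form Airy expressions are documented identities for the 2×2
transfer-matrix products actually computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    C_UM_PS,
    GridMismatchError,
    ModelSignError,
    RefractiveIndexCurve,
    TransferFunction,
)

__all__ = [
    "LorentzOscillator",
    "LorentzDielectric",
    "dielectric_eval",
    "index_from_dielectric",
    "refractive_index",
    "slab_amplitudes",
    "stack_transmission",
    "slab_transmission",
    "slab_reflectivity",
    "echo_sum_oracle",
    "composite_transmission",
]


@dataclass(frozen=True)
class LorentzOscillator:
    """One damped resonance: Δε f₀² / (f₀² − f² − iγf).

    ``strength`` is the dimensionless static contribution Δε ≥ 0, ``center``
    the resonance frequency f₀ ≥ 0 in THz, ``damping`` the width γ > 0 in
    THz.  A heavily overdamped oscillator with f₀ far below the band mimics
    the Debye relaxation of liquid water.
    """

    strength: float
    center: float
    damping: float

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("oscillator strength Δε must be >= 0")
        if self.center < 0:
            raise ValueError("oscillator center f0 must be >= 0")
        if self.damping <= 0:
            raise ValueError("oscillator damping γ must be > 0")


@dataclass(frozen=True)
class LorentzDielectric:
    """ε(f) = ε∞ + Σⱼ Δεⱼ f₀ⱼ² / (f₀ⱼ² − f² − i γⱼ f)."""

    eps_inf: float
    oscillators: tuple[LorentzOscillator, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.eps_inf < 1:
            raise ValueError("eps_inf must be >= 1")
        object.__setattr__(self, "oscillators", tuple(self.oscillators))

    @property
    def eps_static(self) -> float:
        return self.eps_inf + sum(o.strength for o in self.oscillators)

    def scaled(self, factor: float) -> "LorentzDielectric":
        """Copy with every oscillator strength multiplied by ``factor`` ≥ 0."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return LorentzDielectric(
            self.eps_inf,
            tuple(
                LorentzOscillator(o.strength * factor, o.center, o.damping)
                for o in self.oscillators
            ),
        )

    def as_dict(self) -> dict:
        return {
            "eps_inf": self.eps_inf,
            "oscillators": [
                {"strength": o.strength, "center": o.center, "damping": o.damping}
                for o in self.oscillators
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LorentzDielectric":
        return cls(
            d["eps_inf"],
            tuple(
                LorentzOscillator(o["strength"], o["center"], o["damping"])
                for o in d.get("oscillators", ())
            ),
        )


def dielectric_eval(model: LorentzDielectric, f: np.ndarray) -> np.ndarray:
    """Evaluate ε(f) on a frequency grid (THz, f ≥ 0)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be >= 0")
    eps = np.full(f.shape, model.eps_inf, dtype=complex)
    for o in model.oscillators:
        eps += o.strength * o.center**2 / (o.center**2 - f**2 - 1j * o.damping * f)
    return eps


def index_from_dielectric(f: np.ndarray, eps: np.ndarray) -> RefractiveIndexCurve:
    """n = √ε with the branch chosen so κ = Im n ≥ 0.

    For a passive medium (Im ε ≥ 0) the principal square root already lies in
    the upper half plane, which keeps κ continuous along the grid; a model
    with Im ε < 0 anywhere is rejected as violating the sign convention.
    """
    f = np.asarray(f, dtype=float)
    eps = np.asarray(eps, dtype=complex)
    if not np.all(np.isfinite(eps)):
        raise ValueError("ε must be finite")
    if np.any(eps.imag < -1e-12):
        raise ModelSignError("Im ε < 0: model violates the absorbing-medium sign")
    n = np.sqrt(eps)
    # principal sqrt maps Im ε ≥ 0 to the first quadrant (κ ≥ 0, n′ ≥ 0);
    # flip any numerically stray branch
    flip = n.real < 0
    n[flip] = -n[flip]
    n.imag[np.abs(n.imag) < 1e-300] = 0.0
    return RefractiveIndexCurve(f, n)


def refractive_index(model: LorentzDielectric, f: np.ndarray) -> RefractiveIndexCurve:
    """Convenience: n(f) of a Lorentz model."""
    return index_from_dielectric(f, dielectric_eval(model, np.asarray(f, dtype=float)))


# ---------------------------------------------------------------------------
# Single-slab transfer-matrix optics
# ---------------------------------------------------------------------------


def _slab_matrix_amplitudes(
    n: np.ndarray, f: np.ndarray, d: float
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (non-referenced) t and r of an air/slab/air system via 2×2 matrices.

    Characteristic-matrix formulation at normal incidence:
    M = [[cos φ, −i sin φ / n], [−i n sin φ, cos φ]] with φ = 2πf n d / c.
    t = 2 / (M00 + M01 + M10 + M11), r = (M00 + M01 − M10 − M11) / (same).

    Documented identity (Airy form), with r₁ = (1−n)/(1+n):
    t = [4n/(n+1)²] e^{i2πfnd/c} / (1 − r₁² e^{i4πfnd/c}).
    """
    phi = 2.0 * np.pi * f * n * d / C_UM_PS
    # guard against overflow of cos/sin for strongly absorbing thick slabs:
    # cos φ, sin φ grow like e^{Im φ}; cap Im φ so e^{Im φ} stays finite while
    # t (∝ 1/e^{Im φ}) has long since underflowed to 0.
    phi = np.where(phi.imag > 650.0, phi.real + 650.0j, phi)
    cos_phi = np.cos(phi)
    sin_phi = np.sin(phi)
    m00 = cos_phi
    m01 = -1j * sin_phi / n
    m10 = -1j * n * sin_phi
    m11 = cos_phi
    denom = m00 + m01 + m10 + m11
    t = 2.0 / denom
    r = (m00 + m01 - m10 - m11) / denom
    return t, r


def slab_amplitudes(
    n: RefractiveIndexCurve, d: float
) -> tuple[np.ndarray, np.ndarray]:
    """Non-referenced complex (t, r) of a slab of thickness ``d`` μm in air.

    ``t`` is the absolute transmission amplitude (field just behind the slab
    over incident field, including the propagation phase through the slab);
    for a lossless slab |t|² + |r|² = 1.
    """
    if d <= 0:
        raise ValueError("thickness must be positive")
    return _slab_matrix_amplitudes(n.n, n.frequency, d)


def stack_transmission(
    layers: list[tuple[RefractiveIndexCurve, float]]
) -> TransferFunction:
    """Vacuum-referenced transmission of a multilayer stack in air.

    The characteristic matrices of the layers are multiplied in order;
    internal reflections between layers are fully included.  For a single
    layer this reduces to :func:`slab_transmission`.
    """
    if not layers:
        raise ValueError("at least one layer required")
    f = layers[0][0].frequency
    m00 = np.ones(f.size, dtype=complex)
    m01 = np.zeros(f.size, dtype=complex)
    m10 = np.zeros(f.size, dtype=complex)
    m11 = np.ones(f.size, dtype=complex)
    d_total = 0.0
    for n, d in layers:
        if d <= 0:
            raise ValueError("thickness must be positive")
        if not np.array_equal(n.frequency, f):
            raise GridMismatchError("layers must share one frequency axis")
        phi = 2.0 * np.pi * f * n.n * d / C_UM_PS
        phi = np.where(phi.imag > 650.0, phi.real + 650.0j, phi)
        c, s = np.cos(phi), np.sin(phi)
        a00, a01, a10, a11 = c, -1j * s / n.n, -1j * n.n * s, c
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
        d_total += d
    t_abs = 2.0 / (m00 + m01 + m10 + m11)
    t_ref = t_abs * np.exp(-2j * np.pi * f * d_total / C_UM_PS)
    return TransferFunction(
        f,
        t_ref,
        geometry="transmission",
        meta={"thickness_um": d_total, "n_layers": len(layers),
              "reference": "equal-length vacuum path"},
    )


def slab_transmission(n: RefractiveIndexCurve, d: float) -> TransferFunction:
    """Vacuum-referenced slab transmission t(ω).

    Referenced to an equal-length vacuum path (empty-aperture reference), so
    t(f) = [4n/(n+1)²] e^{i2πf(n−1)d/c} / (1 − r₁² e^{i4πfnd/c}).
    """
    t_abs, _ = slab_amplitudes(n, d)
    t_ref = t_abs * np.exp(-2j * np.pi * n.frequency * d / C_UM_PS)
    return TransferFunction(
        n.frequency,
        t_ref,
        geometry="transmission",
        meta={"thickness_um": d, "reference": "equal-length vacuum path"},
    )


def slab_reflectivity(
    n: RefractiveIndexCurve, d: float, backing: str = "air"
) -> TransferFunction:
    """Mirror-referenced slab reflection r(ω) with air or metal backing.

    r(f) = (r₀₁ + r₁₂ e^{i4πfnd/c}) / (1 + r₀₁ r₁₂ e^{i4πfnd/c}) with
    r₀₁ = (1−n)/(1+n); r₁₂ = (n−1)/(n+1) for air backing, −1 for an ideal
    metal.  The reference is a perfect mirror at the front surface, so the
    reported reflectivity is R̂ = |r|².
    """
    if d <= 0:
        raise ValueError("thickness must be positive")
    if backing not in ("air", "metal"):
        raise ValueError(f"unknown backing {backing!r}")
    nv = n.n
    f = n.frequency
    r01 = (1.0 - nv) / (1.0 + nv)
    r12 = (nv - 1.0) / (nv + 1.0) if backing == "air" else np.full_like(nv, -1.0)
    phase = np.exp(4j * np.pi * f * nv * d / C_UM_PS)
    # e^{iφ} underflows to 0 for opaque slabs; that is the correct limit
    phase = np.where(
        (2.0 * np.pi * f * nv.imag * d / C_UM_PS) > 650.0, 0.0, phase
    )
    r = (r01 + r12 * phase) / (1.0 + r01 * r12 * phase)
    return TransferFunction(
        f,
        r,
        geometry="reflection",
        meta={
            "thickness_um": d,
            "backing": backing,
            "reference": "perfect mirror at front surface",
        },
    )


def echo_sum_oracle(
    n: RefractiveIndexCurve,
    d: float,
    N: int,
    geometry: str = "transmission",
    backing: str = "air",
) -> TransferFunction:
    """Transmission/reflection built by explicit summation of the first N echoes.

    Independent of the transfer-matrix implementation: the geometric series
    of internal reflections is truncated after N terms.  For transmission
    (vacuum-referenced) the k-th term is
    [4n/(n+1)²] e^{i2πf(n−1)d/c} (r₁² e^{i4πfnd/c})^{k}.
    """
    if N < 1:
        raise ValueError("echo count N must be >= 1")
    if d <= 0:
        raise ValueError("thickness must be positive")
    nv = n.n
    f = n.frequency
    prop2 = np.exp(4j * np.pi * f * nv * d / C_UM_PS)  # one internal round trip
    prop2 = np.where((4.0 * np.pi * f * nv.imag * d / C_UM_PS) > 650.0, 0.0, prop2)
    if geometry == "transmission":
        r1 = (nv - 1.0) / (nv + 1.0)
        base = (
            4.0
            * nv
            / (nv + 1.0) ** 2
            * np.exp(2j * np.pi * f * (nv - 1.0) * d / C_UM_PS)
        )
        ratio = r1**2 * prop2
        total = base * sum(ratio**k for k in range(N))
    elif geometry == "reflection":
        r01 = (1.0 - nv) / (1.0 + nv)
        r12 = (nv - 1.0) / (nv + 1.0) if backing == "air" else np.full_like(nv, -1.0)
        t01 = 2.0 / (1.0 + nv)
        t10 = 2.0 * nv / (1.0 + nv)
        # first echo: front-surface reflection; k-th internal echo picks up
        # one extra internal round trip and an internal reflection pair
        total = np.copy(r01).astype(complex)
        for k in range(1, N):
            total += t01 * t10 * r12 * (r12 * (-r01)) ** (k - 1) * prop2**k
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return TransferFunction(
        f, total, geometry=geometry, meta={"thickness_um": d, "echo_count": N}
    )


def composite_transmission(
    components: list[tuple[TransferFunction, float]]
) -> TransferFunction:
    """Coherent area-weighted sum t = Σ wᵢ tᵢ of parallel beam paths.

    Models a beam straddling regions of slightly different optical
    properties: the partial beams interfere, producing spectral dips where
    their phases differ by π.  Weights must be ≥ 0 and sum to 1; all
    components must share one frequency axis and geometry.
    """
    if not components:
        raise ValueError("at least one component required")
    weights = np.array([w for _, w in components], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be >= 0 and sum to 1")
    first = components[0][0]
    total = np.zeros_like(first.values)
    mask = np.ones(first.values.size, dtype=bool)
    for tf, w in components:
        if tf.frequency.size != first.frequency.size or not np.array_equal(
            tf.frequency, first.frequency
        ):
            raise GridMismatchError("components must share one frequency axis")
        if tf.geometry != first.geometry:
            raise ValueError("components must share one geometry")
        total = total + w * tf.values
        mask &= tf.mask
    return TransferFunction(
        first.frequency,
        total,
        geometry=first.geometry,
        mask=mask,
        meta={"composite_weights": weights.tolist()},
    )
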