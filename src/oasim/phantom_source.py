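"""Layered absorber, irradiation beam and volumetric energy density.

The optical source term of the optoacoustic problem factorizes for
plane-parallel, non-scattering layered media into a lateral beam profile
``f(x, y)`` and an axial Beer--Lambert depth profile ``g(z)``.  This module
holds both factors plus the dimensionless diffraction parameter
``D = 2|z_D| / (mu a0^2)`` that separates the acoustic near field (D < 1)
from the far field (D > 1).

All lengths are in cm and absorption coefficients in cm^-1; the speed of
sound never enters (signal axes are propagation distances ``ct``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AbsorbingLayer",
    "LayerStack",
    "TopHatBeam",
    "DetectionPoint",
    "SourceConstant",
    "mu_a_at",
    "optical_depth",
    "depth_profile_g",
    "beam_profile",
    "volumetric_energy",
    "diffraction_parameter",
]


@dataclass(frozen=True)
class AbsorbingLayer:
    """One plane-parallel absorbing layer.

    Depth interval is half-open, ``[z_start, z_end)``, so the absorption
    coefficient is single-valued at internal layer boundaries.

    Parameters
    ----------
    z_start, z_end : float
        Depth range in cm, measured from the irradiated surface (z = 0).
    mu_a : float
        Optical absorption coefficient in cm^-1.
    """

    z_start: float
    z_end: float
    mu_a: float

    def __post_init__(self) -> None:
        if self.z_start < 0:
            raise ValueError(f"z_start must be >= 0, got {self.z_start}")
        if self.z_end <= self.z_start:
            raise ValueError(
                f"z_end ({self.z_end}) must exceed z_start ({self.z_start})"
            )
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")

    @property
    def thickness(self) -> float:
        return self.z_end - self.z_start


@dataclass(frozen=True)
class LayerStack:
    """Ordered, non-overlapping stack of absorbing layers on [0, L_z].

    Gaps between layers (zero absorption) are permitted; overlapping layers
    are a validation error.
    """

    layers: tuple[AbsorbingLayer, ...]
    L_z: float

    def __init__(self, layers, L_z: float) -> None:
        object.__setattr__(self, "layers", tuple(layers))
        object.__setattr__(self, "L_z", float(L_z))
        self._validate()

    def _validate(self) -> None:
        if self.L_z <= 0:
            raise ValueError("domain depth L_z must be positive")
        prev_end = 0.0
        prev_start = -1.0
        for lay in self.layers:
            if lay.z_start < prev_start:
                raise ValueError("layers must be sorted by z_start")
            if lay.z_start < prev_end - 1e-12:
                raise ValueError(
                    f"layer starting at {lay.z_start} overlaps previous layer"
                )
            if lay.z_end > self.L_z + 1e-12:
                raise ValueError(
                    f"layer ending at {lay.z_end} exceeds domain depth {self.L_z}"
                )
            prev_start, prev_end = lay.z_start, lay.z_end

    @property
    def total_optical_depth(self) -> float:
        return float(sum(l.mu_a * l.thickness for l in self.layers))


@dataclass(frozen=True)
class TopHatBeam:
    """Top-hat irradiation profile: flat up to radius ``a``, Gaussian edge
    of width ``d`` beyond.
    """

    a: float
    d: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("flat-top radius a must be positive")
        if self.d <= 0:
            raise ValueError("edge width d must be positive")

    @property
    def R(self) -> float:
        """Edge-to-flat-top ratio d/a."""
        return self.d / self.a

    @property
    def support_radius(self) -> float:
        """Radius beyond which the profile is negligible (< e^-16)."""
        return self.a + 4.0 * self.d


@dataclass(frozen=True)
class DetectionPoint:
    """Detector location (x_D, 0, z_D) in the beam-axis frame.

    z_D < 0 places the detector on the irradiated side, outside the
    absorber (backward mode).
    """

    x_D: float
    z_D: float

    def __post_init__(self) -> None:
        if self.z_D >= 0:
            raise ValueError("z_D must be negative (detector outside absorber)")

    @property
    def standoff(self) -> float:
        """Axial detector-to-surface distance |z_D| in cm."""
        return -self.z_D

    @property
    def on_axis(self) -> bool:
        return self.x_D == 0.0


@dataclass(frozen=True)
class SourceConstant:
    """Effective source scale f0*Gamma/c folded into a single constant.

    Signals are reported in arbitrary units; the conventional choice 4*pi
    cancels the 1/(4*pi) of the free-space Green's function.
    """

    prefactor: float = 4.0 * np.pi

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")


def _check_nonneg(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def mu_a_at(stack: LayerStack, z):
    """Absorption coefficient mu_a(z) in cm^-1.

    Layers own the half-open interval [z_start, z_end); depths outside all
    layers return 0.  Accepts scalars or arrays; negative depths raise.
    """
    arr = _check_nonneg(z, "depth z")
    out = np.zeros_like(arr)
    for lay in stack.layers:
        out = np.where((arr >= lay.z_start) & (arr < lay.z_end), lay.mu_a, out)
    return out if np.ndim(z) else float(out)


def optical_depth(stack: LayerStack, z):
    """Cumulative optical depth integral of mu_a from the surface to z.

    Exact piecewise-linear closed form: sum of mu_a times the overlap of
    [0, z] with each layer.  Non-decreasing in z.
    """
    arr = _check_nonneg(z, "depth z")
    out = np.zeros_like(arr)
    for lay in stack.layers:
        overlap = np.clip(np.minimum(arr, lay.z_end) - lay.z_start, 0.0, None)
        out += lay.mu_a * overlap
    return out if np.ndim(z) else float(out)


def depth_profile_g(stack: LayerStack, z):
    """Beer--Lambert depth profile g(z) = mu_a(z) * exp(-optical_depth(z))."""
    mu = np.asarray(mu_a_at(stack, z), dtype=float)
    out = mu * np.exp(-np.asarray(optical_depth(stack, z), dtype=float))
    return out if np.ndim(z) else float(out)


def beam_profile(beam: TopHatBeam, rho):
    """Lateral intensity profile f_I(rho): 1 on the flat top rho <= a,
    Gaussian shoulder exp(-(rho - a)^2 / d^2) beyond; continuous at rho = a.
    """
    arr = _check_nonneg(rho, "radius rho")
    excess = np.clip(arr - beam.a, 0.0, None)
    out = np.exp(-((excess / beam.d) ** 2))
    return out if np.ndim(rho) else float(out)


def volumetric_energy(
    stack: LayerStack,
    beam: TopHatBeam,
    const: SourceConstant | None,
    x,
    y,
    z,
):
    """Factorized volumetric energy density W(x, y, z) = f(x, y) * g(z).

    The overall scale (``const.prefactor``) is deliberately *not* applied
    here: the solvers apply it exactly once, so it cannot enter squared.
    """
    rho = np.hypot(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    out = np.asarray(beam_profile(beam, rho), dtype=float) * np.asarray(
        depth_profile_g(stack, z), dtype=float
    )
    return out if (np.ndim(x) or np.ndim(y) or np.ndim(z)) else float(out)


def mean_absorption(stack: LayerStack) -> float:
    """Thickness-weighted mean of mu_a over the absorbing layers only.

    Layers with mu_a = 0 and gaps between layers do not contribute to the
    averaging domain; an entirely clear stack raises.
    """
    absorbing = [l for l in stack.layers if l.mu_a > 0]
    if not absorbing:
        raise ValueError("mean absorption undefined for a non-absorbing stack")
    total_thickness = sum(l.thickness for l in absorbing)
    return sum(l.mu_a * l.thickness for l in absorbing) / total_thickness


def diffraction_parameter(stack: LayerStack, beam: TopHatBeam, z_D: float) -> float:
    """Dimensionless diffraction parameter D = 2|z_D| / (mu * a0^2).

    mu is the thickness-weighted mean absorption over the absorbing layers
    and a0 = 1.25 * a is the effective beam radius.  D < 1 marks the
    acoustic near field, D > 1 the far field.
    """
    if z_D >= 0:
        raise ValueError("z_D must be negative")
    mu = mean_absorption(stack)
    a0 = 1.25 * beam.a
    return 2.0 * abs(z_D) / (mu * a0 * a0)


def classify_regime(stack: LayerStack, beam: TopHatBeam, z_D: float) -> str:
    """Return ``"NF"`` (near field, D < 1) or ``"FF"`` (far field, D >= 1)."""
    return "NF" if diffraction_parameter(stack, beam, z_D) < 1.0 else "FF"
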