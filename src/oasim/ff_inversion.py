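"""Far-field approximate inversion of a pressure transient to the initial
acoustic stress depth profile, with MSE benchmarking.

In the deep far field the on-axis transient is (up to scale) the temporal
derivative of the initial stress profile p0(z) = Gamma * W(z), so the
cumulative integral of the signal over the retarded depth ctau recovers an
approximate predictor p0_FF(z = ctau).  Both the exact and the
reconstructed profile are normalized to unit sum before comparison by the
mean squared error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .detector_model import FoilModel, to_retarded_depth
from .forward_cylindrical import CylindricalGrid, solve
from .phantom_source import (
    DetectionPoint,
    LayerStack,
    SourceConstant,
    TopHatBeam,
    depth_profile_g,
)
from .signal import PressureSignal

__all__ = [
    "StressProfile",
    "exact_p0",
    "reconstruct_p0_ff",
    "normalize_profile",
    "mse",
    "mse_sweep",
]


@dataclass(frozen=True)
class StressProfile:
    """Depth-resolved initial acoustic stress p0(z) on a uniform z grid.

    ``normalized`` marks profiles rescaled so the samples sum to one.
    """

    z_values: np.ndarray
    p0_values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        p0 = np.asarray(self.p0_values, dtype=float)
        if z.shape != p0.shape or z.ndim != 1:
            raise ValueError("z and p0 must be 1-D arrays of equal length")
        if z.size >= 2:
            steps = np.diff(z)
            if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
                raise ValueError("z grid must be uniform")
        if self.normalized and abs(p0.sum() - 1.0) > 1e-9:
            raise ValueError("profile flagged normalized but samples do not sum to 1")
        object.__setattr__(self, "z_values", z)
        object.__setattr__(self, "p0_values", p0)


def exact_p0(
    stack: LayerStack,
    const: SourceConstant | None = None,
    n_z: int | None = None,
    grid: CylindricalGrid | None = None,
) -> StressProfile:
    """Exact on-axis initial stress profile, proportional to the
    Beer--Lambert depth profile g(z) (the beam is 1 on axis).

    Sampled at the axial cell midpoints of ``grid`` if given, else on
    ``n_z`` midpoints over [0, stack.L_z] (default 150).
    """
    if grid is not None:
        z = grid.z_centers
    else:
        n = n_z if n_z is not None else 150
        z = (np.arange(n) + 0.5) * (stack.L_z / n)
    scale = const.prefactor if const is not None else 1.0
    return StressProfile(z_values=z, p0_values=scale * depth_profile_g(stack, z))


def reconstruct_p0_ff(
    signal: PressureSignal,
    z_min: float = 0.0,
    z_max: float | None = None,
) -> StressProfile:
    """Far-field predictor p0_FF: cumulative trapezoidal integral of the
    transient over the retarded depth, mapped to depth z = ctau.

    The signal must be on the retarded-depth axis.  The reconstruction
    domain is clipped to [z_min, z_max] (diffraction tails beyond the
    absorber are excluded before any normalization); returned unnormalized.
    """
    if signal.axis != "ctau":
        raise ValueError("signal must be on the retarded-depth (ctau) axis")
    prof = cumulative_trapezoid(signal.p, signal.ct, initial=0.0)
    mask = signal.ct >= z_min - 1e-12
    if z_max is not None:
        mask &= signal.ct <= z_max + 1e-12
    return StressProfile(z_values=signal.ct[mask], p0_values=prof[mask])


def normalize_profile(profile: StressProfile) -> StressProfile:
    """Rescale the profile so its samples sum to one (scale invariant)."""
    total = float(profile.p0_values.sum())
    if total == 0.0 or not np.isfinite(total):
        raise ValueError("cannot normalize a zero-sum profile")
    return replace(profile, p0_values=profile.p0_values / total, normalized=True)


def mse(exact: StressProfile, recon: StressProfile) -> float:
    """Mean squared error sum_i [p0(z_i) - p0_FF(z_i)]^2 / N_z between two
    normalized profiles; the reconstruction is linearly resampled onto the
    exact profile's z grid first."""
    if not (exact.normalized and recon.normalized):
        raise ValueError("both profiles must be normalized before comparison")
    tol = exact.z_values[1] - exact.z_values[0] if exact.z_values.size > 1 else 1e-9
    if (
        recon.z_values[0] > exact.z_values[0] + tol
        or recon.z_values[-1] < exact.z_values[-1] - tol
    ):
        raise ValueError("reconstruction does not cover the exact profile's z grid")
    resampled = np.interp(exact.z_values, recon.z_values, recon.p0_values)
    # re-normalize after resampling so both sides genuinely sum to one
    total = resampled.sum()
    if total != 0.0:
        resampled = resampled / total
    return float(np.mean((exact.p0_values - resampled) ** 2))


def mse_sweep(
    stack: LayerStack,
    beam: TopHatBeam,
    const: SourceConstant,
    grid: CylindricalGrid,
    foil: FoilModel,
    z_D_list,
    bin_width: float | None = None,
    x_D: float = 0.0,
) -> pd.DataFrame:
    """Reconstruction error versus detector distance.

    For each z_D: simulate with the fast solver, shift to retarded depth,
    integrate to p0_FF, normalize, and compare against the normalized exact
    profile on the same z grid.  Returns a DataFrame (z_D_cm, mse).
    """
    exact = normalize_profile(exact_p0(stack, const, grid=grid))
    rows = []
    for z_D in z_D_list:
        if z_D >= 0:
            raise ValueError("z_D values must be negative")
        det = DetectionPoint(x_D=x_D, z_D=float(z_D))
        sig = solve(stack, beam, const, det, grid=grid, bin_width=bin_width, foil=foil)
        recon = reconstruct_p0_ff(to_retarded_depth(sig), z_min=0.0, z_max=stack.L_z)
        err = mse(exact, normalize_profile(recon))
        rows.append((float(z_D), err))
    return pd.DataFrame(rows, columns=["z_D_cm", "mse"])
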