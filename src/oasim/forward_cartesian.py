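"""Brute-force Cartesian oracle for the optoacoustic Poisson integral.

Voxelizes the source volume, accumulates W(r') * dV / |r_D - r'| into
propagation-distance bins voxel by voxel, and differentiates in time —
an O(N_x N_y N_z) evaluation used to validate the fast cylindrical solver.
The default grid is deliberately coarse; the oracle only needs enough
resolution to bound the fast solver's error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .forward_cylindrical import BinnedIntegrand, temporal_derivative, _GUARD_BINS
from .phantom_source import (
    DetectionPoint,
    LayerStack,
    SourceConstant,
    TopHatBeam,
    beam_profile,
    depth_profile_g,
)
from .signal import PressureSignal, moving_average

__all__ = ["CartesianGrid", "DEFAULT_ORACLE_GRID", "solve_oracle"]


@dataclass(frozen=True)
class CartesianGrid:
    """Voxelized box (L_x, L_y, L_z) with (N_x, N_y, N_z) voxels; x and y
    are centred on the beam axis, z spans [0, L_z] below the surface."""

    L_x: float
    L_y: float
    L_z: float
    N_x: int
    N_y: int
    N_z: int

    def __post_init__(self) -> None:
        if min(self.N_x, self.N_y, self.N_z) < 2:
            raise ValueError("all voxel counts must be >= 2")
        if min(self.L_x, self.L_y, self.L_z) <= 0:
            raise ValueError("box extents must be positive")

    @property
    def d_x(self) -> float:
        return self.L_x / self.N_x

    @property
    def d_y(self) -> float:
        return self.L_y / self.N_y

    @property
    def d_z(self) -> float:
        return self.L_z / self.N_z

    @property
    def x_centers(self) -> np.ndarray:
        return -0.5 * self.L_x + (np.arange(self.N_x) + 0.5) * self.d_x

    @property
    def y_centers(self) -> np.ndarray:
        return -0.5 * self.L_y + (np.arange(self.N_y) + 0.5) * self.d_y

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.N_z) + 0.5) * self.d_z


#: Desk-scale oracle default; the full-resolution (1500, 1500, 150) box is
#: supported but needs hundreds of millions of voxels.
DEFAULT_ORACLE_GRID = CartesianGrid(
    L_x=0.6, L_y=0.6, L_z=0.15, N_x=300, N_y=300, N_z=75
)


def solve_oracle(
    stack: LayerStack,
    beam: TopHatBeam,
    const: SourceConstant,
    detection: DetectionPoint,
    grid: CartesianGrid = DEFAULT_ORACLE_GRID,
    bin_width: float = 0.001,
    foil=None,
    smooth_bins: int = 3,
) -> PressureSignal:
    """Direct voxel sum of the Poisson integral followed by the same
    smoothing / differentiation / foil-averaging chain as the fast solver.

    W is evaluated at voxel centers with no sub-voxel averaging.  Emits a
    warning and returns a zero signal if no voxel absorbs.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    standoff = detection.standoff
    x = grid.x_centers
    y = grid.y_centers
    z = grid.z_centers
    g = np.asarray(depth_profile_g(stack, z), dtype=float)
    f_xy = beam_profile(beam, np.hypot(x[:, None], y[None, :]))
    dV = grid.d_x * grid.d_y * grid.d_z
    scale = const.prefactor / (4.0 * math.pi) * dV

    # distance range over voxel centers (detector at (x_D, 0, z_D))
    dx2 = (x - detection.x_D) ** 2
    r_lat2 = dx2[:, None] + y[None, :] ** 2
    lat_lo, lat_hi = r_lat2.min(), r_lat2.max()
    s_lo = math.sqrt(lat_lo + (standoff + z[0]) ** 2)
    s_hi = math.sqrt(lat_hi + (standoff + z[-1]) ** 2)
    ct_min = max(0.0, s_lo - _GUARD_BINS * bin_width)
    n_bins = int(math.ceil((s_hi - ct_min) / bin_width)) + _GUARD_BINS

    q = np.zeros(n_bins)
    active = np.flatnonzero((g > 0.0) & (f_xy.max() > 0.0))
    if active.size == 0 or f_xy.max() == 0.0:
        warnings.warn("no absorbing voxels inside the Cartesian grid", stacklevel=2)
    for k in active:  # slab-by-slab to bound memory
        s = np.sqrt(r_lat2 + (standoff + z[k]) ** 2)
        w = scale * f_xy * (g[k] / s)
        idx = ((s - ct_min) / bin_width).astype(np.int64)
        q += np.bincount(idx.ravel(), weights=w.ravel(), minlength=n_bins)

    ct = ct_min + (np.arange(n_bins) + 0.5) * bin_width
    binned = BinnedIntegrand(ct=ct, q=q, bin_width=bin_width, detection=detection)
    if smooth_bins > 1:
        binned = BinnedIntegrand(
            ct=ct,
            q=moving_average(binned.q, smooth_bins),
            bin_width=bin_width,
            detection=detection,
        )
    signal = temporal_derivative(binned)
    if foil is not None:
        from .detector_model import foil_average

        signal = foil_average(signal, foil)
    return signal
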