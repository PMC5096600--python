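"""Pressure-transient container and shared moving-average primitive.

Signal axes are propagation distances ``ct`` in cm (the speed of sound is
never needed numerically); after shifting by the detector standoff the axis
becomes the retarded depth ``ctau = ct + z_D`` with ctau = 0 at the
absorber surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .phantom_source import DetectionPoint

__all__ = ["PressureSignal", "moving_average", "write_signal_csv", "read_signal_csv"]


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean that shrinks at the record edges (no padding).

    Odd windows are symmetric and shrink symmetrically near the boundaries,
    so no zero-padding transients are introduced.  Even windows take the
    extra sample from the past side and are clipped at the edges.
    window <= 1 is the identity.
    """
    values = np.asarray(values, dtype=float)
    if window <= 1:
        return values.copy()
    n = values.size
    if window > n:
        raise ValueError(f"window ({window}) exceeds record length ({n})")
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    if window % 2:
        k = np.minimum(window // 2, np.minimum(idx, n - 1 - idx))
        lo, hi = idx - k, idx + k
    else:
        lo = np.clip(idx - (window - 1) // 2 - 1, 0, None)  # extra past sample
        hi = np.clip(idx + window // 2 - 1, None, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


@dataclass(frozen=True)
class PressureSignal:
    """Uniformly sampled pressure transient in arbitrary units.

    Parameters
    ----------
    ct : ndarray
        Uniform propagation-distance grid in cm (or retarded depth if
        ``axis == "ctau"``).
    p : ndarray
        Pressure samples, arbitrary units.
    detection : DetectionPoint
        Where the signal was observed.
    bin_width : float
        Sample spacing in cm.
    axis : str
        ``"ct"`` for raw propagation distance, ``"ctau"`` for retarded depth.
    """

    ct: np.ndarray
    p: np.ndarray
    detection: DetectionPoint
    bin_width: float
    axis: str = "ct"

    def __post_init__(self) -> None:
        ct = np.asarray(self.ct, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if ct.shape != p.shape or ct.ndim != 1:
            raise ValueError("ct and p must be 1-D arrays of equal length")
        if ct.size >= 2:
            steps = np.diff(ct)
            if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
                raise ValueError("ct axis must be uniformly spaced")
        if self.axis not in ("ct", "ctau"):
            raise ValueError("axis must be 'ct' or 'ctau'")
        object.__setattr__(self, "ct", ct)
        object.__setattr__(self, "p", p)

    def with_values(self, p: np.ndarray) -> "PressureSignal":
        return replace(self, p=np.asarray(p, dtype=float))

    @property
    def ctau(self) -> np.ndarray:
        """Retarded depth axis ctau = ct + z_D (identity if already shifted)."""
        if self.axis == "ctau":
            return self.ct
        return self.ct + self.detection.z_D

    def __len__(self) -> int:
        return self.ct.size


def write_signal_csv(signal: PressureSignal, path: str | Path) -> None:
    """Two-column CSV (axis in cm, pressure in a.u.); a third ``ctau_cm``
    column is added for raw-axis signals."""
    path = Path(path)
    if signal.axis == "ct":
        header = "ct_cm,p_au,ctau_cm"
        data = np.column_stack([signal.ct, signal.p, signal.ctau])
    else:
        header = "ctau_cm,p_au"
        data = np.column_stack([signal.ct, signal.p])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def read_signal_csv(path: str | Path, detection: DetectionPoint) -> PressureSignal:
    """Read a signal written by :func:`write_signal_csv`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    axis = "ctau" if header[0].startswith("ctau") else "ct"
    ct, p = data[:, 0], data[:, 1]
    return PressureSignal(
        ct=ct, p=p, detection=detection, bin_width=float(ct[1] - ct[0]), axis=axis
    )
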