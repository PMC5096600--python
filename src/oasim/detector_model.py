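"""Finite-foil detector model and measured-trace utilities.

A piezoelectric foil of thickness delta_w integrates the incident pressure
over the transit time delta_w / c; on the ct axis that is a centered moving
mean over a window of delta_w (in cm).  Also provides the retarded-depth
axis shift ctau = ct + z_D, a least-squares amplitude calibration against a
reference trace, and the oversampled-voltage smoothing utility.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal import PressureSignal, moving_average

__all__ = [
    "FoilModel",
    "MeasuredTrace",
    "foil_average",
    "to_retarded_depth",
    "amplitude_calibration",
    "smooth_measured",
    "ct_to_time",
]

#: Default speed of sound for ct <-> t conversion, cm/s (soft tissue).
DEFAULT_SPEED_OF_SOUND = 1.5e5


@dataclass(frozen=True)
class FoilModel:
    """Transducer foil of thickness ``delta_w`` in micrometres.

    delta_w = 0 models an ideal (infinitely thin) detector.
    """

    delta_w: float = 50.0

    def __post_init__(self) -> None:
        if self.delta_w < 0:
            raise ValueError("foil thickness must be >= 0")

    @property
    def window_ct(self) -> float:
        """Averaging window on the ct axis in cm (1 um = 1e-4 cm)."""
        return self.delta_w * 1e-4


@dataclass(frozen=True)
class MeasuredTrace:
    """Uniformly sampled detector voltage trace."""

    sample_rate: float  # samples per second
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def foil_average(signal: PressureSignal, foil: FoilModel) -> PressureSignal:
    """Average the signal over the foil transit window delta_w / c.

    The window is rounded to the nearest odd bin count; zero thickness is
    the identity.  Edges shrink the window symmetrically.
    """
    if foil.delta_w == 0:
        return signal
    n = foil.window_ct / signal.bin_width
    window = int(round(n))
    if window % 2 == 0:
        window += 1
    if window <= 1:
        return signal
    return signal.with_values(moving_average(signal.p, window))


def to_retarded_depth(signal: PressureSignal) -> PressureSignal:
    """Shift the axis to retarded depth ctau = ct + z_D (ctau = 0 at the
    absorber surface); pressure values are untouched."""
    if signal.axis == "ctau":
        return signal
    return replace(signal, ct=signal.ct + signal.detection.z_D, axis="ctau")


def amplitude_calibration(
    simulated: PressureSignal | np.ndarray, reference: PressureSignal | np.ndarray
) -> float:
    """Least-squares scale s minimizing ||s * simulated - reference||^2.

    Closed form s = <sim, ref> / <sim, sim>.  Both signals must already be
    resampled to a common axis.
    """
    sim = simulated.p if isinstance(simulated, PressureSignal) else np.asarray(simulated)
    ref = reference.p if isinstance(reference, PressureSignal) else np.asarray(reference)
    if sim.shape != ref.shape:
        raise ValueError("signals must share a common sampling axis")
    denom = float(np.dot(sim, sim))
    if denom == 0.0:
        raise ValueError("cannot calibrate against an identically zero simulation")
    return float(np.dot(sim, ref)) / denom


def smooth_measured(trace: MeasuredTrace, window_ns: float) -> MeasuredTrace:
    """Moving-average smoothing of an oversampled voltage trace.

    The window is round(window_ns * sample_rate) samples — e.g. 20 ns at
    2 GS/s is 40 samples; a sub-sample window is the identity.
    """
    n_samples = window_ns * 1e-9 * trace.sample_rate
    if n_samples < 1:
        raise ValueError("smoothing window is shorter than one sample")
    window = int(round(n_samples))
    if window > trace.values.size:
        raise ValueError("smoothing window exceeds trace length")
    return MeasuredTrace(
        sample_rate=trace.sample_rate, values=moving_average(trace.values, window)
    )


def smoothing_window_samples(window_ns: float, sample_rate: float) -> int:
    """Number of samples in a smoothing window of ``window_ns`` nanoseconds."""
    return int(round(window_ns * 1e-9 * sample_rate))


def ct_to_time(ct_cm, c: float = DEFAULT_SPEED_OF_SOUND):
    """Convert a propagation-distance axis (cm) to time (s) for a given
    speed of sound; the core never needs this, it only interfaces measured
    traces recorded versus time."""
    return np.asarray(ct_cm, dtype=float) / c
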