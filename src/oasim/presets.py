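"""Bundled scenario configurations and signal feature extraction.

Every simulation scenario used in the package's validation — the two-layer
near-/far-field demonstrations, the off-axis sensitivity study, and the
three melanin-doped hydrogel phantom models PI-PIII (S = skin-like weak
absorber, M = melanoma-like strong absorber) — is generated here from its
printed parameters; no external data files exist or are needed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .detector_model import FoilModel
from .forward_cylindrical import DEFAULT_GRID, CylindricalGrid
from .phantom_source import (
    AbsorbingLayer,
    DetectionPoint,
    LayerStack,
    SourceConstant,
    TopHatBeam,
)
from .signal import PressureSignal

__all__ = [
    "ScenarioConfig",
    "SignalFeature",
    "preset",
    "PRESET_NAMES",
    "extract_features",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """A complete, serializable simulation scenario.

    ``stack_frame`` records whether layer coordinates are measured from the
    absorber surface (``"surface"``) or from the detector (``"detector"``,
    used by the phantom presets whose layer depths are quoted relative to
    the detection point); :meth:`surface_stack` always yields the
    solver-ready surface-relative stack.
    """

    name: str
    stack: LayerStack
    beam: TopHatBeam
    detections: tuple[DetectionPoint, ...]
    grid: CylindricalGrid
    foil: FoilModel
    const: SourceConstant
    stack_frame: str = "surface"

    def __post_init__(self) -> None:
        if self.stack_frame not in ("surface", "detector"):
            raise ValueError("stack_frame must be 'surface' or 'detector'")
        object.__setattr__(self, "detections", tuple(self.detections))

    def surface_stack(self, detection: DetectionPoint | None = None) -> LayerStack:
        """Layer stack with depths measured from the absorber surface.

        Detector-frame presets are shifted by the standoff |z_D| of the
        given detection point (default: the scenario's first one).
        """
        if self.stack_frame == "surface":
            return self.stack
        det = detection if detection is not None else self.detections[0]
        shift = det.standoff
        layers = [
            AbsorbingLayer(l.z_start - shift, l.z_end - shift, l.mu_a)
            for l in self.stack.layers
        ]
        return LayerStack(layers=layers, L_z=self.stack.L_z - shift)

    # -- lossless JSON round trip -------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "stack_frame": self.stack_frame,
            "layers": [asdict(l) for l in self.stack.layers],
            "L_z": self.stack.L_z,
            "beam": {"a": self.beam.a, "d": self.beam.d},
            "detections": [{"x_D": d.x_D, "z_D": d.z_D} for d in self.detections],
            "grid": asdict(self.grid),
            "foil": {"delta_w": self.foil.delta_w},
            "const": {"prefactor": self.const.prefactor},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        try:
            return cls(
                name=d["name"],
                stack=LayerStack(
                    layers=[AbsorbingLayer(**l) for l in d["layers"]], L_z=d["L_z"]
                ),
                beam=TopHatBeam(**d["beam"]),
                detections=tuple(DetectionPoint(**p) for p in d["detections"]),
                grid=CylindricalGrid(**d["grid"]),
                foil=FoilModel(**d["foil"]),
                const=SourceConstant(**d["const"]),
                stack_frame=d.get("stack_frame", "surface"),
            )
        except KeyError as exc:
            raise ValueError(f"config is missing required key {exc}") from exc
        except TypeError as exc:
            raise ValueError(f"malformed config: {exc}") from exc

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScenarioConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def _two_layer(name: str, mu_first: float, mu_second: float) -> ScenarioConfig:
    stack = LayerStack(
        layers=[
            AbsorbingLayer(0.0, 0.05, mu_first),
            AbsorbingLayer(0.05, 0.10, mu_second),
        ],
        L_z=0.15,
    )
    return ScenarioConfig(
        name=name,
        stack=stack,
        beam=TopHatBeam(a=0.15, d=0.15 / 4),
        detections=(DetectionPoint(0.0, -0.04), DetectionPoint(0.0, -4.0)),
        grid=DEFAULT_GRID,
        foil=FoilModel(delta_w=50.0),
        const=SourceConstant(),
    )


def _phantom(
    name: str,
    layers: list[AbsorbingLayer],
    L_z_detector: float,
    a: float,
    R: float,
    grid: CylindricalGrid,
) -> ScenarioConfig:
    # layer depths quoted relative to the detector at z_D = -0.3 cm
    return ScenarioConfig(
        name=name,
        stack=LayerStack(layers=layers, L_z=L_z_detector),
        beam=TopHatBeam(a=a, d=R * a),
        detections=(DetectionPoint(0.0, -0.3),),
        grid=grid,
        foil=FoilModel(delta_w=50.0),
        const=SourceConstant(),
        stack_frame="detector",
    )


def _build_presets() -> dict[str, ScenarioConfig]:
    presets: dict[str, ScenarioConfig] = {}
    presets["fig3a"] = _two_layer("fig3a", 10.0, 20.0)
    presets["fig3b"] = _two_layer("fig3b", 20.0, 10.0)

    fig3a = presets["fig3a"]
    presets["fig4"] = ScenarioConfig(
        name="fig4",
        stack=fig3a.stack,
        beam=fig3a.beam,
        detections=tuple(
            DetectionPoint(x_D, z_D)
            for z_D in (-0.2, -1.0, -5.0)
            for x_D in (0.0, 0.1, 0.2)
        ),
        grid=DEFAULT_GRID,
        foil=FoilModel(delta_w=50.0),
        const=SourceConstant(),
    )

    presets["PI"] = _phantom(
        "PI",
        [AbsorbingLayer(0.3, 0.395, 11.0)],
        L_z_detector=0.5,
        a=0.054,
        R=1.5,
        grid=CylindricalGrid(L_rho=0.4, N_rho=8000, N_phi=360, L_z=0.2, N_z=200),
    )
    presets["PII"] = _phantom(
        "PII",
        [AbsorbingLayer(0.3, 0.408, 1.4), AbsorbingLayer(0.408, 0.504, 11.0)],
        L_z_detector=0.55,
        a=0.056,
        R=1.2,
        grid=CylindricalGrid(L_rho=0.35, N_rho=7000, N_phi=360, L_z=0.25, N_z=250),
    )
    presets["PIII"] = _phantom(
        "PIII",
        [AbsorbingLayer(0.3, 0.5, 1.4), AbsorbingLayer(0.5, 0.595, 11.0)],
        L_z_detector=0.6,
        a=0.08,
        R=1.2,
        grid=CylindricalGrid(L_rho=0.5, N_rho=10000, N_phi=360, L_z=0.3, N_z=300),
    )
    return presets


_PRESETS = _build_presets()
PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> ScenarioConfig:
    """Return the named bundled scenario.

    Valid names: fig3a, fig3b, fig4 (two-layer demonstrations and off-axis
    study) and PI, PII, PIII (hydrogel phantom models).
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None


@dataclass(frozen=True)
class SignalFeature:
    """A compression peak (positive amplitude) or rarefaction dip
    (negative amplitude) at retarded depth ``ctau``."""

    kind: str  # "compression_peak" | "rarefaction_dip"
    ctau: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.kind == "compression_peak":
            if self.amplitude <= 0:
                raise ValueError("compression peaks must have positive amplitude")
        elif self.kind == "rarefaction_dip":
            if self.amplitude >= 0:
                raise ValueError("rarefaction dips must have negative amplitude")
        else:
            raise ValueError(f"unknown feature kind {self.kind!r}")


def extract_features(
    signal: PressureSignal, min_prominence: float = 0.05
) -> list[SignalFeature]:
    """Locate compression peaks and rarefaction dips of a transient.

    ``min_prominence`` is relative to max|p|; the 5% default sits above the
    binning noise floor yet below the smallest physical feature of the
    bundled scenarios.  The signal must be on the retarded-depth axis;
    features are returned ordered by ctau.
    """
    if signal.axis != "ctau":
        raise ValueError("feature extraction expects a retarded-depth axis")
    p = signal.p
    peak_scale = float(np.max(np.abs(p))) if p.size else 0.0
    if peak_scale == 0.0:
        return []
    prominence = min_prominence * peak_scale
    feats: list[SignalFeature] = []
    maxima, _ = find_peaks(p, prominence=prominence)
    for i in maxima:
        if p[i] > 0:
            feats.append(SignalFeature("compression_peak", float(signal.ct[i]), float(p[i])))
    minima, _ = find_peaks(-p, prominence=prominence)
    for i in minima:
        if p[i] < 0:
            feats.append(SignalFeature("rarefaction_dip", float(signal.ct[i]), float(p[i])))
    feats.sort(key=lambda f: f.ctau)
    return feats
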