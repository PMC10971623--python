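"""Analysis configuration: YAML-backed settings with embedded defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .errors import ParameterError
from .model import FRAMES


@dataclass
class AnalysisConfig:
    """Effective parameters of the smooth -> resample -> label -> metrics pipeline."""

    smoothing_factor: float = 0.1
    smoothing_iterations: int = 100
    resample_spacing_mm: float = 5.0
    curvature_spacing_mm: float = 5.0
    bifurcation_window_mm: float = 15.0
    bifurcation_area_spacing_mm: float = 5.0
    frame: str = "LPS"
    radius_array: str = "MaximumInscribedSphereRadius"

    def __post_init__(self):
        if not 0 < self.smoothing_factor < 1:
            raise ParameterError("smoothing.factor must lie in (0, 1)")
        if self.smoothing_iterations < 0:
            raise ParameterError("smoothing.iterations must be non-negative")
        for name in (
            "resample_spacing_mm",
            "curvature_spacing_mm",
            "bifurcation_window_mm",
            "bifurcation_area_spacing_mm",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.frame not in FRAMES:
            raise ParameterError(f"frame must be one of {FRAMES}")

    def to_dict(self) -> dict:
        return asdict(self)


_YAML_KEYS = {
    ("smoothing", "factor"): "smoothing_factor",
    ("smoothing", "iterations"): "smoothing_iterations",
    ("resample", "spacing_mm"): "resample_spacing_mm",
    ("curvature", "spacing_mm"): "curvature_spacing_mm",
    ("bifurcation", "window_mm"): "bifurcation_window_mm",
    ("bifurcation", "area_spacing_mm"): "bifurcation_area_spacing_mm",
    ("frame",): "frame",
    ("radius_array",): "radius_array",
}


def load_config(path=None, **overrides) -> AnalysisConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    The YAML schema is nested (``smoothing: {factor: 0.1, iterations: 100}``,
    ``resample: {spacing_mm: 5.0}``, ``curvature: {spacing_mm: 5.0}``,
    ``bifurcation: {window_mm: 15.0, area_spacing_mm: 5.0}``, ``frame: LPS``,
    ``radius_array: ...``); unknown keys raise.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ParameterError(f"config {path} must be a YAML mapping")
        flat = {}
        for k, v in doc.items():
            if isinstance(v, dict):
                for k2, v2 in v.items():
                    flat[(k, k2)] = v2
            else:
                flat[(k,)] = v
        for key, v in flat.items():
            if key not in _YAML_KEYS:
                raise ParameterError(f"unknown config key {'.'.join(key)!r}")
            values[_YAML_KEYS[key]] = v
    values.update({k: v for k, v in overrides.items() if v is not None})
    return AnalysisConfig(**values)
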