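"""Pipeline configuration: a flat, schema-validated parameter set.

Every tunable of the reconstruction/registration pipeline lives here so a
run is reproducible from (inputs, config, seed) alone.  Unknown keys are
rejected on load; the config round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig"]

_SCHEMA = "gridstereo-config/1"


@dataclass
class PipelineConfig:
    """All pipeline parameters with their defaults.

    Units: windows/radii/tolerances in pixels unless suffixed ``_mm``.
    """

    # preprocessing
    intensity_correction: bool = True  # ablation switch
    correction_window: int = 31  # box size for the local mean (px)
    correction_mode: str = "half"  # 'half' (default) or 'squared'
    roi: bool = True  # ablation switch
    roi_close_radius: int = 18  # >= half the inter-line spacing in px
    roi_min_area_fraction: float = 0.02
    # 'background' exploits the flat 127.5 background that intensity
    # correction establishes; when correction is disabled the pipeline falls
    # back to conventional Otsu thresholding regardless of this setting.
    threshold_method: str = "background"  # 'background', 'otsu' or 'fixed'
    threshold_level: float | None = None  # for 'fixed'
    clean_radius: int = 1
    clean_min_size: int = 25  # px; remove smaller components before closing
    clean_max_hole: int = 100  # px; fill smaller background holes after closing

    # junction detection
    cpn_threshold: float = 3.0  # in [3, 4]
    min_separation: float | None = None  # px; None = auto (half median spacing)
    refine: bool = True
    score_match_radius: float = 3.0  # px, for detection-vs-truth scoring

    # matching
    pattern_rows: int = 7
    pattern_cols: int = 11
    epipolar_tol: float = 2.0  # px

    # triangulation / surface fit
    max_ray_gap_mm: float = 2.0
    upsample: int = 8
    surface_method: str = "bicubic"  # 'bicubic' or 'tps'

    # registration
    icp_max_iter: int = 100
    icp_tol: float = 1e-4  # mm change in RMS distance
    icp_trim_fraction: float = 0.0
    asd_direction: str = "forward"

    seed: int = 0

    def __post_init__(self) -> None:
        if not (3.0 <= self.cpn_threshold <= 4.0):
            raise ConfigError("cpn_threshold must lie in [3, 4]")
        if self.correction_window < 3 or self.correction_window % 2 == 0:
            raise ConfigError("correction_window must be odd and >= 3")
        if self.pattern_rows < 2 or self.pattern_cols < 2:
            raise ConfigError("pattern must have at least 2 rows and 2 columns")
        if self.epipolar_tol <= 0 or self.max_ray_gap_mm <= 0:
            raise ConfigError("tolerances must be positive")

    def to_yaml(self, path) -> None:
        doc = {"schema": _SCHEMA}
        doc.update(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        schema = doc.pop("schema", None)
        if schema != _SCHEMA:
            raise ConfigError(f"unsupported config schema {schema!r}; expected {_SCHEMA!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
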