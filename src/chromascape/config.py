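"""Pipeline configuration: a flat, strictly-validated key-value file.

All stage parameters live in one :class:`PipelineConfig`; unknown keys in
a YAML config are rejected so typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .metrics import DEFAULT_SCALES, MetricsConfig
from .palette import EXCLUSIVE_PRECEDENCE, ColorPalette, default_palette

__all__ = ["PipelineConfig", "load_config"]


@dataclasses.dataclass
class PipelineConfig:
    """All tunables of the image -> metrics -> psychometrics pipeline."""

    # segmentation
    palette: ColorPalette = dataclasses.field(default_factory=default_palette)
    segmentation_mode: str = "exclusive"
    precedence: tuple[str, ...] = EXCLUSIVE_PRECEDENCE
    # spatial metrics
    box_scales: tuple[int, ...] = DEFAULT_SCALES
    lattice_shape: tuple[int, int] = (100, 100)
    weights_scheme: str = "rook"
    row_standardized: bool = True
    diversity_grid: tuple[int, int] = (8, 8)
    diversity_normalized: bool = True
    # healing-rating selection
    mean_min: float = 5.0
    median_min: float = 5.0
    sd_max: float = 1.2
    # factor analysis
    retention: str = "kaiser"          # or "fixed"
    n_factors: int | None = None       # used when retention == "fixed"
    observation_mode: str = "participant_by_image"  # or "image_mean"
    scoring_method: str = "regression"
    load_min: float = 0.40
    crossload_gap: float = 0.20
    # clustering
    cluster_k: int | None = 8          # None -> silhouette-selected
    # bookkeeping
    seed: int = 0
    output_dir: str = "chromascape_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.segmentation_mode not in ("exclusive", "non_exclusive"):
            raise ValueError(
                f"bad segmentation_mode {self.segmentation_mode!r}")
        if self.weights_scheme not in ("rook", "queen"):
            raise ValueError(f"bad weights_scheme {self.weights_scheme!r}")
        if self.retention not in ("kaiser", "fixed"):
            raise ValueError(f"bad retention {self.retention!r}")
        if self.retention == "fixed" and not self.n_factors:
            raise ValueError("retention='fixed' requires n_factors")
        if self.observation_mode not in ("participant_by_image",
                                         "image_mean"):
            raise ValueError(
                f"bad observation_mode {self.observation_mode!r}")
        if self.sd_max <= 0:
            raise ValueError("sd_max must be positive")

    def metrics_config(self) -> MetricsConfig:
        return MetricsConfig(
            scales=tuple(self.box_scales),
            lattice_shape=tuple(self.lattice_shape),
            weights_scheme=self.weights_scheme,
            row_standardized=self.row_standardized,
            diversity_grid=tuple(self.diversity_grid),
            diversity_normalized=self.diversity_normalized)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["palette"] = self.palette.to_dict()
        d["precedence"] = list(self.precedence)
        d["box_scales"] = list(self.box_scales)
        d["lattice_shape"] = list(self.lattice_shape)
        d["diversity_grid"] = list(self.diversity_grid)
        return d


_TUPLE_KEYS = {"precedence", "box_scales", "lattice_shape",
               "diversity_grid"}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, and optional
    overrides (applied last).  Unknown keys raise ``ValueError``."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "palette" in data and not isinstance(data["palette"], ColorPalette):
        data["palette"] = ColorPalette.from_dict(data["palette"])
    for key in _TUPLE_KEYS & set(data):
        data[key] = tuple(data[key])
    return PipelineConfig(**data)
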