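"""Pipeline configuration: stage parameters and the channel map.

A single YAML file drives the CLI; each section maps onto one of the
dataclasses below. Defaults reproduce the published analysis settings
(level-set weights, area filters, vessel rule, attachment radius, k = 100
neighbours, 4-100 px particle window).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import yaml

from .types import ConfigError, LevelSetParams


@dataclass
class SegmentationConfig:
    """Parameters of the staged microglia segmentation."""

    nucleus_params: LevelSetParams = field(default_factory=lambda: LevelSetParams(nu=2.0, mu=3.0))
    soma_params: LevelSetParams = field(default_factory=lambda: LevelSetParams(nu=2.0, mu=3.0))
    cytoplasm_params: LevelSetParams = field(default_factory=lambda: LevelSetParams(nu=2.0, mu=2.0))
    min_soma_area_px: int = 50
    min_nucleus_area_px: int = 30
    vessel_min_area_px: int = 4000  # strictly-greater rule
    process_attach_radius_px: float = 10.0
    connectivity: int = 8
    require_nucleus_overlap: bool = True
    plaque_mode: str = "threshold"  # 'threshold' or 'classifier'
    min_plaque_area_px: int = 100

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ConfigError(f"connectivity must be 4 or 8, got {self.connectivity}")
        for name in ("min_soma_area_px", "min_nucleus_area_px", "vessel_min_area_px"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.process_attach_radius_px < 0:
            raise ConfigError("process_attach_radius_px must be >= 0")
        if self.plaque_mode not in ("threshold", "classifier"):
            raise ConfigError(f"plaque_mode must be 'threshold' or 'classifier', got {self.plaque_mode!r}")


@dataclass
class PhenotypeConfig:
    """Parameters of kNN-graph phenotyping and cluster post-processing."""

    k_neighbors: int = 100
    resolution: float = 1.0
    seed: int = 0
    exclude_median_z_below: float = -0.5  # TMEM119/P2RY12/Iba1 all below → non-microglia
    merge_median_distance: float = 0.0  # 0 disables automatic merging
    manual_merges: List[List[int]] = field(default_factory=list)
    max_clusters_warn: int = 12
    tsne_perplexity: float = 30.0


@dataclass
class SpatialConfig:
    plaque_dilation_px: int = 0
    bonferroni_m: int = 1
    force_test: Optional[str] = None  # override normality-based selection


@dataclass
class IronConfig:
    threshold: int = 128
    min_size_px: int = 4
    max_size_px: int = 100
    connectivity: int = 8
    dark_objects: bool = True
    auto_threshold: bool = False  # Otsu on the ROI; not part of the published protocol


@dataclass
class PipelineConfig:
    channel_map: Dict[str, int] = field(default_factory=dict)  # channel name → TIFF page
    pixel_size_um: float = 0.5
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    iron: IronConfig = field(default_factory=IronConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def _levelset_from_dict(d: dict) -> LevelSetParams:
    return LevelSetParams(**d)


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    seg_raw = dict(raw.get("segmentation", {}))
    for key in ("nucleus_params", "soma_params", "cytoplasm_params"):
        if key in seg_raw and isinstance(seg_raw[key], dict):
            seg_raw[key] = _levelset_from_dict(seg_raw[key])
    try:
        return PipelineConfig(
            channel_map=dict(raw.get("channel_map", {})),
            pixel_size_um=float(raw.get("pixel_size_um", 0.5)),
            segmentation=SegmentationConfig(**seg_raw),
            phenotype=PhenotypeConfig(**raw.get("phenotype", {})),
            spatial=SpatialConfig(**raw.get("spatial", {})),
            iron=IronConfig(**raw.get("iron", {})),
        )
    except TypeError as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
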