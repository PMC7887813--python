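"""Iron-positive particle counting on DAB-enhanced Perl's brightfield images.

Mirrors the ImageJ workflow: RGB → 8-bit grayscale (luminance), a per-subject
intensity threshold selecting the dark DAB-positive deposits, then
connected-component particle analysis keeping components whose area lies in
an inclusive [4, 100] px window. Thresholds are per-subject inputs (they were
set manually, blinded, in the source protocol); an optional Otsu mode
automates them but is not part of that protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage as ndi

from .config import IronConfig
from .segmentation import otsu_threshold
from .types import GliaquantError

_STRUCTS = {4: ndi.generate_binary_structure(2, 1), 8: ndi.generate_binary_structure(2, 2)}


@dataclass
class ParticleConfig:
    """Threshold and size window of the particle analysis."""

    threshold: int = 128
    min_size_px: int = 4
    max_size_px: int = 100
    connectivity: int = 8
    dark_objects: bool = True
    roi_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise GliaquantError("threshold must be in [0, 255]")
        if not 0 < self.min_size_px <= self.max_size_px:
            raise GliaquantError("require 0 < min_size_px <= max_size_px")
        if self.connectivity not in (4, 8):
            raise GliaquantError("connectivity must be 4 or 8")

    @classmethod
    def from_iron_config(cls, cfg: IronConfig, roi_mask=None) -> "ParticleConfig":
        return cls(
            threshold=cfg.threshold,
            min_size_px=cfg.min_size_px,
            max_size_px=cfg.max_size_px,
            connectivity=cfg.connectivity,
            dark_objects=cfg.dark_objects,
            roi_mask=roi_mask,
        )


@dataclass
class ParticleResult:
    """Count and areas of size-window particles; density when pixel size known."""

    n_particles: int
    areas: List[int] = field(default_factory=list)
    density_per_mm2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_particles != len(self.areas):
            raise GliaquantError("n_particles must equal len(areas)")


def rgb_to_gray8(rgb: np.ndarray) -> np.ndarray:
    """Luminance conversion 0.299 R + 0.587 G + 0.114 B, rounded to uint8."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise GliaquantError(f"expected an (h, w, 3) RGB image, got shape {rgb.shape}")
    gray = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def count_particles(
    gray: np.ndarray,
    config: Optional[ParticleConfig] = None,
    pixel_size_um: Optional[float] = None,
    auto_threshold: bool = False,
) -> ParticleResult:
    """ImageJ-style particle analysis within the configured size window.

    Dark-object polarity (the default, matching the DAB reaction product)
    selects pixels with ``gray <= threshold``; bright polarity selects
    ``gray >= threshold``. The size window is inclusive on both ends and is
    applied after labelling, so relaxing the threshold never decreases the
    number of components above the minimum before the maximum-size cut.
    """
    config = config or ParticleConfig()
    gray = np.asarray(gray)
    roi = config.roi_mask
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != gray.shape:
            raise GliaquantError("ROI mask shape differs from image shape")
        if not roi.any():
            raise GliaquantError("ROI mask is empty")
    threshold = config.threshold
    if auto_threshold:
        sample = gray[roi] if roi is not None else gray
        t, _ = otsu_threshold(sample.astype(float))
        threshold = int(t)
    binary = (gray <= threshold) if config.dark_objects else (gray >= threshold)
    if roi is not None:
        binary &= roi
    labels, n = ndi.label(binary, structure=_STRUCTS[config.connectivity])
    if n == 0:
        areas: List[int] = []
    else:
        counts = np.bincount(labels.ravel())[1:]
        areas = sorted(
            int(a) for a in counts if config.min_size_px <= a <= config.max_size_px
        )
    density = None
    if pixel_size_um is not None:
        region_px = int(roi.sum()) if roi is not None else gray.size
        area_mm2 = region_px * (pixel_size_um / 1000.0) ** 2
        density = len(areas) / area_mm2 if area_mm2 > 0 else None
    return ParticleResult(n_particles=len(areas), areas=areas, density_per_mm2=density)
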