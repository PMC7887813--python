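"""Domain types shared across the pipeline.

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, 0-based, origin at the top-left;
* label masks are 2D integer arrays with 0 = background and instances 1..n;
* intensities are non-negative floats (integer TIFF input is promoted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Mapping, Optional, Tuple

import numpy as np

#: The four membrane markers whose mean intensities define a cell's phenotype.
MEMBRANE_MARKERS: Tuple[str, ...] = ("TMEM119", "P2RY12", "FTL", "Iba1")

#: All channel names the pipeline understands.
KNOWN_CHANNELS: Tuple[str, ...] = MEMBRANE_MARKERS + ("DAPI", "Abeta", "autofluorescence")

PixelSet = FrozenSet[Tuple[int, int]]


class GliaquantError(Exception):
    """Base class for all package errors."""


class FormatError(GliaquantError):
    """Malformed input file (shape mismatch, dtype overflow, bad CSV)."""


class ConfigError(GliaquantError):
    """Invalid configuration or missing required channel."""


class GenerationError(GliaquantError):
    """Synthetic-data generation could not satisfy its constraints."""


class MaskKind(str, Enum):
    nucleus = "nucleus"
    soma = "soma"
    cell = "cell"
    plaque = "plaque"
    vessel = "vessel"
    component = "component"


@dataclass
class ComponentImage:
    """Aligned single-marker grayscale planes of one multiplexed field of view.

    Parameters
    ----------
    planes
        Mapping from channel name (see :data:`KNOWN_CHANNELS`) to a 2D
        non-negative float array. All planes must share one shape.
    pixel_size_um
        Side length of one pixel in micrometres (0.5 for the imaging setup
        this pipeline targets).
    subject_id
        Donor identifier the field of view came from.
    region_mask
        Optional categorical raster: 0 = excluded, 1 = grey matter,
        2 = white matter. When absent all cells are reported as GM.
    """

    planes: Mapping[str, np.ndarray]
    pixel_size_um: float = 0.5
    subject_id: str = ""
    region_mask: Optional[np.ndarray] = None

    REGION_GM = 1
    REGION_WM = 2

    def __post_init__(self) -> None:
        if not self.planes:
            raise FormatError("ComponentImage requires at least one plane")
        if self.pixel_size_um <= 0:
            raise ConfigError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        shape = None
        promoted = {}
        for name, plane in self.planes.items():
            if name not in KNOWN_CHANNELS:
                raise ConfigError(
                    f"unknown channel {name!r}; known channels: {KNOWN_CHANNELS}"
                )
            arr = np.asarray(plane, dtype=np.float64)
            if arr.ndim != 2:
                raise FormatError(f"plane {name!r} is not 2D (ndim={arr.ndim})")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise FormatError(
                    f"plane {name!r} has shape {arr.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"plane {name!r} contains non-finite values")
            if arr.min() < 0:
                raise FormatError(f"plane {name!r} contains negative intensities")
            promoted[name] = arr
        self.planes = promoted
        if self.region_mask is not None:
            rm = np.asarray(self.region_mask)
            if rm.shape != shape:
                raise FormatError("region_mask shape differs from plane shape")
            self.region_mask = rm.astype(np.int8)

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.planes.values())).shape

    def plane(self, name: str) -> np.ndarray:
        try:
            return self.planes[name]
        except KeyError:
            raise ConfigError(f"channel {name!r} not present in image") from None

    def has(self, name: str) -> bool:
        return name in self.planes

    def require_membrane_markers(self) -> None:
        missing = [m for m in MEMBRANE_MARKERS if m not in self.planes]
        if missing:
            raise ConfigError(f"missing membrane marker channel(s): {missing}")

    def region_at(self, row: int, col: int) -> str:
        """Region label ('GM'/'WM') at a pixel; GM when no region mask is set."""
        if self.region_mask is None:
            return "GM"
        code = int(self.region_mask[row, col])
        return "WM" if code == self.REGION_WM else "GM"


@dataclass
class LabelMask:
    """Integer-labelled instance mask: 0 background, 1..n instances."""

    labels: np.ndarray
    kind: MaskKind = MaskKind.component

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise FormatError("LabelMask must be 2D")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.array_equal(arr, arr.astype(np.int64)):
                raise FormatError("LabelMask labels must be integers")
            arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            raise FormatError("LabelMask labels must be non-negative")
        self.labels = arr
        self.kind = MaskKind(self.kind)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def compact(self) -> "LabelMask":
        """Relabel instances to a gap-free 1..n, preserving order."""
        ids = self.label_ids()
        lut = np.zeros(int(self.labels.max(initial=0)) + 1, dtype=np.int64)
        lut[ids] = np.arange(1, len(ids) + 1)
        return LabelMask(lut[self.labels], self.kind)

    def binary(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class LevelSetParams:
    """Weights of the level-set regularization energy.

    ``nu`` weights the perimeter term, ``mu`` the foreground-area term; larger
    values yield smoother / more conservative segmentations.
    """

    nu: float = 2.0
    mu: float = 3.0
    max_iter: int = 200
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.nu < 0 or self.mu < 0:
            raise ConfigError("nu and mu must be >= 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")


def _as_pixel_set(pixels) -> PixelSet:
    return frozenset((int(r), int(c)) for r, c in pixels)


@dataclass
class CellRecord:
    """One segmented microglia: pixel ownership, marker means, context flags."""

    cell_id: int
    soma_pixels: PixelSet
    cytoplasm_pixels: PixelSet
    process_pixels: PixelSet
    mean_intensity: Mapping[str, float]
    subject_id: str = ""
    nucleus_id: Optional[int] = None
    region: str = "GM"
    infiltrates_plaque: bool = False
    plaque_id: Optional[int] = None
    cluster: Optional[int] = None
    centroid: Tuple[float, float] = field(default=(0.0, 0.0))
    total_area_px: int = 0

    def __post_init__(self) -> None:
        self.soma_pixels = _as_pixel_set(self.soma_pixels)
        self.cytoplasm_pixels = _as_pixel_set(self.cytoplasm_pixels)
        self.process_pixels = _as_pixel_set(self.process_pixels)
        if self.soma_pixels & self.process_pixels:
            raise GliaquantError(
                f"cell {self.cell_id}: soma and process pixel sets overlap"
            )
        union = self.all_pixels()
        if not union:
            raise GliaquantError(f"cell {self.cell_id} has no pixels")
        if self.total_area_px == 0:
            self.total_area_px = len(union)
        elif self.total_area_px != len(union):
            raise GliaquantError(
                f"cell {self.cell_id}: total_area_px={self.total_area_px} "
                f"!= |soma ∪ cytoplasm ∪ processes|={len(union)}"
            )
        if set(self.mean_intensity) != set(MEMBRANE_MARKERS):
            raise GliaquantError(
                f"cell {self.cell_id}: mean_intensity must cover exactly "
                f"{MEMBRANE_MARKERS}, got {sorted(self.mean_intensity)}"
            )
        if self.region not in ("GM", "WM"):
            raise GliaquantError(f"region must be GM or WM, got {self.region!r}")
        if self.centroid == (0.0, 0.0):
            rows = [p[0] for p in union]
            cols = [p[1] for p in union]
            self.centroid = (float(np.mean(rows)), float(np.mean(cols)))

    def all_pixels(self) -> PixelSet:
        return self.soma_pixels | self.cytoplasm_pixels | self.process_pixels

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for r, c in self.all_pixels():
            out[r, c] = True
        return out


_ROMAN = {"0": 0, "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6}


@dataclass
class SubjectMeta:
    """Donor-level metadata: diagnosis group and pathology staging."""

    subject_id: str
    group: str  # 'control' or 'AD'
    braak: Optional[str] = None  # ordinal I..VI
    thal: Optional[str] = None  # ordinal 0..V
    apoe: Optional[str] = None
    onset: Optional[str] = None  # 'EOAD' / 'LOAD'

    def __post_init__(self) -> None:
        if self.group not in ("control", "AD"):
            raise ConfigError(f"group must be 'control' or 'AD', got {self.group!r}")
        if self.braak is not None and self.braak not in ("I", "II", "III", "IV", "V", "VI"):
            raise ConfigError(f"braak must be I..VI, got {self.braak!r}")
        if self.thal is not None and self.thal not in ("0", "I", "II", "III", "IV", "V"):
            raise ConfigError(f"thal must be 0..V, got {self.thal!r}")
        if self.onset is not None and self.onset not in ("EOAD", "LOAD"):
            raise ConfigError(f"onset must be EOAD or LOAD, got {self.onset!r}")

    @property
    def braak_score(self) -> Optional[int]:
        return _ROMAN.get(self.braak) if self.braak is not None else None

    @property
    def thal_score(self) -> Optional[int]:
        return _ROMAN.get(self.thal) if self.thal is not None else None
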