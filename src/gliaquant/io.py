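"""File I/O: multi-page TIFF component images, integer label masks, cell tables.

All coordinates written to CSV are (row, col), 0-based, origin top-left.
Label masks round-trip losslessly through 16- or 32-bit integer TIFF.
"""

from __future__ import annotations

import json
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import tifffile

from .types import (
    MEMBRANE_MARKERS,
    CellRecord,
    ComponentImage,
    ConfigError,
    FormatError,
    LabelMask,
    MaskKind,
    SubjectMeta,
)

#: Fixed, documented cell-table header.
CELL_TABLE_COLUMNS: List[str] = [
    "cell_id",
    "subject_id",
    "centroid_row",
    "centroid_col",
    "soma_area_px",
    "cytoplasm_area_px",
    "process_area_px",
    "total_area_px",
    *[f"mean_{m}" for m in MEMBRANE_MARKERS],
    "nucleus_id",
    "region",
    "cluster",
    "infiltrates_plaque",
    "plaque_id",
]


def read_component_image(
    path,
    channel_map: Mapping[str, int],
    pixel_size_um: float = 0.5,
    subject_id: str = "",
    region_mask: Optional[np.ndarray] = None,
) -> ComponentImage:
    """Read a multi-page TIFF into a :class:`ComponentImage`.

    ``channel_map`` maps channel names to 0-based TIFF page indices; only the
    mapped pages are loaded. Unknown channel names and mismatched page shapes
    raise :class:`ConfigError` / :class:`FormatError` respectively.
    """
    with tifffile.TiffFile(str(path)) as tif:
        n_pages = len(tif.pages)
        planes = {}
        for name, page_idx in channel_map.items():
            if not 0 <= int(page_idx) < n_pages:
                raise FormatError(
                    f"channel {name!r} maps to page {page_idx} but file has {n_pages} pages"
                )
            planes[name] = tif.pages[int(page_idx)].asarray()
    return ComponentImage(
        planes=planes,
        pixel_size_um=pixel_size_um,
        subject_id=subject_id,
        region_mask=region_mask,
    )


def write_component_image(image: ComponentImage, path) -> Dict[str, int]:
    """Write planes as a multi-page float32 TIFF; returns the channel map used."""
    names = list(image.planes)
    stack = np.stack([image.planes[n].astype(np.float32) for n in names])
    meta = {"channels": names, "pixel_size_um": image.pixel_size_um}
    tifffile.imwrite(str(path), stack, description=json.dumps(meta))
    return {name: i for i, name in enumerate(names)}


def write_label_mask(mask: LabelMask, path) -> None:
    """Write a label mask as a 16- or 32-bit unsigned-integer TIFF."""
    max_label = mask.n_labels
    if max_label <= np.iinfo(np.uint16).max:
        dtype = np.uint16
    elif max_label <= np.iinfo(np.uint32).max:
        dtype = np.uint32
    else:
        raise FormatError(f"label {max_label} exceeds 32-bit integer TIFF range")
    tifffile.imwrite(str(path), mask.labels.astype(dtype), description=mask.kind.value)


def read_label_mask(path, kind: Optional[MaskKind] = None) -> LabelMask:
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.pages[0].asarray()
        if kind is None:
            desc = tif.pages[0].description or ""
            try:
                kind = MaskKind(desc.strip())
            except ValueError:
                kind = MaskKind.component
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"label mask TIFF has non-integer dtype {arr.dtype}")
    return LabelMask(arr.astype(np.int64), kind)


def export_cell_table(cells: List[CellRecord], path) -> None:
    """Write one row per cell with the fixed :data:`CELL_TABLE_COLUMNS` header."""
    rows = []
    for cell in cells:
        row = {
            "cell_id": cell.cell_id,
            "subject_id": cell.subject_id,
            "centroid_row": cell.centroid[0],
            "centroid_col": cell.centroid[1],
            "soma_area_px": len(cell.soma_pixels),
            "cytoplasm_area_px": len(cell.cytoplasm_pixels),
            "process_area_px": len(cell.process_pixels),
            "total_area_px": cell.total_area_px,
            "nucleus_id": cell.nucleus_id,
            "region": cell.region,
            "cluster": cell.cluster,
            "infiltrates_plaque": cell.infiltrates_plaque,
            "plaque_id": cell.plaque_id,
        }
        for m in MEMBRANE_MARKERS:
            row[f"mean_{m}"] = repr(float(cell.mean_intensity[m]))
        rows.append(row)
    df = pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_cell_table(path) -> pd.DataFrame:
    """Read a cell table written by :func:`export_cell_table`."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table missing columns: {missing}")
    return df


def read_subject_table(path) -> List[SubjectMeta]:
    """Read subject metadata (subject_id, group, braak, thal, apoe, onset) from CSV."""
    df = pd.read_csv(path, encoding="utf-8", dtype=str)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise FormatError("subject table requires 'subject_id' and 'group' columns")
    subjects = []
    for _, row in df.iterrows():
        subjects.append(
            SubjectMeta(
                subject_id=row["subject_id"],
                group=row["group"],
                braak=row.get("braak") if pd.notna(row.get("braak")) else None,
                thal=row.get("thal") if pd.notna(row.get("thal")) else None,
                apoe=row.get("apoe") if pd.notna(row.get("apoe")) else None,
                onset=row.get("onset") if pd.notna(row.get("onset")) else None,
            )
        )
    return subjects


def write_subject_table(subjects: List[SubjectMeta], path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "braak": s.braak,
                "thal": s.thal,
                "apoe": s.apoe,
                "onset": s.onset,
            }
            for s in subjects
        ]
    )
    df.to_csv(path, index=False, encoding="utf-8")
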