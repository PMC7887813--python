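"""Synthetic multi-channel images, feature tables and cohorts with ground truth.

The generator emulates the structure the pipeline assumes rather than the
optics of the microscope: ramified cells with bright somas and dimmer,
sometimes detached processes; a DAPI nucleus inside each soma; per-cluster
marker co-expression profiles on the four membrane channels; amyloid plaques
as soft blobs on the Abeta channel with configurable infiltration enrichment
of one cluster; elongated autofluorescent vessels larger than 4000 px; and
additive Gaussian noise clipped at zero. Every generator takes an explicit
seed and draws from a single RNG stream, so output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .types import (
    MEMBRANE_MARKERS,
    ComponentImage,
    GenerationError,
    LabelMask,
    MaskKind,
    SubjectMeta,
)

# ---------------------------------------------------------------------------
# Nominal per-cluster marker profiles (mean, sd of the cell's amplitude).
# Qualitative shapes only: a homeostatic P2RY12+TMEM119+ profile, an
# iron-associated FTL+Iba1+ profile, an intermediate TMEM119+FTL+ profile,
# an Iba1-only profile and a P2RY12-high profile. Absolute values are free
# parameters of the simulation, not measurements.
# ---------------------------------------------------------------------------
DEFAULT_CLUSTER_PROFILES: Dict[int, Dict[str, Tuple[float, float]]] = {
    1: {  # homeostatic: P2RY12+ TMEM119+
        "TMEM119": (140.0, 15.0), "P2RY12": (140.0, 15.0),
        "FTL": (35.0, 10.0), "Iba1": (55.0, 10.0),
    },
    2: {  # iron-associated: FTL+ Iba1+, homeostatic markers lost
        "TMEM119": (30.0, 10.0), "P2RY12": (30.0, 10.0),
        "FTL": (150.0, 15.0), "Iba1": (140.0, 15.0),
    },
    3: {  # intermediate: TMEM119+ FTL+ Iba1+
        "TMEM119": (120.0, 15.0), "P2RY12": (35.0, 10.0),
        "FTL": (120.0, 15.0), "Iba1": (100.0, 15.0),
    },
    4: {  # Iba1-only (macrophage-like)
        "TMEM119": (30.0, 10.0), "P2RY12": (30.0, 10.0),
        "FTL": (40.0, 10.0), "Iba1": (150.0, 15.0),
    },
    5: {  # P2RY12-high
        "TMEM119": (55.0, 12.0), "P2RY12": (155.0, 15.0),
        "FTL": (35.0, 10.0), "Iba1": (60.0, 12.0),
    },
}

#: Process intensity relative to the soma amplitude.
PROCESS_INTENSITY_FACTOR = 0.55
#: Default erased-gap width (px) for detached processes; < 10 so the
#: attachment stage can recover them.
DEFAULT_DETACH_GAP_PX = 4.0
#: Default per-channel additive Gaussian noise sd ("moderate" noise for
#: amplitudes in the 100-150 range above).
DEFAULT_NOISE_SD = 5.0


@dataclass
class SyntheticCellSpec:
    """Geometry and expression profile of one simulated microglia."""

    soma_radius_px: float = 5.0
    n_processes: int = 4
    process_length_px: float = 22.0
    detach_probability: float = 0.0
    detach_gap_px: float = DEFAULT_DETACH_GAP_PX
    marker_profile: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_PROFILES[1])
    )
    cluster_id: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.detach_probability <= 1.0:
            raise GenerationError("detach_probability must be in [0, 1]")
        if any(sd < 0 for _, sd in self.marker_profile.values()):
            raise GenerationError("marker profile sds must be >= 0")
        if self.soma_radius_px <= 0:
            raise GenerationError("soma_radius_px must be > 0")


@dataclass
class GroundTruth:
    """Per-image truth: instance masks, cluster identities, planted effects."""

    cell_masks: LabelMask
    nucleus_masks: LabelMask
    plaque_mask: LabelMask
    vessel_mask: LabelMask
    true_cluster: Dict[int, int] = field(default_factory=dict)
    planted_infiltration_enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.planted_infiltration_enrichment < 1.0:
            raise GenerationError("infiltration enrichment must be >= 1")
        cell_ids = set(int(i) for i in self.cell_masks.label_ids())
        unknown = set(self.true_cluster) - cell_ids
        if unknown:
            raise GenerationError(f"true_cluster refers to unknown cell ids {sorted(unknown)}")


@dataclass
class CohortSpec:
    """Study-level simulation: group sizes, composition and plaque burden."""

    n_control: int = 2
    n_ad: int = 2
    cells_per_subject: int = 20
    cluster_proportions: Dict[str, Sequence[float]] = field(
        default_factory=lambda: {
            "control": (0.55, 0.05, 0.10, 0.10, 0.20),
            "AD": (0.30, 0.30, 0.15, 0.10, 0.15),
        }
    )
    plaques_per_subject: Dict[str, int] = field(
        default_factory=lambda: {"control": 0, "AD": 3}
    )
    infiltration_enrichment: float = 3.0  # odds multiplier for the enriched cluster
    enriched_cluster: int = 2
    image_size: Tuple[int, int] = (384, 384)
    noise_sd: float = DEFAULT_NOISE_SD
    detach_probability: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_ad < 0 or self.cells_per_subject < 0:
            raise GenerationError("counts must be >= 0")
        for group, props in self.cluster_proportions.items():
            if abs(sum(props) - 1.0) > 1e-9:
                raise GenerationError(f"cluster proportions for {group!r} must sum to 1")


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------

def _disk_mask(shape, center, radius) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    out[rr, cc] = True
    return out


def _render_processes(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    center: Tuple[float, float],
    spec: SyntheticCellSpec,
) -> Tuple[np.ndarray, List[bool]]:
    """Random-walk polyline processes rooted at the soma boundary.

    Returns the combined process mask and, per process, whether it was
    detached (its root gap erased).
    """
    h, w = shape
    proc_mask = np.zeros(shape, dtype=bool)
    detach_flags: List[bool] = []
    r0 = spec.soma_radius_px
    base_angles = rng.uniform(0, 2 * np.pi) + np.arange(spec.n_processes) * (
        2 * np.pi / max(1, spec.n_processes)
    )
    for i in range(spec.n_processes):
        angle = float(base_angles[i]) + float(rng.normal(0, 0.2))
        detached = bool(rng.random() < spec.detach_probability)
        detach_flags.append(detached)
        pos = np.array(center, dtype=float) + (r0 - 0.5) * np.array(
            [np.sin(angle), np.cos(angle)]
        )
        single = np.zeros(shape, dtype=bool)
        step = 2.0
        n_steps = max(1, int(round(spec.process_length_px / step)))
        for _ in range(n_steps):
            angle += float(rng.normal(0, 0.35))
            nxt = pos + step * np.array([np.sin(angle), np.cos(angle)])
            r1, c1 = int(round(pos[0])), int(round(pos[1]))
            r2, c2 = int(round(nxt[0])), int(round(nxt[1]))
            r1 = np.clip(r1, 0, h - 1); c1 = np.clip(c1, 0, w - 1)
            r2 = np.clip(r2, 0, h - 1); c2 = np.clip(c2, 0, w - 1)
            rr, cc = draw_line(r1, c1, r2, c2)
            single[rr, cc] = True
            pos = nxt
        if rng.random() < 0.5:  # widen to ~3 px for about half the processes
            single = ndi.binary_dilation(single, ndi.generate_binary_structure(2, 2))
        if detached:
            # erase a gap at the process root: pixels within gap of the soma rim
            rows, cols = np.nonzero(single)
            dist_c = np.hypot(rows - center[0], cols - center[1])
            erase = dist_c <= (r0 + spec.detach_gap_px)
            single[rows[erase], cols[erase]] = False
        proc_mask |= single
    return proc_mask, detach_flags


def generate_image(
    image_size: Tuple[int, int] = (384, 384),
    cell_specs: Sequence[SyntheticCellSpec] = (),
    n_plaques: int = 0,
    n_vessels: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    subject_id: str = "synthetic",
    cell_centers: Optional[Sequence[Tuple[float, float]]] = None,
    plaque_centers: Optional[Sequence[Tuple[float, float]]] = None,
    infiltration_enrichment: float = 1.0,
    pixel_size_um: float = 0.5,
) -> Tuple[ComponentImage, GroundTruth]:
    """Render one multi-channel field of view with full ground truth.

    Cells are placed by rejection sampling (bounded retries) so that soma
    centres keep a minimum separation; processes may still overlap, which is
    what the watershed stage downstream has to resolve. Channels rendered:
    the four membrane markers (soma at the cell's drawn amplitude, processes
    at ``PROCESS_INTENSITY_FACTOR`` of it), DAPI (nuclei), Abeta (plaques)
    and autofluorescence (vessels). Gaussian noise of sd ``noise_sd`` is
    added per channel and clipped at 0.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    shape = (h, w)
    channels = {name: np.zeros(shape, dtype=np.float64) for name in MEMBRANE_MARKERS}
    channels["DAPI"] = np.zeros(shape, dtype=np.float64)
    channels["Abeta"] = np.zeros(shape, dtype=np.float64)
    channels["autofluorescence"] = np.zeros(shape, dtype=np.float64)

    cell_labels = np.zeros(shape, dtype=np.int64)
    nucleus_labels = np.zeros(shape, dtype=np.int64)
    plaque_labels = np.zeros(shape, dtype=np.int64)
    vessel_labels = np.zeros(shape, dtype=np.int64)
    true_cluster: Dict[int, int] = {}

    # --- plaques first (cells may be biased toward them by the cohort layer)
    placed_plaques: List[Tuple[float, float, float]] = []
    for pid in range(1, n_plaques + 1):
        radius = float(rng.uniform(9.0, 15.0))
        if plaque_centers is not None and pid - 1 < len(plaque_centers):
            cy, cx = plaque_centers[pid - 1]
        else:
            cy = float(rng.uniform(radius + 5, h - radius - 5))
            cx = float(rng.uniform(radius + 5, w - radius - 5))
        pm = _disk_mask(shape, (cy, cx), radius)
        plaque_labels[pm & (plaque_labels == 0)] = pid
        channels["Abeta"][pm] += 150.0
        placed_plaques.append((cy, cx, radius))

    # --- vessels
    for vid in range(1, n_vessels + 1):
        angle = float(rng.uniform(0, np.pi))
        cy, cx = float(rng.uniform(0.3 * h, 0.7 * h)), float(rng.uniform(0.3 * w, 0.7 * w))
        L = max(h, w)
        r1 = int(np.clip(cy - L * np.sin(angle), 0, h - 1))
        c1 = int(np.clip(cx - L * np.cos(angle), 0, w - 1))
        r2 = int(np.clip(cy + L * np.sin(angle), 0, h - 1))
        c2 = int(np.clip(cx + L * np.cos(angle), 0, w - 1))
        vm = np.zeros(shape, dtype=bool)
        rr, cc = draw_line(r1, c1, r2, c2)
        vm[rr, cc] = True
        vm = ndi.binary_dilation(vm, ndi.generate_binary_structure(2, 2), iterations=7)
        if vm.sum() <= 4000:
            raise GenerationError("vessel rendering produced <= 4000 px; enlarge the image")
        vessel_labels[vm & (vessel_labels == 0)] = vid
        channels["autofluorescence"][vm] += 170.0

    # --- cells
    margin = 10.0
    min_sep = 2.0 * max((s.soma_radius_px for s in cell_specs), default=5.0) + 18.0
    centers: List[Tuple[float, float]] = []
    for idx, spec in enumerate(cell_specs):
        cid = idx + 1
        if cell_centers is not None and idx < len(cell_centers) and cell_centers[idx] is not None:
            center = (float(cell_centers[idx][0]), float(cell_centers[idx][1]))
        else:
            center = None
            lo = spec.soma_radius_px + margin
            for _ in range(400):
                cand = (
                    float(rng.uniform(lo, h - lo)),
                    float(rng.uniform(lo, w - lo)),
                )
                if all(np.hypot(cand[0] - y, cand[1] - x) >= min_sep for y, x in centers):
                    center = cand
                    break
            if center is None:
                raise GenerationError(
                    f"could not place cell {cid} after bounded retries; "
                    "reduce cell count or enlarge the image"
                )
        centers.append(center)

        soma = _disk_mask(shape, center, spec.soma_radius_px)
        processes, _ = _render_processes(rng, shape, center, spec)
        processes &= ~soma
        # nuclei are ~5 µm across (≈ 4-5 px radius at 0.5 µm/px), slightly
        # smaller than the soma that contains them
        nucleus = _disk_mask(shape, center, max(4.0, 0.7 * spec.soma_radius_px))

        cell_mask = soma | processes
        cell_labels[cell_mask & (cell_labels == 0)] = cid
        nucleus_labels[nucleus & (nucleus_labels == 0)] = cid
        true_cluster[cid] = spec.cluster_id

        for marker in MEMBRANE_MARKERS:
            mean, sd = spec.marker_profile[marker]
            amp = max(0.0, float(rng.normal(mean, sd)))
            channels[marker][soma] += amp
            channels[marker][processes] += PROCESS_INTENSITY_FACTOR * amp
        channels["DAPI"][nucleus] += 160.0

    # --- soften edges, add noise, clip
    for name, plane in channels.items():
        plane = ndi.gaussian_filter(plane, sigma=0.7)
        if noise_sd > 0:
            plane = plane + rng.normal(0.0, noise_sd, size=shape)
        channels[name] = np.clip(plane, 0.0, None)

    image = ComponentImage(
        planes=channels, pixel_size_um=pixel_size_um, subject_id=subject_id
    )
    truth = GroundTruth(
        cell_masks=LabelMask(cell_labels, MaskKind.cell),
        nucleus_masks=LabelMask(nucleus_labels, MaskKind.nucleus),
        plaque_mask=LabelMask(plaque_labels, MaskKind.plaque),
        vessel_mask=LabelMask(vessel_labels, MaskKind.vessel),
        true_cluster=true_cluster,
        planted_infiltration_enrichment=infiltration_enrichment,
    )
    return image, truth


def default_cell_specs(
    n_cells: int,
    rng: np.random.Generator,
    proportions: Sequence[float] = (0.55, 0.05, 0.10, 0.10, 0.20),
    detach_probability: float = 0.2,
) -> List[SyntheticCellSpec]:
    """Draw cell specs with cluster identities from ``proportions``."""
    clusters = sorted(DEFAULT_CLUSTER_PROFILES)
    if len(proportions) != len(clusters):
        raise GenerationError(
            f"proportions must have {len(clusters)} entries, got {len(proportions)}"
        )
    labels = rng.choice(clusters, size=n_cells, p=np.asarray(proportions, float))
    specs = []
    for cl in labels:
        specs.append(
            SyntheticCellSpec(
                soma_radius_px=float(rng.uniform(4.5, 6.0)),
                n_processes=int(rng.integers(3, 6)),
                process_length_px=float(rng.uniform(16.0, 28.0)),
                detach_probability=detach_probability,
                marker_profile=dict(DEFAULT_CLUSTER_PROFILES[int(cl)]),
                cluster_id=int(cl),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Feature-space simulation
# ---------------------------------------------------------------------------

def generate_feature_table(
    n_cells: int,
    cluster_means: Mapping[int, Sequence[float]],
    cluster_sds: Mapping[int, Sequence[float]],
    proportions: Sequence[float],
    seed: int = 0,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Gaussian-mixture draws in the four-marker space; returns (table, labels)."""
    props = np.asarray(proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise GenerationError("proportions must sum to 1")
    clusters = sorted(cluster_means)
    if len(props) != len(clusters):
        raise GenerationError("one proportion per cluster required")
    rng = np.random.default_rng(seed)
    labels = rng.choice(clusters, size=n_cells, p=props)
    X = np.empty((n_cells, len(MEMBRANE_MARKERS)))
    import warnings

    for cl in clusters:
        mu = np.asarray(cluster_means[cl], dtype=float)
        sd = np.asarray(cluster_sds[cl], dtype=float)
        if np.all(sd == 0):
            for other in clusters:
                if other != cl and np.allclose(cluster_means[other], mu):
                    warnings.warn(
                        f"clusters {cl} and {other} have sd=0 and identical means; "
                        "they are indistinguishable",
                        stacklevel=2,
                    )
        sel = labels == cl
        X[sel] = rng.normal(mu, sd, size=(int(sel.sum()), len(mu)))
    df = pd.DataFrame(X, columns=list(MEMBRANE_MARKERS))
    return df, labels.astype(int)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> List[Tuple[ComponentImage, GroundTruth, SubjectMeta]]:
    """Simulate an imaged cohort: control and AD subjects with planted contrasts.

    AD subjects receive more plaques and a higher proportion of the
    iron-associated FTL+Iba1+ cluster; cells of the enriched cluster are
    preferentially placed adjacent to plaques with the configured odds
    multiplier, so the downstream infiltration analysis has a recoverable
    planted effect.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    subjects = [("control", i + 1) for i in range(spec.n_control)] + [
        ("AD", i + 1) for i in range(spec.n_ad)
    ]
    for group, num in subjects:
        sid = f"{'CTRL' if group == 'control' else 'AD'}{num:02d}"
        n_plaques = int(spec.plaques_per_subject.get(group, 0))
        props = spec.cluster_proportions[group]
        specs = default_cell_specs(
            spec.cells_per_subject, rng, proportions=props,
            detach_probability=spec.detach_probability,
        )
        # plaque positions drawn here so enriched-cluster cells can be pulled in
        h, w = spec.image_size
        plaque_centers = [
            (float(rng.uniform(30, h - 30)), float(rng.uniform(30, w - 30)))
            for _ in range(n_plaques)
        ]
        cell_centers: List[Optional[Tuple[float, float]]] = [None] * len(specs)
        if n_plaques and spec.infiltration_enrichment > 1.0:
            base_p = 0.15
            odds = base_p / (1 - base_p)
            for i, s in enumerate(specs):
                p = base_p
                if s.cluster_id == spec.enriched_cluster:
                    o = odds * spec.infiltration_enrichment
                    p = o / (1 + o)
                if rng.random() < p:
                    cy, cx = plaque_centers[int(rng.integers(n_plaques))]
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0, 8.0)
                    cell_centers[i] = (
                        float(np.clip(cy + rad * np.sin(ang), 15, h - 15)),
                        float(np.clip(cx + rad * np.cos(ang), 15, w - 15)),
                    )
        img_seed = int(rng.integers(0, 2**31 - 1))
        image, truth = generate_image(
            image_size=spec.image_size,
            cell_specs=specs,
            n_plaques=n_plaques,
            n_vessels=0,
            noise_sd=spec.noise_sd,
            seed=img_seed,
            subject_id=sid,
            cell_centers=[c for c in cell_centers] if any(c is not None for c in cell_centers) else None,
            plaque_centers=plaque_centers,
            infiltration_enrichment=spec.infiltration_enrichment,
        )
        meta = SubjectMeta(
            subject_id=sid,
            group=group,
            braak="V" if group == "AD" else "I",
            thal="V" if group == "AD" else "0",
        )
        out.append((image, truth, meta))
    return out


def simulate_infiltration_cohort(
    n_subjects: int = 12,
    cells_per_subject: int = 400,
    proportions: Sequence[float] = (0.55, 0.05, 0.10, 0.10, 0.20),
    enriched_cluster: int = 2,
    enrichment: float = 3.0,
    base_infiltration_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Statistical cohort simulation at the cell-table level (no rendering).

    Each cell gets a cluster label from ``proportions`` and an
    ``infiltrates_plaque`` flag drawn with probability ``base_infiltration_rate``,
    its odds multiplied by ``enrichment`` for the enriched cluster. Used to
    study power and calibration of the all-mic vs Abeta-mic comparison at
    realistic cohort sizes without image rendering.
    """
    rng = np.random.default_rng(seed)
    clusters = np.arange(1, len(proportions) + 1)
    base_odds = base_infiltration_rate / (1 - base_infiltration_rate)
    p_enriched = (base_odds * enrichment) / (1 + base_odds * enrichment)
    rows = []
    for s in range(n_subjects):
        labels = rng.choice(clusters, size=cells_per_subject, p=np.asarray(proportions, float))
        p = np.where(labels == enriched_cluster, p_enriched, base_infiltration_rate)
        infiltrates = rng.random(cells_per_subject) < p
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": f"S{s + 1:02d}",
                    "cluster": labels.astype(int),
                    "infiltrates_plaque": infiltrates,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
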