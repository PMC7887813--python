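"""Staged level-set microglia segmentation.

The pipeline identifies whole microglia in four stages, each feeding the next:

1. **Nuclei** — a two-phase level set on the DAPI plane (nu=2, mu=3),
   initialized from the Otsu mask; components smaller than 30 px are removed.
2. **Somas** — the same evolution on the pixelwise sum of the four membrane
   marker planes (nu=2, mu=3); components smaller than 50 px are removed and,
   by default, somas overlapping no nucleus are discarded.
3. **Cytoplasm** — a finer evolution (nu=2, mu=2) on the membrane sum captures
   the dimmer cell area. When the autofluorescence plane contains a vessel
   (a thresholded component larger than 4000 px) initialization switches from
   Otsu to Li thresholding, which is less sensitive to the bright vessel
   pixels. Components overlapping a soma become cells; components overlapping
   several somas are split by marker-controlled watershed; the rest are
   candidate detached processes, attached to the nearest soma when within a
   10 px Euclidean radius and discarded otherwise.
4. **Plaques** — amyloid blobs from the Abeta plane, either by thresholding +
   morphology or by a scribble-trained random-forest pixel classifier.

Evaluation against ground truth uses the Dice similarity index with greedy
one-to-one matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import filters, morphology
from skimage.segmentation import watershed

from .config import SegmentationConfig
from .types import (
    MEMBRANE_MARKERS,
    CellRecord,
    ComponentImage,
    ConfigError,
    GliaquantError,
    LabelMask,
    LevelSetParams,
    MaskKind,
)

logger = logging.getLogger(__name__)

_STRUCTS = {4: ndi.generate_binary_structure(2, 1), 8: ndi.generate_binary_structure(2, 2)}


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(plane: np.ndarray) -> Tuple[float, np.ndarray]:
    """Otsu threshold (maximal between-class variance); mask = plane > t.

    Integer input is thresholded on its native 8/16-bit bins; float input is
    histogrammed into 256 bins over its range.
    """
    plane = np.asarray(plane)
    if np.ptp(plane) == 0:
        raise GliaquantError("cannot threshold a constant image")
    t = float(filters.threshold_otsu(plane))
    return t, plane > t


def li_threshold(plane: np.ndarray) -> Tuple[float, np.ndarray]:
    """Li minimum-cross-entropy threshold; mask = plane > t.

    Chosen over Otsu for level-set initialization when a bright vessel is in
    the field, because the iterative cross-entropy criterion is less pulled
    up by a small number of very bright pixels.
    """
    plane = np.asarray(plane)
    if np.ptp(plane) == 0:
        raise GliaquantError("cannot threshold a constant image")
    # tight tolerance: run the fixed-point iteration to convergence rather
    # than stopping at the first intensity-resolution step
    t = float(filters.threshold_li(plane, tolerance=1e-8))
    return t, plane > t


# ---------------------------------------------------------------------------
# Level-set evolution
# ---------------------------------------------------------------------------

def evolve_level_set(
    plane: np.ndarray, init_mask: np.ndarray, params: LevelSetParams
) -> np.ndarray:
    """Two-phase piecewise-constant (Chan–Vese-type) region evolution.

    Minimizes ``∫_in (I-c1)² + ∫_out (I-c2)² + nu·Perimeter + mu·Area`` by
    threshold dynamics: each sweep recomputes the region means c1/c2 and flips
    every pixel to the phase of lower energy, where the perimeter term enters
    through a Gaussian-smoothed indicator (a mean-curvature proxy) and the
    area term as a constant penalty ``mu`` on foreground membership. Larger
    ``nu``/``mu`` produce smoother and more conservative masks. Stops when the
    relative symmetric difference between sweeps falls below ``params.tol``.
    """
    I = np.asarray(plane, dtype=np.float64)
    mask = np.asarray(init_mask, dtype=bool).copy()
    if not mask.any():
        raise GliaquantError("evolve_level_set requires a non-empty init mask")
    if mask.all():
        raise GliaquantError("init mask covers the whole image; no background phase")
    for _ in range(params.max_iter):
        c1 = I[mask].mean()
        c2 = I[~mask].mean()
        # >0 favours foreground membership of the pixel
        data = (I - c2) ** 2 - (I - c1) ** 2
        u = ndi.gaussian_filter(mask.astype(np.float64), sigma=1.0)
        curvature = 2.0 * u - 1.0  # in [-1, 1]; negative outside / at convexities
        score = data + params.nu * curvature - params.mu
        new_mask = score > 0
        if not new_mask.any():
            # area/perimeter penalties annihilated the foreground
            logger.warning("level set collapsed to empty foreground")
            return new_mask
        denom = max(1, int(mask.sum()))
        change = np.count_nonzero(new_mask ^ mask) / denom
        mask = new_mask
        if change < params.tol:
            return mask
    logger.warning("level set did not converge within %d iterations", params.max_iter)
    return mask


def _label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    labels, _ = ndi.label(mask, structure=_STRUCTS[connectivity])
    return labels


def _remove_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Drop components with area < min_area; relabel 1..n."""
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    lut = np.zeros(len(counts), dtype=np.int64)
    lut[keep] = np.arange(1, int(keep.sum()) + 1)
    return lut[labels]


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def segment_nuclei(image: ComponentImage, config: SegmentationConfig) -> LabelMask:
    """Level-set nucleus segmentation on the DAPI plane (nu=2, mu=3, >=30 px)."""
    dapi = image.plane("DAPI")
    try:
        _, init = otsu_threshold(dapi)
        mask = evolve_level_set(dapi, init, config.nucleus_params)
    except GliaquantError as exc:
        logger.warning("nucleus segmentation degenerate (%s); returning empty mask", exc)
        return LabelMask(np.zeros(image.shape, dtype=np.int64), MaskKind.nucleus)
    labels = _remove_small(_label(mask, config.connectivity), config.min_nucleus_area_px)
    return LabelMask(labels, MaskKind.nucleus)


def membrane_sum(image: ComponentImage) -> np.ndarray:
    """Pixelwise sum of the four membrane marker planes."""
    image.require_membrane_markers()
    out = np.zeros(image.shape, dtype=np.float64)
    for m in MEMBRANE_MARKERS:
        out += image.plane(m)
    return out


def segment_somas(
    image: ComponentImage,
    config: SegmentationConfig,
    nucleus_mask: Optional[LabelMask] = None,
) -> LabelMask:
    """Level-set soma segmentation on the membrane sum (nu=2, mu=3, >=50 px).

    When ``nucleus_mask`` is given and ``config.require_nucleus_overlap`` is
    set, somas with zero nucleus-pixel overlap are discarded (a soma should
    contain its cell's nucleus).
    """
    summed = membrane_sum(image)
    try:
        _, init = otsu_threshold(summed)
        mask = evolve_level_set(summed, init, config.soma_params)
    except GliaquantError as exc:
        logger.warning("soma segmentation degenerate (%s); returning empty mask", exc)
        return LabelMask(np.zeros(image.shape, dtype=np.int64), MaskKind.soma)
    labels = _remove_small(_label(mask, config.connectivity), config.min_soma_area_px)
    if nucleus_mask is not None and config.require_nucleus_overlap and labels.max() > 0:
        has_nucleus = np.unique(labels[(nucleus_mask.labels > 0) & (labels > 0)])
        keep = np.zeros(labels.max() + 1, dtype=bool)
        keep[has_nucleus] = True
        lut = np.zeros(labels.max() + 1, dtype=np.int64)
        lut[keep] = np.arange(1, int(keep.sum()) + 1)
        labels = lut[labels]
    return LabelMask(labels, MaskKind.soma)


def detect_vessels(image: ComponentImage, config: SegmentationConfig) -> LabelMask:
    """Vessels: Otsu on the autofluorescence plane, components > 4000 px (strict)."""
    if not image.has("autofluorescence"):
        logger.info("no autofluorescence channel; vessel mask empty")
        return LabelMask(np.zeros(image.shape, dtype=np.int64), MaskKind.vessel)
    try:
        _, mask = otsu_threshold(image.plane("autofluorescence"))
    except GliaquantError:
        return LabelMask(np.zeros(image.shape, dtype=np.int64), MaskKind.vessel)
    labels = _remove_small(_label(mask, config.connectivity), config.vessel_min_area_px + 1)
    return LabelMask(labels, MaskKind.vessel)


def segment_cytoplasm(
    image: ComponentImage,
    soma_mask: LabelMask,
    vessel_mask: LabelMask,
    config: SegmentationConfig,
) -> LabelMask:
    """Finer level-set pass (nu=2, mu=2) on the membrane sum.

    Initialization is the Otsu mask, or the Li mask when a vessel was
    detected; vessel pixels are excluded from the result. Components are
    labelled without soma assignment (that happens in
    :func:`assign_components`).
    """
    summed = membrane_sum(image)
    use_li = vessel_mask.n_labels > 0
    try:
        if use_li:
            logger.info("vessel present: initializing cytoplasm level set from Li threshold")
            _, init = li_threshold(summed)
        else:
            _, init = otsu_threshold(summed)
        init &= ~vessel_mask.binary()
        mask = evolve_level_set(summed, init, config.cytoplasm_params)
    except GliaquantError as exc:
        logger.warning("cytoplasm segmentation degenerate (%s); returning empty mask", exc)
        return LabelMask(np.zeros(image.shape, dtype=np.int64), MaskKind.component)
    mask &= ~vessel_mask.binary()
    return LabelMask(_label(mask, config.connectivity), MaskKind.component)


@dataclass
class ComponentAssignment:
    """Result of overlaying cytoplasm components on the soma mask."""

    cells: Dict[int, np.ndarray]  # soma_id → boolean pixel mask (body: soma ∪ cytoplasm)
    orphans: List[np.ndarray]  # candidate detached processes (boolean masks)
    shared: List[np.ndarray]  # components overlapping >= 2 somas, not yet assigned


def assign_components(components: LabelMask, soma_mask: LabelMask) -> ComponentAssignment:
    """Assign cytoplasm components to somas by pixel overlap.

    A component overlapping exactly one soma joins that soma's cell; a
    component overlapping none is an orphan (candidate detached process); a
    component overlapping two or more somas is deferred to
    :func:`split_shared_cytoplasm`.
    """
    if components.shape != soma_mask.shape:
        raise GliaquantError("component and soma masks must share one shape")
    cells: Dict[int, np.ndarray] = {
        int(sid): soma_mask.labels == sid for sid in soma_mask.label_ids()
    }
    orphans: List[np.ndarray] = []
    shared: List[np.ndarray] = []
    for cid in components.label_ids():
        comp = components.labels == cid
        soma_ids = np.unique(soma_mask.labels[comp])
        soma_ids = soma_ids[soma_ids > 0]
        if len(soma_ids) == 0:
            orphans.append(comp)
        elif len(soma_ids) == 1:
            sid = int(soma_ids[0])
            cells[sid] = cells[sid] | comp
        else:
            shared.append(comp)
    return ComponentAssignment(cells=cells, orphans=orphans, shared=shared)


def split_shared_cytoplasm(
    shared_component: np.ndarray, soma_mask: LabelMask
) -> Dict[int, np.ndarray]:
    """Partition a component shared by >= 2 somas with marker-controlled watershed.

    The somas overlapping the component seed the watershed; flooding runs on
    the distance-to-nearest-soma landscape, so each pixel ends up with the
    geodesically closest soma. The partition covers the component exactly and
    each part contains its soma's overlap pixels.
    """
    comp = np.asarray(shared_component, dtype=bool)
    markers = np.where(comp, soma_mask.labels, 0)
    soma_ids = np.unique(markers)
    soma_ids = soma_ids[soma_ids > 0]
    if len(soma_ids) < 2:
        raise GliaquantError(
            f"split_shared_cytoplasm requires >= 2 overlapping somas, found {len(soma_ids)}"
        )
    elevation = ndi.distance_transform_edt(markers == 0)
    ws = watershed(elevation, markers=markers, mask=comp)
    # watershed may leave mask pixels unlabelled only if disconnected from all
    # markers; hand those to the nearest soma via another distance transform
    unassigned = comp & (ws == 0)
    if unassigned.any():
        _, (ir, ic) = ndi.distance_transform_edt(ws == 0, return_indices=True)
        ws[unassigned] = ws[ir[unassigned], ic[unassigned]]
    return {int(sid): (ws == sid) for sid in soma_ids}


def attach_processes(
    cells: Dict[int, np.ndarray],
    orphans: Sequence[np.ndarray],
    soma_mask: LabelMask,
    radius_px: float = 10.0,
) -> Tuple[Dict[int, np.ndarray], Dict[int, np.ndarray]]:
    """Attach orphan components within ``radius_px`` of a soma; discard the rest.

    Distance is the minimum Euclidean distance between pixel centres of the
    orphan and any soma pixel ("within a 10 px radius" read as <= radius,
    measured from the soma boundary). The nearest soma wins; exact ties
    (squared pixel distances are integers) go to the lower soma id, logged.

    Returns ``(cells, processes)`` where ``processes[soma_id]`` is the boolean
    mask of attached detached-process pixels (disjoint from the cell body).
    """
    shape = soma_mask.shape
    processes: Dict[int, np.ndarray] = {sid: np.zeros(shape, dtype=bool) for sid in cells}
    soma_pts = np.argwhere(soma_mask.labels > 0)
    if len(soma_pts) == 0 or not orphans:
        return cells, processes
    soma_labels_flat = soma_mask.labels[soma_pts[:, 0], soma_pts[:, 1]]
    tree = cKDTree(soma_pts)
    for orphan in orphans:
        pts = np.argwhere(orphan)
        dists, idx = tree.query(pts)
        best = np.argmin(dists)
        d = float(dists[best])
        if d > radius_px:
            logger.info("orphan component at distance %.2f px discarded", d)
            continue
        # exact tie handling: all soma pixels at the minimal distance
        d2min = round(d * d)
        candidates = set()
        for p, dd in zip(pts, dists):
            if round(dd * dd) == d2min:
                for j in tree.query_ball_point(p, d + 1e-9):
                    pr, pc = soma_pts[j]
                    if (pr - p[0]) ** 2 + (pc - p[1]) ** 2 == d2min:
                        candidates.add(int(soma_labels_flat[j]))
        target = min(candidates) if candidates else int(soma_labels_flat[idx[best]])
        if len(candidates) > 1:
            logger.info(
                "orphan equidistant (%.2f px) from somas %s; assigned to %d",
                d, sorted(candidates), target,
            )
        processes[target] |= orphan & ~cells[target]
    return cells, processes


# ---------------------------------------------------------------------------
# Plaques
# ---------------------------------------------------------------------------

class PlaqueClassifier:
    """Semi-supervised pixel classifier for amyloid plaques.

    A random forest over a small Gaussian/gradient feature bank, trained from
    sparse scribble annotations (foreground/background masks) on one or more
    images — a lightweight stand-in for interactive pixel-classification
    tools, with an explicit seed for reproducibility.
    """

    SIGMAS = (1.0, 2.0, 4.0)

    def __init__(self, seed: int = 0, n_estimators: int = 50):
        from sklearn.ensemble import RandomForestClassifier

        self._rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        self._fitted = False

    @classmethod
    def features(cls, plane: np.ndarray) -> np.ndarray:
        plane = np.asarray(plane, dtype=np.float64)
        feats = [plane]
        for s in cls.SIGMAS:
            g = ndi.gaussian_filter(plane, s)
            feats.append(g)
            feats.append(ndi.gaussian_gradient_magnitude(plane, s))
            feats.append(ndi.gaussian_laplace(plane, s))
        return np.stack(feats, axis=-1)

    def fit(self, planes: Sequence[np.ndarray], fg_masks: Sequence[np.ndarray],
            bg_masks: Sequence[np.ndarray]) -> "PlaqueClassifier":
        X, y = [], []
        for plane, fg, bg in zip(planes, fg_masks, bg_masks):
            F = self.features(plane)
            X.append(F[np.asarray(fg, bool)])
            y.append(np.ones(int(np.count_nonzero(fg))))
            X.append(F[np.asarray(bg, bool)])
            y.append(np.zeros(int(np.count_nonzero(bg))))
        self._rf.fit(np.concatenate(X), np.concatenate(y))
        self._fitted = True
        return self

    def predict_proba(self, plane: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise GliaquantError("PlaqueClassifier used before fit")
        F = self.features(plane)
        p = self._rf.predict_proba(F.reshape(-1, F.shape[-1]))[:, 1]
        return p.reshape(plane.shape)


def identify_plaques(
    image: ComponentImage,
    config: SegmentationConfig,
    classifier: Optional[PlaqueClassifier] = None,
) -> LabelMask:
    """Label amyloid plaques on the Abeta plane.

    ``threshold`` mode: Otsu threshold, binary closing, minimum-area filter.
    ``classifier`` mode: pixel-probability map from a trained
    :class:`PlaqueClassifier`, thresholded at 0.5, then the same minimum-area
    filter.
    """
    abeta = image.plane("Abeta")
    mode = config.plaque_mode
    if mode == "classifier":
        if classifier is None:
            raise ConfigError("plaque_mode='classifier' requires a trained PlaqueClassifier")
        mask = classifier.predict_proba(abeta) > 0.5
    else:
        if np.ptp(abeta) == 0:
            return LabelMask(np.zeros(image.shape, dtype=np.int64), MaskKind.plaque)
        _, mask = otsu_threshold(abeta)
        mask = morphology.closing(mask, morphology.disk(2))
    labels = _remove_small(_label(mask, config.connectivity), config.min_plaque_area_px)
    return LabelMask(labels, MaskKind.plaque)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _pixels(mask: np.ndarray) -> frozenset:
    return frozenset(map(tuple, np.argwhere(mask)))


def segment_image(
    image: ComponentImage,
    config: Optional[SegmentationConfig] = None,
    plaque_classifier: Optional[PlaqueClassifier] = None,
) -> Tuple[List[CellRecord], LabelMask, LabelMask]:
    """Run the full staged segmentation on one field of view.

    Returns ``(cells, plaque_mask, vessel_mask)``. Cell ids follow soma ids;
    per-marker mean intensities are computed over the union of soma,
    cytoplasm and attached-process pixels. The pipeline is deterministic:
    identical input and configuration yield identical records.
    """
    config = config or SegmentationConfig()
    image.require_membrane_markers()
    nuclei = segment_nuclei(image, config)
    somas = segment_somas(image, config, nucleus_mask=nuclei)
    vessels = detect_vessels(image, config)
    components = segment_cytoplasm(image, somas, vessels, config)
    assignment = assign_components(components, somas)
    cells = assignment.cells
    for comp in assignment.shared:
        for sid, part in split_shared_cytoplasm(comp, somas).items():
            cells[sid] = cells[sid] | part
    cells, processes = attach_processes(
        cells, assignment.orphans, somas, radius_px=config.process_attach_radius_px
    )
    if image.has("Abeta"):
        plaques = identify_plaques(image, config, classifier=plaque_classifier)
    else:
        plaques = LabelMask(np.zeros(image.shape, dtype=np.int64), MaskKind.plaque)

    records: List[CellRecord] = []
    soma_labels = somas.labels
    for sid in sorted(cells):
        body = cells[sid]
        soma_px = soma_labels == sid
        cyto_px = body & ~soma_px
        proc_px = processes.get(sid, np.zeros(image.shape, bool)) & ~body
        full = body | proc_px
        means = {m: float(image.plane(m)[full].mean()) for m in MEMBRANE_MARKERS}
        nuc_ids = np.unique(nuclei.labels[soma_px])
        nuc_ids = nuc_ids[nuc_ids > 0]
        nucleus_id = int(nuc_ids[0]) if len(nuc_ids) else None
        rows, cols = np.nonzero(full)
        centroid = (float(rows.mean()), float(cols.mean()))
        region = image.region_at(int(round(centroid[0])), int(round(centroid[1])))
        records.append(
            CellRecord(
                cell_id=int(sid),
                soma_pixels=_pixels(soma_px),
                cytoplasm_pixels=_pixels(cyto_px),
                process_pixels=_pixels(proc_px),
                mean_intensity=means,
                subject_id=image.subject_id,
                nucleus_id=nucleus_id,
                region=region,
                centroid=centroid,
            )
        )
    return records, plaques, vessels


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def dice_index(mask_a, mask_b) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); raises when both masks are empty."""
    if isinstance(mask_a, np.ndarray) and isinstance(mask_b, np.ndarray):
        a, b = mask_a.astype(bool), mask_b.astype(bool)
        na, nb = int(a.sum()), int(b.sum())
        inter = int((a & b).sum())
    else:
        a, b = set(mask_a), set(mask_b)
        na, nb = len(a), len(b)
        inter = len(a & b)
    if na + nb == 0:
        raise GliaquantError("Dice undefined: both masks are empty")
    return 2.0 * inter / (na + nb)


@dataclass
class MatchResult:
    """Instance-level evaluation of predicted cells against ground truth."""

    n_truth: int
    n_correct: int
    n_false_positive: int
    n_false_negative: int
    per_cell_dice: List[float] = field(default_factory=list)

    @property
    def median_dice(self) -> float:
        return float(np.median(self.per_cell_dice)) if self.per_cell_dice else float("nan")

    @property
    def detection_rate(self) -> float:
        return self.n_correct / self.n_truth if self.n_truth else float("nan")


def match_cells(
    predicted: Sequence[CellRecord],
    truth: LabelMask,
    match_dice_min: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of predicted cells to truth instances.

    Candidate pairs are ranked by descending Dice (ties by lower truth id,
    then lower prediction index); pairs with Dice >= ``match_dice_min`` are
    correct. Unmatched predictions are false positives, unmatched truth
    instances false negatives.
    """
    if not 0 < match_dice_min <= 1:
        raise GliaquantError("match_dice_min must be in (0, 1]")
    truth_ids = [int(t) for t in truth.label_ids()]
    truth_masks = {t: truth.labels == t for t in truth_ids}
    pred_masks = [p.mask(truth.shape) for p in predicted]
    pairs = []
    for pi, pm in enumerate(pred_masks):
        if not pm.any():
            continue
        overlapping = np.unique(truth.labels[pm])
        for t in overlapping[overlapping > 0]:
            d = dice_index(pm, truth_masks[int(t)])
            if d >= match_dice_min:
                pairs.append((-d, int(t), pi))
    pairs.sort()
    used_t, used_p = set(), set()
    dices = []
    for negd, t, pi in pairs:
        if t in used_t or pi in used_p:
            continue
        used_t.add(t)
        used_p.add(pi)
        dices.append(-negd)
    n_correct = len(dices)
    return MatchResult(
        n_truth=len(truth_ids),
        n_correct=n_correct,
        n_false_positive=len(predicted) - n_correct,
        n_false_negative=len(truth_ids) - n_correct,
        per_cell_dice=dices,
    )
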