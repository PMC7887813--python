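"""Plaque-infiltration spatial analysis and cohort statistics.

A cell *infiltrates* a plaque when its pixel set intersects the (optionally
dilated) plaque mask — the most conservative reading of plaque proximity,
with the dilation radius as the proximity knob. Each cell is assigned to at
most one plaque (largest overlap, ties to the lower plaque id). The all-mic
vs Abeta-mic comparison contrasts the full phenotyped population with the
infiltrating subset, per subject. Group statistics follow the published
rule: Shapiro–Wilk normality per group at alpha = 0.05, then an unpaired
two-tailed Student's t-test (normal) or Mann–Whitney U (non-normal); paired
normal data use the paired t-test (Wilcoxon signed-rank otherwise); optional
Bonferroni correction multiplies p by the family size, capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .types import CellRecord, GliaquantError, LabelMask

logger = logging.getLogger(__name__)


@dataclass
class InfiltrationTable:
    """Per-plaque and per-cell infiltration assignments."""

    per_plaque: pd.DataFrame  # plaque_id, area_px, n_infiltrating, infiltrated
    per_cell: pd.DataFrame  # cell_id, infiltrates_plaque, plaque_id

    @property
    def fraction_plaques_infiltrated(self) -> float:
        if len(self.per_plaque) == 0:
            return 0.0
        return float(self.per_plaque["infiltrated"].mean())


def infiltration(
    cells: Sequence[CellRecord],
    plaque_mask: LabelMask,
    dilation_px: int = 0,
) -> InfiltrationTable:
    """Assess every cell for overlap with the (dilated) plaque mask.

    Updates each cell's ``infiltrates_plaque``/``plaque_id`` fields in place
    and returns the table. A plaque is *infiltrated* when at least one cell
    overlaps it.
    """
    labels = plaque_mask.labels
    if dilation_px > 0:
        # dilate each plaque's footprint while keeping labels: nearest-label
        # expansion limited to dilation_px
        dist, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
        expanded = labels.copy()
        grow = (labels == 0) & (dist <= dilation_px)
        expanded[grow] = labels[ir[grow], ic[grow]]
        labels = expanded
    plaque_ids = [int(p) for p in plaque_mask.label_ids()]
    areas = {p: int((plaque_mask.labels == p).sum()) for p in plaque_ids}
    n_infiltrating = {p: 0 for p in plaque_ids}
    cell_rows = []
    for cell in cells:
        overlaps: Dict[int, int] = {}
        for r, c in cell.all_pixels():
            p = int(labels[r, c])
            if p > 0:
                overlaps[p] = overlaps.get(p, 0) + 1
        if overlaps:
            # largest overlap wins, ties to lower plaque id
            best = min(overlaps, key=lambda p: (-overlaps[p], p))
            cell.infiltrates_plaque = True
            cell.plaque_id = best
            n_infiltrating[best] = n_infiltrating.get(best, 0) + 1
        else:
            cell.infiltrates_plaque = False
            cell.plaque_id = None
        cell_rows.append(
            {
                "cell_id": cell.cell_id,
                "subject_id": cell.subject_id,
                "infiltrates_plaque": cell.infiltrates_plaque,
                "plaque_id": cell.plaque_id,
            }
        )
    plaque_rows = [
        {
            "plaque_id": p,
            "area_px": areas[p],
            "n_infiltrating": n_infiltrating[p],
            "infiltrated": n_infiltrating[p] >= 1,
        }
        for p in plaque_ids
    ]
    return InfiltrationTable(
        per_plaque=pd.DataFrame(
            plaque_rows, columns=["plaque_id", "area_px", "n_infiltrating", "infiltrated"]
        ),
        per_cell=pd.DataFrame(
            cell_rows, columns=["cell_id", "subject_id", "infiltrates_plaque", "plaque_id"]
        ),
    )


@dataclass
class AbMicComposition:
    """All-mic vs Abeta-mic cluster compositions."""

    per_subject: pd.DataFrame  # subject_id, cluster, all_mic, abeta_mic
    pooled: pd.DataFrame  # cluster, all_mic, abeta_mic, fraction_infiltrating
    excluded_subjects: Tuple[str, ...] = ()


def abmic_composition(table: pd.DataFrame) -> AbMicComposition:
    """Compare the full population with the plaque-infiltrating subset.

    ``table`` needs columns ``subject_id``, ``cluster`` and
    ``infiltrates_plaque``. Per subject and pooled, returns the cluster
    proportions of all cells (all-mic) and of infiltrating cells (Abeta-mic),
    plus the per-cluster fraction of cells that infiltrate. Subjects with no
    infiltrating cells have an undefined Abeta-mic composition and are
    excluded (logged).
    """
    required = {"subject_id", "cluster", "infiltrates_plaque"}
    missing = required - set(table.columns)
    if missing:
        raise GliaquantError(f"table missing columns {sorted(missing)}")
    clusters = sorted(int(c) for c in table["cluster"].unique())
    rows = []
    excluded = []
    for subj, sub in table.groupby("subject_id"):
        inf = sub[sub["infiltrates_plaque"]]
        if len(inf) == 0:
            excluded.append(str(subj))
            logger.info("subject %s has no infiltrating cells; Abeta-mic undefined", subj)
            continue
        for cl in clusters:
            rows.append(
                {
                    "subject_id": subj,
                    "cluster": cl,
                    "all_mic": float((sub["cluster"] == cl).mean()),
                    "abeta_mic": float((inf["cluster"] == cl).mean()),
                }
            )
    per_subject = pd.DataFrame(rows, columns=["subject_id", "cluster", "all_mic", "abeta_mic"])
    inf_all = table[table["infiltrates_plaque"]]
    pooled_rows = []
    for cl in clusters:
        in_cluster = table["cluster"] == cl
        pooled_rows.append(
            {
                "cluster": cl,
                "all_mic": float(in_cluster.mean()),
                "abeta_mic": float((inf_all["cluster"] == cl).mean()) if len(inf_all) else np.nan,
                "fraction_infiltrating": float(table.loc[in_cluster, "infiltrates_plaque"].mean())
                if in_cluster.any()
                else np.nan,
            }
        )
    pooled = pd.DataFrame(
        pooled_rows, columns=["cluster", "all_mic", "abeta_mic", "fraction_infiltrating"]
    )
    return AbMicComposition(
        per_subject=per_subject, pooled=pooled, excluded_subjects=tuple(excluded)
    )


@dataclass
class GroupComparison:
    """Result of a two-group (or paired) comparison with test selection."""

    statistic_name: str
    statistic: float
    p_value: float
    n_per_group: Tuple[int, ...]
    test_used: str
    adjustment: str = "none"

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise GliaquantError(f"p-value out of range: {self.p_value}")


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    # Shapiro-Wilk is undefined for constant samples; treat those as
    # non-normal so the rank test handles them
    if np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    bonferroni_m: int = 1,
    force_test: Optional[str] = None,
) -> GroupComparison:
    """Two-sided two-group comparison with normality-based test selection.

    Unpaired: Student's t when both groups pass Shapiro–Wilk (alpha = 0.05),
    Mann–Whitney U otherwise. Paired: paired t on normal differences,
    Wilcoxon signed-rank otherwise. ``force_test`` overrides selection
    ('t', 'mannwhitney', 'paired_t', 'wilcoxon'). Bonferroni multiplies p by
    ``bonferroni_m`` and caps at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise GliaquantError("paired comparison requires equal-length samples")
        if len(a) < 2:
            raise GliaquantError("paired comparison requires >= 2 pairs")
    else:
        if len(a) < 2 or len(b) < 2:
            raise GliaquantError("each group requires >= 2 values")
    if bonferroni_m < 1:
        raise GliaquantError("bonferroni_m must be >= 1")

    if force_test is not None:
        test = force_test
    elif paired:
        test = "paired_t" if _is_normal(a - b) else "wilcoxon"
    else:
        test = "t" if (_is_normal(a) and _is_normal(b)) else "mannwhitney"

    if test == "t":
        res = stats.ttest_ind(a, b)
        name = "t"
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "U"
    elif test == "paired_t":
        res = stats.ttest_rel(a, b)
        name = "t"
    elif test == "wilcoxon":
        res = stats.wilcoxon(a, b)
        name = "W"
    else:
        raise GliaquantError(f"unknown test {test!r}")
    p = float(res.pvalue)
    adjustment = "none"
    if bonferroni_m > 1:
        p = min(1.0, p * bonferroni_m)
        adjustment = f"bonferroni(m={bonferroni_m})"
    return GroupComparison(
        statistic_name=name,
        statistic=float(res.statistic),
        p_value=p,
        n_per_group=(len(a), len(b)),
        test_used=test,
        adjustment=adjustment,
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation with the two-sided t-distribution p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise GliaquantError("correlate requires two equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise GliaquantError("correlate requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise GliaquantError("correlate undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def export_overlay(
    image,
    cells: Sequence[CellRecord],
    infiltration_table: InfiltrationTable,
    plaque_mask: LabelMask,
    path,
    cluster_colors: Optional[Mapping[int, str]] = None,
) -> None:
    """Static overlay: cluster-coloured cell dots, pie glyphs on infiltrated plaques.

    A pure function of its inputs: rendering twice to two paths produces
    byte-identical files.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = sorted({c.cluster for c in cells if c.cluster is not None})
    cmap = plt.get_cmap("tab10")
    colors = cluster_colors or {cl: cmap((i % 10)) for i, cl in enumerate(clusters)}

    fig, ax = plt.subplots(figsize=(7, 7), dpi=100)
    bg = image.plane("Abeta") if image.has("Abeta") else next(iter(image.planes.values()))
    ax.imshow(bg, cmap="gray", interpolation="nearest")
    for cl in clusters:
        xs = [c.centroid[1] for c in cells if c.cluster == cl]
        ys = [c.centroid[0] for c in cells if c.cluster == cl]
        ax.scatter(xs, ys, s=12, color=colors[cl], label=f"cluster {cl}", linewidths=0)
    # pie glyphs on infiltrated plaques
    per_plaque = infiltration_table.per_plaque
    for _, row in per_plaque[per_plaque["infiltrated"]].iterrows():
        pid = int(row["plaque_id"])
        members = [c for c in cells if c.plaque_id == pid and c.cluster is not None]
        if not members:
            continue
        ys, xs = np.nonzero(plaque_mask.labels == pid)
        cy, cx = float(ys.mean()), float(xs.mean())
        radius = max(6.0, np.sqrt(row["area_px"] / np.pi))
        comp: Dict[int, int] = {}
        for c in members:
            comp[c.cluster] = comp.get(c.cluster, 0) + 1
        total = sum(comp.values())
        start = 0.0
        import matplotlib.patches as mpatches

        for cl in sorted(comp):
            frac = comp[cl] / total
            wedge = mpatches.Wedge(
                (cx, cy), radius, 360 * start, 360 * (start + frac),
                facecolor=colors.get(cl, "white"), edgecolor="black", linewidth=0.5,
            )
            ax.add_patch(wedge)
            start += frac
    # scale bar: 50 um
    bar_px = 50.0 / image.pixel_size_um
    h, w = bg.shape
    ax.plot([w - bar_px - 10, w - 10], [h - 12, h - 12], color="white", linewidth=3)
    ax.text(w - 10 - bar_px / 2, h - 18, "50 µm", color="white", ha="center", fontsize=8)
    ax.legend(loc="upper right", fontsize=7)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", metadata={"Software": "gliaquant"})
    plt.close(fig)
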