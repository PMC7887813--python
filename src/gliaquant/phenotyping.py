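"""Marker-based phenotyping: z-scoring, kNN-graph community detection, summaries.

The phenotyping follows the Phenograph recipe: pooled z-score of the four
per-cell marker means, a k-nearest-neighbour graph (k = 100 to avoid
overclustering in a four-marker space) reweighted by the Jaccard overlap of
neighbour sets, Louvain modularity maximization with a fixed seed, and
config-driven cluster post-processing (exclusion of non-microglial clusters
with sub-threshold TMEM119/P2RY12/Iba1 medians; merging of near-duplicate
expression profiles). Summaries are per-cluster marker medians and
per-subject prevalences; t-SNE provides the 2D overview embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .config import PhenotypeConfig
from .types import MEMBRANE_MARKERS, CellRecord, GliaquantError, SubjectMeta

logger = logging.getLogger(__name__)

Z_COLUMNS = [f"z_{m}" for m in MEMBRANE_MARKERS]


def extract_features(cells: Sequence[CellRecord]) -> pd.DataFrame:
    """One row per cell with the four raw marker means plus context columns."""
    rows = []
    for cell in cells:
        row = {
            "cell_id": cell.cell_id,
            "subject_id": cell.subject_id,
            "region": cell.region,
            "infiltrates_plaque": cell.infiltrates_plaque,
        }
        for m in MEMBRANE_MARKERS:
            if m not in cell.mean_intensity:
                raise GliaquantError(f"cell {cell.cell_id} lacks marker {m}")
            row[m] = float(cell.mean_intensity[m])
        rows.append(row)
    columns = ["cell_id", "subject_id", "region", "infiltrates_plaque", *MEMBRANE_MARKERS]
    return pd.DataFrame(rows, columns=columns)


def zscore(table: pd.DataFrame, columns: Sequence[str] = MEMBRANE_MARKERS) -> pd.DataFrame:
    """Append z-scored marker columns (pooled over all rows, sample sd).

    Z-scoring an already-standardized column is the identity. A zero-variance
    column raises, naming the marker.
    """
    if len(table) < 2:
        raise GliaquantError("z-score requires at least 2 rows")
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise GliaquantError(f"marker {col!r} has zero variance; cannot z-score")
        out[f"z_{col}"] = (x - x.mean()) / sd
    return out


def build_knn_graph(
    table: pd.DataFrame,
    k: int = 100,
    columns: Sequence[str] = Z_COLUMNS,
) -> nx.Graph:
    """kNN graph in z-scored marker space with Jaccard edge weights.

    Each cell is linked to its ``k`` Euclidean nearest neighbours; every edge
    is then reweighted by the Jaccard overlap of the two endpoints' neighbour
    sets (the Phenograph refinement) and zero-weight edges are dropped.
    Nodes are the row positions 0..n-1.
    """
    X = table[list(columns)].to_numpy(dtype=float)
    n = len(X)
    if n <= k:
        raise GliaquantError(f"need more than k={k} rows (got {n}); reduce k")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)  # first neighbour is the point itself
    neighbor_sets = [set(row[1:]) for row in idx]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in neighbor_sets[i]:
            j = int(j)
            if G.has_edge(i, j):
                continue
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            wt = inter / union if union else 0.0
            if wt > 0:
                G.add_edge(i, j, weight=wt)
    return G


def cluster_graph(graph: nx.Graph, seed: int = 0, resolution: float = 1.0) -> np.ndarray:
    """Louvain modularity communities, labelled 1..K by decreasing size."""
    if graph.number_of_nodes() == 0:
        raise GliaquantError("cannot cluster an empty graph")
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.zeros(graph.number_of_nodes(), dtype=int)
    for label, members in enumerate(comms, start=1):
        for node in members:
            labels[node] = label
    return labels


@dataclass
class ClusterRules:
    """Post-processing rules applied to raw communities.

    ``exclude_median_z_below``: clusters whose median z-scores for TMEM119,
    P2RY12 *and* Iba1 are all below this threshold are flagged non-microglial
    and removed. ``merge_median_distance``: cluster pairs whose median
    z-profiles differ (Euclidean) by less than this are merged; 0 disables.
    ``manual_merges``: explicit lists of cluster labels to merge.
    """

    exclude_median_z_below: float = -0.5
    merge_median_distance: float = 0.0
    manual_merges: List[List[int]] = field(default_factory=list)


_MICROGLIAL_MARKERS = ("TMEM119", "P2RY12", "Iba1")


def postprocess_clusters(
    table: pd.DataFrame,
    labels: np.ndarray,
    rules: Optional[ClusterRules] = None,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Exclude non-microglial clusters and merge near-duplicates.

    Returns the filtered table and compacted labels (1..K by decreasing
    size). Rules referencing unknown cluster labels raise.
    """
    rules = rules or ClusterRules()
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(table):
        raise GliaquantError("labels and table lengths differ")
    present = set(int(l) for l in np.unique(labels))
    for group in rules.manual_merges:
        unknown = set(group) - present
        if unknown:
            raise GliaquantError(f"merge rule references unknown clusters {sorted(unknown)}")

    medians = {
        cl: {m: float(np.median(table.loc[labels == cl, f"z_{m}"])) for m in MEMBRANE_MARKERS}
        for cl in present
    }
    excluded = {
        cl
        for cl in present
        if all(medians[cl][m] < rules.exclude_median_z_below for m in _MICROGLIAL_MARKERS)
    }
    if excluded:
        logger.info("excluding non-microglial clusters %s", sorted(excluded))

    # union-find over merge rules
    parent = {cl: cl for cl in present}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for group in rules.manual_merges:
        for other in group[1:]:
            union(group[0], other)
    if rules.merge_median_distance > 0:
        keep = sorted(present - excluded)
        for i, a in enumerate(keep):
            for b in keep[i + 1:]:
                va = np.array([medians[a][m] for m in MEMBRANE_MARKERS])
                vb = np.array([medians[b][m] for m in MEMBRANE_MARKERS])
                if np.linalg.norm(va - vb) < rules.merge_median_distance:
                    union(a, b)

    merged = np.array([find(int(l)) for l in labels])
    keep_mask = ~np.isin(merged, sorted(excluded))
    out_table = table.loc[keep_mask].reset_index(drop=True)
    kept = merged[keep_mask]
    # compact to 1..K by decreasing size
    ids, counts = np.unique(kept, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    lut = {int(old): new for new, old in enumerate(order, start=1)}
    return out_table, np.array([lut[int(l)] for l in kept], dtype=int)


@dataclass
class ClusterSummary:
    """Per-cluster medians, counts and per-subject/region prevalences."""

    median_z: pd.DataFrame  # clusters × markers
    counts: pd.Series  # cells per cluster
    prevalence: pd.DataFrame  # (subject, region, cluster) → fraction of subject cells
    cells_per_mm2: Optional[pd.Series] = None


def summarize_clusters(
    table: pd.DataFrame,
    labels: np.ndarray,
    subject_meta: Optional[Mapping[str, SubjectMeta]] = None,
    pixel_size_um: float = 0.5,
    area_mm2_per_subject: Optional[Mapping[str, float]] = None,
) -> ClusterSummary:
    """Cluster-level summary used for the expression heatmap and prevalences."""
    labels = np.asarray(labels, dtype=int)
    df = table.copy()
    df["cluster"] = labels
    med = df.groupby("cluster")[Z_COLUMNS].median()
    med.columns = list(MEMBRANE_MARKERS)
    counts = df.groupby("cluster").size()
    prev_rows = []
    for (subj, region), sub in df.groupby(["subject_id", "region"]):
        n_subj = len(df[df["subject_id"] == subj])
        for cl, n in sub.groupby("cluster").size().items():
            prev_rows.append(
                {"subject_id": subj, "region": region, "cluster": int(cl), "prevalence": n / n_subj}
            )
    prevalence = pd.DataFrame(prev_rows, columns=["subject_id", "region", "cluster", "prevalence"])
    cells_per_mm2 = None
    if area_mm2_per_subject:
        dens = {}
        for subj, area in area_mm2_per_subject.items():
            dens[subj] = len(df[df["subject_id"] == subj]) / area
        cells_per_mm2 = pd.Series(dens)
    return ClusterSummary(
        median_z=med, counts=counts, prevalence=prevalence, cells_per_mm2=cells_per_mm2
    )


def embed_tsne(
    table: pd.DataFrame,
    seed: int = 0,
    perplexity: float = 30.0,
    columns: Sequence[str] = Z_COLUMNS,
) -> np.ndarray:
    """t-SNE of the z-scored marker matrix; deterministic for a fixed seed."""
    from sklearn.manifold import TSNE

    X = table[list(columns)].to_numpy(dtype=float)
    if len(X) < 3 * perplexity:
        raise GliaquantError(
            f"t-SNE needs at least 3*perplexity={3 * perplexity:.0f} rows, got {len(X)}"
        )
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        method="barnes_hut",
    )
    return ts.fit_transform(X)


def phenotype(
    table: pd.DataFrame,
    config: Optional[PhenotypeConfig] = None,
    rules: Optional[ClusterRules] = None,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Full phenotyping pass: z-score → kNN graph → Louvain → post-processing."""
    config = config or PhenotypeConfig()
    table = zscore(table)
    graph = build_knn_graph(table, k=config.k_neighbors)
    labels = cluster_graph(graph, seed=config.seed, resolution=config.resolution)
    n_raw = labels.max(initial=0)
    if n_raw > config.max_clusters_warn:
        logger.warning(
            "community detection produced %d clusters (> %d); "
            "consider a larger k to avoid overclustering",
            n_raw, config.max_clusters_warn,
        )
    if rules is None:
        rules = ClusterRules(exclude_median_z_below=config.exclude_median_z_below,
                             merge_median_distance=config.merge_median_distance,
                             manual_merges=list(config.manual_merges))
    return postprocess_clusters(table, labels, rules)
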