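"""Graph-based discovery of the disease-associated B-cell cluster.

Cells pooled across a (preprocessed) cohort are clustered by Louvain
community detection on a k-nearest-neighbour graph in marker space.  The
disease-associated cluster is the one dominated by cells of the disease
group; its defining markers are ranked by Wilcoxon rank-sum tests of
in-cluster versus out-of-cluster expression.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.neighbors import kneighbors_graph

from .containers import Cohort
from .stats import wilcoxon_rank_sum

DEFAULT_K_NEIGHBORS = 20
DEFAULT_RESOLUTION = 0.8


@dataclass
class ClusterResult:
    """Cluster assignment of pooled cells plus the composition table.

    ``cells``/``meta`` keep the exact pooled matrix the graph was built on
    (cell order matches ``labels``), so downstream stages can reuse the same
    cells.  ``composition`` has one row per (cluster, group) with the cell
    count and the within-cluster group fraction.
    """

    labels: np.ndarray
    cells: np.ndarray
    meta: pd.DataFrame
    k_neighbors: int
    resolution: float
    composition: pd.DataFrame = field(default_factory=pd.DataFrame)
    embedding: np.ndarray | None = None

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.labels))

    def cluster_mask(self, cluster: int) -> np.ndarray:
        return self.labels == cluster


def _composition_table(labels: np.ndarray, groups: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame({"cluster": labels, "group": groups.to_numpy()})
    counts = (df.groupby(["cluster", "group"], observed=True)
                .size().rename("count").reset_index())
    totals = counts.groupby("cluster")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts


def cluster_cells(cohort: Cohort, k_neighbors: int = DEFAULT_K_NEIGHBORS,
                  resolution: float = DEFAULT_RESOLUTION, seed: int = 0,
                  max_cells_per_sample: int | None = None,
                  embed: bool = False) -> ClusterResult:
    """Louvain communities on the symmetrised kNN graph of pooled cells.

    Cells may be subsampled per sample (seeded) to bound graph size.  The
    optional 2-D embedding is for visual checks only; nothing downstream
    reads it.
    """
    rng = np.random.default_rng(seed)
    X, meta = cohort.pooled(max_cells_per_sample=max_cells_per_sample,
                            rng=rng)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be below the "
                         f"number of pooled cells ({n})")

    adj = kneighbors_graph(X, k_neighbors, mode="connectivity",
                           include_self=False)
    adj = adj.maximum(adj.T).tocoo()
    edges = np.column_stack([adj.row, adj.col])
    edges = edges[edges[:, 0] < edges[:, 1]]
    graph = ig.Graph(n=n, edges=edges.tolist())

    # igraph's Louvain sweep consults its global RNG; pin it for determinism
    ig.set_random_number_generator(random.Random(int(seed)))
    membership = np.asarray(
        graph.community_multilevel(resolution=resolution).membership,
        dtype=int)
    ig.set_random_number_generator(random)

    embedding = None
    if embed:
        try:
            import umap
            embedding = umap.UMAP(random_state=int(seed)).fit_transform(X)
        except ImportError:  # visualization-only extra
            embedding = None

    composition = _composition_table(membership, meta["group"])
    return ClusterResult(labels=membership, cells=X, meta=meta,
                         k_neighbors=k_neighbors, resolution=resolution,
                         composition=composition, embedding=embedding)


def identify_disease_cluster(result: ClusterResult, disease_group: str = "cGVHD",
                             min_fraction: float = 0.75) -> int:
    """Cluster with the largest disease-group fraction, required to reach
    ``min_fraction``; ties broken by the larger absolute disease cell count."""
    comp = result.composition
    if disease_group not in set(comp["group"]):
        raise ValueError(f"composition table has no group {disease_group!r}")
    sub = comp[comp["group"] == disease_group]
    best_frac = sub["fraction"].max()
    if best_frac < min_fraction:
        raise ValueError(
            "no disease-associated cluster: best "
            f"{disease_group} fraction {best_frac:.3f} < {min_fraction}")
    top = sub[np.isclose(sub["fraction"], best_frac, atol=1e-12)]
    top = top.sort_values(["count", "cluster"], ascending=[False, True])
    return int(top.iloc[0]["cluster"])


@dataclass
class MarkerRanking:
    """Per-marker rank-sum statistics for one cluster vs the rest."""

    table: pd.DataFrame          # marker, statistic, p_value, direction, ...
    selected: list[str]
    cluster: int
    alpha: float
    effect_floor: float


def rank_cluster_markers(cohort_or_result, result: ClusterResult | None = None,
                         cluster: int | None = None, alpha: float = 1e-4,
                         effect_floor: float = 1.0,
                         top_n: int = 8,
                         values: np.ndarray | None = None) -> MarkerRanking:
    """Rank markers by in-cluster vs out-of-cluster expression.

    Two-sided Wilcoxon rank-sum per marker (normal approximation with tie
    correction at these cell counts); the selected set is the markers with
    ``p < alpha`` and absolute median difference above ``effect_floor``,
    capped at the ``top_n`` largest effects.

    Accepts ``(cohort, result, cluster)`` — the cohort is only used for
    marker names — or ``(result, cluster=...)``.  ``values`` optionally
    replaces the clustered matrix with another cell-aligned matrix (for
    example the same cells on the unscaled arcsinh axis, so that effect
    sizes are in interpretable intensity units).
    """
    if isinstance(cohort_or_result, ClusterResult):
        res = cohort_or_result
        markers = None
    else:
        res = result
        markers = cohort_or_result.markers
    if res is None or cluster is None:
        raise TypeError("need a ClusterResult and a cluster id")
    if markers is None:
        markers = [f"M{j}" for j in range(res.cells.shape[1])]

    cells = res.cells if values is None else np.asarray(values, dtype=float)
    if cells.shape[0] != len(res.labels):
        raise ValueError("values must align with the clustered cells")
    mask = res.cluster_mask(int(cluster))
    n_in = int(mask.sum())
    if n_in == 0:
        raise ValueError(f"cluster {cluster} does not exist or is empty")
    if n_in < 2:
        raise ValueError(f"cluster {cluster} has fewer than 2 cells")

    rows = []
    for j, marker in enumerate(markers):
        inside = cells[mask, j]
        outside = cells[~mask, j]
        r = wilcoxon_rank_sum(inside, outside, mode="normal")
        rows.append({
            "marker": marker,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "median_difference": r.median_difference,
            "direction": "up" if r.median_difference > 0 else "down",
        })
    table = pd.DataFrame(rows)
    table["abs_effect"] = table["median_difference"].abs()
    passing = table[(table["p_value"] < alpha)
                    & (table["abs_effect"] > effect_floor)]
    selected = (passing.sort_values(["abs_effect", "marker"],
                                    ascending=[False, True])
                       .head(top_n)["marker"].tolist())
    table = table.drop(columns="abs_effect")
    return MarkerRanking(table=table, selected=selected, cluster=int(cluster),
                         alpha=alpha, effect_floor=effect_floor)
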