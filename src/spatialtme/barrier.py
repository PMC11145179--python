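"""αSMA⁺ fibroblast barrier score.

Quantifies the physical interposition of tumor-adjacent αSMA⁺ fibroblasts
between CD8 T cells and the tumor bulk:

1. tumor cells are spatially clustered (DBSCAN, eps 25 μm, ≥3 cells) and
   cluster boundaries/areas computed with a concave hull; only tumor cells
   in clusters of ≥ 2,000 μm² are "eligible" targets — a macroscopic
   barrier is ill-defined for isolated tumor cells;
2. a k-nearest-neighbor cell graph (k=5, mutualized/undirected) is built
   over all cells of a core;
3. for each non-perivascular CD8 T cell, breadth-first search gives hop
   distances to every eligible tumor cell; the shortest paths to the
   nearest tumor cell(s) are scored for the presence (indicator mode,
   default) or number (count mode) of *counted* fibroblasts — αSMA⁺,
   non-perivascular, and graph-adjacent to at least one eligible tumor
   cell;
4. the per-cell score is the mean over the tied nearest-target paths, the
   per-core score the mean over CD8 T cells.

When several equal-length shortest paths connect the same CD8/tumor pair,
one canonical BFS path is scored: each node's predecessor is its
smallest-indexed neighbor at the previous BFS level, making the choice
deterministic and order-independent given the cell-id ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint
from sklearn.cluster import DBSCAN

__all__ = [
    "TumorClusterSet",
    "cluster_tumor_cells",
    "build_knn_graph",
    "barrier_scores",
    "score_cd8_cell",
]


@dataclass
class TumorClusterSet:
    """DBSCAN clusters of tumor cells with boundary polygons and areas (μm²)."""

    labels: pd.Series                  # cell_id -> cluster label (-1 = noise)
    polygons: dict[int, object] = field(default_factory=dict)
    areas: dict[int, float] = field(default_factory=dict)

    def eligible_cells(self, min_area_um2: float = 2000.0) -> set:
        ok = {c for c, a in self.areas.items() if a >= min_area_um2}
        return set(self.labels.index[self.labels.isin(ok)])


def cluster_tumor_cells(
    cells: pd.DataFrame,
    eps: float = 25.0,
    min_cells: int = 3,
    concavity: float = 0.3,
) -> TumorClusterSet:
    """Spatially cluster tumor cells and trace their boundaries.

    DBSCAN on μm coordinates of cells with ``tumor_cell`` set (eps in μm,
    ``min_cells`` as the minimum samples). Boundaries come from shapely's
    concave hull (``concavity`` is the hull ratio; 1 = convex hull), falling
    back to the convex hull when the concave hull is degenerate. Areas are
    polygon areas in μm². Fewer than ``min_cells`` tumor cells gives an
    empty set.
    """
    tum = cells[cells["tumor_cell"].astype(bool)]
    if len(tum) < min_cells:
        return TumorClusterSet(labels=pd.Series(dtype=int, name="tumor_cluster"))
    xy = tum[["x_um", "y_um"]].to_numpy(float)
    lab = DBSCAN(eps=eps, min_samples=min_cells).fit_predict(xy)
    labels = pd.Series(lab, index=pd.Index(tum["cell_id"], name="cell_id"), name="tumor_cluster")
    polys, areas = {}, {}
    for c in sorted(set(lab) - {-1}):
        pts = MultiPoint(list(map(tuple, xy[lab == c])))
        try:
            hull = shapely.concave_hull(pts, ratio=concavity)
        except Exception:  # pragma: no cover - library edge case
            hull = pts.convex_hull
        if hull.geom_type != "Polygon" or not hull.is_valid or hull.area == 0:
            hull = pts.convex_hull
        polys[c] = hull
        areas[c] = float(hull.area) if hull.geom_type == "Polygon" else 0.0
    return TumorClusterSet(labels=labels, polygons=polys, areas=areas)


def build_knn_graph(cells: pd.DataFrame, k: int = 5) -> nx.Graph:
    """Undirected k-nearest-neighbor graph of cell locations.

    Each cell is connected to its k nearest neighbors (Euclidean, μm); the
    union of directed edges is taken, so interior nodes have degree ≥ k.
    Nodes are cell_ids. Exact coordinate duplicates tie-break by cell id
    (with a warning).
    """
    n = len(cells)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells")
    sub = cells.sort_values("cell_id")
    ids = sub["cell_id"].to_numpy()
    xy = sub[["x_um", "y_um"]].to_numpy(float)
    if len(np.unique(xy, axis=0)) < n:
        warnings.warn("duplicate coordinates; neighbor ties broken by cell id")
    tree = cKDTree(xy)
    dist, nbr = tree.query(xy, k=k + 1)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(n):
        order = np.lexsort((nbr[i], np.round(dist[i], 9)))
        chosen = [j for j in nbr[i][order] if j != i][:k]
        for j in chosen:
            g.add_edge(ids[i], ids[j])
    return g


def _bfs_levels_pred(adj: dict, order: dict, source) -> tuple[dict, dict]:
    """BFS hop distances and canonical predecessors from ``source``.

    The predecessor of a node is its neighbor at the previous level with
    the smallest id order, which makes the reconstructed shortest path
    unique and deterministic.
    """
    dist = {source: 0}
    pred: dict = {source: None}
    frontier = [source]
    while frontier:
        nxt = []
        for u in sorted(frontier, key=order.__getitem__):
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    pred[v] = u
                    nxt.append(v)
        frontier = nxt
    return dist, pred


def score_cd8_cell(
    graph: nx.Graph,
    source,
    eligible_tumor: set,
    counted_fibroblasts: set,
    mode: str = "indicator",
) -> float | None:
    """Barrier score of one CD8 T cell.

    BFS from ``source``; among eligible tumor cells take those at the
    minimal hop distance; reconstruct the canonical shortest path to each;
    score a path by the presence (indicator) or number (count) of counted
    fibroblasts among its intermediate nodes; return the mean over the tied
    paths, or None when no eligible tumor cell is reachable.
    """
    order = {u: i for i, u in enumerate(sorted(graph.nodes))}
    adj = {u: sorted(graph.neighbors(u), key=order.__getitem__) for u in graph.nodes}
    return _score_from_adj(adj, order, source, eligible_tumor, counted_fibroblasts, mode)


def _score_from_adj(adj, order, source, eligible_tumor, counted_fibroblasts, mode):
    dist, pred = _bfs_levels_pred(adj, order, source)
    reach = [t for t in eligible_tumor if t in dist and t != source]
    if not reach:
        return None
    dmin = min(dist[t] for t in reach)
    scores = []
    for t in sorted(reach, key=order.__getitem__):
        if dist[t] != dmin:
            continue
        node = t
        n_fib = 0
        while pred[node] is not None:
            node = pred[node]
            if node != source and node in counted_fibroblasts:
                n_fib += 1
        scores.append(float(n_fib > 0) if mode == "indicator" else float(n_fib))
    return float(np.mean(scores))


def barrier_scores(
    cells: pd.DataFrame,
    graph: nx.Graph | None = None,
    clusters: TumorClusterSet | None = None,
    mode: str = "indicator",
    k: int = 5,
    eps: float = 25.0,
    min_cells: int = 3,
    min_cluster_area_um2: float = 2000.0,
    cd8_label: str = "CD8 T cell",
    fibroblast_label: str = "aSMA+ fibroblast",
) -> tuple[float, pd.Series]:
    """Per-core barrier score and the per-CD8-cell scores for one core.

    ``cells`` must carry ``cell_type``, ``tumor_cell`` and ``perivascular``
    columns for a single image. The graph and tumor clusters are computed
    with the defaults when not supplied. Returns ``(mean score, per-cell
    scores indexed by cell_id)``; the mean is NaN (with a warning) when the
    core has no eligible tumor cells or no CD8 T cells.
    """
    if mode not in ("indicator", "count"):
        raise ValueError("mode must be 'indicator' or 'count'")
    if cells["image_id"].nunique() > 1:
        raise ValueError("barrier_scores operates on a single core")
    if graph is None:
        graph = build_knn_graph(cells, k=k)
    if clusters is None:
        clusters = cluster_tumor_cells(cells, eps=eps, min_cells=min_cells)
    periv = set(cells.loc[cells["perivascular"].astype(bool), "cell_id"])
    eligible = clusters.eligible_cells(min_cluster_area_um2)
    cd8 = [
        c for c in cells.loc[cells["cell_type"] == cd8_label, "cell_id"]
        if c not in periv
    ]
    if not eligible or not cd8:
        warnings.warn("no eligible tumor cells or no CD8 T cells; core score missing")
        return float("nan"), pd.Series(dtype=float, name="barrier_score")
    fibs = set(cells.loc[cells["cell_type"] == fibroblast_label, "cell_id"]) - periv
    counted = {
        f for f in fibs
        if f in graph and any(nb in eligible for nb in graph.neighbors(f))
    }
    order = {u: i for i, u in enumerate(sorted(graph.nodes))}
    adj = {u: sorted(graph.neighbors(u), key=order.__getitem__) for u in graph.nodes}
    per_cell = {}
    for c in cd8:
        if c not in graph:
            continue
        s = _score_from_adj(adj, order, c, eligible, counted, mode)
        if s is not None:
            per_cell[c] = s
    scores = pd.Series(per_cell, name="barrier_score")
    if scores.empty:
        warnings.warn("no CD8 T cell reaches an eligible tumor cell")
        return float("nan"), scores
    return float(scores.mean()), scores


def barrier_scores_by_core(cells: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply :func:`barrier_scores` per core; one row per image."""
    rows = []
    for img, sub in cells.groupby("image_id", observed=True, sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, per_cell = barrier_scores(sub, **kwargs)
        rows.append(
            {"image_id": img, "barrier_score": mean, "n_cd8": len(per_cell)}
        )
    return pd.DataFrame(rows).set_index("image_id")
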