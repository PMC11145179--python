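"""Tumor clustering, k-NN graph, and barrier-score semantics."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import spatialtme as st
from spatialtme.barrier import (
    build_knn_graph,
    cluster_tumor_cells,
    score_cd8_cell,
    barrier_scores,
)
from tests.conftest import make_positions


def _cells(xy, types, tumor=None, periv=None):
    n = len(xy)
    return pd.DataFrame({
        "cell_id": [f"c{i:03d}" for i in range(n)],
        "image_id": "img", "patient_id": "p",
        "x_um": [p[0] for p in xy], "y_um": [p[1] for p in xy],
        "cell_type": types,
        "tumor_cell": [t == "tumor" for t in types] if tumor is None else tumor,
        "perivascular": [False] * n if periv is None else periv,
    })


# ---------------------------------------------------------------- clustering

def test_three_collinear_cells_one_cluster():
    cells = _cells([(0, 0), (20, 0), (40, 0)], ["tumor"] * 3)
    cs = cluster_tumor_cells(cells, eps=25, min_cells=3)
    assert set(cs.labels) == {0}
    assert 0 in cs.areas


def test_two_distant_cells_are_noise():
    cells = _cells([(0, 0), (100, 0)], ["tumor"] * 2)
    cs = cluster_tumor_cells(cells)
    assert len(cs.labels) == 0 or (cs.labels == -1).all()


def _brute_dbscan(xy, eps, min_pts):
    """Reference DBSCAN by region growing on the eps-graph."""
    n = len(xy)
    d = np.hypot(xy[:, 0:1] - xy[:, 0].T, xy[:, 1:2] - xy[:, 1].T)
    core = (d <= eps).sum(axis=1) >= min_pts  # includes self
    labels = np.full(n, -1)
    cur = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cur
        while stack:
            u = stack.pop()
            if not core[u]:
                continue
            for v in np.where(d[u] <= eps)[0]:
                if labels[v] == -1:
                    labels[v] = cur
                    stack.append(v)
        cur += 1
    return labels


def test_dbscan_labels_match_reference():
    rng = np.random.default_rng(0)
    xy = np.vstack([rng.normal(0, 15, (25, 2)), rng.normal(200, 15, (25, 2))])
    cells = _cells(list(map(tuple, xy)), ["tumor"] * 50)
    cs = cluster_tumor_cells(cells, eps=25, min_cells=3)
    ref = _brute_dbscan(xy, 25, 3)
    got = cs.labels.to_numpy()
    from sklearn.metrics import adjusted_rand_score
    mask = (ref >= 0) | (got >= 0)
    assert (ref == -1).sum() == (got == -1).sum()
    assert adjusted_rand_score(ref[mask], got[mask]) == 1.0


# ---------------------------------------------------------------- knn graph

def test_six_cells_on_line_k5_complete():
    cells = _cells([(i * 10, 0) for i in range(6)], ["tumor"] * 6)
    g = build_knn_graph(cells, k=5)
    assert g.number_of_edges() == 15


def test_knn_matches_brute_force():
    rng = np.random.default_rng(1)
    cells = make_positions(rng, 300)
    cells["cell_type"] = "x"
    cells["tumor_cell"] = False
    cells["perivascular"] = False
    g = build_knn_graph(cells, k=5)
    xy = cells[["x_um", "y_um"]].to_numpy()
    ids = cells.cell_id.to_numpy()
    expected = set()
    for i in range(300):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        order = np.argsort(d, kind="stable")
        for j in order[1:6]:
            expected.add(frozenset((ids[i], ids[j])))
    got = {frozenset(e) for e in g.edges}
    assert got == expected


def test_knn_graph_connected_on_generator_core(small_core):
    cells, _ = small_core
    g = build_knn_graph(cells, k=5)
    assert nx.is_connected(g)


def test_too_few_cells_rejected():
    cells = _cells([(0, 0), (1, 1)], ["tumor"] * 2)
    with pytest.raises(ValueError):
        build_knn_graph(cells, k=5)


# ---------------------------------------------------------------- barrier

def _toy_three_paths(n_blocked=2, hops=6):
    """One CD8 cell with three disjoint paths of equal length to tumor cells;
    the penultimate node of the first ``n_blocked`` paths is a counted
    fibroblast (tumor-adjacent by construction)."""
    g = nx.Graph()
    tumors, fibs = set(), set()
    for p in range(3):
        nodes = ["S"] + [f"p{p}n{i}" for i in range(hops - 1)] + [f"T{p}"]
        nx.add_path(g, nodes)
        tumors.add(f"T{p}")
        if p < n_blocked:
            fibs.add(nodes[-2])
    return g, tumors, fibs


def test_worked_example_two_of_three_paths_blocked():
    g, tumors, fibs = _toy_three_paths(2)
    assert score_cd8_cell(g, "S", tumors, fibs) == pytest.approx(2 / 3)


def test_single_path_scores_one_or_zero():
    g = nx.Graph()
    nx.add_path(g, ["S", "a", "f", "T"])
    assert score_cd8_cell(g, "S", {"T"}, {"f"}) == 1.0
    assert score_cd8_cell(g, "S", {"T"}, set()) == 0.0


def test_count_mode_counts_fibroblasts():
    g = nx.Graph()
    nx.add_path(g, ["S", "f1", "f2", "T"])
    assert score_cd8_cell(g, "S", {"T"}, {"f1", "f2"}, mode="count") == 2.0
    assert score_cd8_cell(g, "S", {"T"}, {"f1", "f2"}, mode="indicator") == 1.0


def test_bfs_distances_match_networkx_on_random_graphs():
    rng = np.random.default_rng(2)
    for _ in range(10):
        g = nx.gnp_random_graph(25, 0.12, seed=int(rng.integers(1 << 30)))
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        from spatialtme.barrier import _bfs_levels_pred

        order = {u: i for i, u in enumerate(sorted(g.nodes))}
        adj = {u: sorted(g.neighbors(u), key=order.__getitem__) for u in g.nodes}
        src = sorted(g.nodes)[0]
        dist, pred = _bfs_levels_pred(adj, order, src)
        ref = nx.single_source_shortest_path_length(g, src)
        assert dist == dict(ref)
        # canonical predecessor path is a valid shortest path
        for t in dist:
            path = [t]
            while pred[path[-1]] is not None:
                path.append(pred[path[-1]])
            assert len(path) - 1 == dist[t]
            assert all(g.has_edge(a, b) for a, b in zip(path, path[1:]))


def test_fibroblast_not_adjacent_to_tumor_not_counted():
    """A fibroblast on the path but not neighboring any eligible tumor cell scores 0."""
    xy = [(0, 0), (10, 0), (20, 0), (30, 0), (40, 0), (50, 0), (60, 0)]
    types = ["CD8 T cell", "x", "aSMA+ fibroblast", "x", "tumor", "tumor", "tumor"]
    cells = _cells(xy, types)
    g = build_knn_graph(cells, k=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean, per = barrier_scores(cells, graph=g, min_cluster_area_um2=0.0)
    # fibroblast c002 neighbors c001/c003 (k=2), not the tumor cells
    assert mean == 0.0


def test_rigid_transform_invariance(small_core):
    cells, _ = small_core
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1, p1 = barrier_scores(cells)
        rot = cells.copy()
        th = 1.1
        x, y = cells.x_um.to_numpy(), cells.y_um.to_numpy()
        rot["x_um"] = np.cos(th) * x - np.sin(th) * y + 500
        rot["y_um"] = np.sin(th) * x + np.cos(th) * y + 200
        m2, p2 = barrier_scores(rot)
    assert m1 == pytest.approx(m2)
    pd.testing.assert_series_equal(p1, p2)


def test_missing_cd8_or_tumor_gives_nan():
    cells = _cells([(i * 10.0, 0) for i in range(8)], ["x"] * 8)
    with pytest.warns(UserWarning):
        mean, per = barrier_scores(cells)
    assert np.isnan(mean) and per.empty


def test_indicator_scores_in_unit_interval(small_core):
    cells, _ = small_core
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, per = barrier_scores(cells)
    assert ((per >= 0) & (per <= 1)).all()
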