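"""Windowed composition, community clustering, elbow, concordance, enrichment."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import spatialtme as st
from tests.conftest import make_positions


def _typed(df, types):
    out = df.copy()
    out["cell_type"] = types
    return out


def test_single_type_core_gives_unit_vectors():
    rng = np.random.default_rng(0)
    cells = _typed(make_positions(rng, 50), "T")
    win = st.build_windows(cells, W=5, eligible_types=["T"])
    assert np.allclose(win.to_numpy(), 1.0)


def test_w2_window_is_center_plus_nearest_neighbor():
    cells = pd.DataFrame({
        "cell_id": ["a", "b", "c"], "image_id": "i", "patient_id": "p",
        "x_um": [0.0, 1.0, 10.0], "y_um": [0.0, 0.0, 0.0],
        "cell_type": ["T", "M", "M"],
    })
    win = st.build_windows(cells, W=2, eligible_types=["M", "T"])
    assert win.loc["a"].tolist() == [0.5, 0.5]   # a + b
    assert win.loc["c"].tolist() == [1.0, 0.0]   # c + b


def test_windows_match_brute_force_on_random_cells():
    rng = np.random.default_rng(1)
    n, W = 200, 10
    cells = _typed(make_positions(rng, n), rng.choice(["A", "B", "C"], n))
    win = st.build_windows(cells, W=W, eligible_types=["A", "B", "C"])
    xy = cells.set_index("cell_id")[["x_um", "y_um"]]
    types = cells.set_index("cell_id")["cell_type"]
    for cid in rng.choice(cells.cell_id, 20, replace=False):
        d = np.hypot(xy.x_um - xy.loc[cid, "x_um"], xy.y_um - xy.loc[cid, "y_um"])
        nearest = d.sort_values(kind="stable").index[:W]
        expect = types.loc[nearest].value_counts(normalize=True)
        for t in ["A", "B", "C"]:
            assert win.loc[cid, t] == pytest.approx(expect.get(t, 0.0))


def test_window_rows_sum_to_one(tme_cohort):
    cells, _, _ = tme_cohort
    sub = cells[cells.image_id.isin(cells.image_id.unique()[:4])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = st.build_windows(sub, W=10)
    assert np.allclose(win.sum(axis=1), 1.0)


def test_small_core_skipped_with_warning():
    rng = np.random.default_rng(2)
    big = _typed(make_positions(rng, 60), "T")
    small = _typed(make_positions(rng, 3), "T")
    small["image_id"] = "tiny"
    small["cell_id"] = ["t0", "t1", "t2"]
    cells = pd.concat([big, small], ignore_index=True)
    with pytest.warns(UserWarning, match="tiny"):
        win = st.build_windows(cells, W=10, eligible_types=["T"])
    assert set(win.attrs["image_id"]) == {"img"}


def test_fit_deterministic_and_k1():
    rng = np.random.default_rng(3)
    cells = _typed(make_positions(rng, 120), rng.choice(["A", "B"], 120))
    win = st.build_windows(cells, W=5, eligible_types=["A", "B"])
    m1 = st.fit_communities(win, k=3, seed=9)
    m2 = st.fit_communities(win, k=3, seed=9)
    assert (m1.assignments == m2.assignments).all()
    assert np.allclose(m1.centroids.sum(axis=1), 1.0)
    m0 = st.fit_communities(win, k=1, seed=0)
    assert m0.assignments.nunique() == 1
    with pytest.raises(ValueError):
        st.fit_communities(win, k=len(win) + 1)


def test_translation_and_rotation_invariance():
    rng = np.random.default_rng(4)
    n = 150
    cells = _typed(make_positions(rng, n), rng.choice(["A", "B"], n))
    win = st.build_windows(cells, W=5, eligible_types=["A", "B"])
    th = 0.7
    rot = cells.copy()
    x, y = cells.x_um.to_numpy(), cells.y_um.to_numpy()
    rot["x_um"] = np.cos(th) * x - np.sin(th) * y + 1000
    rot["y_um"] = np.sin(th) * x + np.cos(th) * y - 50
    win2 = st.build_windows(rot, W=5, eligible_types=["A", "B"])
    pd.testing.assert_frame_equal(win, win2, check_exact=False, atol=1e-12)


def test_planted_two_communities_recovered():
    prof_t = {("CD8 T cell", "stroma"): 500, ("CD4 T cell", "stroma"): 300,
              ("CD163+CD206+ macrophage", "stroma"): 30, ("neutrophil", "stroma"): 20}
    prof_m = {("CD8 T cell", "stroma"): 40, ("CD4 T cell", "stroma"): 30,
              ("CD163+CD206+ macrophage", "stroma"): 350, ("neutrophil", "stroma"): 250}
    cfg = st.SyntheticConfig(n_patients=2, cores_per_patient=(2, 2),
                             community_spec=[prof_t, prof_m], n_nests=2, rng_seed=5)
    cells, truth = st.generate_cohort(cfg)
    imm = ["CD8 T cell", "CD4 T cell", "CD163+CD206+ macrophage", "neutrophil"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = st.build_windows(cells, W=10, eligible_types=imm)
    model = st.fit_communities(win, k=2, seed=0)
    planted = truth.cells.loc[model.assignments.index, "community_id"]
    assert adjusted_rand_score(planted, model.assignments) >= 0.9


def test_select_k_finds_planted_three_profiles():
    prof3 = [
        {("CD8 T cell", "stroma"): 600, ("neutrophil", "stroma"): 15,
         ("CD163+CD206+ macrophage", "stroma"): 15},
        {("CD8 T cell", "stroma"): 20, ("neutrophil", "stroma"): 500,
         ("CD163+CD206+ macrophage", "stroma"): 15},
        {("CD8 T cell", "stroma"): 20, ("neutrophil", "stroma"): 15,
         ("CD163+CD206+ macrophage", "stroma"): 500},
    ]
    cfg = st.SyntheticConfig(n_patients=2, cores_per_patient=(2, 2),
                             community_spec=prof3, n_nests=2, rng_seed=6)
    cells, _ = st.generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = st.build_windows(
            cells, W=10,
            eligible_types=["CD8 T cell", "neutrophil", "CD163+CD206+ macrophage"])
    curve, k_star = st.select_k(win, k_range=range(1, 9), seed=0)
    assert k_star == 3
    # distortion nonincreasing within stochastic tolerance
    d = curve.distortion.to_numpy()
    assert (np.diff(d) <= np.abs(d[:-1]) * 0.02 + 1e-9).all()


def test_concordance_perfectly_separated_is_one():
    rng = np.random.default_rng(7)
    n = 300
    comp = np.zeros((n, 2))
    comp[: n // 2, 0] = 1.0
    comp[n // 2:, 1] = 1.0
    win = pd.DataFrame(comp, columns=["A", "B"],
                       index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"))
    win.attrs["window_size"] = 1
    model = st.fit_communities(win, k=2, seed=0)
    conc = st.concordance(win, model, seed=1)
    assert conc["median"] == 1.0
    assert len(conc["per_rep"]) == 3


def test_enrichment_planted_positive_and_absent_community_contributes():
    rng = np.random.default_rng(8)
    rows = []
    for p in range(6):
        for c in range(2):
            img = f"P{p}_{c}"
            n = 150
            com = rng.choice([0, 1], n)
            t = np.where((com == 0) & (rng.uniform(size=n) < 0.6), "T",
                         rng.choice(["M", "N"], n))
            rows.append(pd.DataFrame({
                "cell_id": [f"{img}_{i}" for i in range(n)], "image_id": img,
                "patient_id": f"P{p}", "cell_type": t, "community": com}))
    cells = pd.concat(rows, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = st.community_enrichment(cells, "T")
    assert res.loc[0, "effect"] > 0
    assert res.loc[0, "p_value"] < 0.05
    # a core lacking community 1 contributes density 0 rather than being dropped
    cells2 = cells.copy()
    first = cells2.image_id == "P0_0"
    cells2.loc[first, "community"] = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res2 = st.community_enrichment(cells2, "T")
    assert np.isfinite(res2.loc[1, "p_value"])
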