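"""ITH scores, bootstrap homogeneity, distances, TAN/TMB/subclonal scores."""

import numpy as np
import pandas as pd
import pytest

import spatialtme as st
from spatialtme.heterogeneity import PhyloTree
from tests.conftest import make_positions


# ------------------------------------------------------------------- ith

def test_identical_cores_have_zero_patient_sd():
    """A patient whose cores agree exactly contributes SD 0 for that feature."""
    dens = pd.DataFrame({"f1": [5.0, 5.0, 1.0, 9.0], "f2": [2.0, 8.0, 1.0, 9.0],
                         "patient_id": ["A", "A", "B", "B"]})
    res = st.ith_score(dens)
    # f1: only patient B varies -> mean SD is half of f2, where both vary
    assert res.loc["f1", "mean_sd"] < res.loc["f2", "mean_sd"]
    z1 = (dens.f1 - dens.f1.mean()) / dens.f1.std(ddof=1)
    expect = np.mean([0.0, z1[2:].std(ddof=1)])
    assert res.loc["f1", "mean_sd"] == pytest.approx(expect)


def test_ith_matches_hand_computed_example():
    """2 patients x 2 cores x 2 features, spreadsheet arithmetic."""
    dens = pd.DataFrame({"f1": [1.0, 3.0, 2.0, 2.0], "f2": [0.0, 0.0, 1.0, 5.0],
                         "patient_id": ["A", "A", "B", "B"]})
    res = st.ith_score(dens)
    z1 = (dens.f1 - dens.f1.mean()) / dens.f1.std(ddof=1)
    z2 = (dens.f2 - dens.f2.mean()) / dens.f2.std(ddof=1)
    m1 = np.mean([z1[:2].std(ddof=1), z1[2:].std(ddof=1)])
    m2 = np.mean([z2[:2].std(ddof=1), z2[2:].std(ddof=1)])
    assert res.loc["f1", "mean_sd"] == pytest.approx(m1)
    assert res.loc["f2", "mean_sd"] == pytest.approx(m2)


def test_ith_scores_standardized_and_order_invariant():
    rng = np.random.default_rng(0)
    dens = pd.DataFrame(rng.gamma(2, 100, (12, 5)), columns=list("abcde"))
    dens["patient_id"] = np.repeat(["P0", "P1", "P2", "P3"], 3)
    res = st.ith_score(dens)
    assert res.ith_score.mean() == pytest.approx(0.0, abs=1e-12)
    assert res.ith_score.std(ddof=1) == pytest.approx(1.0)
    rev = st.ith_score(dens[["e", "d", "c", "b", "a", "patient_id"]])
    assert res.loc["a", "ith_score"] == pytest.approx(rev.loc["a", "ith_score"])


def test_ith_requires_multicore_patient():
    dens = pd.DataFrame({"f": [1.0, 2.0], "patient_id": ["A", "B"]})
    with pytest.raises(ValueError):
        st.ith_score(dens)


# ----------------------------------------------------------- homogeneity

def test_all_same_class_probability_one():
    labels = pd.DataFrame({"patient_id": ["T1"] * 3, "tme_class": ["X"] * 3})
    res = st.class_homogeneity_probability(labels, reps=200, seed=0)
    assert res.loc["X", "probability"] == 1.0
    assert res.loc["X", "ith_probability"] == 0.0


def test_xxy_tumor_matches_exact_enumeration():
    """[X,X,Y] at n=2: P(all X) = (2/3)^2 = 4/9 within 3 sigma binomial error."""
    labels = pd.DataFrame({"patient_id": ["T1"] * 3, "tme_class": ["X", "X", "Y"]})
    reps = 1000
    res = st.class_homogeneity_probability(labels, n_samples=(2,), reps=reps, seed=1)
    p = 4 / 9
    se = np.sqrt(p * (1 - p) / reps)
    assert abs(res.loc["X", "probability"] - p) < 3 * se
    assert abs(res.loc["Y", "probability"] - 1 / 9) < 3 * np.sqrt((1 / 9) * (8 / 9) / reps)


def test_cohort_value_matches_enumeration_over_small_tumors():
    """Mean over tumors reproduced by exhaustive enumeration on <=3-core tumors."""
    labels = pd.DataFrame({
        "patient_id": ["T1"] * 3 + ["T2"] * 2 + ["T3"] * 3,
        "tme_class": ["X", "X", "Y", "X", "Y", "Y", "Y", "Y"],
    })
    n = 3
    res = st.class_homogeneity_probability(labels, n_samples=(n,), reps=4000, seed=2)
    # exact: per tumor having X, P(all n draws X) = (fraction X)^n
    exact_x = ((2 / 3) ** n + (1 / 2) ** n) / 2
    exact_y = ((1 / 3) ** n + (1 / 2) ** n + 1.0) / 3
    assert res.loc["X", "probability"] == pytest.approx(exact_x, abs=0.03)
    assert res.loc["Y", "probability"] == pytest.approx(exact_y, abs=0.03)


def test_probabilities_in_unit_interval(tme_cohort, tme_model):
    _, _, dens = tme_cohort
    labels = pd.DataFrame({
        "patient_id": dens["patient_id"].to_numpy(),
        "tme_class": tme_model.labels_.to_numpy(),
    })
    res = st.class_homogeneity_probability(labels, reps=200, seed=3)
    assert ((res.probability >= 0) & (res.probability <= 1)).all()


# ------------------------------------------------------------- distances

def test_single_pair_distance():
    cells = pd.DataFrame({
        "cell_id": ["a", "b"], "image_id": "i", "patient_id": "p",
        "x_um": [0.0, 30.0], "y_um": [0.0, 0.0],
        "cell_type": ["tumor", "endothelial"],
    })
    d = st.median_distance_to_type(cells, "tumor", "endothelial")
    assert d["i"] == 30.0


def test_nearest_distances_match_brute_force():
    rng = np.random.default_rng(1)
    cells = make_positions(rng, 300)
    cells["cell_type"] = rng.choice(["tumor", "endothelial"], 300)
    med = st.median_distance_to_type(cells, "tumor", "endothelial")["img"]
    src = cells[cells.cell_type == "tumor"][["x_um", "y_um"]].to_numpy()
    tgt = cells[cells.cell_type == "endothelial"][["x_um", "y_um"]].to_numpy()
    ref = np.median([np.hypot(*(tgt - s).T).min() for s in src])
    assert med == pytest.approx(ref)


def test_adding_farther_target_never_increases_median():
    rng = np.random.default_rng(2)
    cells = make_positions(rng, 100)
    cells["cell_type"] = ["tumor"] * 50 + ["endothelial"] * 50
    base = st.median_distance_to_type(cells, "tumor", "endothelial")["img"]
    extra = cells.iloc[[0]].assign(cell_id="far", cell_type="endothelial",
                                   x_um=10000.0, y_um=10000.0)
    more = st.median_distance_to_type(pd.concat([cells, extra]), "tumor",
                                      "endothelial")["img"]
    assert more <= base


def test_target_absent_warns_nan():
    cells = pd.DataFrame({"cell_id": ["a"], "image_id": "i", "patient_id": "p",
                          "x_um": [0.0], "y_um": [0.0], "cell_type": ["tumor"]})
    with pytest.warns(UserWarning):
        d = st.median_distance_to_type(cells, "tumor", "endothelial")
    assert np.isnan(d["i"])


# ------------------------------------------------------------ TAN / TMB

@pytest.mark.parametrize("ttan,stan,hist,expect", [
    (5.0, 0.0, "LUAD", "high"),   # tTAN 5% > 2% cutoff
    (0.0, 0.0, "LUAD", "low"),
    (0.0, 1.5, "LUAD", "high"),   # sTAN 1.5% > 1%
    (2.5, 0.0, "LUSC", "low"),    # LUSC tTAN cutoff is 3%
    (0.0, 2.5, "LUSC", "high"),
])
def test_tan_classification(ttan, stan, hist, expect):
    assert st.tan_classify(ttan, stan, hist) == expect


def test_tan_unknown_histology_and_range():
    with pytest.raises(ValueError, match="histology"):
        st.tan_classify(1.0, 1.0, "SCLC")
    with pytest.raises(ValueError):
        st.tan_classify(150.0, 0.0, "LUAD")


def test_tan_cutoff_derivation_recovers_planted_threshold():
    """derive_cutoff applied to separable TAN scores finds the separating value."""
    from spatialtme.tme import derive_cutoff

    scores = [0.5, 1.0, 1.5, 4.0, 5.0, 6.0]
    member = [False, False, False, True, True, True]
    cut = derive_cutoff(scores, member)
    assert 1.5 < cut.cutoff < 4.0
    assert cut.cutoff == pytest.approx((1.5 + 4.0) / 2)


def test_tmb_boundaries():
    assert st.tmb_status(300, 30.0) == ("high", pytest.approx(10.0))
    assert st.tmb_status(299, 30.0)[0] == "low"
    assert st.tmb_status(0, 30.0) == ("low", 0.0)
    with pytest.raises(ValueError):
        st.tmb_status(10, 0.0)


# ------------------------------------------------------------- phylogeny

def test_leaf_scores():
    t = PhyloTree(parents={"c": None, "s1": "c", "s2": "c"},
                  ccf={"R1": {"c": 1.0, "s1": 0.2, "s2": 0.5}})
    assert st.subclonal_expansion_score(t, "R1") == 0.5


def test_single_node_tree_root_is_terminal():
    t = PhyloTree(parents={"c": None}, ccf={"R1": {"c": 1.0}})
    assert st.subclonal_expansion_score(t, "R1") == 1.0


def test_random_trees_match_bruteforce_leaf_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(2, 12))
        parents = {"n0": None}
        for i in range(1, n):
            parents[f"n{i}"] = f"n{int(rng.integers(0, i))}"
        ccf = {"R": {f"n{i}": float(rng.uniform()) for i in range(n)}}
        t = PhyloTree(parents=parents, ccf=ccf)
        children = set(p for p in parents.values() if p is not None)
        ref = max(ccf["R"][c] for c in parents if c not in children)
        assert st.subclonal_expansion_score(t, "R") == pytest.approx(ref)


def test_tree_validation_errors(tmp_path):
    with pytest.raises(ValueError, match="root"):
        PhyloTree(parents={"a": "b", "b": "a"}).validate()
    with pytest.raises(ValueError, match="region"):
        st.subclonal_expansion_score(
            PhyloTree(parents={"a": None}, ccf={}), "R9")
    t = PhyloTree(parents={"a": None, "b": "a"}, ccf={"R": {"a": 1.0, "b": 0.3}})
    p = tmp_path / "tree.json"
    t.to_json(p)
    back = PhyloTree.from_json(p)
    assert back.parents == t.parents
    assert st.subclonal_expansion_score(back, "R") == 0.3
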