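"""Cell–cell interaction/avoidance permutation testing and cross-core aggregation.

Per image, the neighborhood of a cell is the set of cells within a contact
radius; for every ordered type pair (A center, B neighbor) the observed
mean number of B neighbors around A cells is compared with its null
distribution under random relabeling of the fixed cell positions
(histoCAT-style). The image-level call is *interaction* when the observed
statistic is in the upper permutation tail, *avoidance* in the lower, and
*ns* otherwise. Image-level calls are then aggregated across cores with a
patient-clustered logistic model and Benjamini–Hochberg correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

__all__ = ["neighbors", "permutation_relations", "aggregate_relations"]


def _radii(cells: pd.DataFrame, default_radius_um: float) -> np.ndarray:
    if "area_um2" in cells.columns:
        return np.sqrt(cells["area_um2"].to_numpy(float) / np.pi)
    return np.full(len(cells), default_radius_um)


def neighbors(
    cells: pd.DataFrame,
    radius_um: float = 5.0,
    adjacency: str = "centroid-threshold",
    cell_radius_um: float = 5.0,
) -> dict:
    """Symmetric per-cell neighbor lists for one image.

    In ``centroid-threshold`` mode two cells are neighbors when their
    centroid distance is at most ``radius_um`` plus both equivalent cell
    radii (from an ``area_um2`` column when present, else a fixed
    ``cell_radius_um``) — a table-level surrogate for the mask-dilation
    contact rule of segmentation pipelines.
    """
    if adjacency != "centroid-threshold":
        raise NotImplementedError(
            "mask-dilation adjacency requires segmentation masks; "
            "use centroid-threshold on cell tables"
        )
    ids = cells["cell_id"].to_numpy()
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    r = _radii(cells, cell_radius_um)
    tree = cKDTree(xy)
    max_d = radius_um + 2 * r.max()
    out: dict = {i: [] for i in ids}
    for i, j in tree.query_pairs(max_d):
        if np.hypot(*(xy[i] - xy[j])) <= radius_um + r[i] + r[j]:
            out[ids[i]].append(ids[j])
            out[ids[j]].append(ids[i])
    return {i: sorted(v) for i, v in out.items()}


def _adjacency_matrix(cells: pd.DataFrame, radius_um: float, cell_radius_um: float) -> csr_matrix:
    ids = {c: i for i, c in enumerate(cells["cell_id"])}
    nbrs = neighbors(cells, radius_um=radius_um, cell_radius_um=cell_radius_um)
    rows, cols = [], []
    for c, vs in nbrs.items():
        for v in vs:
            rows.append(ids[c])
            cols.append(ids[v])
    n = len(cells)
    return csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))


def permutation_relations(
    cells: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    radius_um: float = 5.0,
    cell_radius_um: float = 5.0,
    type_column: str = "cell_type",
) -> pd.DataFrame:
    """Permutation interaction test for one image.

    For each ordered pair (A, B) the statistic is the mean count of B
    neighbors over A cells. Type labels are permuted over the fixed
    positions ``n_perm`` times (one permutation shared by all pairs per
    repetition); ``p_high = (1 + #{perm ≥ obs}) / (n_perm + 1)`` and
    ``p_low`` analogously, so p-values are never exactly 0. Relation is
    ``interaction`` when p_high ≤ α, ``avoidance`` when p_low ≤ α, else
    ``ns``. Pairs with an absent type are skipped.
    """
    if cells["image_id"].nunique() > 1:
        raise ValueError("permutation_relations operates on a single image")
    img = cells["image_id"].iloc[0]
    rng = np.random.default_rng(seed)
    types = sorted(cells[type_column].unique())
    tmap = {t: i for i, t in enumerate(types)}
    codes = cells[type_column].map(tmap).to_numpy()
    if pairs is None:
        pairs = [(a, b) for a in types for b in types]
    pairs = [(a, b) for a, b in pairs if a in tmap and b in tmap]
    adj = _adjacency_matrix(cells, radius_um, cell_radius_um)
    n = len(cells)
    n_types = len(types)

    def pair_stats(code_vec: np.ndarray) -> np.ndarray:
        ind = np.zeros((n, n_types))
        ind[np.arange(n), code_vec] = 1.0
        counts = adj @ ind                      # cells × types: neighbor counts
        sums = ind.T @ counts                   # A type × B type total counts
        n_a = ind.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_a[:, None] > 0, sums / np.maximum(n_a, 1)[:, None], np.nan)

    obs = pair_stats(codes)
    ge = np.zeros((n_types, n_types))
    le = np.zeros((n_types, n_types))
    for _ in range(n_perm):
        perm = pair_stats(rng.permutation(codes))
        ge += perm >= obs - 1e-12
        le += perm <= obs + 1e-12
    p_high = (1.0 + ge) / (n_perm + 1.0)
    p_low = (1.0 + le) / (n_perm + 1.0)
    recs = []
    for a, b in pairs:
        i, j = tmap[a], tmap[b]
        ph, pl = float(p_high[i, j]), float(p_low[i, j])
        if ph <= alpha and ph < pl:
            rel = "interaction"
        elif pl <= alpha and pl < ph:
            rel = "avoidance"
        else:
            rel = "ns"
        recs.append(
            {
                "image_id": img, "type_A": a, "type_B": b,
                "obs": float(obs[i, j]), "p_high": ph, "p_low": pl, "relation": rel,
            }
        )
    return pd.DataFrame(recs)


def permutation_relations_by_core(cells: pd.DataFrame, seed: int = 0, **kwargs) -> pd.DataFrame:
    """Run :func:`permutation_relations` per image with per-image subseeds."""
    rng = np.random.default_rng(seed)
    frames = []
    for _, sub in cells.groupby("image_id", observed=True, sort=True):
        frames.append(
            permutation_relations(sub, seed=int(rng.integers(2**31 - 1)), **kwargs)
        )
    return pd.concat(frames, ignore_index=True)


def aggregate_relations(
    results: pd.DataFrame,
    groups: pd.Series,
    patients: pd.Series,
    relation: str = "interaction",
    min_presence: float = 0.9,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test whether a relation is enriched in a group of cores.

    ``results`` concatenates per-image outputs of
    :func:`permutation_relations`; ``groups`` is a boolean per-image series
    marking the class of interest and ``patients`` maps image to patient.
    The binary presence of the relation per core is modeled with a logistic
    model clustered on patient (GEE with exchangeable working correlation,
    the marginal counterpart of a patient random intercept), comparing the
    group against all other cores, with Benjamini–Hochberg adjustment
    across pairs. Pairs are tested only when both constituent types were
    present (i.e. the pair was testable) in at least ``min_presence`` of
    cores; degenerate all-0/all-1 outcomes are flagged without an estimate.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    if groups.astype(bool).nunique() < 2:
        raise ValueError("need at least 2 groups (cores inside and outside the class)")
    all_images = groups.index
    recs = []
    for (a, b), sub in results.groupby(["type_A", "type_B"], observed=True):
        tested_imgs = sub["image_id"].unique()
        presence = len(set(tested_imgs) & set(all_images)) / len(all_images)
        if presence < min_presence:
            continue
        y = (
            sub.set_index("image_id")["relation"].eq(relation).astype(float)
            .reindex(tested_imgs)
        )
        g = groups.reindex(tested_imgs).astype(float)
        pat = patients.reindex(tested_imgs)
        rec = {
            "type_A": a, "type_B": b, "relation": relation,
            "frac_group": float(y[g == 1].mean()) if (g == 1).any() else np.nan,
            "frac_other": float(y[g == 0].mean()) if (g == 0).any() else np.nan,
            "n_cores": len(y),
        }
        if y.nunique() < 2 or g.nunique() < 2:
            rec.update({"effect": np.nan, "p_value": np.nan, "degenerate": True})
        else:
            X = sm.add_constant(g.to_numpy())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = sm.GEE(
                        y.to_numpy(), X, groups=pat.to_numpy(),
                        family=sm.families.Binomial(),
                        cov_struct=sm.cov_struct.Exchangeable(),
                    ).fit()
                    rec.update(
                        {
                            "effect": float(fit.params[1]),
                            "p_value": float(fit.pvalues[1]),
                            "degenerate": False,
                        }
                    )
                except Exception:
                    rec.update({"effect": np.nan, "p_value": np.nan, "degenerate": True})
        recs.append(rec)
    out = pd.DataFrame(recs)
    if len(out) and out["p_value"].notna().any():
        ok = out["p_value"].notna()
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
        out["significant"] = out.get("p_adj", np.nan) < alpha
    else:
        out["p_adj"] = np.nan
        out["significant"] = False
    return out
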