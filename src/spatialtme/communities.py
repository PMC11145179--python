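"""Recurrent cellular community detection from windowed neighbor composition.

Around every eligible cell a window of its W nearest cells (center included)
is formed and summarized as a composition vector over cell types; windows
pooled across all cores are clustered with mini-batch k-means, so a
community is a recurrent local multicellular composition. Includes the
elbow-based choice of k, subsampling concordance, and per-community cell
type enrichment with a patient-level random effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from sklearn.cluster import MiniBatchKMeans

__all__ = [
    "CommunityModel",
    "build_windows",
    "fit_communities",
    "select_k",
    "concordance",
    "community_enrichment",
]


@dataclass
class CommunityModel:
    """Fitted community model: centroid compositions and per-cell labels."""

    window_size: int
    k: int
    centroids: pd.DataFrame              # k × types, rows sum to 1
    assignments: pd.Series               # cell_id -> community in [0, k)
    seed: int
    distortion: float

    def to_json_dict(self) -> dict:
        return {
            "window_size": self.window_size,
            "k": self.k,
            "seed": self.seed,
            "distortion": self.distortion,
            "types": list(self.centroids.columns),
            "centroids": self.centroids.to_numpy().tolist(),
        }


def eligible_cell_types(
    cells: pd.DataFrame,
    type_column: str = "cell_type",
    min_mean_per_core: float = 10.0,
    exclude: tuple[str, ...] = ("unassigned", "ambiguous"),
) -> list[str]:
    """Cell types with at least ``min_mean_per_core`` cells per core on average."""
    n_cores = cells["image_id"].nunique()
    counts = cells[~cells[type_column].isin(exclude)].groupby(type_column, observed=True).size()
    return sorted(counts.index[counts / n_cores >= min_mean_per_core])


def build_windows(
    cells: pd.DataFrame,
    W: int = 10,
    eligible_types: list[str] | None = None,
    type_column: str = "cell_type",
) -> pd.DataFrame:
    """Window composition matrix: one row per eligible cell, columns = types.

    Each row is the fraction of each eligible type among the W cells of the
    window (the center cell and its W−1 nearest eligible neighbors, Euclidean
    distance on μm coordinates, per core). Distance ties break by cell id.
    Cores with fewer than W eligible cells are skipped with a warning.
    Rows sum to 1. ``image_id`` per window is kept in ``.attrs``.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    if eligible_types is None:
        eligible_types = eligible_cell_types(cells, type_column)
    elig = cells[cells[type_column].isin(eligible_types)]
    type_index = {t: i for i, t in enumerate(eligible_types)}
    rows, ids, imgs = [], [], []
    for img, sub in elig.groupby("image_id", observed=True, sort=True):
        n = len(sub)
        if n < W:
            warnings.warn(f"core {img}: {n} eligible cells < window size {W}; skipped")
            continue
        sub = sub.sort_values("cell_id")
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        codes = sub[type_column].map(type_index).to_numpy()
        tree = cKDTree(xy)
        k_query = min(n, W + 3)  # headroom so distance ties can be re-sorted by id
        dist, nbr = tree.query(xy, k=k_query)
        comp = np.zeros((n, len(eligible_types)))
        for i in range(n):
            order = np.lexsort((nbr[i], np.round(dist[i], 9)))
            sel = nbr[i][order][:W]
            np.add.at(comp[i], codes[sel], 1.0)
        comp /= W
        rows.append(comp)
        ids.extend(sub["cell_id"])
        imgs.extend([img] * n)
    if not rows:
        raise ValueError("no core has enough eligible cells")
    out = pd.DataFrame(
        np.vstack(rows), index=pd.Index(ids, name="cell_id"), columns=eligible_types
    )
    out.attrs["image_id"] = pd.Series(imgs, index=out.index)
    out.attrs["window_size"] = W
    return out


def fit_communities(windows: pd.DataFrame, k: int = 10, seed: int = 0) -> CommunityModel:
    """Cluster window compositions with mini-batch k-means into k communities."""
    if len(windows) == 0:
        raise ValueError("windows is empty")
    if k > len(windows):
        raise ValueError(f"k={k} exceeds number of windows ({len(windows)})")
    km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3, batch_size=1024)
    labels = km.fit_predict(windows.to_numpy())
    cent = km.cluster_centers_.clip(min=0)
    cent = cent / np.maximum(cent.sum(axis=1, keepdims=True), 1e-12)
    return CommunityModel(
        window_size=int(windows.attrs.get("window_size", 0)),
        k=k,
        centroids=pd.DataFrame(cent, columns=windows.columns),
        assignments=pd.Series(labels, index=windows.index, name="community"),
        seed=seed,
        distortion=float(km.inertia_),
    )


def select_k(
    windows: pd.DataFrame,
    k_range: range = range(1, 21),
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Distortion (within-cluster sum of squares) over k, and the elbow k*.

    k* maximizes the discrete curvature (second difference) of the
    distortion curve; for fewer than three candidate k values the smallest
    k is returned.
    """
    ks = [k for k in k_range if k <= len(windows)]
    if not ks:
        raise ValueError("empty k range")
    dist = [fit_communities(windows, k=k, seed=seed).distortion for k in ks]
    curve = pd.DataFrame({"k": ks, "distortion": dist})
    if len(ks) < 3:
        return curve, ks[0]
    d = np.array(dist)
    curv = d[:-2] - 2 * d[1:-1] + d[2:]
    k_star = ks[1 + int(np.argmax(curv))]
    return curve, k_star


def concordance(
    windows: pd.DataFrame,
    model: CommunityModel,
    fraction: float = 1 / 3,
    reps: int = 3,
    seed: int = 0,
) -> dict:
    """Subsampling stability of the community assignment.

    Each repetition reclusters a random ``fraction`` of the windows, matches
    the new labels to the reference model's by solving the assignment
    problem on the confusion matrix, and reports the proportion of cells
    assigned to the same community. Returns per-rep values and their median.
    """
    rng = np.random.default_rng(seed)
    ref = model.assignments
    per_rep = []
    for _ in range(reps):
        idx = rng.choice(len(windows), size=max(model.k, int(len(windows) * fraction)), replace=False)
        sub = windows.iloc[np.sort(idx)]
        refit = fit_communities(sub, k=model.k, seed=int(rng.integers(2**31 - 1)))
        a = ref.loc[sub.index].to_numpy()
        b = refit.assignments.to_numpy()
        conf = np.zeros((model.k, model.k))
        np.add.at(conf, (b, a), 1.0)
        rows, cols = linear_sum_assignment(-conf)
        mapping = dict(zip(rows, cols))
        per_rep.append(float(np.mean([mapping[x] for x in b] == a)))
    return {"per_rep": per_rep, "median": float(np.median(per_rep))}


def community_enrichment(
    cells: pd.DataFrame,
    cell_type: str,
    community_column: str = "community",
    type_column: str = "cell_type",
) -> pd.DataFrame:
    """Per-community enrichment of a cell type, patient as a random effect.

    For every core and community the local density of the type (fraction of
    the community's cells that are of the type) is compared with its density
    among the core's remaining cells; the in/out contrast is tested with a
    linear mixed model with a patient-level random intercept (Wald test on
    the contrast). Cores lacking the community contribute a density of 0.
    With a single patient the model degenerates to an ordinary fixed-effect
    comparison (with a warning).

    Returns a DataFrame indexed by community with columns ``effect`` (mean
    in − out density difference) and ``p_value``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if community_column not in cells.columns:
        raise ValueError(f"no {community_column!r} column; fit communities first")
    labeled = cells.dropna(subset=[community_column])
    communities = sorted(labeled[community_column].unique())
    single_patient = cells["patient_id"].nunique() < 2
    if single_patient:
        warnings.warn("single patient: falling back to fixed-effect comparison")
    out = {}
    for com in communities:
        recs = []
        for (img, pid), sub in labeled.groupby(["image_id", "patient_id"], observed=True):
            inside = sub[sub[community_column] == com]
            outside = sub[sub[community_column] != com]
            y_in = (inside[type_column] == cell_type).mean() if len(inside) else 0.0
            y_out = (outside[type_column] == cell_type).mean() if len(outside) else 0.0
            recs.append({"image_id": img, "patient_id": pid, "y": y_in, "inside": 1})
            recs.append({"image_id": img, "patient_id": pid, "y": y_out, "inside": 0})
        df = pd.DataFrame(recs)
        effect = df.loc[df.inside == 1, "y"].mean() - df.loc[df.inside == 0, "y"].mean()
        if df["y"].nunique() < 2:
            out[com] = {"effect": 0.0, "p_value": 1.0}
            continue
        if single_patient:
            fit = smf.ols("y ~ inside", data=df).fit()
            p = float(fit.pvalues["inside"])
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    md = smf.mixedlm("y ~ inside", data=df, groups=df["patient_id"])
                    fit = md.fit(reml=True)
                    p = float(fit.pvalues["inside"])
                except Exception:
                    # variance component on the boundary: the mixed fit
                    # degenerates to the ordinary fixed-effect comparison
                    fit = smf.ols("y ~ inside", data=df).fit()
                    p = float(fit.pvalues["inside"])
        out[com] = {"effect": float(effect), "p_value": p}
    res = pd.DataFrame.from_dict(out, orient="index")
    res.index.name = "community"
    return res
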