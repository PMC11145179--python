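"""Four-class tumor-microenvironment (TME) classification.

Cores are clustered by their compartment-wise immune cell densities
(robust z-scores) with consensus clustering: repeated hierarchical
clustering (Chebyshev distance, Ward linkage) on 75% subsamples, a
consensus matrix of co-clustering proportions, and a CDF/ΔAUC diagnostic
over the number of clusters k. The k=4 solution is then converted into
explicit per-class decision criteria — a feature group, a direction and an
automatically derived cutoff (equal sensitivity/specificity point) — so
that each core either satisfies its cluster's criteria and keeps the class
label or is labeled ``undefined``.

Class names follow the tumor-and-stroma (TS) naming convention:
``TS:TIL+MP high``, ``T:TIL+MP excluded``, ``TS:Immune low``,
``TS:Neutrophil high``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from spatialtme.density import robust_z

__all__ = [
    "ConsensusResult",
    "CutoffResult",
    "TMEModel",
    "consensus_cluster",
    "derive_cutoff",
    "build_tme_model",
    "assign_tme",
    "TME_CLASS_NAMES",
]

TME_CLASS_NAMES = (
    "TS:TIL+MP high",
    "T:TIL+MP excluded",
    "TS:Immune low",
    "TS:Neutrophil high",
)

#: default feature groups: (classes, compartments) used to build the
#: clustering features. B lineage and other myeloid cells are stromal only
#: (they are essentially absent from tumor nests).
DEFAULT_FEATURES: tuple[tuple[str, str], ...] = (
    ("CD8 T cell", "tumor_nest"), ("CD8 T cell", "stroma"),
    ("CD4 T cell", "tumor_nest"), ("CD4 T cell", "stroma"),
    ("B cell", "stroma"),
    ("CD163+CD206+ macrophage", "tumor_nest"), ("CD163+CD206+ macrophage", "stroma"),
    ("CD163- macrophage", "tumor_nest"), ("CD163- macrophage", "stroma"),
    ("neutrophil", "tumor_nest"), ("neutrophil", "stroma"),
    ("myeloid other", "stroma"),
)

_TIL_CLASSES = ("CD8 T cell", "CD4 T cell", "B cell")
_MAC_CLASSES = ("CD163+CD206+ macrophage", "CD163- macrophage")


@dataclass
class ConsensusResult:
    """Consensus-clustering output over a range of k."""

    labels: pd.DataFrame               # cores × k (columns are k values)
    consensus: dict[int, pd.DataFrame]  # k -> cores × cores consensus matrix
    auc: pd.Series                     # CDF area under curve per k
    delta_auc: pd.Series               # relative AUC change vs k−1; AUC itself at k_min


def consensus_cluster(
    densities: pd.DataFrame,
    k_range=range(2, 7),
    subsample: float = 0.75,
    reps: int = 1000,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of a normalized core × feature matrix.

    Each repetition draws ``subsample`` of the cores without replacement and
    clusters them hierarchically (Chebyshev distance, Ward linkage, the
    ward.D analogue of clustering an arbitrary dissimilarity). The consensus
    value for a pair of cores is the proportion of co-sampled repetitions in
    which they co-cluster; pairs never co-sampled get 0.5 with a warning.
    Final per-k labels come from Ward clustering of 1 − consensus. The CDF
    area (AUC) of the consensus values and its increment over k are the
    model-selection diagnostic.
    """
    num = densities.select_dtypes(include=[np.number])
    X = num.to_numpy(float)
    n = len(X)
    ks = [k for k in k_range if 2 <= k <= n // 2]  # need >= 2k cores per k
    if not ks:
        raise ValueError(f"no k in range supported by {n} cores (need >= 2k)")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))
    co_sample = np.zeros((n, n))
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = X[idx]
        Z = linkage(pdist(sub, metric="chebyshev"), method="ward")
        co_sample[np.ix_(idx, idx)] += 1.0
        for k in ks:
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same
    never = (co_sample == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(f"{int(never.sum() // 2)} core pairs never co-sampled; consensus set to 0.5")
    consensus = {}
    labels = {}
    auc = {}
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.5)
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2.0
        cdf_vals = C[np.triu_indices(n, k=1)]
        # AUC of the empirical CDF of consensus values over [0, 1]
        xs = np.sort(cdf_vals)
        cdf = np.arange(1, len(xs) + 1) / len(xs)
        grid = np.concatenate([[0.0], xs, [1.0]])
        cdfg = np.concatenate([[0.0], cdf, [1.0]])
        auc[k] = float(np.trapezoid(cdfg, grid))
        Zf = linkage(squareform(1.0 - C, checks=False), method="ward")
        labels[k] = fcluster(Zf, t=k, criterion="maxclust")
        consensus[k] = pd.DataFrame(C, index=num.index, columns=num.index)
    auc = pd.Series(auc).sort_index()
    # relative change in CDF area, the consensus-clustering convention:
    # the base area at the smallest k, then (A(k) − A(k−1)) / A(k−1)
    delta = auc.diff() / auc.shift(1)
    delta.iloc[0] = auc.iloc[0]
    return ConsensusResult(
        labels=pd.DataFrame(labels, index=num.index),
        consensus=consensus,
        auc=auc,
        delta_auc=delta,
    )


@dataclass
class CutoffResult:
    """Decision threshold: pass iff direction × (score − cutoff) > 0."""

    cutoff: float
    direction: int  # +1 high scores in class, −1 low scores in class

    def passes(self, score) -> np.ndarray:
        s = np.asarray(score, float)
        return self.direction * (s - self.cutoff) > 0


def derive_cutoff(score, membership) -> CutoffResult:
    """Equal-sensitivity/specificity cutoff for a one-dimensional score.

    Separates in-class from out-of-class cores at the ROC point where
    |sensitivity − specificity| is minimal, evaluated at midpoints between
    consecutive distinct scores; ties resolve to the midpoint of the optimal
    interval. The direction flag is negative when in-class scores are lower.
    A single-predictor logistic model orders cores identically to the raw
    score, so thresholding the score is equivalent to thresholding the
    fitted probability.
    """
    s = np.asarray(score, float)
    mem = np.asarray(membership, bool)
    if mem.all() or (~mem).all():
        raise ValueError("both classes must be nonempty")
    if np.ptp(s) == 0:
        raise ValueError("score is constant; no cutoff exists")
    direction = 1 if s[mem].mean() >= s[~mem].mean() else -1
    z = direction * s
    uniq = np.unique(z)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    n_in, n_out = mem.sum(), (~mem).sum()
    sens = (z[mem][:, None] > cands[None, :]).sum(axis=0) / n_in
    spec = (z[~mem][:, None] <= cands[None, :]).sum(axis=0) / n_out
    gap = np.abs(sens - spec)
    best = gap == gap.min()
    t = (cands[best].min() + cands[best].max()) / 2.0
    return CutoffResult(cutoff=direction * t if direction == 1 else -t, direction=direction)


@dataclass
class TMEModel:
    """Fitted TME classifier: consensus clusters plus explicit criteria.

    ``criteria`` maps a class name to a list of (score name, CutoffResult);
    every criterion must pass for a core to keep its cluster's class.
    ``center``/``scale`` store the robust-z normalization of the training
    features so new cores can be scored on the same scale.
    """

    feature_columns: list[str]
    center: pd.Series
    scale: pd.Series
    cluster_class: dict[int, str]
    criteria: dict[str, list[tuple[str, CutoffResult]]]
    consensus: ConsensusResult
    k: int = 4
    labels_: pd.Series | None = None

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "features": self.feature_columns,
            "center": self.center.to_dict(),
            "scale": self.scale.to_dict(),
            "cluster_class": {str(c): n for c, n in self.cluster_class.items()},
            "criteria": {
                cls: [
                    {"score": name, "direction": cr.direction, "cutoff": cr.cutoff}
                    for name, cr in crits
                ]
                for cls, crits in self.criteria.items()
            },
            "delta_auc": {str(k): float(v) for k, v in self.consensus.delta_auc.items()},
        }


def _feature_cols(features, available) -> list[str]:
    cols = [f"{cls}__{comp}" for cls, comp in features]
    return [c for c in cols if c in available]


def _group_scores(z: pd.DataFrame, densities: pd.DataFrame) -> pd.DataFrame:
    """Per-core criterion scores from z-scored features and raw densities.

    'TIL or macrophage' criteria take the max of the group's z features
    (a core qualifies if any member is high). The neutrophil score is the
    robust z of the neutrophil proportion of all cells, max over the two
    compartments.
    """
    def gmax(classes, comps):
        cols = [f"{c}__{p}" for c in classes for p in comps if f"{c}__{p}" in z.columns]
        return z[cols].max(axis=1) if cols else pd.Series(np.nan, index=z.index)

    scores = pd.DataFrame(index=z.index)
    scores["til_mac_nest"] = gmax(_TIL_CLASSES + _MAC_CLASSES, ("tumor_nest",))
    scores["til_mac_stroma"] = gmax(_TIL_CLASSES + _MAC_CLASSES, ("stroma",))
    scores["immune_nest"] = gmax(
        _TIL_CLASSES + _MAC_CLASSES + ("neutrophil", "myeloid other"), ("tumor_nest",)
    )
    num = densities.select_dtypes(include=[np.number])
    for comp in ("tumor_nest", "stroma"):
        comp_cols = [c for c in num.columns if c.endswith(f"__{comp}")]
        tot = num[comp_cols].sum(axis=1)
        neut = num.get(f"neutrophil__{comp}", pd.Series(0.0, index=num.index))
        prop = (neut / tot.replace(0, np.nan)).fillna(0.0)
        med = prop.median()
        mad = (prop - med).abs().median()
        scores[f"neut_prop_{comp}"] = (prop - med) / (mad if mad > 0 else 1.0)
    scores["neut_prop"] = scores[["neut_prop_tumor_nest", "neut_prop_stroma"]].max(axis=1)
    return scores


def build_tme_model(
    densities: pd.DataFrame,
    features: tuple[tuple[str, str], ...] = DEFAULT_FEATURES,
    k: int = 4,
    k_range=range(2, 7),
    reps: int = 1000,
    subsample: float = 0.75,
    seed: int = 0,
) -> TMEModel:
    """Fit the TME classifier on a raw per-core density matrix.

    Robust z-scores the configured features, runs consensus clustering,
    names the k=4 clusters from their mean criterion scores, derives each
    class's cutoffs (class cluster vs all other clusters), and stores the
    final per-core labels (cores failing their cluster's criteria are
    ``undefined``).
    """
    cols = _feature_cols(features, densities.columns)
    if not cols:
        raise ValueError("none of the requested features are in the density matrix")
    feat = densities[cols].astype(float)
    x = feat.to_numpy()
    center = pd.Series(np.nanmedian(x, axis=0), index=cols)
    mad = pd.Series(np.nanmedian(np.abs(x - center.to_numpy()), axis=0), index=cols)
    scale = mad.where(mad > 0, other=1.0)
    z = (feat - center) / scale
    cons = consensus_cluster(z, k_range=k_range, subsample=subsample, reps=reps, seed=seed)
    if k not in cons.labels.columns:
        raise ValueError(f"k={k} not in consensus k range")
    clusters = cons.labels[k]
    scores = _group_scores(z, densities)

    means = scores.groupby(clusters).mean()
    remaining = list(means.index)
    neut_cl = int(means.loc[remaining, "neut_prop"].idxmax())
    remaining.remove(neut_cl)
    high_cl = int(means.loc[remaining, "til_mac_nest"].idxmax())
    remaining.remove(high_cl)
    low_cl = int(means.loc[remaining, "immune_nest"].idxmin())
    remaining.remove(low_cl)
    # any clusters left over (k > 4) default to the excluded phenotype
    excl_cl = remaining[0] if remaining else low_cl
    cluster_class = {high_cl: "TS:TIL+MP high", low_cl: "TS:Immune low",
                     neut_cl: "TS:Neutrophil high"}
    for c in remaining:
        cluster_class[c] = "T:TIL+MP excluded"

    def cut(score_name: str, cluster: int, versus: int | None = None) -> tuple[str, CutoffResult]:
        # versus=None: cluster vs all other clusters; else the pairwise contrast
        if versus is None:
            keep = pd.Series(True, index=clusters.index)
        else:
            keep = clusters.isin([cluster, versus])
        return score_name, derive_cutoff(
            scores.loc[keep, score_name], (clusters == cluster)[keep]
        )

    criteria = {
        "TS:TIL+MP high": [cut("til_mac_nest", high_cl)],
        "TS:Immune low": [cut("immune_nest", low_cl)],
        "TS:Neutrophil high": [cut("neut_prop", neut_cl)],
    }
    if "T:TIL+MP excluded" in cluster_class.values():
        # nest infiltrate below the high class, stromal infiltrate above the
        # immune-low class: the canonical excluded phenotype
        criteria["T:TIL+MP excluded"] = [
            cut("til_mac_nest", excl_cl, versus=high_cl),
            cut("til_mac_stroma", excl_cl, versus=low_cl),
        ]
    model = TMEModel(
        feature_columns=cols,
        center=center,
        scale=scale,
        cluster_class=cluster_class,
        criteria=criteria,
        consensus=cons,
        k=k,
    )
    model.labels_ = assign_tme(densities, model, _clusters=clusters)
    return model


def assign_tme(
    densities: pd.DataFrame,
    model: TMEModel,
    _clusters: pd.Series | None = None,
) -> pd.Series:
    """Assign each core its TME class, or ``undefined``.

    A core keeps its consensus cluster's class only if it passes every one
    of that class's criteria. Out-of-sample cores (not in the fitted
    consensus) are assigned the class of the best-matching criteria set:
    the first class (in fixed order) whose criteria all pass, else
    undefined. Cores with missing criterion features are undefined with a
    warning. Assignment is row-order invariant.
    """
    cols = model.feature_columns
    feat = densities.reindex(columns=cols).astype(float)
    z = (feat - model.center) / model.scale
    scores = _group_scores(z, densities)
    out = pd.Series("undefined", index=densities.index, dtype=object, name="tme_class")
    clusters = _clusters
    if clusters is None and model.consensus is not None:
        clusters = model.consensus.labels[model.k]
    for img in densities.index:
        row = scores.loc[img]
        if clusters is not None and img in clusters.index:
            cls = model.cluster_class[int(clusters.loc[img])]
            crits = model.criteria.get(cls, [])
            vals = [row[name] for name, _ in crits]
            if any(pd.isna(v) for v in vals):
                warnings.warn(f"core {img}: missing criterion feature; undefined")
                continue
            if all(cr.passes(row[name]) for name, cr in crits):
                out.loc[img] = cls
        else:
            for cls in TME_CLASS_NAMES:
                crits = model.criteria.get(cls, [])
                if crits and all(
                    not pd.isna(row[name]) and cr.passes(row[name]) for name, cr in crits
                ):
                    out.loc[img] = cls
                    break
    return out
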