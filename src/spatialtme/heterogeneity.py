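"""Spatial intratumor-heterogeneity (ITH) statistics and auxiliary scores.

Covers: the cohort ITH score of per-feature density variability across a
tumor's regions; bootstrap probabilities that all regions of a tumor share
a TME class; nearest-cell distance summaries; tumor-associated-neutrophil
(TAN) high/low classification from pathologist area percentages; tumor
mutational burden (TMB) status; and the recent-subclonal-expansion score
from clone phylogenies with per-region cancer cell fractions (CCF).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ith_score",
    "class_homogeneity_probability",
    "median_distance_to_type",
    "tan_classify",
    "tmb_status",
    "PhyloTree",
    "subclonal_expansion_score",
    "DEFAULT_TAN_CUTOFFS",
]


def ith_score(densities: pd.DataFrame, grouping: pd.Series | str = "patient_id") -> pd.DataFrame:
    """Spatial ITH score per feature.

    Pipeline: z-score each numeric feature across the cohort; per patient
    with ≥2 cores take the standard deviation across that patient's cores;
    average the SDs over patients (``mean_sd``); finally z-score the means
    across features (``ith_score``, mean 0 / SD 1 across features). The
    result is invariant to feature ordering.
    """
    if isinstance(grouping, str):
        if grouping not in densities.columns:
            raise ValueError(f"no {grouping!r} column in densities")
        grouping = densities[grouping]
    num = densities.select_dtypes(include=[np.number])
    counts = grouping.groupby(grouping).size()
    multi = counts.index[counts >= 2]
    if len(multi) == 0:
        raise ValueError("no patient has 2 or more cores")
    z = (num - num.mean()) / num.std(ddof=1)
    sds = (
        z[grouping.isin(multi)]
        .groupby(grouping[grouping.isin(multi)])
        .std(ddof=1)
    )
    mean_sd = sds.mean(axis=0)
    score = (mean_sd - mean_sd.mean()) / mean_sd.std(ddof=1)
    out = pd.DataFrame({"mean_sd": mean_sd, "ith_score": score})
    out.index.name = "feature"
    return out


def class_homogeneity_probability(
    labels: pd.DataFrame,
    n_samples: tuple[int, ...] = (2, 3, 4),
    reps: int = 1000,
    seed: int = 0,
    tumor_column: str = "patient_id",
    class_column: str = "tme_class",
) -> pd.DataFrame:
    """Bootstrap probability that all sampled regions share a class.

    Per iteration and per number of samples n: every tumor with the class in
    any core contributes n cores drawn with replacement from its cores; the
    ratio of tumors whose n draws all carry the class to the number of
    tumors having the class is recorded. The reported probability averages
    the ratio over iterations and over n; the ITH probability is its
    complement. Classes absent from the cohort are not reported.
    """
    rng = np.random.default_rng(seed)
    tumors = {
        t: sub[class_column].to_numpy()
        for t, sub in labels.groupby(tumor_column, observed=True)
    }
    classes = sorted(labels[class_column].dropna().unique())
    out = {}
    for cls in classes:
        having = [t for t, arr in tumors.items() if (arr == cls).any()]
        if not having:
            continue
        ratios = []
        for n in n_samples:
            for _ in range(reps):
                all_same = 0
                for t in having:
                    arr = tumors[t]
                    draw = arr[rng.integers(0, len(arr), size=n)]
                    all_same += int((draw == cls).all())
                ratios.append(all_same / len(having))
        p = float(np.mean(ratios))
        out[cls] = {"probability": p, "ith_probability": 1.0 - p, "n_tumors": len(having)}
    res = pd.DataFrame.from_dict(out, orient="index")
    res.index.name = class_column
    return res


def median_distance_to_type(
    cells: pd.DataFrame,
    source: str,
    target: str,
    type_column: str = "cell_type",
) -> pd.Series:
    """Per-core median Euclidean distance from source cells to the nearest target cell."""
    out = {}
    for img, sub in cells.groupby("image_id", observed=True, sort=True):
        src = sub[sub[type_column] == source][["x_um", "y_um"]].to_numpy(float)
        tgt = sub[sub[type_column] == target][["x_um", "y_um"]].to_numpy(float)
        if len(src) == 0 or len(tgt) == 0:
            warnings.warn(f"core {img}: source or target class absent; distance missing")
            out[img] = np.nan
            continue
        d, _ = cKDTree(tgt).query(src, k=1)
        out[img] = float(np.median(d))
    return pd.Series(out, name=f"median_dist_{source}_to_{target}")


#: diagnostic-slide TAN cutoffs (tTAN%, sTAN%) per histology
DEFAULT_TAN_CUTOFFS: dict[str, tuple[float, float]] = {
    "LUAD": (2.0, 1.0),
    "LUSC": (3.0, 2.0),
}


def tan_classify(
    ttan: float,
    stan: float,
    histology: str,
    cutoffs: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Classify a TAN record high/low.

    tTAN/sTAN are percentages (of tumor / stroma compartment area occupied
    by neutrophils). A record is 'high' when either score exceeds its
    histology-specific cutoff.
    """
    cutoffs = DEFAULT_TAN_CUTOFFS if cutoffs is None else cutoffs
    if histology not in cutoffs:
        raise ValueError(f"unknown histology {histology!r}; cutoffs available for {sorted(cutoffs)}")
    if not (0 <= ttan <= 100 and 0 <= stan <= 100):
        raise ValueError("TAN percentages must be in [0, 100]")
    t_cut, s_cut = cutoffs[histology]
    return "high" if (ttan > t_cut or stan > s_cut) else "low"


def tmb_status(mutations: int, coding_mb: float) -> tuple[str, float]:
    """Tumor mutational burden: muts/Mb and its clinical high/low status.

    High at ≥ 10 mutations per coding megabase (boundary inclusive).
    """
    if coding_mb <= 0:
        raise ValueError("coding_mb must be > 0")
    if mutations < 0:
        raise ValueError("mutation count must be >= 0")
    rate = mutations / coding_mb
    return ("high" if rate >= 10.0 else "low"), rate


@dataclass
class PhyloTree:
    """Clone phylogeny with per-region CCFs.

    ``parents`` maps clone id to parent id (root maps to None);
    ``ccf`` maps region id to {clone id: CCF in [0, 1]}.
    """

    parents: dict[str, str | None]
    ccf: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        roots = [c for c, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for c, p in self.parents.items():
            if p is not None and p not in self.parents:
                raise ValueError(f"parent {p!r} of {c!r} is not a node")
            seen = {c}
            node = p
            while node is not None:
                if node in seen:
                    raise ValueError(f"cycle through {node!r}")
                seen.add(node)
                node = self.parents[node]
        for region, m in self.ccf.items():
            for clone, v in m.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"CCF of {clone!r} in {region!r} outside [0, 1]")

    @property
    def leaves(self) -> list[str]:
        """Terminal clones: nodes that are nobody's parent (a lone root is a leaf)."""
        parents_of = {p for p in self.parents.values() if p is not None}
        return sorted(c for c in self.parents if c not in parents_of)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"parents": self.parents, "ccf": self.ccf}, fh)

    @classmethod
    def from_json(cls, path) -> "PhyloTree":
        with open(path) as fh:
            d = json.load(fh)
        tree = cls(parents=d["parents"], ccf=d.get("ccf", {}))
        tree.validate()
        return tree


def subclonal_expansion_score(tree: PhyloTree, region: str) -> float:
    """Recent subclonal expansion score of a region.

    The maximum CCF among the tree's leaf clones in the region — the size
    of the largest recently expanded subclone. A single-node tree scores
    its root CCF (the root is terminal).
    """
    tree.validate()
    if region not in tree.ccf:
        raise ValueError(f"region {region!r} absent from tree CCFs")
    ccfs = tree.ccf[region]
    vals = [ccfs[leaf] for leaf in tree.leaves if leaf in ccfs]
    if not vals:
        raise ValueError(f"no leaf CCFs recorded for region {region!r}")
    return float(max(vals))
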