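"""Rule-based marker positivity, lineage and subtype assignment.

A deterministic three-stage pipeline replaces probabilistic phenotyping:

1. per-marker positivity from a two-component mixture fit on log intensities
   (quantile fallback for degenerate fits);
2. major-lineage assignment by scoring each lineage's marker set against the
   cell's positive markers;
3. subtype assignment from a rule table of required-positive /
   required-negative markers, most-specific rule first.

Pathology-mask relabeling (perivascular αSMA⁺ cells, alveolar macrophages,
tumor-cell flags) operates on cell centers, i.e. a point-in-mask test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "PanelDefinition",
    "SubtypeRule",
    "PositivityMatrix",
    "default_panel",
    "call_positivity",
    "assign_major_lineage",
    "assign_subtype",
    "apply_pathology_labels",
]


@dataclass(frozen=True)
class SubtypeRule:
    name: str
    parents: tuple[str, ...]          # lineages the rule applies to
    required_pos: tuple[str, ...]
    required_neg: tuple[str, ...] = ()

    def validate(self) -> None:
        clash = set(self.required_pos) & set(self.required_neg)
        if clash:
            raise ValueError(
                f"rule {self.name!r}: markers both required and forbidden: {sorted(clash)}"
            )


@dataclass
class PanelDefinition:
    """Antibody panel: marker list, lineage marker sets, subtype rule table."""

    markers: tuple[str, ...]
    lineages: dict[str, tuple[str, ...]]
    subtype_rules: tuple[SubtypeRule, ...] = ()

    def validate(self) -> None:
        panel = set(self.markers)
        for lin, ms in self.lineages.items():
            missing = set(ms) - panel
            if missing:
                raise ValueError(f"lineage {lin!r} references unknown markers {sorted(missing)}")
        for rule in self.subtype_rules:
            rule.validate()
            missing = (set(rule.required_pos) | set(rule.required_neg)) - panel
            if missing:
                raise ValueError(f"rule {rule.name!r} references unknown markers {sorted(missing)}")

    @property
    def lineage_markers(self) -> frozenset:
        return frozenset(m for ms in self.lineages.values() for m in ms)


@dataclass
class PositivityMatrix:
    """Boolean cells × markers matrix plus the per-marker threshold used."""

    calls: pd.DataFrame
    thresholds: pd.Series


def default_panel() -> PanelDefinition:
    """The default pan-immune + stromal panel.

    Lineage marker sets follow the convention of IMC lung-cancer panels:
    endothelial (CD31), epithelial (panCK), T-cell subsets (CD45/CD3 plus
    CD4 or CD8a), B cells (CD45/CD79a/CD20), monocytes, macrophages, other
    myeloid and leukocyte catch-alls, and αSMA⁺ mesenchymal cells
    (Vimentin/αSMA).
    """
    markers = (
        "panCK", "CD31", "CD45", "CD3", "CD4", "CD8a", "CD20", "CD79a", "CD38",
        "CD68", "CD163", "CD206", "CD11b", "CD14", "MPO", "aSMA", "Vimentin",
        "CD45RA", "GZMB", "CD103", "CD57", "CD39", "FOXP3", "CD27", "CCR7", "TCRd",
    )
    lineages = {
        "endothelial": ("CD31",),
        "epithelial": ("panCK",),
        "CD4 T cell": ("CD45", "CD3", "CD4"),
        "CD8 T cell": ("CD45", "CD3", "CD8a"),
        "T cell other": ("CD45", "CD3"),
        "B cell": ("CD45", "CD79a", "CD20"),
        "monocyte": ("CD45", "CD11b", "CD14"),
        "macrophage": ("CD45", "CD11b", "CD14", "CD68", "CD206", "CD163"),
        "myeloid other": ("CD45", "CD11b"),
        "leukocyte other": ("CD45",),
        "aSMA+ cell": ("Vimentin", "aSMA"),
        "Vim+ cell": ("Vimentin",),
    }
    t_parents = ("CD4 T cell", "CD8 T cell", "T cell other")
    myeloid_parents = ("myeloid other", "monocyte", "macrophage", "leukocyte other")
    b_parents = ("B cell", "leukocyte other")
    rules = (
        SubtypeRule("CD163+CD206+ macrophage", ("macrophage",), ("CD68", "CD206", "CD163")),
        SubtypeRule("CD163- macrophage", ("macrophage",), ("CD68",), ("CD163",)),
        SubtypeRule("neutrophil", myeloid_parents, ("CD11b", "MPO"),
                    ("CD14", "CD68", "CD163", "CD206")),
        SubtypeRule("myeloid other", myeloid_parents, ("CD11b",), ("MPO", "CD14", "CD68")),
        SubtypeRule("plasma cell", b_parents, ("CD79a", "CD38")),
        SubtypeRule("B cell", b_parents, ("CD79a", "CD20")),
        SubtypeRule("B cell lineage other", b_parents, ("CD79a",), ("CD20", "CD38")),
        SubtypeRule("Tgd", t_parents, ("CD3", "TCRd")),
        SubtypeRule("Treg", t_parents, ("FOXP3",)),
        SubtypeRule("exhausted td T cell", t_parents, ("CD57", "CD39")),
        SubtypeRule("Tem", t_parents, ("CD27",), ("CCR7",)),
        SubtypeRule("Tcm", t_parents, ("CCR7",)),
        SubtypeRule("naive T cell", t_parents, ("CD45RA",)),
        SubtypeRule("cytotoxic T cell", t_parents, ("GZMB",)),
        SubtypeRule("Trm", t_parents, ("CD103",)),
        SubtypeRule("CD57 T cell", t_parents, ("CD57",)),
        SubtypeRule("aSMA+ fibroblast", ("aSMA+ cell",), ("aSMA",)),
    )
    panel = PanelDefinition(markers=markers, lineages=lineages, subtype_rules=rules)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# positivity


def _two_component_threshold(x: np.ndarray, quantile: float) -> float:
    """Intensity cutoff separating the two log-intensity mixture components.

    Falls back to the per-marker quantile when the fit is degenerate
    (components unseparated or one component nearly empty).
    """
    logx = np.log(np.maximum(x, 1e-6))
    if np.ptp(logx) < 1e-9:
        return np.inf
    gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(logx.reshape(-1, 1))
    means = gm.means_.ravel()
    order = np.argsort(means)
    lo, hi = means[order]
    sd = float(np.sqrt(gm.covariances_.ravel()[order].mean()))
    weights = gm.weights_[order]
    if hi - lo < 1.0 * sd or weights.min() < 0.01:
        return float(np.quantile(x, quantile))
    # posterior-0.5 crossing between the component means, found on a grid
    grid = np.linspace(lo, hi, 513).reshape(-1, 1)
    post_hi = gm.predict_proba(grid)[:, order[1]]
    cross = np.searchsorted(post_hi >= 0.5, True)
    cut = float(grid[min(cross, len(grid) - 1), 0])
    return float(np.exp(cut))


def call_positivity(
    intensities: pd.DataFrame,
    method: str = "two-component",
    quantile: float = 0.9,
) -> PositivityMatrix:
    """Call per-marker positivity from a cells × markers intensity matrix.

    ``method='two-component'`` fits a two-component Gaussian mixture to the
    log intensities of each marker and thresholds at the posterior-0.5
    crossing; ``method='quantile'`` thresholds at the given quantile.
    A call is positive iff intensity > threshold, so positivity is monotone
    in intensity. All-zero (or constant) columns yield no positive calls and
    a warning.
    """
    if len(intensities) == 0:
        raise ValueError("need at least one cell")
    if (intensities.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    thresholds = {}
    for m in intensities.columns:
        x = intensities[m].to_numpy(float)
        if np.ptp(x) < 1e-12:
            warnings.warn(f"marker {m!r}: constant intensity column, all cells negative")
            thresholds[m] = np.inf
            continue
        if method == "quantile":
            thresholds[m] = float(np.quantile(x, quantile))
        elif method == "two-component":
            thresholds[m] = _two_component_threshold(x, quantile)
        else:
            raise ValueError(f"unknown method {method!r}")
    thr = pd.Series(thresholds)
    calls = intensities.gt(thr, axis=1)
    return PositivityMatrix(calls=calls, thresholds=thr)


# ---------------------------------------------------------------------------
# lineage and subtype


def assign_major_lineage(positivity: PositivityMatrix | pd.DataFrame, panel: PanelDefinition) -> pd.Series:
    """Assign each cell the best-matching major lineage.

    Score for lineage L = (#required markers positive)
    − (#required markers negative)
    − (#positive lineage-defining markers outside L's set).
    The highest score wins; ties go to the larger marker set (most specific)
    then panel order. Cells with no positive-scoring lineage are 'unassigned'.
    """
    if not panel.lineages:
        raise ValueError("panel has no lineages")
    calls = positivity.calls if isinstance(positivity, PositivityMatrix) else positivity
    lin_markers = panel.lineage_markers
    names = list(panel.lineages)
    pos = calls.to_numpy(bool)
    cols = {m: i for i, m in enumerate(calls.columns)}
    n = len(calls)
    scores = np.zeros((n, len(names)))
    for j, lin in enumerate(names):
        req = [m for m in panel.lineages[lin] if m in cols]
        other = [m for m in lin_markers - set(panel.lineages[lin]) if m in cols]
        matched = pos[:, [cols[m] for m in req]].sum(axis=1) if req else 0
        missing = len(req) - matched
        violated = pos[:, [cols[m] for m in other]].sum(axis=1) if other else 0
        scores[:, j] = matched - missing - violated
    # tie-breaks: specificity (marker-set size), then panel order
    sizes = np.array([len(panel.lineages[l]) for l in names])
    order_bonus = (sizes * len(names) - np.arange(len(names))) * 1e-6
    best = np.argmax(scores + order_bonus[None, :], axis=1)
    labels = np.where(scores[np.arange(n), best] > 0, np.array(names)[best], "unassigned")
    return pd.Series(labels, index=calls.index, name="lineage")


def assign_subtype(
    lineages: pd.Series,
    positivity: PositivityMatrix | pd.DataFrame,
    panel: PanelDefinition,
) -> pd.Series:
    """Refine lineage labels into subtypes via the panel rule table.

    Rules apply only to cells of their parent lineages and require all
    required-positive markers positive and all required-negative markers
    negative. The most specific rule (largest required-positive set) wins;
    ties break by rule-table order. Cells matching no rule keep their
    lineage label.
    """
    panel.validate()
    calls = positivity.calls if isinstance(positivity, PositivityMatrix) else positivity
    labels = lineages.astype(object).copy()
    ranked = sorted(
        enumerate(panel.subtype_rules),
        key=lambda t: (-len(t[1].required_pos), t[0]),
    )
    assigned = pd.Series(False, index=lineages.index)
    for _, rule in ranked:
        mask = lineages.isin(rule.parents) & ~assigned
        for m in rule.required_pos:
            mask &= calls[m] if m in calls.columns else False
        for m in rule.required_neg:
            mask &= ~calls[m] if m in calls.columns else True
        labels[mask] = rule.name
        assigned |= mask
    return labels.rename("subtype")


# ---------------------------------------------------------------------------
# pathology masks


def _lookup_mask(mask: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xi = np.floor(x).astype(int)
    yi = np.floor(y).astype(int)
    h, w = mask.shape
    if ((xi < 0) | (xi >= w) | (yi < 0) | (yi >= h)).any():
        raise ValueError("cell centers fall outside the mask bounds; frame mismatch?")
    return mask[yi, xi] > 0


def apply_pathology_labels(
    cells: pd.DataFrame,
    tumor_mask: np.ndarray | None = None,
    vessel_mask: np.ndarray | None = None,
    alveolar_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Apply pathology-annotation masks by point-in-mask tests on cell centers.

    * αSMA⁺ cells (cell_type containing 'aSMA') inside the large-vessel mask
      are flagged perivascular;
    * CD163+CD206+ macrophages inside the alveolar-macrophage mask are
      relabeled 'alveolar macrophage';
    * epithelial/tumor cells inside the tumor mask get ``tumor_cell=True``
      (False outside or when the mask is absent and no prior flag exists).

    Masks are label images in the same μm frame as the coordinates
    (1 px = 1 μm, origin top-left).
    """
    out = cells.copy()
    x = out["x_um"].to_numpy(float)
    y = out["y_um"].to_numpy(float)
    if vessel_mask is not None:
        in_vessel = _lookup_mask(vessel_mask, x, y)
        is_asma = out["cell_type"].str.contains("aSMA", regex=False).to_numpy()
        out["perivascular"] = in_vessel & is_asma
    elif "perivascular" not in out.columns:
        out["perivascular"] = False
    if alveolar_mask is not None:
        in_alv = _lookup_mask(alveolar_mask, x, y)
        is_m2 = out["cell_type"].eq("CD163+CD206+ macrophage").to_numpy()
        out.loc[in_alv & is_m2, "cell_type"] = "alveolar macrophage"
    if tumor_mask is not None:
        in_tumor = _lookup_mask(tumor_mask, x, y)
        is_epi = out["cell_type"].isin(["epithelial", "tumor"]).to_numpy()
        out["tumor_cell"] = in_tumor & is_epi & ~out["perivascular"].to_numpy()
    elif "tumor_cell" not in out.columns:
        out["tumor_cell"] = False
    return out
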