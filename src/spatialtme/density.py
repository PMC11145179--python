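"""Tissue-compartment assignment and compartment-wise cell-density matrices.

Densities are cell counts normalized by imaged tissue area: for each core
and cell class we report cells/mm² separately in the tumor-nest and stroma
compartments and in the total imaged tissue (sum of compartment areas).
Background (unstained air space) contributes neither cells nor area.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["assign_compartment", "compute_densities", "robust_z", "COMPARTMENTS"]

COMPARTMENTS = ("tumor_nest", "stroma")
_MASK_LABELS = {0: "background", 1: "tumor_nest", 2: "stroma"}


def assign_compartment(cells: pd.DataFrame, mask: np.ndarray | None = None) -> pd.DataFrame:
    """Label every cell tumor_nest / stroma / background.

    With ``mask`` (label image, 0 background / 1 tumor nest / 2 stroma, same
    μm frame as the coordinates) the label at each cell center is used;
    without a mask an existing ``compartment`` column is required.
    """
    out = cells.copy()
    if mask is None:
        if "compartment" not in out.columns:
            raise ValueError("no compartment mask and no 'compartment' column")
        return out
    xi = np.floor(out["x_um"].to_numpy(float)).astype(int)
    yi = np.floor(out["y_um"].to_numpy(float)).astype(int)
    h, w = mask.shape
    if ((xi < 0) | (xi >= w) | (yi < 0) | (yi >= h)).any():
        raise ValueError("cell centers fall outside the mask bounds")
    lab = mask[np.clip(yi, 0, h - 1), np.clip(xi, 0, w - 1)]
    out["compartment"] = pd.Series(lab, index=out.index).map(_MASK_LABELS).fillna("background")
    return out


def compute_densities(
    cells: pd.DataFrame,
    areas: pd.DataFrame,
    class_column: str = "cell_type",
) -> pd.DataFrame:
    """Per-core density matrix: columns ``<class>__<compartment>`` in cells/mm².

    ``areas`` must be indexed by image_id with columns ``tumor_nest`` and
    ``stroma`` in mm². The ``total`` compartment divides the summed count by
    the summed area. A compartment with zero area yields NaN densities (and
    is an error if it nevertheless contains cells). Metadata columns
    (patient_id) are carried through; areas are stored in ``.attrs['areas']``.
    """
    for comp in COMPARTMENTS:
        if comp not in areas.columns:
            raise ValueError(f"areas missing column {comp!r}")
    if (areas[list(COMPARTMENTS)].to_numpy() < 0).any():
        raise ValueError("areas must be >= 0")
    body = cells[cells["compartment"].isin(COMPARTMENTS)]
    counts = (
        body.groupby(["image_id", class_column, "compartment"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    classes = sorted(body[class_column].unique())
    rows = {}
    for img in areas.index:
        a_nest = float(areas.loc[img, "tumor_nest"])
        a_stroma = float(areas.loc[img, "stroma"])
        a_tot = a_nest + a_stroma
        sub = counts[counts["image_id"] == img]
        row = {}
        for cls in classes:
            c = sub[sub[class_column] == cls].set_index("compartment")["n"]
            n_nest = int(c.get("tumor_nest", 0))
            n_stroma = int(c.get("stroma", 0))
            for comp, n, a in (
                ("tumor_nest", n_nest, a_nest),
                ("stroma", n_stroma, a_stroma),
                ("total", n_nest + n_stroma, a_tot),
            ):
                if a <= 0:
                    if n > 0:
                        raise ValueError(
                            f"core {img}: {n} cells in zero-area compartment {comp}"
                        )
                    row[f"{cls}__{comp}"] = np.nan
                else:
                    row[f"{cls}__{comp}"] = n / a
        rows[img] = row
    mat = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    mat.index.name = "image_id"
    meta_cols = [c for c in ("patient_id", "tumor_id", "histology") if c in cells.columns]
    if meta_cols:
        meta = cells.groupby("image_id")[meta_cols].first()
        mat = mat.join(meta)
    mat.attrs["areas"] = areas.copy()
    return mat


def robust_z(
    matrix: pd.DataFrame,
    mode: str = "robust",
    consistency: bool = False,
) -> pd.DataFrame:
    """Column-wise normalization of a density matrix.

    ``robust`` mode centers by the median and scales by the median absolute
    deviation (MAD), by default WITHOUT the 1.4826 Gaussian consistency
    factor; pass ``consistency=True`` to enable it. ``standard`` mode is the
    ordinary z-score. Constant columns (zero scale) are returned as zeros
    with a warning. Non-numeric metadata columns pass through unchanged.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to normalize")
    num = matrix.select_dtypes(include=[np.number])
    rest = matrix.drop(columns=num.columns)
    x = num.to_numpy(float)
    if mode == "robust":
        center = np.nanmedian(x, axis=0)
        scale = np.nanmedian(np.abs(x - center), axis=0)
        if consistency:
            scale = scale * 1.4826
    elif mode == "standard":
        center = np.nanmean(x, axis=0)
        scale = np.nanstd(x, axis=0, ddof=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    degenerate = ~(scale > 0)
    if degenerate.any():
        bad = list(num.columns[degenerate])
        warnings.warn(f"zero scale in columns {bad}; values set to 0")
        scale = np.where(degenerate, 1.0, scale)
        z = (x - center) / scale
        z[:, degenerate] = 0.0
    else:
        z = (x - center) / scale
    out = pd.DataFrame(z, index=num.index, columns=num.columns)
    out = pd.concat([out, rest], axis=1)[matrix.columns]
    out.attrs = dict(matrix.attrs)
    return out
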