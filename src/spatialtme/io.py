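"""Cell-table I/O, pipeline configuration, and the end-to-end driver.

Cell tables travel as CSV (the de-facto interchange emitted by IMC
segmentation pipelines), compartment masks as TIFF label images, fitted
models as JSON. ``run_pipeline`` chains the stages on a synthetic cohort
and stamps every artifact directory with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

log = logging.getLogger("spatialtme")

__all__ = ["read_cell_table", "write_cell_table", "PipelineConfig", "run_pipeline"]

REQUIRED_COLUMNS = ("cell_id", "image_id", "patient_id", "x_um", "y_um")


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell-table CSV.

    Requires ``cell_id``, ``image_id``, ``patient_id``, ``x_um``, ``y_um``
    plus either marker (``marker__*``) or type (``cell_type``) columns.
    Raises descriptive errors on missing columns, non-numeric coordinates,
    or duplicate cell ids.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing required columns: {missing}")
    for c in ("x_um", "y_um"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "cell_id"].iloc[0]
            raise ValueError(f"non-numeric coordinate {c} for cell {bad!r}")
        df[c] = vals
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell_id {dup.iloc[0]!r}")
    has_markers = any(c.startswith("marker__") for c in df.columns)
    if not has_markers and "cell_type" not in df.columns:
        raise ValueError("cell table needs marker__* columns or a cell_type column")
    return df


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def write_label_mask(mask: np.ndarray, path) -> None:
    """Write a label mask (0 background / 1 tumor nest / 2 stroma, 1 px = 1 μm)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_label_mask(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


_STAGE_DEFAULTS = {
    "synthetic": {},
    "phenotyping": {"method": "two-component", "quantile": 0.9},
    "communities": {"window_size": 10, "k": 10},
    "tme": {"k": 4, "reps": 1000, "subsample": 0.75},
    "barrier": {"knn": 5, "eps": 25.0, "min_cells": 3,
                "min_cluster_area_um2": 2000.0, "mode": "indicator"},
    "interactions": {"n_perm": 1000, "alpha": 0.05, "radius_um": 5.0},
    "heterogeneity": {"reps": 1000, "n_samples": [2, 3, 4]},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    log_level: str = "INFO"
    synthetic: dict = field(default_factory=dict)
    phenotyping: dict = field(default_factory=dict)
    communities: dict = field(default_factory=dict)
    tme: dict = field(default_factory=dict)
    barrier: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)
    heterogeneity: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for stage, defaults in _STAGE_DEFAULTS.items():
            params = getattr(cfg, stage)
            if stage != "synthetic":
                bad = set(params) - set(defaults)
                if bad:
                    raise ValueError(f"unknown keys in {stage!r} config: {sorted(bad)}")
            merged = {**defaults, **params}
            applied = {k: v for k, v in defaults.items() if k not in params}
            if applied:
                log.debug("stage %s: defaults applied: %s", stage, applied)
            setattr(cfg, stage, merged)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _synthetic_config(cfg: PipelineConfig):
    from spatialtme.synthetic import SyntheticConfig

    params = dict(cfg.synthetic)
    params.setdefault("rng_seed", cfg.seed)
    if "cores_per_patient" in params:
        params["cores_per_patient"] = tuple(params["cores_per_patient"])
    if "planted_tme_class" in params and isinstance(params["planted_tme_class"], tuple):
        params["planted_tme_class"] = list(params["planted_tme_class"])
    if "densities" in params and params["densities"] is not None:
        params["densities"] = {tuple(k.split("|")): v for k, v in params["densities"].items()}
    return SyntheticConfig(**params)


def core_areas_from_truth(truth, core_diameter_um: float = 1500.0) -> pd.DataFrame:
    """Compartment areas (mm²) per core from the generator's nest geometry."""
    import math

    R = core_diameter_um / 2.0
    disc_area = math.pi * R * R
    rows = {}
    for img, nests in truth.nests.items():
        nest_area = shapely.unary_union(nests).area if nests else 0.0
        rows[img] = {
            "tumor_nest": nest_area / 1e6,
            "stroma": (disc_area - nest_area) / 1e6,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "image_id"
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full stack on a synthetic cohort and write all artifacts.

    Stages, in order: simulate → phenotype → densities → TME classification
    → communities → barrier → heterogeneity. Any stage failure aborts with
    the stage name and cause. Every run writes ``run_meta.json`` with the
    config hash and seed; reruns with the same config and seed are
    bit-identical.
    """
    from spatialtme import (
        assign_major_lineage, assign_subtype, barrier, build_tme_model,
        build_windows, call_positivity, class_homogeneity_probability,
        compute_densities, default_panel, fit_communities, generate_cohort,
        ith_score,
    )
    from spatialtme.barrier import barrier_scores_by_core

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        syn_cfg = _synthetic_config(config)
        cells, truth = generate_cohort(syn_cfg)
        write_cell_table(cells, out / "cells.csv")
        truth.to_json(out / "ground_truth.json")

        stage = "phenotype"
        panel = default_panel()
        markers = [c for c in cells.columns if c.startswith("marker__")]
        intens = cells[markers].rename(columns=lambda c: c.removeprefix("marker__"))
        intens = intens[[m for m in panel.markers if m in intens.columns]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            posmat = call_positivity(intens, method=config.phenotyping["method"],
                                     quantile=config.phenotyping["quantile"])
            lineage = assign_major_lineage(posmat, panel)
            subtype = assign_subtype(lineage, posmat, panel)
        pheno = cells.copy()
        pheno["lineage"] = lineage.to_numpy()
        pheno["subtype"] = subtype.to_numpy()
        write_cell_table(pheno, out / "cells_phenotyped.csv")

        stage = "densities"
        areas = core_areas_from_truth(truth, syn_cfg.core_diameter_um)
        dens = compute_densities(cells, areas)
        dens.to_csv(out / "densities.csv")

        stage = "tme"
        model = build_tme_model(
            dens, k=config.tme["k"], reps=config.tme["reps"],
            subsample=config.tme["subsample"], seed=config.seed,
        )
        with open(out / "tme_model.json", "w") as fh:
            json.dump(model.to_json_dict(), fh, indent=1)
        labeled = dens.copy()
        labeled["tme_class"] = model.labels_
        labeled.to_csv(out / "densities_tme.csv")

        stage = "communities"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            windows = build_windows(cells, W=config.communities["window_size"])
            cmodel = fit_communities(windows, k=min(config.communities["k"], len(windows)),
                                     seed=config.seed)
        cmodel.assignments.rename("community").to_frame().to_csv(out / "communities.csv")
        with open(out / "community_model.json", "w") as fh:
            json.dump(cmodel.to_json_dict(), fh, indent=1)

        stage = "barrier"
        bar = barrier_scores_by_core(
            cells, mode=config.barrier["mode"], k=config.barrier["knn"],
            eps=config.barrier["eps"], min_cells=config.barrier["min_cells"],
            min_cluster_area_um2=config.barrier["min_cluster_area_um2"],
        )
        bar.to_csv(out / "barrier_scores.csv")

        stage = "heterogeneity"
        ith = ith_score(dens.drop(columns=["patient_id"], errors="ignore")
                        .join(dens["patient_id"]) if "patient_id" in dens.columns else dens,
                        grouping="patient_id")
        ith.to_csv(out / "ith_scores.csv")
        hom_in = labeled.reset_index()[["image_id", "patient_id", "tme_class"]]
        hom = class_homogeneity_probability(
            hom_in, reps=config.heterogeneity["reps"],
            n_samples=tuple(config.heterogeneity["n_samples"]), seed=config.seed,
        )
        hom.to_csv(out / "tme_homogeneity.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "config": config.to_dict()}
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    return out
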