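"""Synthetic multi-core, multi-patient tissue generator with planted ground truth.

Emulates the acquisition geometry of a tissue-microarray (TMA) imaging
mass-cytometry experiment: circular 1.5 mm cores at 1 μm/px, irregular
epithelial tumor nests embedded in stroma, and configurable per-class cell
densities per compartment.  Planted structure — a tumor-microenvironment
(TME) archetype per core, spatial community domains, and αSMA⁺ fibroblast
barrier rings along nest boundaries — is recorded in a :class:`GroundTruth`
object so downstream estimators can be scored against it.

The generator emits the same cell-table currency the rest of the package
consumes: one row per cell with μm coordinates, a generating cell class,
compartment label, marker intensities drawn from a two-component log-normal
mixture per marker, and the generating positivity flags.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_core",
    "generate_cohort",
    "plant_barrier",
    "render_compartment_mask",
    "CLASS_MARKERS",
    "TME_ARCHETYPES",
    "TME_CLASSES",
]

#: Marker sets that each generating class expresses (positive component).
#: Chosen so the rule-based phenotyping pipeline can recover every class.
CLASS_MARKERS: dict[str, tuple[str, ...]] = {
    "tumor": ("panCK",),
    "endothelial": ("CD31",),
    "CD4 T cell": ("CD45", "CD3", "CD4"),
    "CD8 T cell": ("CD45", "CD3", "CD8a"),
    "B cell": ("CD45", "CD79a", "CD20"),
    "CD163+CD206+ macrophage": ("CD45", "CD11b", "CD14", "CD68", "CD206", "CD163"),
    "CD163- macrophage": ("CD45", "CD11b", "CD14", "CD68"),
    "neutrophil": ("CD45", "CD11b", "MPO"),
    "monocyte": ("CD45", "CD11b", "CD14"),
    "myeloid other": ("CD45", "CD11b"),
    "aSMA+ fibroblast": ("Vimentin", "aSMA"),
}

ALL_MARKERS: tuple[str, ...] = tuple(
    dict.fromkeys(m for ms in CLASS_MARKERS.values() for m in ms)
)

TME_CLASSES = (
    "TS:TIL+MP high",
    "T:TIL+MP excluded",
    "TS:Immune low",
    "TS:Neutrophil high",
)

# Per-archetype target densities in cells/mm² per (class, compartment).
# TIL = CD8 + CD4 + B lineage; B cells are stromal only. Magnitudes follow
# typical NSCLC TMA single-cell densities (total ~2,000-5,000 cells/mm²).
_TIL_SPLIT = {"CD8 T cell": 0.55, "CD4 T cell": 0.35, "B cell": 0.10}
_MAC_SPLIT = {"CD163+CD206+ macrophage": 0.6, "CD163- macrophage": 0.4}


def _archetype(til_nest, til_stroma, mac_nest, mac_stroma, neut_nest, neut_stroma):
    dens: dict[tuple[str, str], float] = {}
    for cls, f in _TIL_SPLIT.items():
        if cls == "B cell":
            dens[(cls, "stroma")] = til_stroma * f
        else:
            dens[(cls, "tumor_nest")] = til_nest * f / (1 - 0.10)
            dens[(cls, "stroma")] = til_stroma * f
    for cls, f in _MAC_SPLIT.items():
        dens[(cls, "tumor_nest")] = mac_nest * f
        dens[(cls, "stroma")] = mac_stroma * f
    dens[("neutrophil", "tumor_nest")] = neut_nest
    dens[("neutrophil", "stroma")] = neut_stroma
    # structural populations shared by every archetype
    dens[("tumor", "tumor_nest")] = 2500.0
    dens[("endothelial", "stroma")] = 250.0
    dens[("aSMA+ fibroblast", "stroma")] = 200.0
    dens[("myeloid other", "stroma")] = 50.0
    dens[("monocyte", "stroma")] = 60.0
    return dens


TME_ARCHETYPES: dict[str, dict[tuple[str, str], float]] = {
    "TS:TIL+MP high": _archetype(300, 350, 200, 220, 40, 60),
    "T:TIL+MP excluded": _archetype(60, 700, 60, 400, 40, 60),
    "TS:Immune low": _archetype(30, 60, 30, 50, 20, 30),
    "TS:Neutrophil high": _archetype(100, 140, 100, 110, 180, 260),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Densities are targets in cells/mm² keyed by ``(cell class, compartment)``
    with compartment one of ``tumor_nest``/``stroma``; realized counts are
    Poisson around ``area × density``.  ``planted_tme_class`` may be a single
    TME label (all cores), a list (assigned round-robin across a tumor's
    cores), or ``None`` (neutral mid-level immune infiltrate).
    """

    n_patients: int = 2
    cores_per_patient: tuple[int, int] = (2, 2)
    core_diameter_um: float = 1500.0
    n_nests: int = 3
    nest_radius_um: tuple[float, float] = (120.0, 280.0)
    nest_irregularity: float = 0.25
    densities: dict[tuple[str, str], float] | None = None
    planted_tme_class: str | list[str] | None = None
    barrier_coverage: float = 0.0
    barrier_thickness_um: float = 10.0
    community_spec: list[dict[tuple[str, str], float]] | None = None
    density_cv: float = 0.15
    marker_separation: float = 10.0
    marker_sigma: float = 0.35
    min_spacing_um: float = 4.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.core_diameter_um <= 0:
            raise ValueError("core_diameter_um must be > 0")
        if not (1 <= self.cores_per_patient[0] <= self.cores_per_patient[1] <= 8):
            raise ValueError("cores_per_patient range must lie in 1..8")
        if not 0.0 <= self.barrier_coverage <= 1.0:
            raise ValueError("barrier_coverage must be in [0, 1]")
        if self.densities is not None and any(d < 0 for d in self.densities.values()):
            raise ValueError("densities must be >= 0")
        classes = set(self.planted_tme_class) if isinstance(self.planted_tme_class, list) else (
            {self.planted_tme_class} if self.planted_tme_class else set()
        )
        unknown = classes - set(TME_CLASSES)
        if unknown:
            raise ValueError(f"unknown TME class(es): {sorted(unknown)}")

    def resolve_densities(self, tme_class: str | None) -> dict[tuple[str, str], float]:
        if self.densities is not None:
            return dict(self.densities)
        if tme_class is not None:
            return dict(TME_ARCHETYPES[tme_class])
        return _archetype(200, 300, 120, 150, 20, 40)


@dataclass
class GroundTruth:
    """Planted generative labels emitted alongside a synthetic cell table.

    ``cells`` is indexed by cell_id with columns ``true_class``,
    ``community_id`` (-1 when no community was planted) and
    ``barrier_member``; ``cores`` has one row per image with the planted TME
    class; ``nests`` maps image_id to the list of tumor-nest polygons.
    """

    cells: pd.DataFrame
    cores: pd.DataFrame
    nests: dict[str, list[Polygon]] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        dup = set(self.cells.index) & set(other.cells.index)
        if dup:
            raise ValueError(f"duplicate cell ids across cores: {sorted(dup)[:5]}")
        return GroundTruth(
            cells=pd.concat([self.cells, other.cells]),
            cores=pd.concat([self.cores, other.cores], ignore_index=True),
            nests={**self.nests, **other.nests},
        )

    def to_json(self, path) -> None:
        payload = {
            "cells": {
                cid: {
                    "true_class": row.true_class,
                    "community_id": int(row.community_id),
                    "barrier_member": bool(row.barrier_member),
                }
                for cid, row in self.cells.iterrows()
            },
            "cores": self.cores.to_dict(orient="records"),
            "nests": {
                img: [list(map(list, p.exterior.coords)) for p in polys]
                for img, polys in self.nests.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cells = pd.DataFrame.from_dict(payload["cells"], orient="index")
        cells.index.name = "cell_id"
        nests = {
            img: [Polygon(coords) for coords in polys]
            for img, polys in payload["nests"].items()
        }
        return cls(cells=cells, cores=pd.DataFrame(payload["cores"]), nests=nests)


# ---------------------------------------------------------------------------
# geometry helpers


def _nest_polygons(cfg: SyntheticConfig, rng: np.random.Generator) -> list[Polygon]:
    """Irregular tumor-nest blobs: jittered-radius stars clipped to the core."""
    R = cfg.core_diameter_um / 2.0
    disc = Point(R, R).buffer(R, quad_segs=64)
    polys: list[Polygon] = []
    for _ in range(cfg.n_nests):
        r0 = rng.uniform(*cfg.nest_radius_um)
        rho = rng.uniform(0, max(R - r0 * 0.5, 1.0))
        phi = rng.uniform(0, 2 * math.pi)
        cx, cy = R + rho * math.cos(phi), R + rho * math.sin(phi)
        theta = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        # low-order harmonic perturbation gives a smooth irregular boundary
        pert = np.zeros_like(theta)
        for h in (2, 3, 5):
            pert += rng.uniform(0, 1) * np.cos(h * theta + rng.uniform(0, 2 * math.pi))
        pert /= max(np.abs(pert).max(), 1e-9)
        radii = r0 * (1.0 + cfg.nest_irregularity * pert)
        poly = Polygon(np.c_[cx + radii * np.cos(theta), cy + radii * np.sin(theta)])
        poly = poly.buffer(0).intersection(disc)
        if poly.is_empty:
            continue
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        polys.append(poly)
    return polys


class _SpacingGrid:
    """Occupancy grid enforcing a minimum inter-cell distance (dart throwing)."""

    def __init__(self, extent: float, spacing: float):
        self.spacing = spacing
        self.cell = spacing / math.sqrt(2.0)
        self.n = int(math.ceil(extent / self.cell)) + 1
        self.grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def try_add(self, x: float, y: float, spacing: float | None = None) -> bool:
        s = self.spacing if spacing is None else spacing
        i, j = int(x / self.cell), int(y / self.cell)
        reach = int(math.ceil(s / self.cell))
        for di in range(-reach, reach + 1):
            for dj in range(-reach, reach + 1):
                for (px, py) in self.grid.get((i + di, j + dj), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < s * s:
                        return False
        self.grid.setdefault((i, j), []).append((x, y))
        return True


def _packing_limit(area_um2: float, spacing: float) -> float:
    # hexagonal packing bound for points at minimum distance `spacing`
    return area_um2 / (spacing * spacing * math.sqrt(3.0) / 2.0)


def _sector_of(x, y, center, k):
    ang = np.arctan2(y - center, x - center) % (2 * math.pi)
    return np.minimum((ang / (2 * math.pi) * k).astype(int), k - 1)


# ---------------------------------------------------------------------------
# core generation


def generate_core(
    config: SyntheticConfig,
    seed: int,
    image_id: str = "core_0",
    patient_id: str = "P000",
    tme_class: str | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one synthetic TMA core.

    Returns a cell table (one row per cell, coordinates in μm with origin at
    the top-left of the bounding square, 1 μm = 1 px) and the matching
    :class:`GroundTruth`.  Cells lie inside the core disc, respect the
    configured minimum spacing, and carry marker intensities drawn from the
    two-component log-normal model plus the generating positivity flags.

    Raises ``ValueError`` when a requested density exceeds the packing limit
    at the minimum cell spacing.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    R = config.core_diameter_um / 2.0
    center = R
    disc = Point(R, R).buffer(R, quad_segs=64)
    nests = _nest_polygons(config, rng)
    nest_union = shapely.unary_union(nests) if nests else Polygon()
    nest_area = nest_union.area
    stroma_area = disc.area - nest_area

    if tme_class is None and not isinstance(config.planted_tme_class, list):
        tme_class = config.planted_tme_class
    dens = config.resolve_densities(tme_class)

    k_comm = len(config.community_spec) if config.community_spec else 0

    grid = _SpacingGrid(config.core_diameter_um, config.min_spacing_um)
    # per-core biological variability: lognormal multiplier per (class, comp)
    cv_sigma = math.sqrt(math.log(1.0 + config.density_cv**2)) if config.density_cv > 0 else 0.0
    records: list[dict] = []
    idx = 0
    for (cls, comp), d in sorted(dens.items()):
        if d <= 0:
            continue
        if cv_sigma > 0:
            d = d * math.exp(rng.normal(0.0, cv_sigma))
        area_um2 = nest_area if comp == "tumor_nest" else stroma_area
        if area_um2 <= 0:
            continue
        # with planted communities, thin a homogeneous process at the
        # sector-maximum rate down to each sector's own rate
        if k_comm and cls != "tumor":
            rates = np.array(
                [spec.get((cls, comp), d) for spec in config.community_spec], float
            )
        else:
            rates = np.array([d], float)
        d_max = float(rates.max())
        if d_max <= 0:
            continue
        expected = d_max * area_um2 / 1e6
        if expected > 0.55 * _packing_limit(area_um2, config.min_spacing_um):
            raise ValueError(
                f"density {d_max:.0f}/mm² for {cls} in {comp} exceeds the packing "
                f"limit at {config.min_spacing_um} μm minimum spacing"
            )
        n_target = rng.poisson(expected)
        placed = 0
        attempts = 0
        max_attempts = 200 * n_target + 1000
        geom = nest_union if comp == "tumor_nest" else None
        while placed < n_target and attempts < max_attempts:
            attempts += 1
            x = rng.uniform(0, 2 * R)
            y = rng.uniform(0, 2 * R)
            if (x - R) ** 2 + (y - R) ** 2 > R * R:
                continue
            in_nest = bool(shapely.contains_xy(nest_union, x, y)) if nests else False
            if (comp == "tumor_nest") != in_nest:
                continue
            if len(rates) > 1:
                s = int(_sector_of(np.array([x]), np.array([y]), center, len(rates))[0])
                if rng.uniform() * d_max > rates[s]:
                    continue
            else:
                s = -1
            if not grid.try_add(x, y):
                continue
            records.append(
                {
                    "cell_id": f"{image_id}_c{idx}",
                    "image_id": image_id,
                    "patient_id": patient_id,
                    "x_um": x,
                    "y_um": y,
                    "cell_type": cls,
                    "compartment": comp,
                    "community_id": s,
                    "barrier_member": False,
                }
            )
            idx += 1
            placed += 1
        if placed < n_target:
            warnings.warn(
                f"placed {placed}/{n_target} {cls} cells in {comp} of {image_id}"
            )

    cells = pd.DataFrame(
        records,
        columns=[
            "cell_id", "image_id", "patient_id", "x_um", "y_um",
            "cell_type", "compartment", "community_id", "barrier_member",
        ],
    )
    if k_comm:
        # planted community id follows the angular sector for every cell
        cells["community_id"] = _sector_of(
            cells["x_um"].to_numpy(), cells["y_um"].to_numpy(), center, k_comm
        ) if len(cells) else cells["community_id"]

    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "true_class": cells["cell_type"].to_numpy(),
                "community_id": cells["community_id"].to_numpy()
                if len(cells)
                else np.array([], dtype=int),
                "barrier_member": cells["barrier_member"].to_numpy()
                if len(cells)
                else np.array([], dtype=bool),
            },
            index=pd.Index(cells["cell_id"], name="cell_id"),
        ),
        cores=pd.DataFrame(
            [{"image_id": image_id, "patient_id": patient_id, "tme_class": tme_class}]
        ),
        nests={image_id: nests},
    )
    cells = cells.drop(columns=["community_id"])

    if config.barrier_coverage > 0:
        cells, truth = plant_barrier(
            cells,
            truth,
            coverage=config.barrier_coverage,
            thickness_um=config.barrier_thickness_um,
            seed=int(rng.integers(2**31 - 1)),
        )

    cells = _attach_markers(cells, rng, config)
    cells["perivascular"] = False
    cells["tumor_cell"] = cells["cell_type"].eq("tumor")
    return cells.reset_index(drop=True), truth


def _attach_markers(cells: pd.DataFrame, rng: np.random.Generator, cfg: SyntheticConfig) -> pd.DataFrame:
    n = len(cells)
    shift = math.log(cfg.marker_separation)
    pos_sets = cells["cell_type"].map(lambda c: frozenset(CLASS_MARKERS.get(c, ())))
    for m in ALL_MARKERS:
        is_pos = np.fromiter((m in s for s in pos_sets), bool, count=n) if n else np.array([], bool)
        logint = rng.normal(0.0, cfg.marker_sigma, size=n) + shift * is_pos
        cells[f"marker__{m}"] = np.exp(logint) if n else np.array([], float)
        cells[f"pos__{m}"] = is_pos
    return cells


# ---------------------------------------------------------------------------
# barrier planting


def plant_barrier(
    cells: pd.DataFrame,
    truth: GroundTruth,
    coverage: float,
    thickness_um: float = 10.0,
    seed: int = 0,
    spacing_um: float = 5.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Place an αSMA⁺ fibroblast band along a fraction of each nest boundary.

    ``coverage`` is the fraction of each nest's perimeter covered by the ring
    (a contiguous arc with random start); the band extends ``thickness_um``
    outward from the boundary in layers ~``spacing_um`` apart.  Planted cells
    are flagged ``barrier_member`` in both the table and the ground truth.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    if coverage == 0.0:
        return cells, truth
    rng = np.random.default_rng(seed)
    image_ids = cells["image_id"].unique() if len(cells) else list(truth.nests)
    new_rows = []
    for img in image_ids:
        nests = truth.nests.get(img, [])
        if not nests:
            raise ValueError(f"core {img} has no tumor nest to plant a barrier on")
        sub = cells[cells["image_id"] == img]
        pid = sub["patient_id"].iloc[0] if len(sub) else truth.cores.set_index("image_id").loc[img, "patient_id"]
        existing = sub[["x_um", "y_um"]].to_numpy()
        from scipy.spatial import cKDTree

        tree = cKDTree(existing) if len(existing) else None
        idx0 = len(sub)
        n_layers = max(1, int(round(thickness_um / spacing_um)))
        for nest in nests:
            ring = nest.exterior
            L = ring.length
            cov_len = coverage * L
            s0 = rng.uniform(0, L)
            n_steps = max(1, int(cov_len / spacing_um))
            for step in range(n_steps):
                s = (s0 + step * spacing_um) % L
                p = ring.interpolate(s)
                q = ring.interpolate((s + 1.0) % L)
                tx, ty = q.x - p.x, q.y - p.y
                norm = math.hypot(tx, ty) or 1.0
                nx, ny = -ty / norm, tx / norm
                probe = Point(p.x + 2.0 * nx, p.y + 2.0 * ny)
                if nest.contains(probe):
                    nx, ny = -nx, -ny  # flip to point out of the nest
                for layer in range(n_layers):
                    off = (layer + 0.5) * thickness_um / n_layers
                    x = p.x + off * nx + rng.normal(0, 0.5)
                    y = p.y + off * ny + rng.normal(0, 0.5)
                    if tree is not None and tree.query([x, y], k=1)[0] < 2.0:
                        continue
                    new_rows.append(
                        {
                            "cell_id": f"{img}_b{idx0 + len(new_rows)}",
                            "image_id": img,
                            "patient_id": pid,
                            "x_um": x,
                            "y_um": y,
                            "cell_type": "aSMA+ fibroblast",
                            "compartment": "stroma",
                            "barrier_member": True,
                        }
                    )
    if not new_rows:
        return cells, truth
    add = pd.DataFrame(new_rows)
    out = pd.concat([cells, add], ignore_index=True)
    truth_add = pd.DataFrame(
        {
            "true_class": "aSMA+ fibroblast",
            "community_id": -1,
            "barrier_member": True,
        },
        index=pd.Index(add["cell_id"], name="cell_id"),
    )
    new_truth = GroundTruth(
        cells=pd.concat([truth.cells, truth_add]),
        cores=truth.cores,
        nests=truth.nests,
    )
    return out, new_truth


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a multi-patient cohort of cores with unique image/cell ids.

    Per-patient core counts are drawn uniformly from the configured range.
    When ``planted_tme_class`` is a list, classes are assigned round-robin
    over the cohort's cores (so the list also sets the class proportions);
    the per-tumor class list is recorded in the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    tables = []
    truth: GroundTruth | None = None
    lo, hi = config.cores_per_patient
    planted = config.planted_tme_class
    core_counter = 0
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        n_cores = int(rng.integers(lo, hi + 1))
        for c in range(n_cores):
            img = f"{pid}_r{c}"
            if isinstance(planted, list):
                tme = planted[core_counter % len(planted)]
            else:
                tme = planted
            core_counter += 1
            core_seed = int(rng.integers(2**31 - 1))
            cells, t = generate_core(
                config, seed=core_seed, image_id=img, patient_id=pid, tme_class=tme
            )
            tables.append(cells)
            truth = t if truth is None else truth.merge(t)
    cohort = pd.concat(tables, ignore_index=True)
    if cohort["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in cohort")
    return cohort, truth


def render_compartment_mask(truth: GroundTruth, image_id: str, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the compartment geometry: 0 background, 1 tumor nest, 2 stroma.

    The full disc interior is stroma except where a nest polygon covers it;
    pixels outside the core disc are background.  1 px = 1 μm.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    R = min(h, w) / 2.0
    mask = np.zeros(shape, dtype=np.uint8)
    inside = (xx + 0.5 - R) ** 2 + (yy + 0.5 - R) ** 2 <= R * R
    mask[inside] = 2
    nests = truth.nests.get(image_id, [])
    if nests:
        union = shapely.unary_union(nests)
        hit = shapely.contains_xy(union, (xx + 0.5).ravel(), (yy + 0.5).ravel()).reshape(shape)
        mask[hit & inside] = 1
    return mask
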