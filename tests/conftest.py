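"""Shared fixtures: synthetic cores and cohorts generated once per session."""

import warnings

import numpy as np
import pandas as pd
import pytest

import spatialtme as st

#: planted TME class sequence for the archetype-recovery cohort; excluded and
#: immune-low are the most frequent classes, as in real NSCLC cohorts
TME_PLAN = [
    "TS:TIL+MP high", "T:TIL+MP excluded", "TS:Immune low", "TS:Neutrophil high",
    "T:TIL+MP excluded", "TS:Immune low", "T:TIL+MP excluded", "TS:Immune low",
]


@pytest.fixture(scope="session")
def small_core():
    cfg = st.SyntheticConfig(n_patients=1, cores_per_patient=(1, 1))
    cells, truth = st.generate_core(cfg, seed=7)
    return cells, truth


@pytest.fixture(scope="session")
def pheno_calls(small_core):
    """Positivity / lineage / subtype computed once on the small core."""
    cells, _ = small_core
    panel = st.default_panel()
    markers = [c for c in cells.columns if c.startswith("marker__")]
    intens = cells[markers].rename(columns=lambda c: c.removeprefix("marker__"))
    intens = intens[[m for m in panel.markers if m in intens.columns]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pos = st.call_positivity(intens)
        lineage = st.assign_major_lineage(pos, panel)
        subtype = st.assign_subtype(lineage, pos, panel)
    return panel, pos, lineage, subtype


@pytest.fixture(scope="session")
def tme_cohort():
    """16 patients x 4 cores with the 4 planted TME archetypes."""
    cfg = st.SyntheticConfig(
        n_patients=16, cores_per_patient=(4, 4), planted_tme_class=TME_PLAN,
        rng_seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cells, truth = st.generate_cohort(cfg)
    from spatialtme.io import core_areas_from_truth

    dens = st.compute_densities(cells, core_areas_from_truth(truth))
    return cells, truth, dens


@pytest.fixture(scope="session")
def tme_model(tme_cohort):
    _, _, dens = tme_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return st.build_tme_model(dens, reps=250, seed=3)


def make_positions(rng, n, extent=400.0):
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:04d}" for i in range(n)],
            "image_id": "img",
            "patient_id": "P0",
            "x_um": rng.uniform(0, extent, n),
            "y_um": rng.uniform(0, extent, n),
        }
    )
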