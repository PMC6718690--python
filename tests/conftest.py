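import numpy as np
import pandas as pd
import pytest

import tamspatial as ts


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic study: 6 patients, one tile per ROI."""
    return ts.SimulationConfig(n_patients=6, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ts.generate_cohort(small_config)


@pytest.fixture(scope="session")
def labelled_cells(small_cohort):
    """Cohort cells with the ground-truth phenotype as the working label."""
    cells = small_cohort.cells.copy()
    cells["phenotype"] = cells["true_phenotype"]
    return cells


@pytest.fixture(scope="session")
def density_all(labelled_cells, small_cohort):
    return ts.density_table(labelled_cells, small_cohort.image_areas)


def make_cells(x, y, phenotype=None, compartment=None, **markers):
    """Hand-build a minimal cell table for unit tests."""
    n = len(x)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "patient_id": "P0",
            "image_id": "img0",
            "roi": "core",
            "x_um": np.asarray(x, dtype=float),
            "y_um": np.asarray(y, dtype=float),
            "compartment": compartment if compartment is not None else "stroma",
        }
    )
    for m in ts.MARKERS:
        df[m] = np.asarray(markers.get(m, np.ones(n)), dtype=float)
    if phenotype is not None:
        df["phenotype"] = phenotype
    return df
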