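import numpy as np
import pandas as pd
import pytest

from ngrscreen.plate_io import CSV_COLUMNS, ExperimentTable
from ngrscreen.synthetic_data import (
    DoseResponseTruth,
    SimulationConfig,
    simulate_plate,
)

GRID = list(np.logspace(0.0, np.log10(5000.0), 7))


def make_table(rows, dose_grid=(10.0, 100.0)):
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return ExperimentTable(df, np.asarray(dose_grid, dtype=float))


def well_row(
    plate_id="P1",
    well="A01",
    cell_line="wt",
    drug="tki",
    concentration_nM=10.0,
    timepoint_h=0.0,
    total_area=100.0,
    dead_area=0.0,
    replicate_id="r1",
):
    return dict(
        plate_id=plate_id,
        well=well,
        cell_line=cell_line,
        drug=drug,
        concentration_nM=concentration_nM,
        timepoint_h=timepoint_h,
        total_area=total_area,
        dead_area=dead_area,
        replicate_id=replicate_id,
    )


@pytest.fixture
def tiny_rows():
    """2 wells x 2 timepoints."""
    return [
        well_row(well="A01", timepoint_h=0.0, total_area=100.0),
        well_row(well="A01", timepoint_h=120.0, total_area=180.0, dead_area=20.0),
        well_row(well="A02", concentration_nM=100.0, timepoint_h=0.0, total_area=90.0),
        well_row(
            well="A02",
            concentration_nM=100.0,
            timepoint_h=120.0,
            total_area=150.0,
            dead_area=60.0,
        ),
    ]


@pytest.fixture
def tiny_table(tiny_rows):
    return make_table(tiny_rows)


@pytest.fixture(scope="session")
def clean_sim_config():
    return SimulationConfig(
        truth={("wt", "tki"): DoseResponseTruth(-0.5, 100.0, 2.0)},
        noise_cv=0.0,
        wells_per_dose=2,
        n_control_wells=4,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_plate(clean_sim_config):
    return simulate_plate(clean_sim_config)
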