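"""Shared fixtures: seeded synthetic datasets and a fitted calibration.

Session-scoped so the full pipeline runs once and is reused by the workflow,
merit and acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest

from nirhist.dataset import SpectraSet
from nirhist.simulate import (
    SimulationConfig,
    generate_blank_set,
    generate_calibration_set,
    generate_qc_set,
    generate_validation_set,
)
from nirhist.workflow import calibrate


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def raw_calibration(sim_config):
    """(SpectraSet, ReferenceTable) for the raw-tuna calibration design."""
    return generate_calibration_set("raw", sim_config)


def combined_calibration_inputs(matrix_kind, config):
    """Calibration + blank + QC spectra and the merged reference table."""
    cal_s, cal_r = generate_calibration_set(matrix_kind, config)
    blk_s, blk_r = generate_blank_set(matrix_kind, config)
    qc_s, qc_r = generate_qc_set(matrix_kind, config)
    spectra = SpectraSet(
        cal_s.grid,
        np.vstack([cal_s.absorbance, blk_s.absorbance, qc_s.absorbance]),
        pd.concat([cal_s.meta, blk_s.meta, qc_s.meta], ignore_index=True),
    )
    reference = pd.concat([cal_r, blk_r, qc_r], ignore_index=True)
    return spectra, reference


@pytest.fixture(scope="session")
def raw_inputs(sim_config):
    return combined_calibration_inputs("raw", sim_config)


@pytest.fixture(scope="session")
def raw_calibrated(raw_inputs):
    """Full calibration pipeline result on the default raw-tuna design."""
    spectra, reference = raw_inputs
    return calibrate(spectra, reference, seed=42)


@pytest.fixture(scope="session")
def raw_validation(sim_config):
    return generate_validation_set("raw", 40, None, sim_config)
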