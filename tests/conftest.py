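import numpy as np
import pytest

from temac.pipeline import ScenarioConfig, _acquire, make_patients, run_grid
from temac.projsim import ScannerGeometry
from temac.synthdata import make_head_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default desk-scale head phantom shared by read-only tests."""
    return make_head_phantom(seed=1, n_vois=16)


@pytest.fixture(scope="session")
def geometry():
    return ScannerGeometry()


@pytest.fixture(scope="session")
def scenario():
    return ScenarioConfig(master_seed=1)


@pytest.fixture(scope="session")
def patient_context(scenario):
    """One simulated patient with its acquisition, initial and reference recon."""
    patient = make_patients(scenario)[0]
    ctx = _acquire(patient, scenario, scenario.patient_seed(0))
    return patient, ctx


@pytest.fixture(scope="session")
def grid_run(scenario, tmp_path_factory):
    """One full patients x (templates + correct) study grid, shared session-wide."""
    outdir = tmp_path_factory.mktemp("grid")
    df, summary = run_grid(scenario, outdir=outdir)
    return df, summary, outdir


def rng(seed=0):
    return np.random.default_rng(seed)
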