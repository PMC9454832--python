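import numpy as np
import pytest

from ivgp import BottleMeta, ConversionContext, RunConfig
from ivgp.synthetic_data import DesignSpec, TrueKinetics, generate_experiment


@pytest.fixture(scope="session")
def run_cfg() -> RunConfig:
    return RunConfig(headspace_ml=110.0)


@pytest.fixture(scope="session")
def ctx(run_cfg) -> ConversionContext:
    return ConversionContext.from_config(run_cfg)


@pytest.fixture(scope="session")
def grid_10min() -> np.ndarray:
    """0–48 h at the 10-min recording interval (289 points)."""
    return np.arange(0.0, 48.0 + 1e-9, 1.0 / 6.0)


@pytest.fixture(scope="session")
def ms_kinetics() -> TrueKinetics:
    """Control-substrate ground truth used across fitting tests."""
    return TrueKinetics("groot", 194.89, 16.92, 2.6)


@pytest.fixture
def ms_meta() -> BottleMeta:
    return BottleMeta(
        bottle_id="b1", treatment="MS", dose_pct=0.0, incubation_id="I1",
        sample_mass_mg=500.0, dm_fraction=0.931,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """Reduced design (2 reps, 2 blanks) for fast unit tests."""
    design = DesignSpec(reps_per_incubation=2, n_blanks=2)
    return generate_experiment(design, seed=7)
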