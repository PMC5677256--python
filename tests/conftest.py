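import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from saltyield import (
    FieldRecord,
    InputPDFs,
    LognormalSpec,
    ResidualPDFTable,
    TrialGeneratorConfig,
    generate_trial,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_trial():
    """Trial generated exactly on the full-model polynomial (no noise, no zeros)."""
    return generate_trial(
        TrialGeneratorConfig(n_sites=40, n_zero_yield=0, yield_noise_sd=0.0, seed=7)
    )


@pytest.fixture
def degenerate_field():
    """One field whose every input PDF is a point mass."""
    return FieldRecord(
        field_id="D0001",
        area_ha=1000.0,
        ece_pred_dsm=6.8,
        texture="fine",
        landcover="cropland",
        b_mean=4.0, b_sd=0.0,
        lf_mean=0.27, lf_sd=0.0,
        theta_mean=0.19, theta_sd=0.0,
    )


@pytest.fixture
def degenerate_residual_table():
    """Residual PDFs that return the predicted salinity (numerically) exactly."""
    rows = tuple((low, 0.0, 1e-12, n) for low, _, _, n in ResidualPDFTable().rows)
    return ResidualPDFTable(rows, (0.0, 1e-12, 4311))


@pytest.fixture
def degenerate_pdfs():
    return InputPDFs(
        boron=LognormalSpec(4.0, 0.0),
        lf=LognormalSpec(0.27, 0.0),
        theta_g=LognormalSpec(0.19, 0.0),
    )
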