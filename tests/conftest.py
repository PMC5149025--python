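import numpy as np
import pytest

from mvcal import (
    DesignSpec,
    central_composite_design,
    default_three_drug_spec,
    make_pure_spectra,
    simulate_mixtures,
)

ANALYTES = ("THEO", "MKST", "LORA")


@pytest.fixture(scope="session")
def noiseless_spec():
    return default_three_drug_spec(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def pure(noiseless_spec):
    return make_pure_spectra(noiseless_spec)


@pytest.fixture(scope="session")
def calib_design():
    """15-run face-centered CCD over 2/8/14 mg/L (calibration levels)."""
    return central_composite_design(DesignSpec(3, 2.0, 14.0, 8.0))


@pytest.fixture(scope="session")
def valid_design():
    """15-run face-centered CCD over 3/7/11 mg/L (validation levels)."""
    return central_composite_design(DesignSpec(3, 3.0, 11.0, 7.0))


@pytest.fixture(scope="session")
def X_noiseless(calib_design, pure, noiseless_spec):
    """Exact Beer-Lambert mixtures of the calibration design (rank 3)."""
    return simulate_mixtures(calib_design, pure, noiseless_spec)


@pytest.fixture(scope="session")
def Xv_noiseless(valid_design, pure, noiseless_spec):
    return simulate_mixtures(valid_design, pure, noiseless_spec, replicate=1)


@pytest.fixture(scope="session")
def cls_oracle(pure):
    """Classical least squares with known pure spectra: C = X S^+ ."""
    S = pure.absorbance

    def _predict(Xm):
        return np.linalg.lstsq(S.T, np.atleast_2d(Xm).T, rcond=None)[0].T

    return _predict
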