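import numpy as np
import pytest

from trtsim import DeliveryRates, DoseConversion, DoseInput, TumorParams, dose_profile


@pytest.fixture(scope="session")
def rates():
    """Published transfer coefficients for At-211 in the mouse."""
    return DeliveryRates()


@pytest.fixture(scope="session")
def conv():
    return DoseConversion()


@pytest.fixture(scope="session")
def params():
    return TumorParams()


@pytest.fixture(scope="session")
def params_exponential():
    """Tumor parameters with carrying capacity disabled (N << Nm regime)."""
    return TumorParams(Nm=np.inf)


@pytest.fixture(scope="session")
def dose_1mbq(rates, conv):
    """Dose input (days/Gy-per-day) for a single 1 MBq injection at t=0."""
    t_h = np.arange(0.0, 96.0 + 0.01, 0.01)
    return DoseInput.from_profile(dose_profile(rates, 1.0, conv, t_h))
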