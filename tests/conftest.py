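import numpy as np
import pytest

from harrierpva.data_model import (
    ModelParams,
    TrackingRecord,
    VitalRates,
)

#: Published posterior means used as "truth" throughout the tests.
POSTERIOR_MEANS = dict(
    phi1=0.502, phi2=0.704, r=0.057, mu0=1.277,
    beta0=0.092, beta1=0.862, sigma_gamma=0.338, psi=1.365,
)


@pytest.fixture
def vital_rates() -> VitalRates:
    m = POSTERIOR_MEANS
    return VitalRates(
        phi1=m["phi1"], phi2=m["phi2"], beta0=m["beta0"],
        beta1=m["beta1"], sigma_gamma=m["sigma_gamma"],
    )


@pytest.fixture
def model_params(vital_rates) -> ModelParams:
    m = POSTERIOR_MEANS
    return ModelParams(r=m["r"], mu0=m["mu0"], psi=m["psi"], vital=vital_rates)


@pytest.fixture
def tracking_fixture() -> list[TrackingRecord]:
    """Thirteen birds tracked one year each, four confirmed deaths."""
    return [
        TrackingRecord(bird_id=f"b{i}", exposure_days=365.0, died=i < 4)
        for i in range(13)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
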