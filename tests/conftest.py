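import numpy as np
import pytest

from eramed import McmcSettings, default_scenario, fit


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ref_scenario():
    """Reference scenario data shared across modules (read-only)."""
    rng = np.random.default_rng(7)
    spec, data, true = default_scenario(150, rng)
    return spec, data, true


@pytest.fixture(scope="session")
def ref_fit(ref_scenario):
    """One moderate-length fit on the reference scenario (read-only)."""
    spec, data, _ = ref_scenario
    settings = McmcSettings(n_iter=1500, burn_in=300, thin=3, seed=11)
    return fit(data, spec, settings=settings)
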