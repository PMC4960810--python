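import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import prodrugpk as pp

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cfg():
    return pp.load_default_config()


@pytest.fixture(scope="session")
def pk_default(cfg):
    return cfg.pk


@pytest.fixture(scope="session")
def paper_times():
    return np.array(pp.synthetic.PAPER_SAMPLING_TIMES_H)


@pytest.fixture
def mono_profile_factory():
    """Build a noise-free mono-exponential plasma profile."""

    def make(c0, half_life_h, times, analyte="CNOB"):
        lam = np.log(2.0) / half_life_h
        times = np.asarray(times, dtype=float)
        return pp.ConcentrationProfile(
            subject_id="mono",
            matrix="plasma",
            analyte=analyte,
            times_h=times,
            conc=c0 * np.exp(-lam * times),
        )

    return make
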