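import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "dsrt",
    settings(max_examples=50, derandomize=True, deadline=None,
             suppress_health_check=[HealthCheck.too_slow]))
settings.load_profile("dsrt")

CONCENTRATIONS = np.array([1.0, 10.0, 100.0, 1000.0, 10000.0])


@pytest.fixture
def concentrations():
    """Default five 10-fold screen concentrations, 1 nM - 10 uM."""
    return CONCENTRATIONS.copy()


def linear_series(slope, intercept=10.0, t_end=120.0, step=3.0, **kwargs):
    """Confluence series rising linearly at `slope` percent/h (clipped to [0,100])."""
    from dsrt.growth import ConfluenceSeries
    t = np.arange(0.0, t_end + 1e-9, step)
    conf = np.clip(intercept + slope * t, 0.0, 100.0)
    defaults = dict(cell_line="L1", compound="D1", concentration=0.0, replicate=0)
    defaults.update(kwargs)
    return ConfluenceSeries(times=t, confluence=conf, **defaults)
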