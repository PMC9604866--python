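import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sardas.forward_sim import ForwardModelParams, simulate_scan
from sardas.phantom import make_default_phantom
from sardas.pulse import PulseParams, default_time_axis
from sardas.sar_locator import locate_tumor, plan_aperture, sar_from_field, synthesize_field


@pytest.fixture(scope="session")
def default_phantom():
    return make_default_phantom()


@pytest.fixture(scope="session")
def tumor_estimate(default_phantom):
    field = synthesize_field(default_phantom, (0.0, 0.0, 60.0))
    return locate_tumor(sar_from_field(field, default_phantom))


@pytest.fixture(scope="session")
def aperture_3x3(default_phantom, tumor_estimate):
    return plan_aperture(tumor_estimate.center_estimate, default_phantom)


@pytest.fixture(scope="session")
def record_pair(default_phantom, aperture_3x3):
    """Noiseless (baseline, cancerous) records on the default 3x3 aperture."""
    pulse = PulseParams()
    params = ForwardModelParams(seed=7)
    baseline = simulate_scan(
        default_phantom.without_tumors(), aperture_3x3, pulse, params, with_tumors=False
    )
    cancerous = simulate_scan(default_phantom, aperture_3x3, pulse, params, with_tumors=True)
    return baseline, cancerous
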