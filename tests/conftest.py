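import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def dim_control():
    """Control-strain event table (no recombined cells), 50k events."""
    from loxkit.synthetic_data import synthesize_cytometry_events
    return synthesize_cytometry_events(0.0, 50_000, seed=101,
                                       sample_id="control")


@pytest.fixture()
def default_gate(dim_control):
    from loxkit.cytometry import derive_gate_from_control
    return derive_gate_from_control(dim_control, q=0.999)
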