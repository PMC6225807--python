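import pytest

from gcsteer import SimConfig, validate_params


@pytest.fixture(scope="session")
def default_params():
    """Reference parameter bundle (Aplysia growth-cone rates, uniform cue)."""
    return validate_params()


@pytest.fixture(scope="session")
def gradient_params(default_params):
    """Steep-gradient, weak-feedback condition: A = 0.9, beta = 0.1."""
    return default_params.replace(A=0.9, beta=0.1)


@pytest.fixture()
def fast_cfg():
    """Short simulation config for unit-level checks (not for averages)."""
    return SimConfig(dt=0.005, t_total=5.0, burn_in=1.0, n_mt=200, seed=11)
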