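import numpy as np
import pytest

from rcn.model import full_state_from_independent, pack_independent
from rcn.parameters import reference_parameters
from rcn.simulate import WNT_OFF, WNT_ON, find_steady_state, steady_state_newton


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def off_state(ref_params):
    """Wnt OFF equilibrium of the reference condition (WNT0 = 1 nM)."""
    return find_steady_state(ref_params, wnt0=WNT_OFF)


@pytest.fixture(scope="session")
def on_state(ref_params, off_state):
    """Wnt ON steady state reached from the OFF equilibrium."""
    p_on = ref_params.with_overrides(WNT0=WNT_ON)
    x = steady_state_newton(p_on, pack_independent(off_state))
    assert x is not None
    return full_state_from_independent(x, p_on)


@pytest.fixture(scope="session")
def lsa_table():
    """Full 33-parameter x 18-factor sensitivity sweep (shared: ~20 s)."""
    import warnings

    from rcn.sensitivity import lsa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lsa()
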