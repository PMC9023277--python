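import numpy as np
import pytest

import quadstack as qs


@pytest.fixture(scope="session")
def sphere_profile():
    """Noise-free analytic sphere (R = 30 A) scattering with sane sigmas."""
    R = 30.0
    q = np.linspace(0.003, 0.3, 300)
    i = 100.0 * qs.sphere_form_factor(q, R)
    return qs.ScatteringProfile(q, i, 0.01 * np.abs(i) + 1e-4 * 100.0), R


@pytest.fixture(scope="session")
def tetrad_model():
    """Four stacked quartets with axial ions: the standard model fixture."""
    return qs.make_tetrad_stack_model(4, axial_ions=True)


@pytest.fixture
def conditions():
    return qs.SolutionConditions()
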