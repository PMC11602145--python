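import numpy as np
import pytest

from stackfit.elasticity import StackedElasticParams, UnstackedElasticParams
from stackfit.stmodel import StackingParams


@pytest.fixture(scope="session")
def eU():
    """Published TC parameters for unstacked ssDNA at 1 M monovalent."""
    return UnstackedElasticParams(l_U=0.652, a=0.65, delta0=0.40, delta_slope=0.0109, C=1.0)


@pytest.fixture(scope="session")
def eS():
    """Published stacked-state WLC at the reference salt."""
    return StackedElasticParams(l_S=0.386, p_inf=9.9, m_p=0.0, C=1.0)


@pytest.fixture(scope="session")
def poly_da():
    """poly-dA stacking parameters at the 1 M-equivalent reference condition."""
    return StackingParams(eps_ST=0.14, gamma_ST=0.86)


@pytest.fixture(scope="session")
def poly_dgda():
    return StackingParams(eps_ST=0.02, gamma_ST=0.67)


@pytest.fixture(scope="session")
def f_grid():
    return np.arange(5.0, 45.01, 0.5)
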