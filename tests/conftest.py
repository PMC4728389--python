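import numpy as np
import pytest

from geldiff import (
    HankelSolver,
    QuadratureConfig,
    reference_parameters,
    solve_fd,
)

# the five extraction radii of the in vivo intensity curves, mm
STUDY_RADII = np.array([2.475, 4.243, 6.790, 8.770, 11.170])


@pytest.fixture(scope="session")
def ref():
    """Reference study parameters (source, initial condition, transport)."""
    return reference_parameters()


@pytest.fixture(scope="session")
def solver(ref):
    """Analytic solver at default (high-accuracy) quadrature."""
    src, ic, tr = ref
    return HankelSolver(src, ic, tr)


@pytest.fixture(scope="session")
def fast_solver(ref):
    """Analytic solver at the cheaper fitting-grade quadrature."""
    src, ic, tr = ref
    return HankelSolver(src, ic, tr, QuadratureConfig.fast())


@pytest.fixture(scope="session")
def fd_solution(ref):
    """Finite-difference run at default resolution, daily output to 60 days.

    Shared by the oracle-equivalence and mass-balance tests.
    """
    src, ic, tr = ref
    return solve_fd(src, ic, tr)
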