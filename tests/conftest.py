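import numpy as np
import pytest

from nanopbpk.branched_model import build_branched
from nanopbpk.compartmental import build_model_a, build_model_b
from nanopbpk.params import MODEL_A_ORGANS, default_murine_table
from nanopbpk.solve import SolverConfig, integrate
from nanopbpk.vascular_tree import build_tree


@pytest.fixture(scope="session")
def murine():
    return default_murine_table()


@pytest.fixture(scope="session")
def murine5(murine):
    return murine.subset(MODEL_A_ORGANS)


@pytest.fixture(scope="session")
def system_a(murine5):
    return build_model_a(murine5)


@pytest.fixture(scope="session")
def system_b(murine):
    return build_model_b(murine)


@pytest.fixture(scope="session")
def tree():
    return build_tree()


@pytest.fixture(scope="session")
def system_branched(murine, tree):
    return build_branched(murine, tree)


@pytest.fixture(scope="session")
def fine_grid():
    """Dense early sampling to resolve distribution-phase dynamics."""
    return np.concatenate([np.linspace(0.0, 600.0, 601),
                           np.linspace(610.0, 1.0e4, 300)])


@pytest.fixture(scope="session")
def traj_b(system_b, fine_grid):
    return integrate(system_b, SolverConfig(t_eval=fine_grid))


@pytest.fixture(scope="session")
def traj_branched(system_branched, fine_grid):
    return integrate(system_branched, SolverConfig(t_eval=fine_grid))
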