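import numpy as np
import pytest

from hyperfix import Hypergraph, default_r_grid


@pytest.fixture(scope="session")
def toggling_hypergraph() -> Hypergraph:
    """Six nodes, four triangles arranged so that majority-rule dynamics
    started from two adjacent mutants can never fixate (two nodes toggle
    forever, two stay resident)."""
    return Hypergraph(6, ((0, 1, 2), (2, 3, 4), (3, 4, 5), (0, 1, 5)))


@pytest.fixture(scope="session")
def r_grid() -> np.ndarray:
    return default_r_grid()


@pytest.fixture(scope="session")
def r_probe() -> tuple[float, ...]:
    """Fitness values used for exact cross-checks."""
    return (0.25, 0.5, 1.0, 2.0, 4.0)
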