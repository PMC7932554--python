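import numpy as np
import pytest

import pathdecomp as pdp


@pytest.fixture(scope="session")
def wheat_system():
    return pdp.datasets.wheat()


@pytest.fixture(scope="session")
def wheat_fit(wheat_system):
    return pdp.fit(wheat_system)


def random_system(seed: int, m: int = 3, p: int = 3, n: int = 100) -> pdp.CorrelationSystem:
    """A random positive-definite correlation system.

    Built as the empirical correlation of a small Gaussian sample, which is
    positive definite with probability one and keeps correlations away from
    the boundary.
    """
    rng = np.random.default_rng(seed)
    k = m + p
    data = rng.standard_normal((max(3 * k, 25), k))
    R = np.corrcoef(data, rowvar=False)
    return pdp.build_system(
        R, n, [f"x{i}" for i in range(1, m + 1)], [f"y{i}" for i in range(1, p + 1)]
    )


@pytest.fixture()
def independent_system():
    """Rxy = 0: the X and Y blocks are exactly uncorrelated."""
    return pdp.build_system(np.eye(4), 100, ["x1", "x2"], ["y1", "y2"])
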