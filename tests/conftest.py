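import numpy as np
import pytest

import basisbrain as bb


@pytest.fixture(scope="session")
def toy_mask() -> bb.Mask:
    """Two-lobed pseudo-striatum on a 12x12x8 grid of 2 mm voxels."""
    return bb.two_lobe_mask()


@pytest.fixture(scope="session")
def small_basis(toy_mask) -> bb.BasisSet:
    """Eight smooth random basis columns on the toy mask."""
    return bb.random_smooth_basis(toy_mask, M=8, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_basis):
    """Cohort of 6 subjects from the generative model (beta = 25)."""
    data, truth = bb.simulate_cohort(
        small_basis, np.eye(small_basis.M), beta=25.0, S=6, seed=202
    )
    return data, truth


def random_instance(rng, V=None, M=None, S=None):
    """A random (basis, data, hyper) triple for oracle comparisons."""
    V = V or int(rng.integers(5, 51))
    M = M or int(rng.integers(1, 11))
    S = S or int(rng.integers(1, 6))
    Phi = rng.standard_normal((V, M))
    basis = bb.BasisSet(Phi, [f"b{i}" for i in range(M)])
    data = bb.DataMatrix(rng.standard_normal((V, S)), [f"s{i}" for i in range(S)])
    hyper = bb.Hyperparameters(
        alpha=rng.uniform(0.1, 5.0, M), beta=float(rng.uniform(0.1, 5.0))
    )
    return basis, data, hyper
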