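import numpy as np
import pytest

from thetadircomm.synthetic import (NmvarGroundTruth, NonlinearTerm,
                                    make_toy_head_model)


@pytest.fixture(scope="session")
def head():
    """Shared toy head model: 6x6x3 grid, 5-unit spacing, 32 sensors."""
    return make_toy_head_model(grid_shape=(6, 6, 3), spacing=5.0,
                               n_sensors=32, seed=0)


@pytest.fixture()
def var21_truth():
    """M=2, p=1 VAR with a single cross-coupling x1 -> x2 of 0.5."""
    A = np.zeros((1, 2, 2))
    A[0, 1, 0] = 0.5
    return NmvarGroundTruth(2, 1, A)


@pytest.fixture()
def quad_truth():
    """M=2, p=2 system with a planted quadratic coupling x2 <- x1(n-1)^2."""
    A = np.zeros((2, 2, 2))
    A[0, 0, 0] = 0.3
    A[0, 1, 1] = 0.3
    return NmvarGroundTruth(2, 2, A, (NonlinearTerm(1, 0, 1, "square", 0.5),))


def random_stationary_var(M=4, p=2, seed=0, n_cross=5, diag=(0.2, 0.4),
                          cross=(-0.4, 0.4)):
    """Random stationary VAR ground truth with a few cross-couplings."""
    r = np.random.default_rng(seed)
    while True:
        A = np.zeros((p, M, M))
        A[0][np.diag_indices(M)] = r.uniform(*diag, M)
        for _ in range(n_cross):
            i, j = r.integers(0, M, 2)
            if i != j:
                A[r.integers(0, p), j, i] = r.uniform(*cross)
        try:
            return NmvarGroundTruth(M, p, A)
        except ValueError:
            continue
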