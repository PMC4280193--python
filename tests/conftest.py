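import numpy as np
import pytest

from commlesion import Cohort, Connectome


def make_connectome(W, hemisphere=None, labels=None, coords=None, node_size=None):
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    labels = labels or [f"n{i}" for i in range(n)]
    hemisphere = hemisphere or ["L"] * (n // 2) + ["R"] * (n - n // 2)
    return Connectome(
        labels=labels, hemisphere=hemisphere, W=W, coords=coords, node_size=node_size
    )


def random_connectome(n, p, seed, weighted=False):
    """G(n, p) connectome (regenerated until connected), optional weights."""
    from scipy.sparse.csgraph import connected_components

    rng = np.random.default_rng(seed)
    while True:
        A = np.triu(rng.random((n, n)) < p, 1).astype(float)
        A = A + A.T
        if connected_components(A > 0, directed=False)[0] == 1:
            break
    if weighted:
        iu = np.triu(A, 1) > 0
        W = np.zeros_like(A)
        W[iu] = rng.lognormal(0.0, 1.0, size=int(iu.sum()))
        A = W + W.T
    return make_connectome(A)


@pytest.fixture
def path3():
    return make_connectome([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


@pytest.fixture
def k3():
    return make_connectome([[0, 1, 1], [1, 0, 1], [1, 1, 0]])


@pytest.fixture
def k4():
    W = 1.0 - np.eye(4)
    return make_connectome(W)


@pytest.fixture
def single_edge():
    return make_connectome([[0, 1], [1, 0]])


@pytest.fixture
def empty3():
    return make_connectome(np.zeros((3, 3)))


@pytest.fixture
def star5():
    """Star with center node 0 and 5 leaves."""
    W = np.zeros((6, 6))
    W[0, 1:] = 1.0
    W[1:, 0] = 1.0
    return make_connectome(W)


@pytest.fixture
def tiny_cohort():
    """4-subject, 12-node synthetic cohort (fast, deterministic)."""
    from commlesion import CohortSpec, generate_cohort

    return generate_cohort(
        CohortSpec(n_subjects=4, n_nodes=12, edge_density=0.4, hub_fraction=0.2),
        seed=7,
    )
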