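import io

import numpy as np
import pytest

import neurojet as nj


@pytest.fixture
def rng():
    return np.random.default_rng(20240801)


@pytest.fixture
def straight_trace():
    """Unbranched 3-node path along x."""
    nodes = [
        nj.TraceNode(1, 1, [0.0, 0.0, 0.0], 1.0, -1),
        nj.TraceNode(2, 3, [5.0, 0.0, 0.0], 1.0, 1),
        nj.TraceNode(3, 3, [10.0, 0.0, 0.0], 1.0, 2),
    ]
    return nj.NeuronTrace(nodes)


@pytest.fixture
def y_trace():
    """Root->A of length 10, A->leaf1 of length 5, A->leaf2 of length 3."""
    nodes = [
        nj.TraceNode(1, 1, [0.0, 0.0, 0.0], 1.0, -1),
        nj.TraceNode(2, 3, [10.0, 0.0, 0.0], 1.0, 1),  # A
        nj.TraceNode(3, 3, [15.0, 0.0, 0.0], 1.0, 2),  # leaf1
        nj.TraceNode(4, 3, [10.0, 3.0, 0.0], 1.0, 2),  # leaf2
    ]
    return nj.NeuronTrace(nodes)


@pytest.fixture
def smooth_map():
    """A gentle, C-infinity, diffeomorphic sinusoidal perturbation with
    exact Jacobian and Hessian."""
    return nj.sinusoidal_map(
        [20.0, 15.0, 10.0],
        np.array([[0.03, 0.005, 0.0], [0.0, 0.02, 0.01], [0.008, 0.0, 0.025]]),
        phases=[0.3, 1.1, 2.0],
    )


@pytest.fixture
def quad_map():
    """x -> x + quadratic perturbation, exact constant Hessian."""
    Q = np.zeros((3, 3, 3))
    Q[1, 0, 0] = 0.02  # phi_y gains x^2/100
    Q[2, 0, 1] = Q[2, 1, 0] = 0.005
    return nj.quadratic_map(Q)


@pytest.fixture
def random_affine(rng):
    A = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
    while np.linalg.det(A) <= 0.1:
        A = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
    return nj.affine(A, rng.normal(scale=50.0, size=3))


def trace_roundtrip(trace):
    buf = io.StringIO()
    nj.write_swc(trace, buf)
    buf.seek(0)
    return nj.read_swc(buf)
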