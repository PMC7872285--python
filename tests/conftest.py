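import numpy as np
import pytest

from gnfields import (
    GraphWilsonCowan,
    LineGraphSpec,
    MetricGraph,
    WilsonCowanParams,
    eigendecompose,
    make_line_graph,
    weighted_laplacian,
)


@pytest.fixture(scope="session")
def path3():
    """Unit-distance 3-vertex path 0-1-2."""
    return MetricGraph(n_vertices=3, edges=np.array([[0, 1], [1, 2]]),
                       distances=np.array([1.0, 1.0]))


@pytest.fixture(scope="session")
def ring24():
    """24-vertex unit-spacing ring (no coordinates: chord != arc)."""
    return make_line_graph(LineGraphSpec(n_vertices=24, spacing=1.0, periodic=True))


@pytest.fixture(scope="session")
def ring24_spectrum(ring24):
    return eigendecompose(weighted_laplacian(ring24))


@pytest.fixture(scope="session")
def decoupled_params():
    """All couplings zero: each vertex an independent pair of OU-like units."""
    return WilsonCowanParams(
        tau_e=0.01, tau_i=0.02, d_e=1.0, d_i=1.0,
        alpha_ee=0.0, alpha_ie=0.0, alpha_ei=0.0, alpha_ii=0.0,
        sigma_ee=0.01, sigma_ie=0.01, sigma_ei=0.01, sigma_ii=0.01,
        p=0.0, q=0.0, sigma_noise=1e-3,
    )


@pytest.fixture(scope="session")
def coupled_params():
    """A coupled, stable parameter set used across model tests."""
    return WilsonCowanParams(
        tau_e=0.01, tau_i=0.01, d_e=1.0, d_i=1.0,
        alpha_ee=10.78, alpha_ie=14.2, alpha_ei=14.2, alpha_ii=10.8,
        sigma_ee=0.01327, sigma_ie=1.37e-3, sigma_ei=1.37e-3, sigma_ii=0.05774,
        p=0.5 * (14.2 - 10.78), q=0.5 * (10.8 - 14.2),
        sigma_noise=1e-3,
    )


@pytest.fixture(scope="session")
def line60():
    """60-vertex line whose low modes match the 1000-vertex resonance ladder."""
    return make_line_graph(LineGraphSpec(n_vertices=60, spacing=1.667e-3))


@pytest.fixture(scope="session")
def line60_model(line60, coupled_params):
    return GraphWilsonCowan(line60, coupled_params)


def random_stable_jacobian(rng):
    """Random stable 2x2 Jacobian (negative trace, positive determinant)."""
    while True:
        j = rng.normal(scale=30.0, size=(2, 2))
        tr = j[0, 0] + j[1, 1]
        det = j[0, 0] * j[1, 1] - j[0, 1] * j[1, 0]
        if tr < -1e-2 and det > 1e-2:
            return j


def random_noise_power(rng):
    return np.diag(rng.uniform(0.1, 2.0, size=2))
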