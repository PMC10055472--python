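import numpy as np
import pytest

from jetmap.diffeo import AffineDiffeo, PolynomialDiffeo, SinusoidalDiffeo
from jetmap.neuron_io import Branch, arc_length_params


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def y_tree_swc(tmp_path):
    """Y-shaped tree: root R, interior A, leaves B (long arm) and C (short arm)."""
    text = """# id type x y z radius parent
1 1 0 0 0 1.0 -1
2 3 1 0 0 1.0 1
3 3 3 0 0 1.0 2
4 3 1 1 0 1.0 2
"""
    path = tmp_path / "y.swc"
    path.write_text(text)
    return path


@pytest.fixture
def gentle_sinusoid():
    """A smooth, clearly non-affine diffeomorphism with closed-form derivatives."""
    return SinusoidalDiffeo(
        amplitudes=[8.0, 6.0, 5.0],
        wavevectors=[[0.02, 0.01, 0.0], [0.0, 0.02, 0.01], [0.01, 0.0, 0.02]],
        phases=[0.5, 1.1, 0.3],
    )


@pytest.fixture
def quadratic_diffeo():
    """Quadratic map with constant, nonzero Hessian (exact order-2 jets)."""
    Q = np.zeros((3, 3, 3))
    Q[0, 0, 0] = 2e-4
    Q[1, 0, 1] = 1e-4
    Q[2, 1, 2] = -1e-4
    return PolynomialDiffeo(A=np.eye(3), b=[1.0, -2.0, 0.5], Q=Q)


def random_polyline(rng, n=8, scale=200.0):
    """Random branch with strictly increasing arc-length parameters."""
    steps = rng.uniform(5.0, 40.0, size=(n - 1, 3)) * rng.choice([-1, 1], (n - 1, 3))
    knots = np.vstack([rng.uniform(-scale / 2, scale / 2, 3), steps]).cumsum(axis=0)
    return Branch(knots, arc_length_params(knots), [])


def random_affine(rng, translate=50.0):
    """Random orientation-preserving affine map close enough to rigid."""
    A = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
    if np.linalg.det(A) <= 0.1:
        A = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
    return AffineDiffeo(A, rng.uniform(-translate, translate, 3))
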