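"""Jet actions, discrete mapping, Hermite reconstruction, ground truth."""

import numpy as np
import pytest

from jetmap.diffeo import AffineDiffeo, ComposedDiffeo, PolynomialDiffeo
from jetmap.jet_core import (
    JetSample,
    dense_ground_truth,
    first_order_map,
    jet_action,
    one_sided_derivatives,
    second_order_map,
    upsample_branch,
    upsample_indices,
    zeroth_order_map,
)
from jetmap.neuron_io import Branch, arc_length_params

from conftest import random_affine, random_polyline

IDENTITY = AffineDiffeo()


def _branch(knots):
    knots = np.asarray(knots, dtype=float)
    return Branch(knots, arc_length_params(knots), [])


# ---------------------------------------------------------------------------
# one-sided derivatives


def test_one_sided_derivatives_axis_aligned():
    br = _branch([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
    d = one_sided_derivatives(br)
    assert d.left[0] is None and d.right[2] is None
    np.testing.assert_allclose(d.right[0], [1, 0, 0])
    np.testing.assert_allclose(d.left[1], [1, 0, 0])
    np.testing.assert_allclose(d.right[1], [0, 1, 0])
    np.testing.assert_allclose(d.left[2], [0, 1, 0])


def test_one_sided_derivatives_are_unit_vectors(rng):
    br = random_polyline(rng, n=10)
    d = one_sided_derivatives(br)
    for v in list(d.left[1:]) + list(d.right[:-1]):
        assert abs(np.linalg.norm(v) - 1.0) < 1e-12


def test_single_segment_normalized():
    br = _branch([[0, 0, 0], [2, 0, 0]])
    d = one_sided_derivatives(br)
    np.testing.assert_allclose(d.right[0], [1, 0, 0])
    np.testing.assert_allclose(d.left[1], [1, 0, 0])


# ---------------------------------------------------------------------------
# jet action


def test_identity_action_is_exact():
    s = JetSample(1.5, [1, 2, 3], [0.1, 0.2, 0.3], [0.0, -0.1, 0.05])
    out = jet_action(IDENTITY, s)
    assert out.t == s.t
    np.testing.assert_array_equal(out.x0, s.x0)
    np.testing.assert_array_equal(out.x1, s.x1)
    np.testing.assert_array_equal(out.x2, s.x2)


def test_affine_action_transports_tangent_by_matrix(rng):
    phi = random_affine(rng)
    s = JetSample(0.7, [5, -3, 2], [0.6, 0.8, 0.0])
    out = jet_action(phi, s)
    assert out.t == s.t
    np.testing.assert_allclose(out.x0, phi.A @ s.x0 + phi.b)
    np.testing.assert_allclose(out.x1, phi.A @ s.x1)


def test_quadratic_action_order2_matches_hand_value():
    # phi(x, y, z) = (x^2, y, z): jet (0,(1,0,0),(1,0,0),(0,0,0)) maps to
    # ((1,0,0),(2,0,0),(2,0,0)) -- Jacobian diag(2x,1,1), Hessian 2 in xx.
    Q = np.zeros((3, 3, 3))
    Q[0, 0, 0] = 1.0
    phi = PolynomialDiffeo(A=np.diag([0.0, 1.0, 1.0]), Q=Q)
    out = jet_action(phi, JetSample(0.0, [1, 0, 0], [1, 0, 0], [0, 0, 0]))
    np.testing.assert_allclose(out.x0, [1, 0, 0])
    np.testing.assert_allclose(out.x1, [2, 0, 0])
    np.testing.assert_allclose(out.x2, [2, 0, 0])


def test_order2_action_matches_finite_difference_chain_rule(quadratic_diffeo):
    # c(t) = x0 + t x1 + t^2/2 x2: compare jet of phi o c with central
    # differences at t = 0
    x0, x1, x2 = np.array([10.0, -5.0, 3.0]), np.array([0.6, 0.8, 0.0]), np.array([0.01, 0.0, -0.02])
    out = jet_action(quadratic_diffeo, JetSample(0.0, x0, x1, x2))
    h = 1e-4

    def curve(t):
        return quadratic_diffeo.map(x0 + t * x1 + 0.5 * t**2 * x2)

    d1 = (curve(h) - curve(-h)) / (2 * h)
    d2 = (curve(h) - 2 * curve(0.0) + curve(-h)) / h**2
    np.testing.assert_allclose(out.x1, d1, atol=1e-6)
    np.testing.assert_allclose(out.x2, d2, atol=1e-4)


def test_order2_requires_hessian():
    class NoHessian(AffineDiffeo):
        has_hessian = False

        def hessian(self, x):
            raise NotImplementedError

    with pytest.raises(Exception):
        jet_action(NoHessian(), JetSample(0, [0, 0, 0], [1, 0, 0], [0, 0, 0]))


def test_group_action_composition_consistency(rng, quadratic_diffeo, gentle_sinusoid):
    """Acting by a composition equals acting successively, up to order 2."""
    comp = ComposedDiffeo(quadratic_diffeo, gentle_sinusoid)
    for _ in range(20):
        s = JetSample(
            rng.uniform(0, 10),
            rng.uniform(-100, 100, 3),
            rng.standard_normal(3),
            0.1 * rng.standard_normal(3),
        )
        via_comp = jet_action(comp, s)
        via_steps = jet_action(quadratic_diffeo, jet_action(gentle_sinusoid, s))
        for a, b in [(via_comp.x0, via_steps.x0), (via_comp.x1, via_steps.x1),
                     (via_comp.x2, via_steps.x2)]:
            np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-10)


# ---------------------------------------------------------------------------
# mapping


def test_identity_maps_preserve_polyline(rng):
    br = random_polyline(rng)
    ts = np.linspace(br.params[0], br.params[-1], 200)
    expected = br.point_at(ts)
    for mapper in (zeroth_order_map, first_order_map):
        curve = mapper(br, IDENTITY)
        np.testing.assert_allclose(curve(ts), expected, atol=1e-9)


def test_affine_mapping_is_exact(rng):
    """Affine maps introduce no error for piecewise-linear curves."""
    for _ in range(10):
        br = random_polyline(rng)
        phi = random_affine(rng)
        gt = dense_ground_truth(br, phi)
        ts = gt.knot_params
        for mapper in (zeroth_order_map, first_order_map):
            err = np.linalg.norm(mapper(br, phi)(ts) - gt.knot_positions, axis=1)
            assert err.max() < 1e-9


def test_first_order_interpolation_contract(rng, gentle_sinusoid):
    """The cubic matches mapped positions and one-sided derivatives exactly."""
    br = random_polyline(rng, n=7)
    curve = first_order_map(br, gentle_sinusoid)
    np.testing.assert_allclose(
        curve(br.params), gentle_sinusoid.map(br.knots), atol=1e-10
    )
    d = one_sided_derivatives(br)
    J = gentle_sinusoid.jacobian(br.knots)
    for i in range(len(br)):
        if d.right[i] is not None:
            np.testing.assert_allclose(
                curve.derivative(br.params[i], side="right"), J[i] @ d.right[i],
                rtol=1e-8, atol=1e-8,
            )
        if d.left[i] is not None:
            np.testing.assert_allclose(
                curve.derivative(br.params[i], side="left"), J[i] @ d.left[i],
                rtol=1e-8, atol=1e-8,
            )


def test_mapping_never_changes_knot_params(rng, gentle_sinusoid):
    br = random_polyline(rng)
    for mapper in (zeroth_order_map, first_order_map):
        np.testing.assert_array_equal(mapper(br, gentle_sinusoid).knot_params, br.params)
    gt = dense_ground_truth(br, gentle_sinusoid)
    assert set(np.round(br.params, 9)) <= set(np.round(gt.knot_params, 9))


def test_first_order_beats_zeroth_on_long_smooth_segment(gentle_sinusoid):
    br = _branch([[0, 0, 0], [100, 0, 0]])
    gt = dense_ground_truth(br, gentle_sinusoid, 0.5)
    ts = gt.knot_params
    e0 = np.linalg.norm(zeroth_order_map(br, gentle_sinusoid)(ts) - gt.knot_positions, axis=1).max()
    e1 = np.linalg.norm(first_order_map(br, gentle_sinusoid)(ts) - gt.knot_positions, axis=1).max()
    assert e0 > 0
    assert e1 < e0


def test_hermite_segments_match_scipy_reference(rng, gentle_sinusoid):
    """Per-segment cubics agree with scipy's Hermite spline as an oracle."""
    from scipy.interpolate import CubicHermiteSpline

    br = random_polyline(rng, n=6)
    curve = first_order_map(br, gentle_sinusoid)
    mapped = gentle_sinusoid.map(br.knots)
    J = gentle_sinusoid.jacobian(br.knots)
    d = one_sided_derivatives(br)
    for i in range(len(br) - 1):
        t0, t1 = br.params[i], br.params[i + 1]
        ref = CubicHermiteSpline(
            [t0, t1],
            np.stack([mapped[i], mapped[i + 1]]),
            np.stack([J[i] @ d.right[i], J[i + 1] @ d.left[i + 1]]),
        )
        ts = np.linspace(t0, t1, 9)
        np.testing.assert_allclose(curve(ts), ref(ts), atol=1e-9)


def test_second_order_map_interpolates_positions(quadratic_diffeo, rng):
    br = random_polyline(rng, n=5)
    curve = second_order_map(br, quadratic_diffeo)
    np.testing.assert_allclose(
        curve(br.params), quadratic_diffeo.map(br.knots), atol=1e-8
    )


# ---------------------------------------------------------------------------
# upsampling / ground truth


def test_uniform_subdivision_counts():
    br = _branch([[0, 0, 0], [10, 0, 0]])
    up = upsample_branch(br, 2.0)
    np.testing.assert_allclose(up.params, [0, 2, 4, 6, 8, 10])

    br5 = _branch([[0, 0, 0], [5, 0, 0]])
    up5 = upsample_branch(br5, 2.0)  # ceil(5/2)=3 equal subintervals
    assert len(up5) == 4
    np.testing.assert_allclose(np.diff(up5.params), 5 / 3)


def test_upsample_retains_original_knots(rng):
    br = random_polyline(rng, n=6)
    up = upsample_branch(br, 2.0)
    idx = upsample_indices(br, 2.0)
    np.testing.assert_allclose(up.knots[idx], br.knots, atol=1e-9)
    assert np.max(np.diff(up.params)) <= 2.0 + 1e-9


def test_ground_truth_identity_preserves_geometry(rng):
    br = random_polyline(rng)
    gt = dense_ground_truth(br, IDENTITY)
    np.testing.assert_allclose(gt.knot_positions, br.point_at(gt.knot_params), atol=1e-9)


def test_bad_spacing_rejected(rng):
    with pytest.raises(ValueError):
        upsample_branch(random_polyline(rng), 0.0)
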