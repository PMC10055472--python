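"""Jet-space actions of diffeomorphisms and discrete curve mapping.

A discretely sampled curve is a sequence of time-stamped jets
``(t_i, x_i^(k))`` where ``x^(k) = (x0, x1, ..., xk)`` holds the position and
first ``k`` derivatives at the knot. A diffeomorphism ``phi`` acts on a jet by
the chain rule (prolongation); for ``k = 2``::

    phi . (t, x0, x1, x2) = (t, phi(x0), Dphi(x0) x1,
                             Dphi(x0) x2 + D2phi(x0)[x1, x1])

Time-stamps are never changed by the action.

*Zeroth order* mapping transforms only knot positions and re-linearizes
(an order-1 spline). *First order* mapping additionally transports the
one-sided tangent vectors by the Jacobian and rebuilds each segment as a
cubic Hermite polynomial matching both endpoint positions and one-sided
derivatives; the result is an order-3 spline that is continuous but not
necessarily differentiable at the knots. Ground truth for error measurement
is the zeroth-order mapping of the polyline upsampled to a maximum knot
spacing of 2 microns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PPoly

from jetmap.neuron_io import Branch, arc_length_params

__all__ = [
    "JetSample",
    "KnotDerivatives",
    "MappedCurve",
    "jet_action",
    "one_sided_derivatives",
    "zeroth_order_map",
    "first_order_map",
    "second_order_map",
    "dense_ground_truth",
    "upsample_branch",
    "upsample_indices",
    "sidecar_table",
]


@dataclass(frozen=True)
class JetSample:
    """A time-stamped element of the jet space J^k, k in {0, 1, 2}.

    ``t`` is the arc-length parameter (microns), ``x0`` the position, ``x1``
    and ``x2`` the first and second derivative vectors with respect to ``t``
    (present only for k >= 1 and k = 2 respectively).
    """

    t: float
    x0: np.ndarray
    x1: np.ndarray | None = None
    x2: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "x0", np.asarray(self.x0, dtype=float).reshape(3))
        for name in ("x1", "x2"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float).reshape(3))
        if self.x2 is not None and self.x1 is None:
            raise ValueError("a jet with x2 must also carry x1")

    @property
    def order(self) -> int:
        return 0 if self.x1 is None else (1 if self.x2 is None else 2)


@dataclass
class KnotDerivatives:
    """One-sided derivatives of a polyline at its knots.

    ``left[i]`` is the incoming derivative ``c'(t_i-)`` (None at the first
    knot); ``right[i]`` is the outgoing derivative ``c'(t_i+)`` (None at the
    last knot). For an arc-length parameterized polyline every one-sided
    derivative is a unit vector.
    """

    left: list
    right: list

    def __len__(self) -> int:
        return len(self.left)


def jet_action(phi, sample: JetSample) -> JetSample:
    """Apply the jet-space action of a diffeomorphism to one sample.

    The time-stamp is fixed; the position is mapped by ``phi``, the first
    derivative by the Jacobian, and the second derivative by the Jacobian
    plus the Hessian bilinear form applied to the first derivative twice.

    Raises
    ------
    NotImplementedError
        If the sample has order 2 but ``phi`` provides no Hessian.
    """
    y0 = phi.map(sample.x0)
    if sample.order == 0:
        return JetSample(sample.t, y0)
    J = phi.jacobian(sample.x0)
    y1 = J @ sample.x1
    if sample.order == 1:
        return JetSample(sample.t, y0, y1)
    H = phi.hessian(sample.x0)  # H[i, j, k] = d2 phi_i / dx_j dx_k
    y2 = J @ sample.x2 + np.einsum("ijk,j,k->i", H, sample.x1, sample.x1)
    return JetSample(sample.t, y0, y1, y2)


def one_sided_derivatives(branch: Branch) -> KnotDerivatives:
    """One-sided derivatives at the knots, from the first-order spline.

    The polyline interpolating the knots has constant derivative on each
    segment: the secant slope ``(x_{i+1} - x_i) / (t_{i+1} - t_i)``. With
    arc-length parameters these slopes are unit vectors.
    """
    diffs = np.diff(branch.knots, axis=0)
    steps = np.diff(branch.params)[:, None]
    slopes = diffs / steps
    n = len(branch)
    left = [None] + [slopes[i - 1] for i in range(1, n)]
    right = [slopes[i] for i in range(n - 1)] + [None]
    return KnotDerivatives(left=left, right=right)


class MappedCurve:
    """A transformed branch as a piecewise-polynomial spline.

    The independent variable is the ORIGINAL arc-length parameter of the
    branch (the jet action leaves time-stamps fixed), so a mapped curve and
    the ground truth of the same branch can be sampled at identical parameter
    values. Order 1 interpolates mapped knot positions linearly; order 3
    additionally matches the mapped one-sided derivatives at segment
    endpoints and is continuous but not necessarily differentiable at knots.
    """

    def __init__(self, order: int, knot_params: np.ndarray, ppoly: PPoly,
                 knot_positions: np.ndarray, knot_derivatives=None):
        if order not in (1, 3, 5):
            raise ValueError("spline order must be 1, 3 or 5")
        self.order = order
        self.knot_params = np.asarray(knot_params, dtype=float)
        self._ppoly = ppoly
        self.knot_positions = np.asarray(knot_positions, dtype=float)
        self.knot_derivatives = knot_derivatives

    def __call__(self, t) -> np.ndarray:
        """Position(s) at parameter value(s) ``t`` within [t_1, t_n]."""
        t = np.asarray(t, dtype=float)
        return self._ppoly(np.clip(t, self.knot_params[0], self.knot_params[-1]))

    def derivative(self, t, side: str = "right") -> np.ndarray:
        """One-sided parameter-derivative at ``t`` (``side`` breaks knot ties).

        PPoly evaluates piece ``i`` on ``[t_i, t_{i+1})``, so the derivative
        at an interior knot is the right-sided one; ``side='left'`` nudges
        the query into the preceding piece instead.
        """
        scalar = np.isscalar(t)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        c, x = self._ppoly.c, self._ppoly.x
        m = c.shape[1]
        lookup = "right" if side == "right" else "left"
        j = np.clip(np.searchsorted(x, t, side=lookup) - 1, 0, m - 1)
        s = t - x[j]
        k = c.shape[0] - 1
        out = np.zeros((t.size, 3))
        for p in range(k):  # derivative of sum c[p] s^(k-p)
            out += (k - p) * c[p, j] * s[:, None] ** (k - p - 1)
        return out[0] if scalar else out

    def sample(self, t) -> np.ndarray:
        """Alias of ``__call__`` returning an (m, 3) array."""
        return np.atleast_2d(self(t))


def _linear_ppoly(params: np.ndarray, points: np.ndarray) -> PPoly:
    steps = np.diff(params)[:, None]
    slopes = np.diff(points, axis=0) / steps
    coeffs = np.stack([slopes, points[:-1]], axis=0)  # (2, n-1, 3)
    return PPoly(coeffs, params, extrapolate=True)


def zeroth_order_map(branch: Branch, phi) -> MappedCurve:
    """Map only knot positions; re-linearize between them (order-1 spline)."""
    mapped = phi.map(branch.knots)
    return MappedCurve(1, branch.params, _linear_ppoly(branch.params, mapped), mapped)


def first_order_map(branch: Branch, phi) -> MappedCurve:
    """Map positions and one-sided derivatives; rebuild with cubic Hermite segments.

    On segment ``[t_{i-1}, t_i]`` the cubic matches the mapped position and
    the mapped one-sided derivative at both endpoints: the right derivative
    at the left endpoint and the left derivative at the right endpoint, each
    transported by the Jacobian of ``phi`` at the corresponding knot.
    """
    derivs = one_sided_derivatives(branch)
    mapped = phi.map(branch.knots)
    J = phi.jacobian(branch.knots)  # (n, 3, 3)
    n = len(branch)
    right = np.array([J[i] @ derivs.right[i] for i in range(n - 1)])
    left = np.array([J[i] @ derivs.left[i] for i in range(1, n)])

    t = branch.params
    h = np.diff(t)[:, None]
    p0, p1 = mapped[:-1], mapped[1:]
    m0, m1 = right, left
    # Hermite cubic in s = t - t_{i-1}: a s^3 + b s^2 + c s + d
    d = p0
    c = m0
    b = (3 * (p1 - p0) - h * (2 * m0 + m1)) / h**2
    a = (2 * (p0 - p1) + h * (m0 + m1)) / h**3
    coeffs = np.stack([a, b, c, d], axis=0)  # (4, n-1, 3)
    mapped_derivs = KnotDerivatives(
        left=[None] + list(left), right=list(right) + [None]
    )
    return MappedCurve(3, t, PPoly(coeffs, t, extrapolate=True), mapped,
                       knot_derivatives=mapped_derivs)


def second_order_map(branch: Branch, phi) -> MappedCurve:
    """EXPERIMENTAL: order-2 mapping with quintic Hermite segments.

    Treats the branch as a polyline, whose second derivative vanishes inside
    every segment, so the mapped second derivative at a knot reduces to the
    Hessian bilinear form ``D2phi(x)[x1, x1]`` of the one-sided tangent. Each
    segment becomes a quintic matching position, first and second derivative
    at both endpoints. Requires ``phi`` to provide a Hessian. This extends
    the demonstrated first-order method and is not part of the core pipeline.
    """
    derivs = one_sided_derivatives(branch)
    mapped = phi.map(branch.knots)
    J = phi.jacobian(branch.knots)
    H = phi.hessian(branch.knots)  # (n, 3, 3, 3)
    n = len(branch)
    t = branch.params
    coeff_list = []
    for i in range(n - 1):
        u0 = derivs.right[i]
        u1 = derivs.left[i + 1]
        p0, p1 = mapped[i], mapped[i + 1]
        m0 = J[i] @ u0
        m1 = J[i + 1] @ u1
        s0 = np.einsum("ijk,j,k->i", H[i], u0, u0)
        s1 = np.einsum("ijk,j,k->i", H[i + 1], u1, u1)
        hseg = t[i + 1] - t[i]
        coeff_list.append(_quintic_hermite(p0, m0, s0, p1, m1, s1, hseg))
    coeffs = np.stack(coeff_list, axis=1)  # (6, n-1, 3)
    return MappedCurve(5, t, PPoly(coeffs, t, extrapolate=True), mapped)


def _quintic_hermite(p0, m0, s0, p1, m1, s1, h) -> np.ndarray:
    """Coefficients (highest power first) of the quintic matching the 2-jets."""
    # Solve for a5..a0 in a5 s^5 + ... + a0 with constraints at s=0 and s=h.
    a0, a1, a2 = p0, m0, s0 / 2.0
    # remaining constraints at s=h
    r0 = p1 - (a0 + a1 * h + a2 * h**2)
    r1 = m1 - (a1 + 2 * a2 * h)
    r2 = s1 - 2 * a2
    h3, h4, h5 = h**3, h**4, h**5
    A = np.array([
        [h3, h4, h5],
        [3 * h**2, 4 * h3, 5 * h4],
        [6 * h, 12 * h**2, 20 * h3],
    ])
    a3, a4, a5 = np.linalg.solve(A, np.stack([r0, r1, r2]))
    return np.stack([a5, a4, a3, a2, a1, a0])


def upsample_branch(branch: Branch, max_spacing: float = 2.0) -> Branch:
    """Subdivide each segment uniformly so knot spacing <= ``max_spacing``.

    A segment of length L is split into ``ceil(L / max_spacing)`` equal
    subintervals; original knots are always retained. Because the polyline is
    straight between knots, the new parameters remain exact cumulative arc
    length.
    """
    if max_spacing <= 0:
        raise ValueError("max_spacing must be positive")
    params = [branch.params[0]]
    knots = [branch.knots[0]]
    for i in range(len(branch) - 1):
        t0, t1 = branch.params[i], branch.params[i + 1]
        n_sub = int(np.ceil((t1 - t0) / max_spacing))
        frac = np.arange(1, n_sub + 1) / n_sub
        params.extend(t0 + frac * (t1 - t0))
        knots.extend(branch.knots[i] + frac[:, None] * (branch.knots[i + 1] - branch.knots[i]))
    return Branch(np.asarray(knots), np.asarray(params), [])


def upsample_indices(branch: Branch, max_spacing: float = 2.0) -> np.ndarray:
    """Indices of the original knots within ``upsample_branch``'s output."""
    if max_spacing <= 0:
        raise ValueError("max_spacing must be positive")
    n_sub = np.ceil(np.diff(branch.params) / max_spacing).astype(int)
    return np.concatenate([[0], np.cumsum(n_sub)])


def dense_ground_truth(branch: Branch, phi, max_spacing: float = 2.0) -> MappedCurve:
    """Ground-truth mapping: upsample to ``max_spacing`` then map zeroth order.

    The original trace is taken at face value as a piecewise-linear curve;
    sampling it densely (default every 2 microns of pre-transformation arc
    length) and transforming the sample positions approximates the true
    transformed polyline to within the zeroth-order error at 2-micron
    spacing. The upsampled parameters are retained in ``knot_params`` so
    comparison curves can be sampled at the same parameter values.
    """
    dense = upsample_branch(branch, max_spacing)
    return zeroth_order_map(dense, phi)


def sidecar_table(curve: MappedCurve):
    """Mapped knots as a plain table: t, position, one-sided derivatives.

    Returns a pandas DataFrame with columns ``t, x, y, z`` and, when the
    curve carries derivative information, ``dxl, dyl, dzl, dxr, dyr, dzr``
    (NaN where a side does not exist).
    """
    import pandas as pd

    data = {
        "t": curve.knot_params,
        "x": curve.knot_positions[:, 0],
        "y": curve.knot_positions[:, 1],
        "z": curve.knot_positions[:, 2],
    }
    kd = curve.knot_derivatives
    if kd is not None:
        nan = np.full(3, np.nan)
        L = np.array([nan if v is None else v for v in kd.left])
        R = np.array([nan if v is None else v for v in kd.right])
        for j, ax in enumerate("xyz"):
            data[f"d{ax}l"] = L[:, j]
            data[f"d{ax}r"] = R[:, j]
    return pd.DataFrame(data)


def mapped_curve_to_swc_rows(curve: MappedCurve, structure: int = 0) -> list[str]:
    """Serialize mapped knot positions as SWC records (derivatives dropped)."""
    if curve.knot_derivatives is not None:
        warnings.warn(
            "SWC cannot carry derivative information; writing knot positions only",
            stacklevel=2,
        )
    rows = []
    for i, p in enumerate(curve.knot_positions, start=1):
        parent = i - 1 if i > 1 else -1
        rows.append(f"{i} {structure} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} 1.0 {parent}")
    return rows
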