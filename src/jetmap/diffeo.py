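"""Diffeomorphism models and mapping-error bounds.

Two families of transformations are provided:

* analytic diffeomorphisms (affine, quadratic-polynomial, sinusoidal) with
  closed-form Jacobians and Hessians, used as exactly-differentiable test
  transformations;
* random diffeomorphisms generated in the LDDMM (Large Deformation
  Diffeomorphic Metric Mapping) framework: an initial momentum field is
  drawn as i.i.d. Gaussian noise with standard deviation ``sigma`` on a
  regular grid, smoothed by a Gaussian kernel into a velocity field, and
  flowed over unit time with the momentum transported by the EPDiff
  conservation law. The resulting map is backed by a displacement field on
  the grid and evaluated by trilinear interpolation; its Jacobian comes
  from central finite differences.

The module also evaluates two worst-case error bounds for discrete curve
mapping: a bound for zeroth-order mapping of an arc-length parameterized
polyline driven by the spectral norm of ``Dphi - I`` and the knot
displacements, and the pair of comparable spline-interpolation bounds that
quantify the advantage of first-order (Hermite) reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from jetmap.neuron_io import Branch

__all__ = [
    "CapabilityError",
    "NotDiffeomorphismError",
    "Diffeomorphism",
    "AffineDiffeo",
    "PolynomialDiffeo",
    "SinusoidalDiffeo",
    "ComposedDiffeo",
    "analytic_diffeo",
    "GridField",
    "GridDiffeomorphism",
    "LddmmConfig",
    "random_lddmm_diffeo",
    "displacement_profile",
    "zeroth_order_error_bound",
    "spline_error_bounds",
    "finite_difference_jacobian",
]


class CapabilityError(RuntimeError):
    """The transformation does not provide the requested derivative order."""


class NotDiffeomorphismError(ValueError):
    """The map fails the positive-Jacobian-determinant probe on its domain."""


class Diffeomorphism:
    """Contract for a smooth invertible map of R^3.

    Subclasses implement ``map`` (positions), ``jacobian`` (3x3 matrices)
    and optionally ``hessian`` (3x3x3 arrays with ``H[i, j, k]`` equal to
    the second partial of component ``i`` with respect to ``x_j, x_k``).
    All three accept arrays of shape ``(..., 3)`` and vectorize over
    leading dimensions.
    """

    has_hessian: bool = False

    def map(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def hessian(self, x: np.ndarray) -> np.ndarray:
        raise CapabilityError(f"{type(self).__name__} provides no Hessian")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.map(x)


def _as_points(x) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.shape == (3,):
        return x[None, :], True
    return x.reshape(-1, 3), False


class AffineDiffeo(Diffeomorphism):
    """phi(x) = A x + b with det(A) > 0; Jacobian constant, Hessian zero."""

    has_hessian = True

    def __init__(self, A=None, b=None):
        self.A = np.eye(3) if A is None else np.asarray(A, dtype=float).reshape(3, 3)
        self.b = np.zeros(3) if b is None else np.asarray(b, dtype=float).reshape(3)
        if np.linalg.det(self.A) <= 0:
            raise NotDiffeomorphismError("affine matrix must have positive determinant")

    def map(self, x):
        x = np.asarray(x, dtype=float)
        return x @ self.A.T + self.b

    def jacobian(self, x):
        x = np.asarray(x, dtype=float)
        return np.broadcast_to(self.A, x.shape[:-1] + (3, 3)).copy()

    def hessian(self, x):
        x = np.asarray(x, dtype=float)
        return np.zeros(x.shape[:-1] + (3, 3, 3))


class PolynomialDiffeo(Diffeomorphism):
    """Quadratic map phi_i(x) = (A x + b)_i + x^T Q_i x.

    ``Q`` has shape (3, 3, 3); each ``Q[i]`` is symmetrized. The Jacobian is
    ``A + 2 Q_i x`` per row and the Hessian is the constant ``2 Q``.
    """

    has_hessian = True

    def __init__(self, A=None, b=None, Q=None):
        self.A = np.eye(3) if A is None else np.asarray(A, dtype=float).reshape(3, 3)
        self.b = np.zeros(3) if b is None else np.asarray(b, dtype=float).reshape(3)
        Q = np.zeros((3, 3, 3)) if Q is None else np.asarray(Q, dtype=float)
        self.Q = 0.5 * (Q + np.swapaxes(Q, 1, 2))

    def map(self, x):
        pts, single = _as_points(x)
        quad = np.einsum("ijk,nj,nk->ni", self.Q, pts, pts)
        out = pts @ self.A.T + self.b + quad
        return out[0] if single else out.reshape(np.shape(x))

    def jacobian(self, x):
        pts, single = _as_points(x)
        J = self.A + 2 * np.einsum("ijk,nk->nij", self.Q, pts)
        return J[0] if single else J.reshape(np.shape(x)[:-1] + (3, 3))

    def hessian(self, x):
        x = np.asarray(x, dtype=float)
        H = 2 * self.Q
        if x.shape == (3,):
            return H.copy()
        return np.broadcast_to(H, x.shape[:-1] + (3, 3, 3)).copy()


class SinusoidalDiffeo(Diffeomorphism):
    """phi_i(x) = x_i + a_i sin(w_i . x + p_i): a smooth wavy perturbation.

    ``amplitudes`` a (3,) in microns, ``wavevectors`` w (3, 3) in 1/micron
    (row i modulates component i), ``phases`` p (3,) in radians. All
    derivatives are closed-form.
    """

    has_hessian = True

    def __init__(self, amplitudes, wavevectors, phases=None):
        self.a = np.asarray(amplitudes, dtype=float).reshape(3)
        self.w = np.asarray(wavevectors, dtype=float).reshape(3, 3)
        self.p = np.zeros(3) if phases is None else np.asarray(phases, dtype=float).reshape(3)

    def _theta(self, pts):
        return pts @ self.w.T + self.p  # (n, 3)

    def map(self, x):
        pts, single = _as_points(x)
        out = pts + self.a * np.sin(self._theta(pts))
        return out[0] if single else out.reshape(np.shape(x))

    def jacobian(self, x):
        pts, single = _as_points(x)
        cos = np.cos(self._theta(pts))  # (n, 3)
        J = np.eye(3) + (self.a[:, None] * self.w) * cos[:, :, None]
        return J[0] if single else J.reshape(np.shape(x)[:-1] + (3, 3))

    def hessian(self, x):
        pts, single = _as_points(x)
        sin = np.sin(self._theta(pts))  # (n, 3)
        H = -(self.a * sin)[:, :, None, None] * (
            self.w[:, :, None] * self.w[:, None, :]
        )
        return H[0] if single else H.reshape(np.shape(x)[:-1] + (3, 3, 3))


class ComposedDiffeo(Diffeomorphism):
    """outer o inner, with chain-rule Jacobian and Hessian.

    D(f o g)(x) = Df(g(x)) Dg(x);
    D2(f o g)(x)[u, v] = D2f(g(x))[Dg u, Dg v] + Df(g(x)) D2g(x)[u, v].
    """

    def __init__(self, outer: Diffeomorphism, inner: Diffeomorphism):
        self.outer = outer
        self.inner = inner
        self.has_hessian = outer.has_hessian and inner.has_hessian

    def map(self, x):
        return self.outer.map(self.inner.map(x))

    def jacobian(self, x):
        gx = self.inner.map(x)
        return self.outer.jacobian(gx) @ self.inner.jacobian(x)

    def hessian(self, x):
        gx = self.inner.map(x)
        Df = self.outer.jacobian(gx)
        Dg = self.inner.jacobian(x)
        Hf = self.outer.hessian(gx)
        Hg = self.inner.hessian(x)
        term1 = np.einsum("...ijk,...jm,...kn->...imn", Hf, Dg, Dg)
        term2 = np.einsum("...ij,...jmn->...imn", Df, Hg)
        return term1 + term2


def analytic_diffeo(kind: str, domain=((-500, 500),) * 3, n_probe: int = 7,
                    **params) -> Diffeomorphism:
    """Build an analytic diffeomorphism and verify invertibility on a probe grid.

    Parameters
    ----------
    kind : {'affine', 'polynomial', 'sinusoidal'}
        Family; remaining keyword arguments go to the family constructor.
    domain : pair of bounds per axis
        Working box (microns) on which the Jacobian determinant is probed.
    n_probe : int
        Probe-grid resolution per axis.

    Raises
    ------
    NotDiffeomorphismError
        If the Jacobian determinant is not strictly positive at every probe
        point.
    """
    families = {
        "affine": AffineDiffeo,
        "polynomial": PolynomialDiffeo,
        "sinusoidal": SinusoidalDiffeo,
    }
    if kind not in families:
        raise ValueError(f"unknown analytic family {kind!r}")
    phi = families[kind](**params)
    axes = [np.linspace(lo, hi, n_probe) for lo, hi in domain]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dets = np.linalg.det(phi.jacobian(grid))
    if np.min(dets) <= 0:
        raise NotDiffeomorphismError(
            f"{kind} map has nonpositive Jacobian determinant "
            f"(min {np.min(dets):.3g}) on the probe grid"
        )
    return phi


def finite_difference_jacobian(phi, x, step: float = 1e-3) -> np.ndarray:
    """Central-difference Jacobian of ``phi.map`` at points ``x``, shape (..., 3, 3)."""
    pts, single = _as_points(x)
    cols = []
    for j in range(3):
        e = np.zeros(3)
        e[j] = step
        cols.append((phi.map(pts + e) - phi.map(pts - e)) / (2 * step))
    J = np.stack(cols, axis=-1)
    return J[0] if single else J.reshape(np.shape(x)[:-1] + (3, 3))


# ---------------------------------------------------------------------------
# Grid-backed diffeomorphisms and the LDDMM generator


@dataclass
class GridField:
    """A 3-component vector field sampled on a regular 3D grid.

    ``values`` has shape ``(nx, ny, nz, 3)``; the node ``(i, j, k)`` sits at
    ``origin + spacing * (i, j, k)`` (microns).
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be strictly positive")
        if self.values.ndim != 4 or self.values.shape[-1] != 3:
            raise ValueError("values must have shape (nx, ny, nz, 3)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    def axes(self) -> list[np.ndarray]:
        return [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]

    def bounds(self) -> np.ndarray:
        """(3, 2) array of [lo, hi] per axis."""
        return np.array(
            [[ax[0], ax[-1]] for ax in self.axes()]
        )

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            self.axes(), self.values, method="linear",
            bounds_error=False, fill_value=None,
        )

    def save(self, path) -> None:
        """Plain-text serialization: a header plus one flat row per node."""
        with open(path, "w") as fh:
            fh.write("# gridfield v1\n")
            fh.write("origin " + " ".join(f"{v:.9g}" for v in self.origin) + "\n")
            fh.write("spacing " + " ".join(f"{v:.9g}" for v in self.spacing) + "\n")
            fh.write("shape " + " ".join(str(v) for v in self.shape) + "\n")
            for row in self.values.reshape(-1, 3):
                fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "GridField":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        header = {}
        for ln in lines[:3]:
            key, *vals = ln.split()
            header[key] = vals
        shape = tuple(int(v) for v in header["shape"])
        values = np.array(
            [[float(v) for v in ln.split()] for ln in lines[3:]]
        ).reshape(shape + (3,))
        return cls(
            origin=[float(v) for v in header["origin"]],
            spacing=[float(v) for v in header["spacing"]],
            values=values,
        )


class GridDiffeomorphism(Diffeomorphism):
    """A map backed by a displacement field on a regular grid.

    ``phi(x) = x + u(x)`` with ``u`` interpolated trilinearly; the Jacobian
    is computed by central finite differences with a step of half the grid
    spacing. No Hessian is available.
    """

    has_hessian = False

    def __init__(self, displacement: GridField):
        self.displacement = displacement
        self._interp = displacement.interpolator()

    def map(self, x):
        pts, single = _as_points(x)
        out = pts + self._interp(pts)
        return out[0] if single else out.reshape(np.shape(x))

    def jacobian(self, x):
        step = float(np.min(self.displacement.spacing)) / 2.0
        return finite_difference_jacobian(self, x, step=step)

    def min_jacobian_det(self) -> float:
        """Minimum Jacobian determinant over interior grid nodes."""
        axes = self.displacement.axes()
        inner = [ax[1:-1] if len(ax) > 2 else ax for ax in axes]
        grid = np.stack(np.meshgrid(*inner, indexing="ij"), axis=-1).reshape(-1, 3)
        return float(np.min(np.linalg.det(self.jacobian(grid))))

    @property
    def is_diffeomorphic(self) -> bool:
        return self.min_jacobian_det() > 0


@dataclass
class LddmmConfig:
    """Configuration of the random-diffeomorphism generator.

    Parameters
    ----------
    sigma : float
        Standard deviation of the Gaussian initial momentum, in
        microns/time. ``sigma = 0`` yields the identity map.
    bounds : (3, 2) array-like
        Working box in microns that the grid must cover.
    grid_spacing : float
        Grid node spacing in microns.
    kernel_width : float or None
        Standard deviation of the Gaussian smoothing kernel in microns;
        defaults to one eighth of the largest box extent.
    n_timesteps : int
        Euler steps used to integrate the flow over unit time.
    margin : float
        Fractional padding added around ``bounds``.
    seed : int
        Seed for the single random generator used.
    """

    sigma: float
    bounds: np.ndarray = field(
        default_factory=lambda: np.array([[-500.0, 500.0]] * 3)
    )
    grid_spacing: float = 100.0
    kernel_width: float | None = None
    n_timesteps: int = 10
    margin: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.bounds = np.asarray(self.bounds, dtype=float).reshape(3, 2)
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.n_timesteps < 1:
            raise ValueError("n_timesteps must be at least 1")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.kernel_width is None:
            # a quarter of the box extent: smooth enough that all of the
            # default sigma levels produce invertible fields on this scale
            extent = float(np.max(self.bounds[:, 1] - self.bounds[:, 0]))
            self.kernel_width = max(extent / 4.0, self.grid_spacing)

    def grid_axes(self) -> list[np.ndarray]:
        axes = []
        for d in range(3):
            lo, hi = self.bounds[d]
            pad = self.margin * (hi - lo)
            lo, hi = lo - pad, hi + pad
            n = max(int(np.ceil((hi - lo) / self.grid_spacing)) + 1, 4)
            axes.append(lo + self.grid_spacing * np.arange(n))
        return axes


def random_lddmm_diffeo(config: LddmmConfig) -> GridDiffeomorphism:
    """Generate a random diffeomorphism by LDDMM geodesic shooting.

    An initial momentum field ``p0`` is drawn i.i.d. Gaussian, N(0, sigma^2)
    per grid-node component; convolution with a Gaussian kernel gives the
    velocity. The flow is integrated over unit time with the momentum
    transported by the EPDiff conservation law in its integrated
    (coadjoint) form

        p_t = |det D psi_t| (D psi_t)^T  p0 o psi_t,

    where ``psi_t`` is the inverse flow, advanced semi-Lagrangially
    (``psi_{t+dt}(x) = psi_t(x - dt v_t(x))``, which is unconditionally
    stable). The returned map carries the final forward displacement field
    on the grid; a warning is issued (and the result flagged) if the
    Jacobian determinant is nonpositive anywhere.
    """
    axes = config.grid_axes()
    spacing = np.array([ax[1] - ax[0] for ax in axes])
    origin = np.array([ax[0] for ax in axes])
    shape = tuple(len(ax) for ax in axes)
    rng = np.random.default_rng(config.seed)

    p0 = config.sigma * rng.standard_normal(shape + (3,))
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    X = grid.copy()        # forward particle positions
    psi = grid.copy()      # inverse map on the grid
    sig_vox = config.kernel_width / spacing
    dt = 1.0 / config.n_timesteps

    lo = np.array([ax[0] for ax in axes])
    hi = np.array([ax[-1] for ax in axes])

    def clamped(values):
        # semi-Lagrangian lookups clamp to the box: no extrapolation feedback
        interp = RegularGridInterpolator(
            axes, values, method="linear", bounds_error=False, fill_value=None
        )
        return lambda pts: interp(np.clip(pts.reshape(-1, 3), lo, hi)).reshape(
            pts.shape
        )

    p0_at = clamped(p0)
    p = p0
    for _ in range(config.n_timesteps):
        # zero boundary condition: the velocity decays toward the padded
        # box edge, so the flow leaves the margin essentially fixed
        v = np.stack(
            [gaussian_filter(p[..., c], sigma=sig_vox, mode="constant")
             for c in range(3)],
            axis=-1,
        )
        # forward particles carry the displacement field we ultimately need
        X = X + dt * clamped(v)(X)
        # inverse flow (semi-Lagrangian update), then conservation-law
        # transport of the initial momentum
        psi = clamped(psi)(grid - dt * v)
        Dpsi = np.stack(
            [np.stack(np.gradient(psi[..., i], *spacing), axis=-1)
             for i in range(3)],
            axis=-2,
        )  # (..., i, j) = d psi_i / d x_j
        det = np.linalg.det(Dpsi)
        p = det[..., None] * np.einsum("...ji,...j->...i", Dpsi, p0_at(psi))

    displacement = GridField(origin=origin, spacing=spacing, values=X - grid)
    phi = GridDiffeomorphism(displacement)
    if config.sigma > 0 and not phi.is_diffeomorphic:
        warnings.warn(
            f"LDDMM field (sigma={config.sigma}, seed={config.seed}) has "
            "nonpositive Jacobian determinant on the grid; result flagged",
            stacklevel=2,
        )
        phi.flagged_non_diffeomorphic = True
    else:
        phi.flagged_non_diffeomorphic = False
    return phi


def displacement_profile(phi: Diffeomorphism, bounds=None, grid_spacing: float = 500.0):
    """Position and tangent displacements of ``phi`` on a uniform probe grid.

    For every probe point ``x`` the table records ``|phi(x) - x|`` and
    ``|Dphi(x) u - u|`` for each canonical unit vector ``u``. ``bounds``
    defaults to the grid of a displacement-backed map.

    Returns a pandas DataFrame with columns
    ``x, y, z, position, tangent_x, tangent_y, tangent_z``.
    """
    import pandas as pd

    if bounds is None:
        if isinstance(phi, GridDiffeomorphism):
            bounds = phi.displacement.bounds()
        else:
            raise ValueError("bounds required for analytic transformations")
    bounds = np.asarray(bounds, dtype=float).reshape(3, 2)
    axes = [np.arange(lo, hi + 1e-9, grid_spacing) for lo, hi in bounds]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    disp = np.linalg.norm(phi.map(pts) - pts, axis=1)
    J = phi.jacobian(pts)
    data = {"x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2], "position": disp}
    for d, ax in enumerate("xyz"):
        u = np.zeros(3)
        u[d] = 1.0
        data[f"tangent_{ax}"] = np.linalg.norm(J @ u - u, axis=1)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Error bounds


def zeroth_order_error_bound(phi: Diffeomorphism, branch: Branch,
                             n_probe: int = 50) -> float:
    """Worst-case error of zeroth-order mapping of an arc-length polyline.

    For the transformed curve ``f = phi o c`` and its zeroth-order spline
    ``g``, the maximum deviation is bounded by the maximum over segments of

        1/2 |Dphi(c(t)) - I|_2 (t_i - t_{i-1}) + |eps_i - eps_{i-1}|

    where ``eps_i = c(t_i) - phi(c(t_i))`` and ``|.|_2`` is the spectral
    norm, with the supremum over ``t`` in each segment approximated by
    ``n_probe`` uniform probe points (so the returned value is a probe-
    refined lower bound to the analytic supremum).
    """
    if n_probe < 2:
        raise ValueError("n_probe must be at least 2")
    eps = branch.knots - phi.map(branch.knots)
    eps_jump = np.linalg.norm(np.diff(eps, axis=0), axis=1)
    I = np.eye(3)
    bound = 0.0
    for i in range(len(branch) - 1):
        t0, t1 = branch.params[i], branch.params[i + 1]
        ts = np.linspace(t0, t1, n_probe)
        pts = branch.point_at(ts)
        dev = np.linalg.matrix_norm(phi.jacobian(pts) - I, ord=2)
        seg = 0.5 * float(np.max(dev)) * (t1 - t0) + eps_jump[i]
        bound = max(bound, float(seg))
    return bound


def spline_error_bounds(m2: float, m3: float, m4: float, delta: float):
    """Comparable worst-case bounds for zeroth- vs first-order reconstruction.

    Given per-coordinate derivative maxima of the transformed curve ``f``
    (``m2``: second derivatives at the knots, ``m3``: third derivatives at
    the knots, ``m4``: fourth derivative anywhere) and the maximum knot
    spacing ``delta``, returns the pair ``(zeroth_bound, first_bound)``:

        zeroth = 3/4 m4 (delta/2)^4 + 3/2 (delta/2)^3 m3 + 3/2 (delta/2)^2 m2
        first  = 3/24 m4 (delta/2)^4

    The first-order bound is never larger than the zeroth-order bound, and
    both are attained by worst-case curves.
    """
    if min(m2, m3, m4) < 0 or delta <= 0:
        raise ValueError("derivative maxima must be >= 0 and delta > 0")
    half = delta / 2.0
    zeroth = 0.75 * m4 * half**4 + 1.5 * half**3 * m3 + 1.5 * half**2 * m2
    first = (3.0 / 24.0) * m4 * half**4
    return zeroth, first
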