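"""Synthetic branches and neuron trees with known smooth generators.

Every fixture keeps its underlying smooth curve so that exact transformed
curves and derivatives can be sampled at arbitrary resolution for oracle
comparisons, independently of the discrete mapping pipeline under test.

Default knot spacings span roughly 1-50 microns, covering the sampling-period
regimes seen in manual neuron reconstructions: below ~10 microns discrete
mapping errors are small for any method, while sparse sampling is where the
choice of mapping order matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from jetmap.neuron_io import Branch, NeuronTree, SwcNode, arc_length_params

__all__ = ["SyntheticCurveSpec", "SmoothCurve", "make_branch", "make_tree"]


@dataclass
class SyntheticCurveSpec:
    """Recipe for a synthetic branch.

    family: 'line', 'helix', 'sinusoid', 'polynomial' or 'random-smooth';
    length: target arc length in microns; knot_spacing: scalar (uniform) or
    explicit list of spacings in microns; seed feeds the random families;
    params: family-specific extras (e.g. radius/pitch for the helix).
    """

    family: str
    length: float
    knot_spacing: float | list = 10.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")


class SmoothCurve:
    """A smooth 3D curve reparameterized by arc length.

    Wraps a parametric map ``f(u)`` on ``[0, u_max]`` (with analytic
    ``f'(u)``) and exposes ``position(s)`` and ``unit_tangent(s)`` for arc
    length ``s`` in ``[0, length]`` via a dense numeric reparameterization.
    """

    def __init__(self, f, df, u_max: float, n_dense: int = 20000):
        self._f = f
        self._df = df
        u = np.linspace(0.0, u_max, n_dense)
        pts = f(u)
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        self._u_of_s = lambda q: np.interp(q, s, u)
        self.length = float(s[-1])

    def position(self, s) -> np.ndarray:
        return self._f(self._u_of_s(np.asarray(s, dtype=float)))

    def unit_tangent(self, s) -> np.ndarray:
        d = self._df(self._u_of_s(np.asarray(s, dtype=float)))
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def sample(self, spacing: float = 0.1) -> np.ndarray:
        """Positions at uniform arc-length resolution (oracle sampling)."""
        s = np.linspace(0.0, self.length, max(int(np.ceil(self.length / spacing)) + 1, 2))
        return self.position(s)


def _perp_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    n1 = np.cross(d, ref)
    n1 /= np.linalg.norm(n1)
    return n1, np.cross(d, n1)


def _curve_from_spec(spec: SyntheticCurveSpec, start=None, direction=None) -> SmoothCurve:
    rng = np.random.default_rng(spec.seed)
    start = np.zeros(3) if start is None else np.asarray(start, dtype=float)
    if direction is None:
        direction = np.array([1.0, 0.0, 0.0])
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    L = spec.length
    p = spec.params

    if spec.family == "line":
        f = lambda u: start + np.multiply.outer(u, direction)
        df = lambda u: np.broadcast_to(direction, np.shape(u) + (3,)).copy()
        return SmoothCurve(f, df, L)

    if spec.family == "helix":
        r = p.get("radius", 20.0)
        pitch = p.get("pitch", 40.0)
        c = pitch / (2 * np.pi)
        q = np.hypot(r, c)  # speed with respect to the winding angle
        n1, n2 = _perp_frame(direction)

        def f(u):
            th = np.asarray(u) / q
            # offset so the curve starts at `start`
            return (
                start
                + np.multiply.outer(r * (np.cos(th) - 1.0), n1)
                + np.multiply.outer(r * np.sin(th), n2)
                + np.multiply.outer(c * th, direction)
            )

        def df(u):
            th = np.asarray(u) / q
            return (
                np.multiply.outer(-r / q * np.sin(th), n1)
                + np.multiply.outer(r / q * np.cos(th), n2)
                + np.multiply.outer(np.full(np.shape(th), c / q), direction)
            )

        return SmoothCurve(f, df, L)

    if spec.family == "sinusoid":
        amp = p.get("amplitude", 0.1 * L)
        wavelength = p.get("wavelength", 0.5 * L)
        k = 2 * np.pi / wavelength
        n1, _ = _perp_frame(direction)

        def f(u):
            u = np.asarray(u)
            return start + np.multiply.outer(u, direction) + np.multiply.outer(
                amp * np.sin(k * u), n1
            )

        def df(u):
            u = np.asarray(u)
            return np.broadcast_to(direction, np.shape(u) + (3,)) + np.multiply.outer(
                amp * k * np.cos(k * u), n1
            )

        return SmoothCurve(f, df, 1.5 * L)

    if spec.family == "polynomial":
        # gentle cubic bend in the two normal directions
        c2 = p.get("c2", 0.3 / L)
        c3 = p.get("c3", 0.1 / L**2)
        n1, n2 = _perp_frame(direction)

        def f(u):
            u = np.asarray(u)
            return (
                start
                + np.multiply.outer(u, direction)
                + np.multiply.outer(c2 * u**2, n1)
                + np.multiply.outer(c3 * u**3, n2)
            )

        def df(u):
            u = np.asarray(u)
            return (
                np.broadcast_to(direction, np.shape(u) + (3,))
                + np.multiply.outer(2 * c2 * u, n1)
                + np.multiply.outer(3 * c3 * u**2, n2)
            )

        return SmoothCurve(f, df, 1.5 * L)

    if spec.family == "random-smooth":
        wiggle = p.get("wiggle", 0.05)
        n_harm = p.get("n_harmonics", 3)
        n1, n2 = _perp_frame(direction)
        ks = np.arange(1, n_harm + 1)
        amp1 = wiggle * L * rng.uniform(0.3, 1.0, n_harm) / ks
        amp2 = wiggle * L * rng.uniform(0.3, 1.0, n_harm) / ks
        ph1 = rng.uniform(0, 2 * np.pi, n_harm)
        ph2 = rng.uniform(0, 2 * np.pi, n_harm)
        w = 2 * np.pi * ks / L

        def f(u):
            u = np.asarray(u)
            s1 = np.sum(amp1 * (np.sin(np.multiply.outer(u, w) + ph1)
                                - np.sin(ph1)), axis=-1)
            s2 = np.sum(amp2 * (np.sin(np.multiply.outer(u, w) + ph2)
                                - np.sin(ph2)), axis=-1)
            return (
                start
                + np.multiply.outer(u, direction)
                + np.multiply.outer(s1, n1)
                + np.multiply.outer(s2, n2)
            )

        def df(u):
            u = np.asarray(u)
            d1 = np.sum(amp1 * w * np.cos(np.multiply.outer(u, w) + ph1), axis=-1)
            d2 = np.sum(amp2 * w * np.cos(np.multiply.outer(u, w) + ph2), axis=-1)
            return (
                np.broadcast_to(direction, np.shape(u) + (3,))
                + np.multiply.outer(d1, n1)
                + np.multiply.outer(d2, n2)
            )

        return SmoothCurve(f, df, 1.5 * L)

    raise ValueError(f"unknown curve family {spec.family!r}")


def make_branch(spec: SyntheticCurveSpec, start=None, direction=None):
    """Sample a branch from a smooth synthetic curve.

    Knots are placed on the curve at the requested arc-length spacing; the
    branch carries cumulative chord-length parameters (the polyline's own
    arc length), exactly like a real trace. The underlying
    :class:`SmoothCurve` is returned alongside, with the knots' true
    arc-length coordinates in ``knot_arclengths``, so exact transformed
    curves are available for oracle comparisons.

    Returns
    -------
    (Branch, SmoothCurve)
    """
    curve = _curve_from_spec(spec, start=start, direction=direction)
    if np.isscalar(spec.knot_spacing):
        if spec.knot_spacing > spec.length:
            raise ValueError("knot_spacing exceeds curve length")
        n_seg = int(round(spec.length / spec.knot_spacing))
        s = np.linspace(0.0, spec.length, n_seg + 1)
    else:
        s = np.concatenate([[0.0], np.cumsum(np.asarray(spec.knot_spacing, dtype=float))])
        if s[-1] > curve.length + 1e-9:
            raise ValueError("spacings exceed curve length")
    knots = curve.position(s)
    branch = Branch(knots, arc_length_params(knots), [])
    curve.knot_arclengths = s
    return branch, curve


def make_tree(n_leaves: int, depth: int = 3, seed: int = 0,
              branch_length=(100.0, 300.0), knot_spacing=None,
              wiggle: float = 0.05) -> NeuronTree:
    """Random binary-ish tree of smooth branches welded at bifurcations.

    A trunk is grown from the origin; each additional leaf attaches a new
    random-smooth branch at a random interior node whose nesting order is
    below ``depth``. Knot spacing is drawn per branch from U(5, 40) microns
    unless given. The result is a valid, SWC-writable tree whose
    decomposition yields exactly ``n_leaves`` branches.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be at least 1")
    rng = np.random.default_rng(seed)

    nodes: list[SwcNode] = []
    # nodes that already have a child (attaching there adds a leaf), with
    # the nesting order of the branch they lie on
    attachable: list[tuple[int, int]] = []

    def grow(start_pos, parent_id, order):
        length = rng.uniform(*branch_length)
        spacing = knot_spacing if knot_spacing is not None else rng.uniform(5.0, 40.0)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        spec = SyntheticCurveSpec(
            "random-smooth", length, spacing,
            seed=int(rng.integers(2**31)), params={"wiggle": wiggle},
        )
        branch, _ = make_branch(spec, start=start_pos, direction=direction)
        pid = parent_id
        created = []
        knots = branch.knots if parent_id == -1 else branch.knots[1:]
        for pos in knots:
            nid = len(nodes) + 1
            nodes.append(SwcNode(nid, 0, pos, 1.0, pid))
            created.append(nid)
            pid = nid
        attachable.extend((nid, order) for nid in created[:-1])

    grow(np.zeros(3), -1, 0)
    for _ in range(n_leaves - 1):
        candidates = [(nid, o) for nid, o in attachable if o < depth]
        if not candidates:
            candidates = attachable
        nid, order = candidates[int(rng.integers(len(candidates)))]
        grow(nodes[nid - 1].position, nid, order + 1)
    return NeuronTree(nodes)
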