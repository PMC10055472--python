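"""SWC neuron trace I/O, validation, and decomposition into non-branching branches.

SWC is the standard plain-text format for neuron reconstructions: one node per
line with columns ``id type x y z radius parent`` (parent ``-1`` marks the
root). Positions are interpreted in microns. Radius is carried through
unchanged but plays no role in any computation here: a trace is treated as a
tree of piecewise-linear curves.

A tree is reduced to curves by recursively removing the root-to-leaf path of
longest arc length; each removal leaves subtrees that are reduced the same
way, starting from their attachment node. The resulting :class:`Branch`
objects are non-bifurcating polylines parameterized by cumulative arc length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SwcNode",
    "NeuronTree",
    "Branch",
    "SwcParseError",
    "TreeStructureError",
    "TreeValidationError",
    "read_swc",
    "write_swc",
    "decompose_tree",
]


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class TreeStructureError(ValueError):
    """Parent pointers do not encode a single rooted tree."""


class TreeValidationError(ValueError):
    """The tree violates a strict-mode invariant (e.g. repeated positions)."""


@dataclass(frozen=True)
class SwcNode:
    """One row of an SWC file.

    Attributes
    ----------
    id : int
        Positive node identifier, unique within a file.
    structure : int
        SWC structure-type code (carried, not interpreted).
    position : ndarray, shape (3,)
        Node coordinates in microns.
    radius : float
        Node radius in microns (carried, unused).
    parent : int
        Id of the parent node, or ``-1`` for the root.
    """

    id: int
    structure: int
    position: np.ndarray
    radius: float
    parent: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if self.id <= 0:
            raise ValueError(f"SWC node id must be positive, got {self.id}")
        if self.radius < 0:
            raise ValueError(f"SWC radius must be nonnegative, got {self.radius}")


class NeuronTree:
    """A rooted tree of SWC nodes with 3D positions in microns.

    Parameters
    ----------
    nodes : sequence of SwcNode
        Node table; parent pointers must encode a single rooted acyclic tree.
    strict : bool
        When True, repeated node positions raise :class:`TreeValidationError`.
        When False, zero-length edges (a child at its parent's exact position)
        are collapsed by re-attaching the child's children to the parent.
    """

    def __init__(self, nodes, strict: bool = True):
        nodes = list(nodes)
        if not strict:
            nodes = _collapse_zero_edges(nodes)
        self._nodes: dict[int, SwcNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise TreeStructureError(f"duplicate node id {node.id}")
            self._nodes[node.id] = node

        roots = [n.id for n in nodes if n.parent == -1]
        if len(roots) != 1:
            raise TreeStructureError(
                f"expected exactly one root, found {len(roots)}: {sorted(roots)}"
            )
        self._root = roots[0]

        self._children: dict[int, list[int]] = {n.id: [] for n in nodes}
        for node in nodes:
            if node.parent == -1:
                continue
            if node.parent not in self._nodes:
                raise TreeStructureError(
                    f"node {node.id} refers to missing parent {node.parent}"
                )
            self._children[node.parent].append(node.id)
        for kids in self._children.values():
            kids.sort()

        self._check_connected_acyclic()
        if strict:
            self._check_unique_positions()

    def _check_connected_acyclic(self) -> None:
        seen = set()
        stack = [self._root]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise TreeStructureError(f"cycle detected at node {nid}")
            seen.add(nid)
            stack.extend(self._children[nid])
        if len(seen) != len(self._nodes):
            orphans = sorted(set(self._nodes) - seen)
            raise TreeStructureError(
                f"{len(orphans)} node(s) unreachable from root: {orphans[:10]}"
            )

    def _check_unique_positions(self) -> None:
        by_pos: dict[tuple, int] = {}
        for node in self._nodes.values():
            key = tuple(node.position)
            if key in by_pos:
                raise TreeValidationError(
                    f"nodes {by_pos[key]} and {node.id} share position {key}"
                )
            by_pos[key] = node.id

    # -- accessors ---------------------------------------------------------
    @property
    def root(self) -> int:
        return self._root

    @property
    def nodes(self) -> dict[int, SwcNode]:
        return dict(self._nodes)

    def node(self, nid: int) -> SwcNode:
        return self._nodes[nid]

    def children(self, nid: int) -> list[int]:
        return list(self._children[nid])

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self):
        return iter(self._nodes.values())

    def edges(self) -> list[tuple[int, int]]:
        """All (parent, child) id pairs."""
        return [
            (n.parent, n.id) for n in self._nodes.values() if n.parent != -1
        ]

    def leaves(self) -> list[int]:
        return [nid for nid, kids in self._children.items() if not kids]

    def positions(self) -> np.ndarray:
        """Node positions stacked in topological order, shape (n, 3)."""
        return np.array([self._nodes[nid].position for nid in self.topological_order()])

    def topological_order(self) -> list[int]:
        """Node ids with every parent before its children (DFS, child ids ascending)."""
        order: list[int] = []
        stack = [self._root]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(self._children[nid]))
        return order

    def translated(self, offset) -> "NeuronTree":
        """A copy of the tree with ``offset`` added to every position."""
        offset = np.asarray(offset, dtype=float).reshape(3)
        return NeuronTree(
            [
                SwcNode(n.id, n.structure, n.position + offset, n.radius, n.parent)
                for n in self._nodes.values()
            ]
        )

    def centroid(self) -> np.ndarray:
        return np.mean([n.position for n in self._nodes.values()], axis=0)


def _collapse_zero_edges(nodes: list[SwcNode]) -> list[SwcNode]:
    """Drop children located exactly at their parent, re-attaching grandchildren."""
    by_id = {n.id: n for n in nodes}
    dropped: dict[int, int] = {}  # dropped child id -> surviving ancestor id
    for n in nodes:
        if n.parent != -1 and n.parent in by_id:
            if np.array_equal(n.position, by_id[n.parent].position):
                dropped[n.id] = n.parent
    if not dropped:
        return nodes

    def resolve(nid: int) -> int:
        while nid in dropped:
            nid = dropped[nid]
        return nid

    logger.info("collapsed %d zero-length edge(s)", len(dropped))
    out = []
    for n in nodes:
        if n.id in dropped:
            continue
        parent = resolve(n.parent) if n.parent != -1 else -1
        out.append(SwcNode(n.id, n.structure, n.position, n.radius, parent))
    return out


@dataclass
class Branch:
    """A non-bifurcating polyline: the curve ``c`` at its knots ``t_i``.

    Attributes
    ----------
    knots : ndarray, shape (n, 3)
        Ordered knot positions in microns; consecutive knots are distinct.
    params : ndarray, shape (n,)
        Cumulative arc length (microns): ``t_1 = 0`` and ``t_i - t_{i-1}``
        is the Euclidean distance between consecutive knots, so the
        piecewise-linear curve is parameterized by arc length.
    source_ids : list of int
        SWC ids the knots originated from (empty for synthetic branches).
    """

    knots: np.ndarray
    params: np.ndarray
    source_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.ndim != 2 or self.knots.shape[1] != 3:
            raise ValueError("knots must have shape (n, 3)")
        if len(self.knots) < 2:
            raise ValueError("a branch needs at least two knots")
        if self.params is None:
            self.params = arc_length_params(self.knots)
        self.params = np.asarray(self.params, dtype=float)
        if self.params.shape != (len(self.knots),):
            raise ValueError("params must have one entry per knot")
        steps = np.diff(self.params)
        if np.any(steps <= 0):
            raise ValueError("params must be strictly increasing")
        chords = np.linalg.norm(np.diff(self.knots, axis=0), axis=1)
        if np.any(chords == 0):
            raise ValueError("consecutive knots must be distinct")
        if not np.allclose(steps, chords, rtol=1e-9, atol=1e-9):
            raise ValueError("params must be cumulative arc length of the knots")

    def __len__(self) -> int:
        return len(self.knots)

    @property
    def length(self) -> float:
        """Total arc length in microns."""
        return float(self.params[-1] - self.params[0])

    def segment_lengths(self) -> np.ndarray:
        return np.diff(self.params)

    def point_at(self, t) -> np.ndarray:
        """Linear interpolation of the polyline at arc-length parameter(s) t."""
        t = np.asarray(t, dtype=float)
        return np.stack(
            [np.interp(t, self.params, self.knots[:, d]) for d in range(3)], axis=-1
        )

    def drop_knot(self, index: int) -> "Branch":
        """The branch with interior knot ``index`` removed and arc length recomputed."""
        if index <= 0 or index >= len(self.knots) - 1:
            raise ValueError("only interior knots can be dropped")
        knots = np.delete(self.knots, index, axis=0)
        ids = [s for i, s in enumerate(self.source_ids) if i != index]
        return Branch(knots, arc_length_params(knots), ids)


def arc_length_params(knots: np.ndarray) -> np.ndarray:
    """Cumulative chord length of a polyline, starting at 0."""
    knots = np.asarray(knots, dtype=float)
    chords = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(chords)])


# ---------------------------------------------------------------------------
# SWC reading / writing


def read_swc(path, strict: bool = True) -> NeuronTree:
    """Read an SWC file into a validated :class:`NeuronTree`.

    Lines starting with ``#`` are comments. Each record must have at least
    seven whitespace-delimited columns (id, type, x, y, z, radius, parent);
    extra trailing columns are ignored with a warning.

    Parameters
    ----------
    path : path-like
        File to read.
    strict : bool
        Reject repeated node positions (and zero-length edges). With
        ``strict=False`` zero-length edges are collapsed instead.
    """
    path = Path(path)
    nodes: list[SwcNode] = []
    extra_cols = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 7:
                raise SwcParseError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            if len(fields) > 7:
                extra_cols = True
            try:
                nodes.append(
                    SwcNode(
                        id=int(fields[0]),
                        structure=int(fields[1]),
                        position=np.array([float(f) for f in fields[2:5]]),
                        radius=float(fields[5]),
                        parent=int(fields[6]),
                    )
                )
            except ValueError as exc:
                raise SwcParseError(f"{path.name}:{lineno}: {exc}") from exc
    if extra_cols:
        warnings.warn(f"{path.name}: ignoring extra trailing columns", stacklevel=2)
    if not nodes:
        raise SwcParseError(f"{path.name}: no records found")
    return NeuronTree(nodes, strict=strict)


def write_swc(tree: NeuronTree, path, precision: int = 6):
    """Write a tree as 7-column SWC, parents before children.

    Positions are written with ``precision`` decimal digits (default 6,
    i.e. picometer resolution for micron coordinates).
    """
    path = Path(path)
    fmt = f"{{:.{precision}f}}"
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in tree.topological_order():
            n = tree.node(nid)
            x, y, z = (fmt.format(v) for v in n.position)
            fh.write(
                f"{n.id} {n.structure} {x} {y} {z} {fmt.format(n.radius)} {n.parent}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Decomposition into branches


def decompose_tree(tree: NeuronTree) -> list[Branch]:
    """Reduce a neuron tree to an ordered list of non-bifurcating branches.

    The root-to-leaf path of longest arc length is removed first; every
    subtree left hanging off a removed path is then reduced by the same rule,
    with its branch starting at the attachment node (the attachment position
    is duplicated into the child branch so each branch is geometrically
    self-contained). Ties in arc length are broken toward the leaf with the
    smaller SWC id, so the decomposition is deterministic.

    Every parent-child edge of the tree appears in exactly one branch, and
    the number of branches equals the number of leaves.

    Returns an empty list for trees with fewer than 2 nodes.
    """
    if len(tree) < 2:
        return []

    # Post-order pass: longest downstream arc length and the leaf realizing it.
    longest: dict[int, tuple[float, int, int]] = {}  # nid -> (arc, leaf_id, next_nid)
    for nid in reversed(tree.topological_order()):
        kids = tree.children(nid)
        if not kids:
            longest[nid] = (0.0, nid, -1)
            continue
        best = None
        for kid in kids:
            edge = float(
                np.linalg.norm(tree.node(kid).position - tree.node(nid).position)
            )
            arc, leaf, _ = longest[kid]
            cand = (edge + arc, leaf, kid)
            if best is None or cand[0] > best[0] or (
                cand[0] == best[0] and cand[1] < best[1]
            ):
                best = cand
        longest[nid] = best

    branches: list[Branch] = []
    # Each queue entry is (attachment node, forced first step or None). The
    # root pass has no forced step; a subtree pass starts at its attachment
    # node and must descend into the subtree's top node.
    queue: list[tuple[int, int | None]] = [(tree.root, None)]
    while queue:
        att, first = queue.pop(0)
        path = [att] if first is None else [att, first]
        nid = path[-1]
        while longest[nid][2] != -1:
            nid = longest[nid][2]
            path.append(nid)
        # Off-path children spawn their own branches, anchored where they
        # attach. In a subtree pass the attachment node's other children were
        # already queued by the pass that extracted the parent branch.
        start_k = 0 if first is None else 1
        for k in range(start_k, len(path)):
            pid = path[k]
            successor = path[k + 1] if k + 1 < len(path) else None
            for kid in tree.children(pid):
                if kid != successor:
                    queue.append((pid, kid))
        knots = np.array([tree.node(p).position for p in path])
        branches.append(Branch(knots, arc_length_params(knots), list(path)))
    return branches
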