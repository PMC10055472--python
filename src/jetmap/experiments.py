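"""Experiment pipelines: sigma-sweep mapping comparison and node-removal study.

The sweep protocol mirrors how mapped neuron morphologies are evaluated:
traces are centered at the origin, random LDDMM diffeomorphisms are drawn at
several momentum-noise levels sigma, and each branch is mapped three ways —
dense ground truth (2-micron upsampling then zeroth order), zeroth order, and
first order. Per neuron, the discrete Frechet error from ground truth and the
Kolmogorov-Smirnov statistics of four morphometric distributions are
recorded, together with the mean sampling period of the trace.

The removal study asks which trace nodes are redundant under mapping: every
non-branching node whose path angle exceeds a straightness threshold
(default 170 degrees) is removed individually from its local segment; if the
first-order mapping of the reduced segment stays within an error threshold
(default 1 micron, discrete Frechet) of the ground-truth mapping of the
original segment, the node is flagged removable.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from jetmap.diffeo import GridDiffeomorphism, LddmmConfig, random_lddmm_diffeo
from jetmap.jet_core import (
    dense_ground_truth,
    first_order_map,
    upsample_branch,
    upsample_indices,
    zeroth_order_map,
)
from jetmap.metrics import discrete_frechet, ks_statistic, morphometrics
from jetmap.neuron_io import Branch, NeuronTree, SwcNode, arc_length_params, decompose_tree

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "center_tree",
    "forest_bounds",
    "mapped_tree_from_curves",
    "run_mapping_experiment",
    "run_removal_experiment",
    "sweep_forest",
    "removal_forest",
]


@dataclass
class ExperimentConfig:
    """Knobs of the experiment pipelines.

    gt_spacing: maximum knot spacing (microns) of the ground-truth
    upsampling. aggregate: how per-branch Frechet errors combine into one
    per-neuron error ('max' is conservative; 'mean' available). center:
    'centroid' or 'bbox' recentering of each trace. grid_spacing /
    kernel_width / n_timesteps configure the LDDMM generator. morphometry
    toggles the KS portion of the sweep.
    """

    gt_spacing: float = 2.0
    aggregate: str = "max"
    center: str = "centroid"
    grid_spacing: float = 100.0
    kernel_width: float | None = None
    n_timesteps: int = 10
    morphometry: bool = True

    def __post_init__(self):
        if self.aggregate not in ("max", "mean"):
            raise ValueError("aggregate must be 'max' or 'mean'")
        if self.center not in ("centroid", "bbox"):
            raise ValueError("center must be 'centroid' or 'bbox'")


def sweep_forest(seed: int, n_trees: int = 20, n_leaves: int = 3) -> list[NeuronTree]:
    """Reference forest for the sigma-sweep study.

    Random smooth trees whose per-branch knot spacing is drawn from
    U(5, 40) microns, covering the range of sampling periods seen in manual
    reconstructions (sparse sampling is where mapping order matters).
    """
    from jetmap.synthetic import make_tree

    rng = np.random.default_rng(seed)
    return [
        make_tree(n_leaves, seed=int(rng.integers(2**31))) for _ in range(n_trees)
    ]


def removal_forest(seed: int, n_trees: int = 20, n_leaves: int = 3) -> list[NeuronTree]:
    """Reference forest for the node-removal study.

    Uses a uniform 10-micron knot spacing, emulating densely sampled
    reconstructions: the removal question (is a nearly collinear node
    redundant?) presumes traces sampled finely enough that a straight
    node's chord deviation is well below the 1-micron error threshold.
    """
    from jetmap.synthetic import make_tree

    rng = np.random.default_rng(seed)
    return [
        make_tree(n_leaves, seed=int(rng.integers(2**31)), knot_spacing=10.0)
        for _ in range(n_trees)
    ]


def center_tree(tree: NeuronTree, mode: str = "centroid") -> NeuronTree:
    """Translate a tree so its centroid (or bounding-box center) is the origin."""
    if mode == "centroid":
        offset = -tree.centroid()
    else:
        pos = tree.positions()
        offset = -(pos.min(axis=0) + pos.max(axis=0)) / 2.0
    return tree.translated(offset)


def forest_bounds(trees) -> np.ndarray:
    """Joint bounding box of several trees, shape (3, 2)."""
    pos = np.vstack([t.positions() for t in trees])
    return np.stack([pos.min(axis=0), pos.max(axis=0)], axis=1)


def mean_sampling_period(tree: NeuronTree) -> float:
    """Average distance between connected trace nodes (microns)."""
    lengths = [
        np.linalg.norm(tree.node(c).position - tree.node(p).position)
        for p, c in tree.edges()
    ]
    return float(np.mean(lengths))


def mapped_tree_from_curves(branches, curves, params_list) -> NeuronTree:
    """Reassemble mapped branches into a NeuronTree for morphometry.

    Each mapped curve is sampled at the supplied parameter values (the
    ground-truth parameters of its branch, whose first and original-knot
    entries coincide with the branch knots). Branches are welded back at
    their attachment nodes via the source SWC ids carried by the
    decomposition.
    """
    nodes: list[SwcNode] = []
    id_map: dict[int, int] = {}  # source SWC id -> new node id
    for branch, curve, ts in zip(branches, curves, params_list):
        pts = np.atleast_2d(curve(ts))
        orig_idx = set(upsample_indices(branch, _spacing_of(branch, ts)).tolist())
        src = branch.source_ids
        if not nodes:
            parent = -1
            start = 0
        else:
            parent = id_map[src[0]]
            start = 1  # first sample duplicates the attachment node
        src_at = {}
        # map dense index -> which original knot it is, if any
        idx_sorted = sorted(orig_idx)
        for rank, di in enumerate(idx_sorted):
            src_at[di] = src[rank] if src else None
        for i in range(start, len(pts)):
            nid = len(nodes) + 1
            nodes.append(SwcNode(nid, 0, pts[i], 1.0, parent))
            parent = nid
            if i in src_at and src_at[i] is not None:
                id_map[src_at[i]] = nid
    return NeuronTree(nodes, strict=False)


def _spacing_of(branch: Branch, ts) -> float:
    # the ground-truth params were produced by upsample_branch; recover the
    # spacing bound from the largest step (robust to exact float layout)
    return float(np.max(np.diff(ts))) + 1e-12


def _branch_error(curve, gt) -> float:
    pts = np.atleast_2d(curve(gt.knot_params))
    return discrete_frechet(pts, gt.knot_positions)


def run_mapping_experiment(trees, sigmas, seeds,
                           config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Sigma-sweep comparison of zeroth- and first-order mapping.

    For every seed, one random diffeomorphism is generated per sigma (the
    same seed scales the same momentum draw, so fields grow nested with
    sigma) over the joint bounding box of the centered trees. Each neuron is
    mapped by both methods and compared to dense ground truth.

    Returns a tidy DataFrame with one row per neuron x sigma x seed x
    method and columns ``neuron, sigma, seed, method, frechet_error,
    ks_path_angle, ks_branch_angle, ks_tortuosity, ks_segment_length,
    mean_sampling_period``.
    """
    config = config or ExperimentConfig()
    centered = [center_tree(t, config.center) for t in trees]
    bounds = forest_bounds(centered)
    records = []
    for seed in seeds:
        for sigma in sigmas:
            t0 = time.perf_counter()
            phi = random_lddmm_diffeo(LddmmConfig(
                sigma=sigma, bounds=bounds, grid_spacing=config.grid_spacing,
                kernel_width=config.kernel_width,
                n_timesteps=config.n_timesteps, seed=seed,
            ))
            if getattr(phi, "flagged_non_diffeomorphic", False):
                logger.warning(
                    "excluding non-diffeomorphic field sigma=%s seed=%s",
                    sigma, seed,
                )
                continue
            for ni, tree in enumerate(centered):
                records.extend(
                    _map_one_tree(ni, tree, phi, sigma, seed, config)
                )
            logger.info("sigma=%s seed=%s done in %.1fs", sigma, seed,
                        time.perf_counter() - t0)
    return pd.DataFrame.from_records(records)


def _map_one_tree(ni, tree, phi, sigma, seed, config) -> list[dict]:
    branches = decompose_tree(tree)
    gts, curves0, curves1 = [], [], []
    err0, err1 = [], []
    for br in branches:
        gt = dense_ground_truth(br, phi, config.gt_spacing)
        c0 = zeroth_order_map(br, phi)
        c1 = first_order_map(br, phi)
        gts.append(gt)
        curves0.append(c0)
        curves1.append(c1)
        err0.append(_branch_error(c0, gt))
        err1.append(_branch_error(c1, gt))
    agg = np.max if config.aggregate == "max" else np.mean
    period = mean_sampling_period(tree)
    rows = []
    ks = {0: {}, 1: {}}
    if config.morphometry:
        params = [gt.knot_params for gt in gts]
        gt_tree = mapped_tree_from_curves(branches, gts, params)
        gt_morph = morphometrics(gt_tree).as_dict()
        for order, curves in ((0, curves0), (1, curves1)):
            m = morphometrics(
                mapped_tree_from_curves(branches, curves, params)
            ).as_dict()
            for name in gt_morph:
                # quantize at 1e-9 (nano-degree / nano-micron): the KS
                # statistic is tie-sensitive, and float jitter between
                # evaluation paths would otherwise register as signal
                a, b = np.round(gt_morph[name], 9), np.round(m[name], 9)
                ks[order][f"ks_{name}"] = (
                    ks_statistic(a, b) if a.size and b.size else np.nan
                )
    for order, errs in ((0, err0), (1, err1)):
        rows.append({
            "neuron": ni, "sigma": sigma, "seed": seed,
            "method": "zeroth" if order == 0 else "first",
            "frechet_error": float(agg(errs)),
            "mean_sampling_period": period,
            **ks[order],
        })
    return rows


# ---------------------------------------------------------------------------
# Node-removal (downsampling) study


def _qualifying_nodes(tree: NeuronTree, branch: Branch,
                      angle_threshold: float) -> list[int]:
    """Interior knot indices that are non-branching and nearly straight."""
    out = []
    for i in range(1, len(branch) - 1):
        sid = branch.source_ids[i] if branch.source_ids else None
        if sid is not None and len(tree.children(sid)) != 1:
            continue  # bifurcation (or leaf) in the full tree
        u = branch.knots[i] - branch.knots[i - 1]
        v = branch.knots[i + 1] - branch.knots[i]
        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        angle = 180.0 - np.degrees(np.arccos(np.clip(cos, -1, 1)))
        if angle > angle_threshold:
            out.append(i)
    return out


def run_removal_experiment(trees, sigmas, seeds, angle_threshold: float = 170.0,
                           error_threshold: float = 1.0,
                           config: ExperimentConfig | None = None):
    """Which straight-segment nodes can be dropped without distorting the map?

    For each non-branching node with path angle above ``angle_threshold``,
    the local two-segment polyline (previous knot, node, next knot) is
    reduced to a single straight segment with the node removed; the reduced
    segment is mapped first order and compared (discrete Frechet) with the
    ground-truth mapping of the original two segments. Nodes are examined
    one at a time, never jointly.

    Returns
    -------
    (records, fractions) : pair of DataFrames
        ``records`` has one row per qualifying node x sigma x seed with the
        post-removal error and a ``removable`` flag (error <=
        ``error_threshold``); ``fractions`` aggregates the removable
        fraction per neuron x sigma x seed.
    """
    if angle_threshold <= 0 or error_threshold <= 0:
        raise ValueError("thresholds must be positive")
    config = config or ExperimentConfig()
    centered = [center_tree(t, config.center) for t in trees]
    bounds = forest_bounds(centered)
    rows = []
    for seed in seeds:
        for sigma in sigmas:
            phi = random_lddmm_diffeo(LddmmConfig(
                sigma=sigma, bounds=bounds, grid_spacing=config.grid_spacing,
                kernel_width=config.kernel_width,
                n_timesteps=config.n_timesteps, seed=seed,
            ))
            if getattr(phi, "flagged_non_diffeomorphic", False):
                logger.warning(
                    "excluding non-diffeomorphic field sigma=%s seed=%s",
                    sigma, seed,
                )
                continue
            for ni, tree in enumerate(centered):
                for br in decompose_tree(tree):
                    if len(br) < 3:
                        continue
                    for i in _qualifying_nodes(tree, br, angle_threshold):
                        err = _removal_error(br, i, phi, config.gt_spacing)
                        rows.append({
                            "neuron": ni,
                            "node": br.source_ids[i] if br.source_ids else i,
                            "sigma": sigma, "seed": seed,
                            "path_angle": _path_angle(br, i),
                            "frechet_error": err,
                            "removable": err <= error_threshold,
                        })
    records = pd.DataFrame.from_records(rows)
    if records.empty:
        return records, records
    fractions = (
        records.groupby(["neuron", "sigma", "seed"])["removable"]
        .mean().rename("removable_fraction").reset_index()
    )
    return records, fractions


def _path_angle(branch: Branch, i: int) -> float:
    u = branch.knots[i] - branch.knots[i - 1]
    v = branch.knots[i + 1] - branch.knots[i]
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(180.0 - np.degrees(np.arccos(np.clip(cos, -1, 1))))


def _removal_error(branch: Branch, i: int, phi, gt_spacing: float) -> float:
    local = branch.knots[i - 1:i + 2]
    original = Branch(local, arc_length_params(local), [])
    reduced_knots = local[[0, 2]]
    reduced = Branch(reduced_knots, arc_length_params(reduced_knots), [])
    gt = dense_ground_truth(original, phi, gt_spacing)
    mapped = first_order_map(reduced, phi)
    dense_reduced = upsample_branch(reduced, gt_spacing)
    pts = np.atleast_2d(mapped(dense_reduced.params))
    return discrete_frechet(pts, gt.knot_positions)
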