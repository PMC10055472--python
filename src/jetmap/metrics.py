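"""Curve comparison and morphometric statistics.

Mapped curves are compared with the discrete Frechet distance: the minimum,
over monotone couplings of two point sequences, of the largest coupled-pair
distance. It upper-bounds the continuous Frechet distance and is computed
with the standard dynamic program.

Whole-neuron comparisons use four common morphometric quantities — path
angle, branch angle, tortuosity, and segment length — whose per-neuron
distributions are compared with the two-sample Kolmogorov-Smirnov statistic.
Zeroth- versus first-order differences across neurons are tested with the
two-sided Wilcoxon signed-rank test under a Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

from jetmap.neuron_io import NeuronTree, decompose_tree

logger = logging.getLogger(__name__)

__all__ = [
    "discrete_frechet",
    "MorphometrySample",
    "morphometrics",
    "ks_statistic",
    "PairedTestResult",
    "paired_comparison",
]


@njit(cache=False)
def _frechet_dp(P: np.ndarray, Q: np.ndarray) -> float:
    n, m = P.shape[0], Q.shape[0]
    prev = np.empty(m)
    curr = np.empty(m)
    for j in range(m):
        d = 0.0
        for k in range(3):
            d += (P[0, k] - Q[j, k]) ** 2
        d = np.sqrt(d)
        prev[j] = d if j == 0 else max(prev[j - 1], d)
    for i in range(1, n):
        for j in range(m):
            d = 0.0
            for k in range(3):
                d += (P[i, k] - Q[j, k]) ** 2
            d = np.sqrt(d)
            if j == 0:
                best = prev[0]
            else:
                best = min(prev[j], prev[j - 1], curr[j - 1])
            curr[j] = max(best, d)
        prev, curr = curr, prev
    return prev[m - 1]


def discrete_frechet(P, Q) -> float:
    """Discrete Frechet distance between two 3D point sequences (microns).

    Symmetric, nonnegative, and zero exactly when the sequences can be
    coupled monotonically at distance zero.
    """
    P = np.ascontiguousarray(np.atleast_2d(np.asarray(P, dtype=float)))
    Q = np.ascontiguousarray(np.atleast_2d(np.asarray(Q, dtype=float)))
    if P.size == 0 or Q.size == 0:
        raise ValueError("point sequences must be nonempty")
    if P.shape[1] != 3 or Q.shape[1] != 3:
        raise ValueError("point sequences must have shape (n, 3)")
    return float(_frechet_dp(P, Q))


@dataclass
class MorphometrySample:
    """Pooled per-neuron morphometric distributions.

    path_angles and branch_angles in degrees within [0, 180]; tortuosities
    dimensionless and >= 1; segment_lengths in microns and > 0.
    """

    path_angles: np.ndarray
    branch_angles: np.ndarray
    tortuosities: np.ndarray
    segment_lengths: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "path_angle": self.path_angles,
            "branch_angle": self.branch_angles,
            "tortuosity": self.tortuosities,
            "segment_length": self.segment_lengths,
        }


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    # atan2 form: well-conditioned near 0 and 180 degrees, where arccos of
    # a normalized dot product loses half the significant digits
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def morphometrics(tree: NeuronTree) -> MorphometrySample:
    """Compute the four morphometric distributions of a neuron tree.

    * path angle: at each non-root node with exactly one child, the angle
      subtended at the node by its parent and child; 180 degrees means
      locally straight;
    * branch angle: at each node with two or more children, the angle
      between the outgoing segments of every unordered child pair;
    * segment length: Euclidean length of every parent-child edge;
    * tortuosity: per decomposed branch, arc length divided by the
      endpoint-to-endpoint Euclidean distance (>= 1).

    Degenerate zero-length vectors are excluded with a logged count.
    """
    if len(tree) < 2:
        raise ValueError("morphometrics require a tree with at least 2 nodes")
    path_angles, branch_angles, seg_lengths = [], [], []
    skipped = 0
    for node in tree:
        pos = node.position
        kids = tree.children(node.id)
        for kid in kids:
            seg = float(np.linalg.norm(tree.node(kid).position - pos))
            if seg > 0:
                seg_lengths.append(seg)
            else:
                skipped += 1
        if node.parent != -1 and len(kids) == 1:
            # angle between the two segments meeting at the node, measured so
            # that a locally straight trace scores 180 degrees
            to_parent = tree.node(node.parent).position - pos
            to_child = tree.node(kids[0]).position - pos
            if np.linalg.norm(to_parent) == 0 or np.linalg.norm(to_child) == 0:
                skipped += 1
            else:
                path_angles.append(_angle_deg(to_parent, to_child))
        if len(kids) >= 2:
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    u = tree.node(kids[a]).position - pos
                    v = tree.node(kids[b]).position - pos
                    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
                        skipped += 1
                    else:
                        branch_angles.append(_angle_deg(u, v))
    tortuosities = []
    for br in decompose_tree(tree):
        span = float(np.linalg.norm(br.knots[-1] - br.knots[0]))
        if span > 0:
            tortuosities.append(br.length / span)
        else:
            skipped += 1
    if skipped:
        logger.info("morphometrics: excluded %d degenerate element(s)", skipped)
    return MorphometrySample(
        path_angles=np.asarray(path_angles),
        branch_angles=np.asarray(branch_angles),
        tortuosities=np.asarray(tortuosities),
        segment_lengths=np.asarray(seg_lengths),
    )


def ks_statistic(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic: sup |ECDF_a - ECDF_b|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    return float(stats.ks_2samp(a, b).statistic)


@dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon signed-rank result with Bonferroni correction.

    ``p_corrected`` is the two-sided p-value multiplied by ``n_corrections``
    and capped at 1; ``degenerate`` is set (and p-values are NaN) when every
    paired difference is zero.
    """

    p_raw: float
    p_corrected: float
    median_difference: float
    n_pairs: int
    degenerate: bool = False


def paired_comparison(errors_zeroth, errors_first,
                      n_corrections: int = 4) -> PairedTestResult:
    """Test paired zeroth- vs first-order errors across neurons.

    Differences are ``zeroth - first`` per neuron; a positive median means
    the first-order method had smaller error. The two-sided Wilcoxon
    signed-rank p-value is Bonferroni-corrected by ``n_corrections`` (one
    per sigma level in the sweep).
    """
    a = np.asarray(errors_zeroth, dtype=float)
    b = np.asarray(errors_first, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("inputs must be equal-length nonempty 1D samples")
    if n_corrections < 1:
        raise ValueError("n_corrections must be at least 1")
    diffs = a - b
    if np.all(diffs == 0):
        return PairedTestResult(np.nan, np.nan, 0.0, a.size, degenerate=True)
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return PairedTestResult(
        p_raw=float(res.pvalue),
        p_corrected=min(1.0, float(res.pvalue) * n_corrections),
        median_difference=float(np.median(diffs)),
        n_pairs=int(a.size),
    )
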