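"""SWC parsing, validation, and decomposition into non-branching branches."""

import numpy as np
import pytest

from jetmap.neuron_io import (
    Branch,
    NeuronTree,
    SwcNode,
    SwcParseError,
    TreeStructureError,
    TreeValidationError,
    arc_length_params,
    decompose_tree,
    read_swc,
    write_swc,
)
from jetmap.synthetic import make_tree


def test_read_minimal_file(y_tree_swc):
    tree = read_swc(y_tree_swc)
    assert len(tree) == 4
    assert tree.root == 1
    assert tree.children(2) == [3, 4]
    np.testing.assert_allclose(tree.node(3).position, [3, 0, 0])


def test_dangling_parent_is_structure_error(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 0 0 0 0 1 -1\n5 0 1 0 0 1 99\n")
    with pytest.raises(TreeStructureError, match="99"):
        read_swc(p)


def test_malformed_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 0 0 0 0 1 -1\n2 0 x 0 0 1 1\n")
    with pytest.raises(SwcParseError, match=":2"):
        read_swc(p)


def test_multiple_roots_rejected(tmp_path):
    p = tmp_path / "two_roots.swc"
    p.write_text("1 0 0 0 0 1 -1\n2 0 1 0 0 1 -1\n")
    with pytest.raises(TreeStructureError, match="root"):
        read_swc(p)


def test_duplicate_positions_strict_vs_lenient(tmp_path):
    p = tmp_path / "dup.swc"
    p.write_text("1 0 0 0 0 1 -1\n2 0 0 0 0 1 1\n3 0 5 0 0 1 2\n")
    with pytest.raises(TreeValidationError, match="1 and 2"):
        read_swc(p, strict=True)
    tree = read_swc(p, strict=False)  # zero-length edge collapsed
    assert len(tree) == 2
    assert tree.node(3).parent == 1


def test_roundtrip_preserves_node_table(tmp_path, rng):
    tree = make_tree(4, seed=11)
    path = write_swc(tree, tmp_path / "t.swc")
    back = read_swc(path)
    assert sorted(back.nodes) == sorted(tree.nodes)
    for nid, node in tree.nodes.items():
        other = back.node(nid)
        assert other.parent == node.parent
        np.testing.assert_allclose(other.position, node.position, atol=1e-6)


def test_single_node_tree_roundtrip(tmp_path):
    tree = NeuronTree([SwcNode(1, 0, [1.5, -2.25, 3.0], 2.0, -1)])
    back = read_swc(write_swc(tree, tmp_path / "one.swc"))
    assert len(back) == 1
    assert back.node(1).parent == -1


def test_extra_columns_warn(tmp_path):
    p = tmp_path / "extra.swc"
    p.write_text("1 0 0 0 0 1 -1 99\n2 0 1 0 0 1 1 99\n")
    with pytest.warns(UserWarning, match="extra"):
        tree = read_swc(p)
    assert len(tree) == 2


# ---------------------------------------------------------------------------
# decomposition


def test_chain_decomposes_to_single_branch():
    nodes = [SwcNode(i + 1, 0, [float(i), 0, 0], 1, i if i else -1) for i in range(5)]
    branches = decompose_tree(NeuronTree(nodes))
    assert len(branches) == 1
    assert len(branches[0]) == 5
    np.testing.assert_allclose(branches[0].params, [0, 1, 2, 3, 4])


def test_tiny_tree_yields_no_branches():
    assert decompose_tree(NeuronTree([SwcNode(1, 0, [0, 0, 0], 1, -1)])) == []


def test_y_tree_longest_path_first(y_tree_swc):
    """Longest root-to-leaf arm (R-A-B, arc 3) is removed before the short arm."""
    branches = decompose_tree(read_swc(y_tree_swc))
    assert [b.source_ids for b in branches] == [[1, 2, 3], [2, 4]]
    # the sub-branch starts at the attachment node, so geometry is continuous
    np.testing.assert_allclose(branches[1].knots[0], [1, 0, 0])


def _brute_force_branches(tree):
    """Oracle: recursively enumerate all start-to-leaf paths and pick longest."""

    def arc(path):
        return sum(
            np.linalg.norm(tree.node(b).position - tree.node(a).position)
            for a, b in zip(path, path[1:])
        )

    def all_paths(start, first=None):
        heads = [first] if first is not None else tree.children(start)
        if not heads:
            return [[start]]
        out = []
        for h in heads:
            for tail in all_paths(h):
                out.append([start] + tail)
        return out

    results = []
    queue = [(tree.root, None)]
    while queue:
        start, first = queue.pop(0)
        paths = all_paths(start, first)
        best = max(paths, key=lambda p: (arc(p), -p[-1]))
        results.append(best)
        start_k = 0 if first is None else 1
        for k in range(start_k, len(best)):
            nxt = best[k + 1] if k + 1 < len(best) else None
            for kid in tree.children(best[k]):
                if kid != nxt:
                    queue.append((best[k], kid))
    return results


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_decomposition_matches_brute_force_path_enumeration(seed):
    tree = make_tree(5, seed=seed)
    got = [b.source_ids for b in decompose_tree(tree)]
    expected = _brute_force_branches(tree)
    assert sorted(map(tuple, got)) == sorted(map(tuple, expected))
    assert got[0] == expected[0]  # longest root-to-leaf path comes first


@pytest.mark.parametrize("n_leaves,seed", [(1, 5), (3, 6), (7, 7), (10, 8)])
def test_edge_conservation_and_leaf_count(n_leaves, seed):
    tree = make_tree(n_leaves, seed=seed)
    branches = decompose_tree(tree)
    assert len(branches) == len(tree.leaves()) == n_leaves
    covered = [
        (a, b) for br in branches for a, b in zip(br.source_ids, br.source_ids[1:])
    ]
    assert sorted(covered) == sorted(tree.edges())
    for br in branches:
        chords = np.linalg.norm(np.diff(br.knots, axis=0), axis=1)
        np.testing.assert_allclose(np.diff(br.params), chords, rtol=1e-9)


def test_equal_arc_tie_broken_by_smaller_leaf_id():
    # two arms of identical arc length 2; leaf 3 < leaf 4
    nodes = [
        SwcNode(1, 0, [0, 0, 0], 1, -1),
        SwcNode(2, 0, [1, 0, 0], 1, 1),
        SwcNode(4, 0, [1, 1, 0], 1, 2),
        SwcNode(3, 0, [1, -1, 0], 1, 2),
    ]
    branches = decompose_tree(NeuronTree(nodes))
    assert branches[0].source_ids == [1, 2, 3]


def test_branch_rejects_non_arclength_params():
    with pytest.raises(ValueError):
        Branch(np.array([[0, 0, 0], [1, 0, 0]]), np.array([0.0, 2.0]), [])
    # and accepts exact chord-length params
    Branch(np.array([[0, 0, 0], [1, 0, 0]]), np.array([0.0, 1.0]), [])
    Branch(np.array([[0, 0, 0], [3, 4, 0]]), arc_length_params(
        np.array([[0, 0, 0], [3, 4, 0]])), [])
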