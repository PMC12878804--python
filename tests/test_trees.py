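"""Local-tree data model, extraction, UPGMA construction and time sanitation."""

import numpy as np
import pytest
import tskit

from argpolar.trees import (LocalTree, TmrcaMatrix, extract_local_tree,
                            local_tree_from_newick, read_tmrca_matrices,
                            sanitize_times, upgma_tree)
from conftest import random_coalescent_tree


# ---------------------------------------------------------------------------
# LocalTree invariants
# ---------------------------------------------------------------------------


def test_local_tree_invariant_violations_rejected():
    with pytest.raises(ValueError, match="root"):
        LocalTree(parent=np.array([-1, -1, 0]), time=np.array([1.0, 1.0, 0.0]),
                  labels={1: "a", 2: "b"})
    with pytest.raises(ValueError, match="time"):
        LocalTree(parent=np.array([2, 2, -1]), time=np.array([5.0, 0.0, 1.0]),
                  labels={0: "a", 1: "b"})
    with pytest.raises(ValueError, match="unique"):
        LocalTree(parent=np.array([2, 2, -1]), time=np.array([0.0, 0.0, 1.0]),
                  labels={0: "a", 1: "a"})
    with pytest.raises(ValueError, match="cycle|disconnected"):
        LocalTree(parent=np.array([1, 0, -1]), time=np.array([0.0, 0.0, 1.0]),
                  labels={0: "a", 1: "b"})


def test_postorder_children_precede_parents():
    rng = np.random.default_rng(0)
    t = random_coalescent_tree(rng, 9, polytomy_prob=0.3)
    seen = set()
    for v in t.postorder:
        for c in t.children[v]:
            assert c in seen
        seen.add(v)
    assert len(seen) == t.n_nodes


# ---------------------------------------------------------------------------
# Extraction from tree sequences
# ---------------------------------------------------------------------------


def two_tree_sequence():
    """Hand-built sequence with a breakpoint at 50: ((a,b),c) then (a,(b,c))."""
    tables = tskit.TableCollection(sequence_length=100)
    for _ in range(3):
        tables.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0)
    n3 = tables.nodes.add_row(time=1.0)   # cherry left
    n4 = tables.nodes.add_row(time=2.0)   # root left
    n5 = tables.nodes.add_row(time=1.5)   # cherry right
    n6 = tables.nodes.add_row(time=3.0)   # root right
    tables.edges.add_row(0, 50, n3, 0)
    tables.edges.add_row(0, 50, n3, 1)
    tables.edges.add_row(0, 50, n4, n3)
    tables.edges.add_row(0, 50, n4, 2)
    tables.edges.add_row(50, 100, n5, 1)
    tables.edges.add_row(50, 100, n5, 2)
    tables.edges.add_row(50, 100, n6, n5)
    tables.edges.add_row(50, 100, n6, 0)
    tables.sort()
    return tables.tree_sequence()


def test_extract_across_recombination_breakpoint():
    ts = two_tree_sequence()
    left = extract_local_tree(ts, 10)
    right = extract_local_tree(ts, 60)
    assert left.time.max() == 2.0 and right.time.max() == 3.0
    # boundary position belongs to the right tree (left-closed, right-open)
    at_break = extract_local_tree(ts, 50)
    assert at_break.time.max() == 3.0
    assert at_break.interval == (50.0, 100.0)
    with pytest.raises(ValueError, match="outside"):
        extract_local_tree(ts, 100)
    with pytest.raises(ValueError, match="outside"):
        extract_local_tree(ts, -1)


def test_extract_two_haplotype_tree_is_three_nodes():
    import msprime

    ts = msprime.sim_ancestry(samples=1, population_size=100,
                              sequence_length=1000, random_seed=4)
    t = extract_local_tree(ts, 500)
    assert t.n_nodes == 3 and t.n_leaves == 2


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def test_upgma_three_leaf_ultrametric_input():
    m = TmrcaMatrix(ids=("a", "b", "c"),
                    values=np.array([[0, 1, 3], [1, 0, 3], [3, 3, 0]], float))
    t = upgma_tree(m)
    ab = t.parent[t.node_of_label("a")]
    assert t.parent[t.node_of_label("b")] == ab
    assert t.time[ab] == 1.0
    assert t.time[t.root] == 3.0


def test_upgma_two_leaves_root_at_tmrca():
    m = TmrcaMatrix(ids=("a", "b"), values=np.array([[0, 5], [5, 0]], float))
    t = upgma_tree(m)
    assert t.n_nodes == 3 and t.time[t.root] == 5.0


def test_upgma_all_equal_ties_join_lexicographically():
    ids = ("d", "b", "c", "a")
    m = TmrcaMatrix(ids=ids, values=np.where(np.eye(4), 0.0, 2.0))
    t = upgma_tree(m)
    # first join is (a, b); every internal node sits at the common height
    a, b = t.node_of_label("a"), t.node_of_label("b")
    assert t.parent[a] == t.parent[b]
    internal = [v for v in range(t.n_nodes) if t.children[v]]
    assert all(t.time[v] == 2.0 for v in internal)


def test_upgma_scale_switch_halves_heights():
    m = TmrcaMatrix(ids=("a", "b"), values=np.array([[0, 5], [5, 0]], float))
    t = upgma_tree(m, distance_scale=1.0)
    assert t.time[t.root] == 2.5


def test_upgma_recovers_random_ultrametric_tree_exactly():
    rng = np.random.default_rng(7)
    for trial in range(5):
        src = random_coalescent_tree(rng, 8)
        # pairwise TMRCA from the tree itself
        labs = [src.labels[v] for v in src.leaf_nodes]
        k = len(labs)
        tm = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                vi, vj = src.node_of_label(labs[i]), src.node_of_label(labs[j])
                anc_i = set()
                u = vi
                while u != -1:
                    anc_i.add(u)
                    u = int(src.parent[u])
                u = vj
                while u not in anc_i:
                    u = int(src.parent[u])
                tm[i, j] = tm[j, i] = src.time[u]
        t = upgma_tree(TmrcaMatrix(ids=tuple(labs), values=tm))
        # same set of (leafset, height) clades
        def clades(tree):
            out = set()
            for v in range(tree.n_nodes):
                if tree.children[v]:
                    below = frozenset(
                        tree.labels[u] for u in tree.leaf_nodes
                        if _has_ancestor(tree, u, v))
                    out.add((below, round(float(tree.time[v]), 9)))
            return out

        assert clades(t) == clades(src)


def _has_ancestor(tree, u, v):
    while u != -1:
        if u == v:
            return True
        u = int(tree.parent[u])
    return False


def test_upgma_matches_scipy_average_linkage_heights():
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(3)
    k = 7
    base = rng.uniform(1, 10, size=(k, k))
    tm = np.triu(base, 1)
    tm = tm + tm.T
    m = TmrcaMatrix(ids=tuple(f"h{i}" for i in range(k)), values=tm)
    t = upgma_tree(m)
    Z = linkage(squareform(2 * tm), method="average")
    ours = sorted(float(t.time[v]) for v in range(t.n_nodes) if t.children[v])
    scipys = sorted(Z[:, 2] / 2.0)
    np.testing.assert_allclose(ours, scipys, rtol=1e-12)


def test_upgma_output_is_exactly_ultrametric():
    rng = np.random.default_rng(11)
    base = rng.uniform(1, 100, size=(6, 6))
    tm = np.triu(base, 1)
    tm = tm + tm.T
    t = upgma_tree(TmrcaMatrix(ids=tuple("abcdef"), values=tm))
    root_time = t.time[t.root]
    depths = []
    for v in t.leaf_nodes:
        d, u = 0.0, v
        while t.parent[u] != -1:
            d += t.time[t.parent[u]] - t.time[u]
            u = int(t.parent[u])
        depths.append(d)
    assert all(d == root_time for d in depths)


def test_tmrca_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        TmrcaMatrix(ids=("a", "b"), values=np.array([[0, 1], [2, 0]], float))
    with pytest.raises(ValueError, match="non-negative"):
        TmrcaMatrix(ids=("a", "b"), values=np.array([[0, -1], [-1, 0]], float))
    with pytest.raises(ValueError, match="> 0"):
        TmrcaMatrix(ids=("a", "b"), values=np.zeros((2, 2)))


def test_read_tmrca_matrices(tmp_path):
    p = tmp_path / "tmrca.txt"
    p.write_text("h0 h1 h2\n"
                 "100 0 2 6\n100 2 0 6\n100 6 6 0\n"
                 "200 0 4 4\n200 4 0 4\n200 4 4 0\n")
    mats = read_tmrca_matrices(p)
    assert [m.position for m in mats] == [100.0, 200.0]
    assert mats[0].values[0, 1] == 2.0
    t = upgma_tree(mats[0])
    assert t.position == 100.0


# ---------------------------------------------------------------------------
# Sanitation
# ---------------------------------------------------------------------------


def test_sanitize_floors_internal_times():
    t = LocalTree(parent=np.array([2, 2, -1]), time=np.array([0.0, 0.0, 0.0]),
                  labels={0: "a", 1: "b"})
    s = sanitize_times(t)
    assert s.time[s.root] == 1e-12
    assert all(s.time[v] == 0.0 for v in s.leaf_nodes)


def test_sanitize_collapses_near_equal_parent_child():
    # internal child at root_time - 1e-15 is deleted, creating a polytomy
    parent = np.array([4, 4, 3, 4, -1])
    time = np.array([0.0, 0.0, 0.0, 2.0 - 1e-15, 2.0])
    t = LocalTree(parent=parent, time=time, labels={0: "a", 1: "b", 2: "c"})
    s = sanitize_times(t)
    assert s.n_nodes == 4
    assert len(s.children[s.root]) == 3


def test_sanitize_idempotent_and_preserves_leaves():
    # caterpillar with a degenerate chain near the root and a zero-time cherry
    parent = np.array([4, 4, 5, 6, 5, 6, 7, -1])
    time = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 3.0 - 2e-15, 3.0 - 1e-15, 3.0])
    t = LocalTree(parent=parent, time=time, labels={0: "a", 1: "b", 2: "c", 3: "d"})
    s1 = sanitize_times(t)
    s2 = sanitize_times(s1)
    assert s1.n_nodes == s2.n_nodes
    np.testing.assert_array_equal(s1.parent, s2.parent)
    np.testing.assert_array_equal(s1.time, s2.time)
    assert sorted(s1.labels.values()) == ["a", "b", "c", "d"]
    # the whole near-root chain collapsed onto the root; cherry floored
    assert len(s1.children[s1.root]) == 3
    already = random_coalescent_tree(np.random.default_rng(5), 10, polytomy_prob=0.2)
    s = sanitize_times(already)
    assert s.n_nodes == already.n_nodes


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def test_newick_roundtrip_preserves_times_and_topology():
    rng = np.random.default_rng(13)
    t = random_coalescent_tree(rng, 6)
    t2 = local_tree_from_newick(t.newick())
    assert sorted(t2.labels.values()) == sorted(t.labels.values())
    np.testing.assert_allclose(sorted(t2.time), sorted(t.time), atol=1e-9)
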