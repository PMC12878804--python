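"""Shared fixtures: hand-built trees, random genealogies, brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from argpolar.models import ALPHABET, STATE_INDEX, SubstitutionModel, transition_matrices
from argpolar.trees import LocalTree


@pytest.fixture(scope="session")
def jc():
    return SubstitutionModel("JC69", mu=1.0)


@pytest.fixture(scope="session")
def k80():
    return SubstitutionModel("K80", mu=1.0, kappa=5.0)


def quartet_tree(t_ab=1.0, t_cd=1.0, t_root=3.0) -> LocalTree:
    """((a,b),(c,d)) with cherry nodes at the given times."""
    parent = np.array([4, 4, 5, 5, 6, 6, -1])
    time = np.array([0.0, 0.0, 0.0, 0.0, t_ab, t_cd, t_root])
    return LocalTree(parent=parent, time=time,
                     labels={0: "a", 1: "b", 2: "c", 3: "d"})


def two_leaf_tree(t_a=1.0, t_b=1.0) -> LocalTree:
    """Root at max height with leaf 'a' and 'b' at depths t_a, t_b below it."""
    h = max(t_a, t_b)
    parent = np.array([2, 2, -1])
    time = np.array([h - t_a, h - t_b, h])
    return LocalTree(parent=parent, time=time, labels={0: "a", 1: "b"})


def random_coalescent_tree(rng: np.random.Generator, n_leaves: int,
                           polytomy_prob: float = 0.0) -> LocalTree:
    """Random rooted genealogy: repeatedly merge lineages at increasing times."""
    parent = [-1] * n_leaves
    time = [0.0] * n_leaves
    roots = list(range(n_leaves))
    t = 0.0
    while len(roots) > 1:
        k = 3 if (len(roots) > 2 and rng.random() < polytomy_prob) else 2
        picks = rng.choice(len(roots), size=k, replace=False)
        t += float(rng.exponential(1.0)) + 1e-3
        node = len(parent)
        parent.append(-1)
        time.append(t)
        for i in sorted(picks, reverse=True):
            parent[roots[i]] = node
            del roots[i]
        roots.append(node)
    labels = {i: f"h{i}" for i in range(n_leaves)}
    return LocalTree(parent=np.array(parent), time=np.array(time), labels=labels)


def random_leaf_states(rng: np.random.Generator, tree: LocalTree,
                       n_states: int = 4) -> dict[str, str]:
    picks = rng.integers(0, n_states, size=tree.n_leaves)
    return {tree.labels[v]: ALPHABET[picks[i]]
            for i, v in enumerate(tree.leaf_nodes)}


# ---------------------------------------------------------------------------
# Independent oracles: exhaustive enumeration over internal-node assignments
# ---------------------------------------------------------------------------


def brute_force_joint_scores(tree: LocalTree, leaf_states: dict[str, str],
                             model: SubstitutionModel) -> np.ndarray:
    """Best joint log likelihood per root state by full enumeration."""
    internal = [v for v in range(tree.n_nodes) if len(tree.children[v]) > 0]
    leaves = {v: STATE_INDEX[leaf_states[tree.labels[v]]] for v in tree.leaf_nodes}
    edges = [(v, int(tree.parent[v])) for v in range(tree.n_nodes)
             if tree.parent[v] != -1]
    logP = {v: np.log(np.maximum(
        transition_matrices(model, tree.time[p] - tree.time[v]), 1e-300))
        for v, p in edges}
    best = np.full(4, -np.inf)
    root = tree.root
    for assign in itertools.product(range(4), repeat=len(internal)):
        states = dict(zip(internal, assign))
        states.update(leaves)
        ll = sum(logP[v][states[p], states[v]] for v, p in edges)
        s = states[root]
        best[s] = max(best[s], ll)
    return best


def brute_force_parsimony(tree: LocalTree, leaf_states: dict[str, str],
                          root_state: str) -> int:
    """Minimum number of state changes over all internal assignments (fixed root)."""
    internal = [v for v in range(tree.n_nodes) if len(tree.children[v]) > 0]
    leaves = {v: STATE_INDEX[leaf_states[tree.labels[v]]] for v in tree.leaf_nodes}
    root = tree.root
    rs = STATE_INDEX[root_state]
    best = np.inf
    free = [v for v in internal if v != root]
    for assign in itertools.product(range(4), repeat=len(free)):
        states = dict(zip(free, assign))
        states[root] = rs
        states.update(leaves)
        changes = sum(1 for v in range(tree.n_nodes)
                      if tree.parent[v] != -1
                      and states[v] != states[int(tree.parent[v])])
        best = min(best, changes)
    return int(best)
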