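"""Rooted local genealogies: data model, construction and time sanitation.

A :class:`LocalTree` is the marginal coalescent tree applying at one genomic
position: a rooted tree with node times in generations and uniquely-labelled
leaves (one label per sampled haplotype).  Trees can be extracted from a
succinct tree sequence, parsed from newick, or built from a matrix of pairwise
TMRCA values by UPGMA average-linkage clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np


@dataclass(frozen=True)
class LocalTree:
    """A rooted genealogy with node times at one genomic position.

    Nodes are integers ``0..n_nodes-1``; ``parent[v]`` is the parent of ``v``
    or ``-1`` for the single root; ``time[v]`` is the age of node ``v`` in
    generations (leaves may be at time 0); ``labels`` maps each leaf node to a
    unique haplotype identifier.
    """

    parent: np.ndarray
    time: np.ndarray
    labels: dict[int, str]
    position: float | None = None
    interval: tuple[float, float] | None = None

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=np.int64)
        time = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "time", time)
        m = parent.shape[0]
        if time.shape != (m,):
            raise ValueError("parent and time must have the same length")
        roots = np.flatnonzero(parent == -1)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        if np.any((parent < -1) | (parent >= m)):
            raise ValueError("parent indices out of range")
        if np.any(time < 0):
            raise ValueError("node times must be non-negative")
        nonroot = parent != -1
        if np.any(time[parent[nonroot]] < time[np.flatnonzero(nonroot)]):
            raise ValueError("time(parent) must be >= time(child) on every edge")
        # acyclicity: every node must reach the root; count reachable via parent chain
        order = self._compute_postorder(parent, int(roots[0]))
        if order.size != m:
            raise ValueError("tree contains cycles or disconnected nodes")
        object.__setattr__(self, "_postorder", order)
        leaves = self.leaf_nodes
        if set(self.labels) != set(leaves.tolist()):
            raise ValueError("labels must cover exactly the leaf nodes")
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("leaf labels must be unique")

    @staticmethod
    def _compute_postorder(parent: np.ndarray, root: int) -> np.ndarray:
        m = parent.shape[0]
        children: list[list[int]] = [[] for _ in range(m)]
        for v in range(m):
            p = parent[v]
            if p != -1:
                children[p].append(v)
        order = []
        stack = [root]
        seen = np.zeros(m, dtype=bool)
        while stack:
            v = stack.pop()
            if seen[v]:
                continue
            seen[v] = True
            order.append(v)
            stack.extend(children[v])
        order.reverse()  # children before parents
        return np.asarray(order, dtype=np.int64)

    # -- derived structure ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @cached_property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @cached_property
    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p != -1:
                out[p].append(v)
        return out

    @cached_property
    def leaf_nodes(self) -> np.ndarray:
        has_child = np.zeros(self.n_nodes, dtype=bool)
        has_child[self.parent[self.parent != -1]] = True
        return np.flatnonzero(~has_child)

    @property
    def n_leaves(self) -> int:
        return self.leaf_nodes.shape[0]

    @cached_property
    def postorder(self) -> np.ndarray:
        """Node ids in postorder (every child precedes its parent)."""
        return self._postorder

    @cached_property
    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def branch_time(self, v: int) -> float:
        """Time difference to the parent of ``v`` (the branch above ``v``)."""
        p = self.parent[v]
        if p == -1:
            raise ValueError("root has no branch")
        return float(self.time[p] - self.time[v])

    def node_of_label(self, label: str) -> int:
        return self._label_to_node[label]

    @cached_property
    def _label_to_node(self) -> dict[str, int]:
        return {lab: v for v, lab in self.labels.items()}

    def newick(self) -> str:
        """Newick string with branch lengths equal to parent-child time differences."""

        def rec(v: int) -> str:
            kids = self.children[v]
            if not kids:
                core = self.labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in kids) + ")"
            p = self.parent[v]
            if p == -1:
                return core + ";"
            return f"{core}:{self.time[p] - self.time[v]:.10g}"

        return rec(self.root)


# ---------------------------------------------------------------------------
# Construction from tree sequences
# ---------------------------------------------------------------------------


def haplotype_labels(ts) -> dict[int, str]:
    """Haplotype labels for the sample nodes of a tree sequence.

    A sample node belonging to individual ``i`` (as written to VCF, sample name
    ``tsk_i``) is labelled ``tsk_i_k`` where ``k`` is the node's index within
    the individual; samples without an individual are labelled ``n<node_id>``.
    """
    labels: dict[int, str] = {}
    for ind in ts.individuals():
        for k, u in enumerate(ind.nodes):
            labels[int(u)] = f"tsk_{ind.id}_{k}"
    for u in ts.samples():
        u = int(u)
        if u not in labels:
            labels[u] = f"n{u}"
    return labels


def local_tree_from_tskit(tree, labels: dict[int, str] | None = None,
                          position: float | None = None) -> LocalTree:
    """Convert a tskit marginal ``Tree`` into a :class:`LocalTree`.

    Node ids are remapped to a contiguous range; leaf labels default to the
    :func:`haplotype_labels` convention of the parent tree sequence.
    """
    if tree.num_roots != 1:
        where = position if position is not None else tree.interval
        raise ValueError(f"marginal tree at {where} has {tree.num_roots} roots; "
                         "a single rooted genealogy is required")
    ts = tree.tree_sequence
    if labels is None:
        labels = haplotype_labels(ts)
    order = tree.postorder()  # ts node ids present in this marginal tree
    local = {int(u): i for i, u in enumerate(order)}
    m = order.shape[0]
    parent = np.full(m, -1, dtype=np.int64)
    times = ts.nodes_time[order]
    for u in order:
        p = tree.parent(u)
        if p != -1:
            parent[local[int(u)]] = local[int(p)]
    leaf_labels = {}
    for u in order:
        if tree.num_children(u) == 0:
            leaf_labels[local[int(u)]] = labels[int(u)]
    left, right = tree.interval
    return LocalTree(parent=parent, time=times, labels=leaf_labels,
                     position=position, interval=(float(left), float(right)))


def extract_local_tree(ts, position: float, labels: dict[int, str] | None = None) -> LocalTree:
    """The marginal tree whose (left-closed, right-open) interval contains ``position``."""
    if not 0 <= position < ts.sequence_length:
        raise ValueError(
            f"position {position} outside sequence span [0, {ts.sequence_length})")
    tree = ts.at(position)
    return local_tree_from_tskit(tree, labels=labels, position=float(position))


# ---------------------------------------------------------------------------
# Construction from newick
# ---------------------------------------------------------------------------


def local_tree_from_newick(newick: str, position: float | None = None) -> LocalTree:
    """Parse a rooted newick tree whose branch lengths are time differences.

    Node times are reconstructed bottom-up: each leaf sits at time 0 unless the
    tree is non-ultrametric, in which case internal times are the maximum leaf
    distance below (leaves keep time 0 and parent >= child still holds).
    """
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    nodes = list(t.postorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    m = len(nodes)
    parent = np.full(m, -1, dtype=np.int64)
    time = np.zeros(m)
    labels: dict[int, str] = {}
    for nd in nodes:
        i = idx[id(nd)]
        if nd.parent_node is not None:
            parent[i] = idx[id(nd.parent_node)]
        kids = nd.child_nodes()
        if not kids:
            if nd.taxon is None or not nd.taxon.label:
                raise ValueError("newick leaf without a label")
            labels[i] = nd.taxon.label
        else:
            time[i] = max(
                time[idx[id(c)]] + (c.edge.length if c.edge.length is not None else 0.0)
                for c in kids
            )
    return LocalTree(parent=parent, time=time, labels=labels, position=position)


def read_newick_trees(path) -> list[LocalTree]:
    """Read one tree per line; a leading ``position<TAB>`` column is accepted."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                pos_s, nwk = line.split("\t", 1)
                out.append(local_tree_from_newick(nwk, position=float(pos_s)))
            else:
                out.append(local_tree_from_newick(line))
    return out


# ---------------------------------------------------------------------------
# Pairwise-TMRCA matrices and UPGMA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TmrcaMatrix:
    """Symmetric pairwise TMRCA values (generations) among haplotypes at one site."""

    ids: tuple[str, ...]
    values: np.ndarray
    position: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if v.shape != (k, k):
            raise ValueError("values must be a square matrix matching ids")
        if np.any(v < 0):
            raise ValueError("TMRCA values must be non-negative")
        if not np.array_equal(v, v.T):
            raise ValueError("TMRCA matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("TMRCA matrix must have a zero diagonal")
        off = v[~np.eye(k, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("off-diagonal TMRCA values must be > 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))


def read_tmrca_matrices(path) -> list[TmrcaMatrix]:
    """Read whitespace-delimited square TMRCA matrices.

    Format: a header row of haplotype ids, then for each site ``k`` rows, each
    beginning with the (shared) genomic position followed by the ``k`` matrix
    entries.  Several sites may be concatenated under one header.
    """
    with open(path) as fh:
        tokens = [line.split() for line in fh if line.strip() and not line.startswith("#")]
    if not tokens:
        raise ValueError(f"{path}: empty TMRCA file")
    ids = tuple(tokens[0])
    k = len(ids)
    body = tokens[1:]
    if len(body) % k != 0:
        raise ValueError(f"{path}: expected blocks of {k} rows after the header")
    out = []
    for b in range(0, len(body), k):
        rows = body[b:b + k]
        pos = {r[0] for r in rows}
        if len(pos) != 1:
            raise ValueError(f"{path}: inconsistent positions within a matrix block")
        vals = np.array([[float(x) for x in r[1:]] for r in rows])
        out.append(TmrcaMatrix(ids=ids, values=vals, position=float(pos.pop())))
    return out


def upgma_tree(m: TmrcaMatrix, distance_scale: float = 2.0) -> LocalTree:
    """Rooted ultrametric tree from pairwise TMRCAs by UPGMA average linkage.

    The distance fed to the clustering is ``distance_scale * TMRCA`` (default 2,
    i.e. total time separating the two lineages), and the node joining two
    clusters is placed at half the linkage distance — so with the default scale
    pair-join heights equal TMRCA values directly.  Ties are broken by joining
    the pair of clusters whose (lexicographically smallest member) labels form
    the smallest pair, making reruns deterministic.
    """
    k = len(m.ids)
    if k < 2:
        raise ValueError("UPGMA needs at least 2 haplotypes")
    # cluster state: representative (smallest) label, member count, node id
    n_total = 2 * k - 1
    parent = np.full(n_total, -1, dtype=np.int64)
    time = np.zeros(n_total)
    labels = {i: m.ids[i] for i in range(k)}
    active: dict[int, tuple[str, int, int]] = {
        i: (m.ids[i], 1, i) for i in range(k)
    }  # cluster key -> (rep label, size, node id)
    dist: dict[frozenset, float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            dist[frozenset((i, j))] = distance_scale * m.values[i, j]
    next_node = k
    while len(active) > 1:
        dmin = min(dist[frozenset((a, b))]
                   for a in active for b in active if a < b)
        best = min(
            (tuple(sorted((active[a][0], active[b][0]))), a, b)
            for a in active for b in active
            if a < b and dist[frozenset((a, b))] == dmin
        )
        _, a, b = best
        height = dmin / 2.0
        node = next_node
        next_node += 1
        for key in (a, b):
            parent[active[key][2]] = node
        time[node] = height
        size = active[a][1] + active[b][1]
        rep = min(active[a][0], active[b][0])
        # Lance-Williams update for average linkage
        for c in list(active):
            if c in (a, b):
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            dist[frozenset((a, c))] = (
                active[a][1] * dac + active[b][1] * dbc) / size
        dist.pop(frozenset((a, b)))
        del active[b]
        active[a] = (rep, size, node)
    return LocalTree(parent=parent, time=time, labels=labels, position=m.position)


# ---------------------------------------------------------------------------
# Node-time sanitation
# ---------------------------------------------------------------------------


def sanitize_times(t: LocalTree, floor: float = 1e-12,
                   collapse_eps: float = 1e-14) -> LocalTree:
    """Apply the node-time sanitation rules used when ingesting inferred trees.

    Internal node times below ``floor`` are raised to ``floor``; an internal
    child whose time is within ``collapse_eps`` of its internal parent's time is
    deleted and its children re-attached to the parent, creating polytomies.
    Idempotent; leaves are never touched.
    """
    m = t.n_nodes
    is_leaf = np.zeros(m, dtype=bool)
    is_leaf[t.leaf_nodes] = True
    time = t.time.copy()
    time[~is_leaf] = np.maximum(time[~is_leaf], floor)
    parent = t.parent.copy()
    removed = np.zeros(m, dtype=bool)
    # top-down (decreasing time) so chains collapse onto the highest survivor
    for v in t.postorder[::-1]:
        p = parent[v]
        if p == -1 or is_leaf[v]:
            continue
        while removed[p]:
            p = parent[p]
        parent[v] = p
        if time[p] - time[v] <= collapse_eps:
            removed[v] = True
    for v in range(m):
        p = parent[v]
        while p != -1 and removed[p]:
            p = parent[p]
        parent[v] = p
    keep = ~removed
    new_id = np.cumsum(keep) - 1
    new_parent = np.array(
        [-1 if parent[v] == -1 else new_id[parent[v]] for v in range(m) if keep[v]],
        dtype=np.int64,
    )
    new_time = time[keep]
    new_labels = {int(new_id[v]): lab for v, lab in t.labels.items()}
    return LocalTree(parent=new_parent, time=new_time, labels=new_labels,
                     position=t.position, interval=t.interval)
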