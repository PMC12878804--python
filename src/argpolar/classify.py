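"""Parsimony mutation mapping and informative/non-informative site classification.

For each candidate ancestral (root) state the minimum number of mutations
needed to explain the observed leaf states is found by a fixed-root small
parsimony (Hartigan/Sankoff, unit costs) dynamic program.  A genealogy is
*non-informative* when two or more candidate ancestral states tie for the
overall minimum — e.g. a single mutation on a root-adjacent branch, where
parsimony cannot tell which side of the root mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ALPHABET, STATE_INDEX
from .trees import LocalTree

_BIG = 10**6  # effectively-infinite unit-cost score


@dataclass(frozen=True)
class SiteClassification:
    """Parsimony summary of one segregating site on its local tree."""

    counts: dict[str, int]            # minimal mutation count per candidate state
    min_count: int
    min_candidates: tuple[str, ...]   # candidate states attaining the minimum
    observed_alleles: tuple[str, ...]
    non_informative: bool
    multiple_mutations: bool
    homoplasy: bool
    polytomy_mutation: bool
    placements: tuple[tuple[int, str], ...] = field(default_factory=tuple)


def _parsimony_table(t: LocalTree, leaf_states: dict[str, str]) -> np.ndarray:
    """(n_nodes, 4) min-sum table; row of the root gives the count per root state."""
    m = t.n_nodes
    S = np.zeros((m, 4), dtype=np.int64)
    for v in t.leaf_nodes:
        lab = t.labels[v]
        if lab not in leaf_states:
            raise ValueError(f"missing leaf state for {lab!r}")
        s = STATE_INDEX.get(leaf_states[lab].upper())
        if s is None:
            raise ValueError(f"leaf {lab!r} has invalid state {leaf_states[lab]!r}")
        S[v, :] = _BIG
        S[v, s] = 0
    for v in t.postorder:
        p = t.parent[v]
        if p == -1:
            continue
        S[p] += np.minimum(S[v], 1 + S[v].min())
    return S


def placements_from_table(order: np.ndarray, parent: np.ndarray, S: np.ndarray,
                          root_state: int) -> tuple[tuple[int, str], ...]:
    """One optimal placement under the topmost-change convention (array form).

    Top-down, each node keeps its parent's state whenever that is optimal, so a
    mutation is recorded on the edge above the highest node whose assigned
    state differs from its parent's.
    """
    state = np.empty(parent.shape[0], dtype=np.int64)
    state[order[-1]] = root_state
    muts = []
    for v in order[::-1]:
        p = parent[v]
        if p == -1:
            continue
        sp = state[p]
        best = S[v].min()
        if S[v, sp] <= 1 + best:
            state[v] = sp
        else:
            state[v] = int(np.flatnonzero(S[v] == best)[0])  # lexicographic A<C<G<T
            muts.append((int(v), ALPHABET[state[v]]))
    return tuple(muts)


def _placements(t: LocalTree, S: np.ndarray, root_state: int) -> tuple[tuple[int, str], ...]:
    return placements_from_table(t.postorder, t.parent, S, root_state)


def map_mutations(t: LocalTree, leaf_states: dict[str, str],
                  fixed_root_state: str) -> tuple[int, tuple[tuple[int, str], ...]]:
    """Minimum mutation count and one optimal placement for a fixed root state.

    Returns ``(count, placements)`` where each placement is ``(node, derived
    state)`` meaning a mutation on the edge above ``node``.  Polytomies are
    supported; the count is the exact Hartigan/Sankoff optimum.
    """
    s = STATE_INDEX.get(fixed_root_state.upper()) if isinstance(fixed_root_state, str) else None
    if s is None:
        raise ValueError(f"invalid root state {fixed_root_state!r}")
    S = _parsimony_table(t, leaf_states)
    count = int(S[t.root, s])
    if count >= _BIG:
        raise ValueError("no valid mutation history for this root state")
    return count, _placements(t, S, s)


def classify_site(t: LocalTree, leaf_states: dict[str, str],
                  candidate_states=None) -> SiteClassification:
    """Classify one segregating site by fixed-root parsimony over candidates.

    Candidates default to the alleles observed at the site (an unobserved root
    state can never beat an observed one when the observed minimum is a single
    mutation); pass all four nucleotides explicitly to widen the search.
    """
    observed = tuple(sorted({leaf_states[t.labels[v]].upper() for v in t.leaf_nodes}))
    if len(observed) < 2:
        raise ValueError("classify_site requires a segregating site (>= 2 alleles)")
    candidates = tuple(sorted(a.upper() for a in candidate_states)) if candidate_states \
        else observed
    S = _parsimony_table(t, leaf_states)
    root_row = S[t.root]
    counts = {a: int(root_row[STATE_INDEX[a]]) for a in candidates}
    min_count = min(counts.values())
    min_candidates = tuple(a for a in candidates if counts[a] == min_count)
    non_informative = len(min_candidates) >= 2
    multiple = min_count > 1
    homoplasy = multiple and len(observed) == 2
    placements = _placements(t, S, STATE_INDEX[min_candidates[0]])
    polytomy_mutation = (not t.is_binary) and any(
        len(t.children[t.parent[v]]) > 2 for v, _ in placements
    )
    return SiteClassification(
        counts=counts, min_count=min_count, min_candidates=min_candidates,
        observed_alleles=observed, non_informative=non_informative,
        multiple_mutations=multiple, homoplasy=homoplasy,
        polytomy_mutation=polytomy_mutation, placements=placements,
    )


FILTER_POLICIES = ("strict", "usfs", "real-data")


def apply_filters(c: SiteClassification, policy: str) -> bool:
    """Whether a site passes the named filtering policy.

    - ``strict``: drop non-informative sites, parsimony minimum > 1 and
      mutations placed under polytomies (the polarisation-accuracy setting).
    - ``usfs``: drop only sites needing more than two mutations.
    - ``real-data``: drop non-informative sites and sites whose mutation count
      exceeds the number of observed alleles.
    """
    if policy == "strict":
        return not c.non_informative and c.min_count == 1 and not c.polytomy_mutation
    if policy == "usfs":
        return c.min_count <= 2
    if policy == "real-data":
        return not c.non_informative and c.min_count <= len(c.observed_alleles)
    raise ValueError(f"unknown filter policy {policy!r}; choose from {FILTER_POLICIES}")
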