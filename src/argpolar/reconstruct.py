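"""Empirical-Bayes joint ancestral-state reconstruction on a local genealogy.

For every candidate root state the maximum joint probability over assignments
of nucleotides to all internal nodes is computed by a max-product dynamic
program run entirely in log space (no underflow for large, old trees).  The
per-root-state scores, combined with the root prior, give the posterior
probability of each nucleotide being ancestral; because they come from joint
(max-product) scores rather than sum-product marginals, these are "joint-path"
posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import logsumexp

from .models import ALPHABET, NEG_SENTINEL, STATE_INDEX, SubstitutionModel, log_transition_matrices
from .trees import LocalTree


@dataclass(frozen=True)
class RootPosterior:
    """Posterior over root nucleotides plus the best joint assignments.

    ``posterior[i]`` is the probability that nucleotide ``ALPHABET[i]`` is the
    root (ancestral) state; ``log_score[i]`` is the corresponding unnormalised
    log score (log prior + best joint log likelihood); ``best_assignments``
    maps each viable root nucleotide to the arg-max assignment of states to all
    nodes (node id -> nucleotide), or is ``None`` when backtraces were not
    requested; ``tied`` flags an exact tie for the arg-max root state.
    """

    posterior: np.ndarray
    log_score: np.ndarray
    best_assignments: dict[str, dict[int, str]] | None
    tied: bool

    @property
    def argmax(self) -> str:
        return ALPHABET[int(np.argmax(self.posterior))]

    def restricted(self, alleles) -> dict[str, float]:
        """Posterior renormalised over a subset of (observed) alleles."""
        idx = [STATE_INDEX[a.upper()] for a in alleles]
        sub = self.posterior[idx]
        tot = sub.sum()
        if tot <= 0:
            # all observed alleles have zero mass: fall back to uniform
            sub = np.full(len(idx), 1.0 / len(idx))
            tot = 1.0
        return {ALPHABET[i]: float(p / tot) for i, p in zip(idx, sub)}


class AncestralCall(NamedTuple):
    allele: str
    probability: float
    ambiguous: bool


def _saturate(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, NEG_SENTINEL, out=x)


def batch_joint_root_scores(order, parent, log_probs, leaf_scores):
    """Max-product root scores for many sites sharing one tree.

    Parameters
    ----------
    order:
        node ids in postorder (children before parents), length ``m``.
    parent:
        parent id per node (-1 for the root).
    log_probs:
        ``(m, 4, 4)`` log transition matrix for the branch above each node
        (unused row for the root).
    leaf_scores:
        ``(m, k, 4)`` initial scores: 0 for each leaf's observed state,
        sentinel elsewhere; zeros for internal nodes.  Modified in place.

    Returns the ``(k, 4)`` root score array (log likelihood per root state).
    """
    L = leaf_scores
    root = order[-1]
    for v in order:
        p = parent[v]
        if p == -1:
            continue
        # contribution to parent: max over child state s' of logP[s, s'] + L[v][:, s']
        contrib = np.max(log_probs[v][None, :, :] + L[v][:, None, :], axis=2)
        L[p] += contrib
        _saturate(L[p])
    return L[root]


def joint_reconstruct(t: LocalTree, leaf_states: dict[str, str],
                      model: SubstitutionModel,
                      prior: np.ndarray | None = None,
                      backtrace: bool = True) -> RootPosterior:
    """Joint (max-product) reconstruction of the root state of one site.

    ``leaf_states`` maps every leaf label of ``t`` to its nucleotide.  The
    posterior combines the per-root-state best joint log likelihood with the
    root prior (``model.pi`` unless overridden) through a log-sum-exp.
    Polytomies are handled natively (product over all children).
    """
    missing = [t.labels[v] for v in t.leaf_nodes if t.labels[v] not in leaf_states]
    if missing:
        raise ValueError(f"missing leaf state for: {', '.join(sorted(missing))}")
    m = t.n_nodes
    order = t.postorder
    branch = np.zeros(m)
    nonroot = t.parent != -1
    branch[nonroot] = t.time[t.parent[nonroot]] - t.time[nonroot]
    logP = log_transition_matrices(model, branch)

    L = np.zeros((m, 1, 4))
    for v in t.leaf_nodes:
        state = leaf_states[t.labels[v]]
        s = STATE_INDEX.get(state.upper())
        if s is None:
            raise ValueError(f"leaf {t.labels[v]!r} has invalid state {state!r}")
        L[v, 0, :] = NEG_SENTINEL
        L[v, 0, s] = 0.0

    ptr: dict[int, np.ndarray] = {}
    root = t.root
    for v in order:
        p = t.parent[v]
        if p == -1:
            continue
        scores = logP[v][None, :, :] + L[v][:, None, :]  # (1, s_parent, s_child)
        if backtrace:
            ptr[v] = np.argmax(scores[0], axis=1)
        L[p] += np.max(scores, axis=2)
        _saturate(L[p])
    root_scores = L[root][0]

    pi = model.pi if prior is None else np.asarray(prior, dtype=float)
    with np.errstate(divide="ignore"):
        log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), NEG_SENTINEL)
    score = np.maximum(root_scores + log_pi, NEG_SENTINEL)
    if np.all(score <= NEG_SENTINEL / 2):
        raise ValueError("all root states impossible for the observed leaf states")
    posterior = np.exp(score - logsumexp(score))
    posterior[score <= NEG_SENTINEL / 2] = 0.0
    posterior /= posterior.sum()

    assignments = None
    if backtrace:
        assignments = {}
        for s in range(4):
            if score[s] <= NEG_SENTINEL / 2:
                continue
            assign = {root: s}
            for v in order[::-1]:
                p = t.parent[v]
                if p == -1:
                    continue
                assign[v] = int(ptr[v][assign[p]])
            assignments[ALPHABET[s]] = {int(v): ALPHABET[a] for v, a in assign.items()}

    best = np.max(posterior)
    tied = int(np.sum(posterior == best)) > 1
    return RootPosterior(posterior=posterior, log_score=score,
                         best_assignments=assignments, tied=tied)


def ancestral_call(p: RootPosterior, observed_alleles) -> AncestralCall:
    """Most probable ancestral allele among those observed at the site.

    The posterior is restricted and renormalised to the observed alleles; exact
    ties are flagged ambiguous and resolved lexicographically (A<C<G<T).
    """
    alleles = sorted(a.upper() for a in observed_alleles)
    if len(alleles) == 1:
        return AncestralCall(alleles[0], 1.0, False)
    restricted = p.restricted(alleles)
    best_p = max(restricted.values())
    winners = sorted(a for a, q in restricted.items() if q == best_p)
    return AncestralCall(winners[0], best_p, len(winners) > 1)
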