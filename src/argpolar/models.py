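"""Nucleotide substitution models (JC69, K80) with closed-form transition probabilities.

Branch "lengths" are times in generations; the expected number of substitutions on a
branch of time ``t`` is ``d = mu * t`` where ``mu`` is the total substitution rate per
site per generation.  Trees whose branch lengths are already in substitutions/site can
be used with ``mu = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
STATE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# Transition (purine<->purine, pyrimidine<->pyrimidine) partner under K80.
_TRANSITION_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T

UNIFORM_PI = np.full(4, 0.25)


def _as_index(state) -> int:
    if isinstance(state, str):
        try:
            return STATE_INDEX[state.upper()]
        except KeyError:
            raise ValueError(f"unknown nucleotide state {state!r}") from None
    i = int(state)
    if not 0 <= i < 4:
        raise ValueError(f"state index {i} out of range 0..3")
    return i


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible nucleotide model with total substitution rate ``mu`` per site.

    Parameters
    ----------
    name:
        ``"JC69"`` (equal rates) or ``"K80"`` (distinct transition/transversion
        rates with ratio ``kappa``).
    mu:
        Total substitution rate per site per generation (> 0).
    kappa:
        Transition/transversion rate ratio; required for K80, ignored for JC69.
        ``kappa = 1`` makes K80 collapse to JC69.
    pi:
        Root state distribution over (A, C, G, T); defaults to uniform.  Used as
        the prior in empirical-Bayes ancestral reconstruction; the transition
        probabilities themselves are those of the symmetric model.
    """

    name: str = "JC69"
    mu: float = 1.0
    kappa: float | None = None
    pi: np.ndarray = field(default_factory=lambda: UNIFORM_PI.copy())

    def __post_init__(self):
        name = self.name.upper()
        if name not in ("JC69", "K80"):
            raise ValueError(f"unsupported model {self.name!r}; use JC69 or K80")
        object.__setattr__(self, "name", name)
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if name == "K80":
            if self.kappa is None:
                raise ValueError("K80 requires kappa")
            if not self.kappa > 0:
                raise ValueError("kappa must be > 0")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be 4 non-negative probabilities summing to 1")
        object.__setattr__(self, "pi", pi)


def transition_matrices(model: SubstitutionModel, times) -> np.ndarray:
    """Transition probability matrices P(t) for an array of branch times.

    Returns an array of shape ``times.shape + (4, 4)`` with ``P[..., i, j] =
    P(state j at the child | state i at the parent, branch time t)``.  Rows sum
    to one.  Negative times are an error.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("branch times must be non-negative")
    d = model.mu * t
    P = np.empty(t.shape + (4, 4))
    if model.name == "JC69":
        e = np.exp(-4.0 * d / 3.0)
        same = 0.25 + 0.75 * e
        diff = 0.25 - 0.25 * e
        P[...] = diff[..., None, None]
        for i in range(4):
            P[..., i, i] = same
    else:  # K80, parameterised so alpha + 2*beta = mu
        kappa = model.kappa
        beta = model.mu / (kappa + 2.0)
        alpha = kappa * beta
        e_tv = np.exp(-4.0 * beta * t)
        e_ts = np.exp(-2.0 * (alpha + beta) * t)
        same = 0.25 + 0.25 * e_tv + 0.5 * e_ts
        ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
        tv = 0.25 - 0.25 * e_tv
        P[...] = tv[..., None, None]
        for i in range(4):
            P[..., i, i] = same
            P[..., i, _TRANSITION_PARTNER[i]] = ts
    return P


def transition_prob(model: SubstitutionModel, from_state, to_state, branch_time: float) -> float:
    """P(to_state | from_state) over a branch of ``branch_time`` generations."""
    i, j = _as_index(from_state), _as_index(to_state)
    return float(transition_matrices(model, float(branch_time))[i, j])


#: log-score used to represent impossibility; additions saturate at this value.
NEG_SENTINEL = -1.0e18


def log_transition_matrices(model: SubstitutionModel, times) -> np.ndarray:
    """Elementwise log of :func:`transition_matrices`, with exact zeros mapped to
    the saturating sentinel instead of ``-inf``."""
    P = transition_matrices(model, times)
    out = np.full_like(P, NEG_SENTINEL)
    np.log(P, out=out, where=P > 0)
    return out
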