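"""Unfolded site-frequency-spectrum estimation from polarised sites.

Three estimators over biallelic sites with n haplotypes:

- **MAX PP**: each site adds one count to the derived-allele-frequency (DAF)
  category of its single best ancestral call (optionally restricted to sites
  kept by a filter, "MAX PP + filtering" — which is biased, because the
  probability that a genealogy is non-informative depends on the DAF).
- **Posterior average**: each site splits unit mass between the two
  complementary categories D_x and D_{n-x} according to the restricted
  posterior that each observed allele is ancestral, E[D_x] = sum_i P_i(D_x).
  Total mass then equals the number of contributing sites exactly.
- **Posterior average with filter correction**: when filtered sites must be
  excluded (e.g. suspect genealogies), the kept sites' mean posterior within
  each folded frequency class {x, n-x} is rescaled by the total number of
  sites L_x in that class: E[D_x] = L_x * (1/L_x') * sum_{i kept} P_i(D_x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polarise import keep_mask


@dataclass(frozen=True)
class USFS:
    """Expected site counts per derived-allele-count category x = 1..n-1.

    ``lx[x]`` is the number of biallelic sites in the folded class {x, n-x}
    (so ``lx[x] == lx[n-x]``); ``lx_prime`` the number of those kept after
    filtering (zeros when no filter was applied).
    """

    n: int
    e_dx: np.ndarray
    estimator: str
    lx: np.ndarray = field(default=None)
    lx_prime: np.ndarray = field(default=None)

    def __post_init__(self):
        e = np.asarray(self.e_dx, dtype=float)
        if e.shape != (self.n - 1,):
            raise ValueError("e_dx must have length n-1")
        if np.any(e < 0):
            raise ValueError("E[Dx] must be non-negative")
        object.__setattr__(self, "e_dx", e)
        for name in ("lx", "lx_prime"):
            v = getattr(self, name)
            object.__setattr__(self, name,
                               np.zeros(self.n - 1) if v is None else np.asarray(v, float))

    @property
    def total(self) -> float:
        return float(self.e_dx.sum())

    @property
    def freq(self) -> np.ndarray:
        """Normalised spectrum (proportions per category)."""
        return self.e_dx / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": np.arange(1, self.n),
            "E_Dx": self.e_dx,
            "Lx": self.lx,
            "Lx_prime": self.lx_prime,
            "freq": self.freq if self.total > 0 else np.nan,
        })


def true_usfs(df: pd.DataFrame, truth: dict[int, str], n: int) -> USFS:
    """The spectrum of true derived-allele counts over biallelic sites."""
    sub = _biallelic(df)
    e = np.zeros(n - 1)
    for pos, alleles, a0, c0 in zip(sub.position, sub.alleles, sub.a0, sub.count_a0):
        anc = truth[pos]
        a, b = alleles.split(",")
        if anc == a0:
            x = n - c0
        elif anc == (b if a == a0 else a):
            x = c0
        else:  # true ancestral allele no longer observed (multiple mutations)
            continue
        e[x - 1] += 1
    return USFS(n=n, e_dx=e, estimator="truth")


def _biallelic(df: pd.DataFrame) -> pd.DataFrame:
    return df[df.n_alleles == 2]


def usfs_max_pp(df: pd.DataFrame, n: int, filtered: bool = False,
                policy: str = "strict") -> USFS:
    """Best-call spectrum: each site counted once in its called DAF category."""
    sub = _biallelic(df)
    if filtered:
        sub = sub[keep_mask(sub, policy)]
    e = np.zeros(n - 1)
    for a0, c0, call in zip(sub.a0, sub.count_a0, sub.call):
        x = n - c0 if call == a0 else c0
        e[x - 1] += 1
    tag = "max_pp_filtered" if filtered else "max_pp"
    return USFS(n=n, e_dx=e, estimator=tag)


def usfs_posterior_average(df: pd.DataFrame, n: int,
                           use_filter_correction: bool = False,
                           policy: str = "usfs") -> USFS:
    """Posterior-average spectrum, optionally with the filtered-site reweighting.

    Without correction every biallelic site contributes its full restricted
    posterior mass, so the spectrum total equals the site count exactly.  With
    correction, folded classes with sites but no kept representative (L_x' = 0)
    fall back to zero mass with a warning.
    """
    sub = _biallelic(df)
    e = np.zeros(n - 1)
    lx = np.zeros(n - 1)
    lxp = np.zeros(n - 1)
    if not use_filter_correction:
        for c0, p0 in zip(sub.count_a0, sub.p_a0):
            # a0 ancestral (prob p0) -> derived count n - c0; else c0
            e[n - c0 - 1] += p0
            e[c0 - 1] += 1.0 - p0
        for c0 in sub.count_a0:
            lx[c0 - 1] += 1
            if c0 != n - c0:
                lx[n - c0 - 1] += 1
        return USFS(n=n, e_dx=e, estimator="posterior_average", lx=lx, lx_prime=lx)

    kept = keep_mask(sub, policy)
    # folded-class tallies and kept posterior sums per actual category
    psum = np.zeros(n - 1)
    for c0 in sub.count_a0:
        lx[c0 - 1] += 1
        if c0 != n - c0:
            lx[n - c0 - 1] += 1
    for c0, p0 in zip(sub.count_a0[kept], sub.p_a0[kept]):
        lxp[c0 - 1] += 1
        if c0 != n - c0:
            lxp[n - c0 - 1] += 1
        psum[n - c0 - 1] += p0
        psum[c0 - 1] += 1.0 - p0
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(lxp > 0, lx * psum / np.maximum(lxp, 1), 0.0)
    empty = (lx > 0) & (lxp == 0)
    if np.any(empty):
        warnings.warn(
            f"{int(empty.sum())} folded frequency classes have no kept sites; "
            "their mass is reported as 0", stacklevel=2)
    return USFS(n=n, e_dx=e, estimator="posterior_average_corrected",
                lx=lx, lx_prime=lxp)


def qq_compare(est: USFS, ref: USFS) -> pd.DataFrame:
    """Cumulative-proportion pairs at each category boundary (QQ-plot table)."""
    if est.n != ref.n:
        raise ValueError(f"sample-size mismatch: {est.n} vs {ref.n}")
    if est.total <= 0 or ref.total <= 0:
        raise ValueError("cannot compare empty spectra")
    return pd.DataFrame({
        "x": np.arange(1, est.n),
        "ref_cumulative": np.cumsum(ref.freq),
        "est_cumulative": np.cumsum(est.freq),
    })


def relative_error(est: USFS, truth: USFS) -> np.ndarray:
    """(estimated frequency - true frequency) / true frequency per category.

    Categories empty in the truth are undefined and reported as NaN.
    """
    if est.n != truth.n:
        raise ValueError(f"sample-size mismatch: {est.n} vs {truth.n}")
    tf = truth.freq
    ef = est.freq
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = (ef - tf) / tf
    rel[tf == 0] = np.nan
    return rel
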