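"""Coalescent simulation scenarios with recorded polarisation truth.

The generator produces neutral coalescent-with-recombination tree sequences for
a constant-size population (Ne = 30,000 diploids, mu = 1.25e-8 per bp per
generation under Jukes-Cantor, uniform recombination 1e-8 by default) and the
variants the study design calls for: a high mutation rate (1e-7) to create
multi-allelic and homoplasic sites, logarithmic population-size change between
960 and 46,000 diploids over the last 150,000 generations (both directions),
a Kimura two-parameter model with kappa = 5, and a GC-biased root nucleotide
distribution (GC:AT = 3:2) with equal exchange rates.

Each replicate carries a truth table (one row per site: position, the
simulated ancestral allele, and the recorded mutation count) against which
polarisation calls and spectra are scored.  Sequence lengths default to the
desk scale of 1-2 Mb; experiment drivers shrink the length as the sample size
grows so per-size site counts stay comparable and runs finish in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd

from .models import SubstitutionModel
from .polarise import accuracy_report, keep_mask, polarise_tree_sequence
from .usfs import (USFS, qq_compare, relative_error, true_usfs, usfs_max_pp,
                   usfs_posterior_average)

DEFAULT_NE = 30_000
DEFAULT_MU = 1.25e-8
HIGH_MU = 1e-7
DEFAULT_RECOMB = 1e-8
SIZE_CHANGE = (960, 46_000)
CHANGE_DURATION = 150_000
GC_ROOT_DISTRIBUTION = (0.2, 0.3, 0.3, 0.2)  # A, C, G, T with GC:AT = 3:2


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario (one population)."""

    n_diploids: int = 10
    sequence_length: float = 1_000_000.0
    mutation_rate: float = DEFAULT_MU
    recombination_rate: float = DEFAULT_RECOMB
    recombination_map: str | None = None   # HapMap-format rate map, overrides the rate
    population_size: int = DEFAULT_NE
    demography: str = "constant"        # constant | increase | decrease
    size_range: tuple[int, int] = SIZE_CHANGE
    change_duration: float = CHANGE_DURATION
    n_epochs: int = 50
    mutation_model: str = "jc69"        # jc69 | k80 | gc_root
    kappa: float = 5.0
    seed: int = 1
    replicates: int = 10

    def __post_init__(self):
        if self.n_diploids < 1 or self.sequence_length <= 0:
            raise ValueError("sample size and sequence length must be positive")
        if min(self.mutation_rate, self.recombination_rate) <= 0:
            raise ValueError("rates must be > 0")
        if self.demography not in ("constant", "increase", "decrease"):
            raise ValueError(f"unknown demography {self.demography!r}")
        if self.mutation_model not in ("jc69", "k80", "gc_root"):
            raise ValueError(f"unknown mutation model {self.mutation_model!r}")


def _demography(cfg: ScenarioConfig) -> msprime.Demography | None:
    if cfg.demography == "constant":
        return None
    lo, hi = cfg.size_range
    # forward-in-time: increase = small past, large present
    n_present, n_ancient = (hi, lo) if cfg.demography == "increase" else (lo, hi)
    demo = msprime.Demography()
    demo.add_population(initial_size=n_present)
    T, k = cfg.change_duration, cfg.n_epochs
    for i in range(1, k + 1):
        t = T * i / k
        # log-linear size trajectory, piecewise constant over >= 50 epochs
        size = n_present * (n_ancient / n_present) ** (t / T)
        demo.add_population_parameters_change(time=t, initial_size=size)
    return demo


def _mutation_model(cfg: ScenarioConfig):
    if cfg.mutation_model == "jc69":
        return msprime.JC69()
    if cfg.mutation_model == "k80":
        return msprime.HKY(kappa=cfg.kappa,
                           equilibrium_frequencies=[0.25, 0.25, 0.25, 0.25])
    jc = msprime.JC69()
    return msprime.MatrixMutationModel(
        alleles=jc.alleles,
        root_distribution=list(GC_ROOT_DISTRIBUTION),
        transition_matrix=jc.transition_matrix,
    )


def reconstruction_model(cfg: ScenarioConfig) -> SubstitutionModel:
    """The substitution model matching a scenario, with a uniform root prior."""
    if cfg.mutation_model == "k80":
        return SubstitutionModel("K80", mu=cfg.mutation_rate, kappa=cfg.kappa)
    return SubstitutionModel("JC69", mu=cfg.mutation_rate)


def truth_table(ts) -> pd.DataFrame:
    """Per-site truth: position, simulated ancestral allele, mutation count."""
    rows = [(int(s.position), s.ancestral_state, len(s.mutations))
            for s in ts.sites()]
    return pd.DataFrame(rows, columns=["position", "ancestral", "n_mutations"])


def simulate_replicate(cfg: ScenarioConfig, seed: int):
    """One tree sequence plus its truth table; byte-identical under a seed."""
    if cfg.recombination_map is not None:
        rate = msprime.RateMap.read_hapmap(cfg.recombination_map)
        kwargs = {"recombination_rate": rate}
    else:
        kwargs = {"sequence_length": cfg.sequence_length,
                  "recombination_rate": cfg.recombination_rate}
    ts = msprime.sim_ancestry(
        samples=cfg.n_diploids,
        population_size=cfg.population_size if cfg.demography == "constant" else None,
        demography=_demography(cfg),
        random_seed=seed,
        **kwargs,
    )
    mts = msprime.sim_mutations(ts, rate=cfg.mutation_rate,
                                model=_mutation_model(cfg), random_seed=seed + 1)
    return mts, truth_table(mts)


def simulate_scenario(cfg: ScenarioConfig):
    """Generator over ``cfg.replicates`` independent (tree sequence, truth) pairs."""
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.replicates):
        yield simulate_replicate(cfg, int(rng.integers(1, 2**31 - 1)))


def remutate(ts, rate: float, cfg: ScenarioConfig, seed: int):
    """Drop existing mutations and re-mutate the same ARG at a new rate."""
    mts = msprime.sim_mutations(ts, rate=rate, model=_mutation_model(cfg),
                                keep=False, random_seed=seed)
    return mts, truth_table(mts)


def watterson_theta(ts) -> float:
    """Watterson's estimator of theta per bp from segregating-site counts."""
    n = ts.num_samples
    a_n = np.sum(1.0 / np.arange(1, n))
    return ts.num_sites / (a_n * ts.sequence_length)


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------


def _maxfreq_calls(df: pd.DataFrame, rng: np.random.Generator
                   ) -> tuple[pd.Series, pd.Series]:
    """Major-allele and frequency-weighted random calls for biallelic sites."""
    maxf, rand = [], []
    for a0, c0, n, alleles in zip(df.a0, df.count_a0, df.n, df.alleles):
        a, b = alleles.split(",")
        other = b if a == a0 else a
        if 2 * c0 > n:
            maxf.append(a0)
        elif 2 * c0 < n:
            maxf.append(other)
        else:
            maxf.append("")  # exact 50/50: treated as missing data
        rand.append(a0 if rng.random() < c0 / n else other)
    return pd.Series(maxf, index=df.index), pd.Series(rand, index=df.index)


def run_accuracy_experiment(sample_sizes, *, lengths=None, replicates: int = 10,
                            seed: int = 1, policy: str = "strict",
                            mutation_rate: float = DEFAULT_MU,
                            base_cfg: ScenarioConfig | None = None,
                            single_mutation_only: bool = True,
                            remutate_rate: float | None = None) -> pd.DataFrame:
    """Polarisation accuracy of the ARG method and baselines across sample sizes.

    For each diploid sample size, ``replicates`` independent simulations are
    polarised from their true marginal trees; accuracy (overall and stratified
    by whether the true ancestral allele is the major, equal-frequency or minor
    one), kept-SNP proportion and the non-informative proportion are reported
    per method.  ``lengths`` maps sample size to sequence length (defaults to
    the base config's length for all sizes).  With ``remutate_rate`` set, the
    simulated ARGs are re-mutated at that rate before polarising (the
    multiple-mutations design).
    """
    cfg0 = base_cfg or ScenarioConfig(mutation_rate=mutation_rate)
    rng = np.random.default_rng(seed)
    rows = []
    for n_dip in sample_sizes:
        L = (lengths or {}).get(n_dip, cfg0.sequence_length)
        cfg = replace(cfg0, n_diploids=n_dip, sequence_length=L,
                      replicates=replicates, seed=int(rng.integers(1, 2**31 - 1)))
        for rep, (ts, truth) in enumerate(simulate_scenario(cfg)):
            if remutate_rate is not None:
                ts, truth = remutate(ts, remutate_rate, cfg,
                                     int(rng.integers(1, 2**31 - 1)))
            model = reconstruction_model(cfg)
            df = polarise_tree_sequence(ts, model)
            tmap = dict(zip(truth.position, truth.ancestral))
            nmut = dict(zip(truth.position, truth.n_mutations))
            if single_mutation_only:
                df = df[[nmut[p] == 1 for p in df.position]].reset_index(drop=True)
            if df.empty:
                continue
            rep_rng = np.random.default_rng(int(rng.integers(1, 2**31 - 1)))
            bi = df[df.n_alleles == 2].copy()
            maxf, randf = _maxfreq_calls(bi, rep_rng)
            bi["call_maxfreq"], bi["call_random"] = maxf, randf
            for method, frame, col, pol in (
                ("arg_filtered", df, "call", policy),
                ("arg_unfiltered", df, "call", None),
                ("max_frequency", bi, "call_maxfreq", None),
                ("random_frequency", bi, "call_random", None),
            ):
                rpt = accuracy_report(frame, tmap, policy=pol, call_column=col)
                rows.append({"sample_size": n_dip, "replicate": rep,
                             "method": method, **{k: v for k, v in rpt.items()
                                                  if k != "flag_counts"}})
    return pd.DataFrame(rows)


def run_usfs_experiment(cfg: ScenarioConfig, *, estimators=("posterior_average",),
                        seed: int | None = None) -> dict:
    """uSFS estimates from true trees, with QQ and relative-error comparisons.

    Pools sites over the scenario's replicates, computes the requested
    estimators (``max_pp``, ``max_pp_filtered``, ``posterior_average``,
    ``posterior_average_corrected``) and compares each against the true
    spectrum.  Returns the spectra plus per-estimator QQ tables and
    relative-error vectors.
    """
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    model = reconstruction_model(cfg)
    shifted, all_truth = [], {}
    offset = 0
    # replicates are independent chromosomes: offset positions to keep keys unique
    for ts, truth in simulate_scenario(cfg):
        f = polarise_tree_sequence(ts, model)
        f["position"] = f["position"] + offset
        shifted.append(f)
        for p, a in zip(truth.position, truth.ancestral):
            all_truth[p + offset] = a
        offset += int(cfg.sequence_length)
    df = pd.concat(shifted, ignore_index=True)
    n = 2 * cfg.n_diploids
    truth_sfs = true_usfs(df, all_truth, n)
    out = {"truth": truth_sfs, "n_sites": int(len(df))}
    for est in estimators:
        if est == "max_pp":
            sfs = usfs_max_pp(df, n, filtered=False)
        elif est == "max_pp_filtered":
            sfs = usfs_max_pp(df, n, filtered=True, policy="strict")
        elif est == "posterior_average":
            sfs = usfs_posterior_average(df, n, use_filter_correction=False)
        elif est == "posterior_average_corrected":
            sfs = usfs_posterior_average(df, n, use_filter_correction=True,
                                         policy="usfs")
        else:
            raise ValueError(f"unknown estimator {est!r}")
        out[est] = {
            "usfs": sfs,
            "qq": qq_compare(sfs, truth_sfs),
            "relative_error": relative_error(sfs, truth_sfs),
        }
    return out
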