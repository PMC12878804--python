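# argpolar

Outgroup-free SNP polarisation and unfolded site-frequency-spectrum (uSFS)
estimation from the local genealogies of an ancestral recombination graph
(ARG).

## The problem

Calling which allele at a segregating site is ancestral and which is derived
("polarisation") is a prerequisite for the uSFS and for many downstream
population-genetic inferences. The standard approach compares against outgroup
species, which fails exactly where it is most needed: species without a close
outgroup, and genomic regions where outgroups cannot be aligned. `argpolar`
instead reads the ancestral state off the *within-population* genealogical
signal: at every position the ARG supplies a rooted local tree with node times,
and the allele configuration on that tree is informative about the state at
its root.

## The method

For a site with observed leaf states **x** on local tree *T* with branch times
*t*, the package computes, for each root nucleotide *s*, the best joint
assignment of states to all internal nodes,

  L(s) = max over assignments z of prod over edges (u→v) P( z_v | z_u, t_uv ),

with P(·|·, t) the transition probability of a symmetric nucleotide model
(JC69, or K80 with transition/transversion ratio κ). The recursion is a
max-product dynamic program kept entirely in log space, so trees with hundreds
of leaves and times of 10⁶ generations do not underflow. An empirical-Bayes
posterior over root states is P(s | x) proportional to π(s)·L(s); the ancestral call is the
max-posterior allele after restricting to the alleles observed at the site.

Fixed-root parsimony (Hartigan/Sankoff) classifies each genealogy:
*non-informative* when two or more candidate ancestral states need the same
minimal number of mutations (e.g. a single mutation on a root-adjacent
branch), *multiple mutations* when the minimum exceeds one, *homoplasy* when a
biallelic site needs more than one mutation, and *polytomy-with-mutation* when
a mutation lands under an unresolved node. Filtering the non-informative
genealogies makes polarisation from true trees essentially error-free; without
filtering, errors concentrate where the ancestral allele is the minor one.

For the uSFS over n haplotypes, each biallelic site with allele counts
(x, n−x) splits its posterior mass between the complementary derived-allele
count classes:

  E[D_x] = sum over sites i of P_i(D_x),

where P_i(D_x) is the restricted posterior that the allele in n−x copies is
ancestral (the "posterior average" estimator). When suspect genealogies must
be filtered, the kept sites' mean posterior in each folded class {x, n−x} is
rescaled by the total class count L_x:

  E[D_x] = L_x · (1 / L_x′) · sum over kept i of P_i(D_x).

Taking only the best call per site ("MAX PP"), or best calls after filtering,
is biased — the probability that a genealogy is non-informative depends on the
derived-allele frequency — and both are provided for comparison.

Local trees can come from a succinct tree sequence (`.trees`), from newick
(one rooted tree per SNP), or be built from per-site pairwise-TMRCA matrices
by UPGMA average-linkage clustering (distance 2·TMRCA, so join heights are
TMRCA values), with the node-time sanitation rules needed by inferred trees
(internal times floored at 1e-12; parent–child gaps ≤ 1e-14 collapsed into
polytomies).

## Worked example

```python
import argpolar as ap
import numpy as np

cfg = ap.ScenarioConfig(n_diploids=10, sequence_length=500_000, seed=7)
ts, truth = ap.simulate_replicate(cfg, 11)
df = ap.polarise_tree_sequence(ts, ap.reconstruction_model(cfg))
report = ap.accuracy_report(df, dict(zip(truth.position, truth.ancestral)),
                            policy="strict")
print(f"segregating sites: {report['n_sites']}")
print(f"kept after strict filtering: {report['n_kept']} "
      f"({report['kept_proportion']:.1%})")
print(f"accuracy on kept sites: {report['accuracy']:.3f}")
print(f"non-informative proportion: {report['non_informative_proportion']:.1%}")

bi = df[df.n_alleles == 2]
sfs = ap.usfs_posterior_average(bi, n=20)
tru = ap.true_usfs(bi, dict(zip(truth.position, truth.ancestral)), n=20)
rel = ap.relative_error(sfs, tru)
print(f"posterior-average uSFS total mass: {sfs.total:.1f} "
      f"(= {len(bi)} biallelic sites)")
print(f"singleton class E[D1] = {sfs.e_dx[0]:.1f} (truth {tru.e_dx[0]:.0f})")
print(f"mean |relative error| across DAF classes: {np.nanmean(np.abs(rel)):.3f}")
```

prints

```
segregating sites: 2568
kept after strict filtering: 1654 (64.4%)
accuracy on kept sites: 0.999
non-informative proportion: 35.3%
posterior-average uSFS total mass: 2559.0 (= 2559 biallelic sites)
singleton class E[D1] = 768.8 (truth 770)
mean |relative error| across DAF classes: 0.052
```

Strict filtering keeps the ~65% of sites whose genealogy identifies the
ancestral allele unambiguously and polarises essentially all of them
correctly (the residual errors are true double mutations that masquerade as
single ones). The posterior-average spectrum carries exactly one unit of mass
per biallelic site and tracks the true spectrum to within a few percent per
frequency class at this sequence length.

The same pipeline is scriptable from a shell:

```sh
argpolar simulate --scenario default --n-diploids 10 --length 500000 \
    --seed 7 --out-prefix sim
argpolar polarise --trees sim.0.trees --vcf sim.0.vcf --policy strict \
    --out sites.tsv
argpolar usfs --sites sites.tsv --estimator posterior-average --out usfs.tsv
```

(`argpolar build-trees` turns per-site TMRCA matrices into UPGMA local trees;
`argpolar validate` checks inputs against the data-model invariants.)

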