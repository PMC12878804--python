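# Methods

## Model and reconstruction procedure

At each segregating site the local genealogy is treated as an independent
rooted tree with node times in generations. Ancestral-state inference is a
*joint* (max-product) reconstruction: for each candidate root nucleotide the
algorithm finds the single best assignment of states to all internal nodes,
accumulating log transition probabilities up the tree. Joint rather than
marginal (sum-product) reconstruction is used deliberately: because no
averaging of conditional likelihoods happens at inner nodes, the whole
recursion can be carried in log space and never underflows, whatever the tree
size or time scale. The price is that the reported posteriors are
"joint-path" posteriors — the softmax of per-root-state best joint scores
combined with the root prior — rather than marginal root posteriors. For the
biallelic, tree-like configurations that dominate polarisation the two are
close, and the calibration of the posterior-average uSFS (below) is checked
empirically by the test suite.

Transition probabilities come from the closed forms of JC69 or K80,
parameterised so that the total substitution rate per site is μ (for K80 with
ratio κ the transition rate is κμ/(κ+2), each transversion μ/(κ+2)). Branch
"lengths" are time differences in generations and d = μ·t; trees whose branch
lengths are already in substitutions per site can be ingested with μ = 1.
Under any symmetric model, exchanging the two observed alleles together with
the two root branch lengths swaps the posteriors exactly; in a two-clade
genealogy with monomorphic clades, the posterior depends only on the two root
branch lengths, not on the within-clade topology. Both properties are
asserted by tests.

The root prior defaults to uniform (1/4 per nucleotide), independent of
whatever root distribution generated the data. Nothing in the reconstruction
assumes stationarity of the data-generating process, and a non-uniform prior
can be supplied for sensitivity analyses. Ancestral calls restrict and
renormalise the posterior to the alleles observed at the site (the probability
of frequency classes that are not observed is null); the unrestricted
four-state posterior is retained in the output.

## Classification and filtering

Fixed-root small parsimony (Hartigan/Sankoff with unit costs) is run once per
site; the root row of the min-sum table gives the minimal mutation count for
every candidate ancestral state simultaneously. Candidate states default to
the alleles observed at the site: an unobserved root state can never tie a
single-mutation observed optimum, and the real-data filter is defined relative
to the number of observed alleles; all four nucleotides can be requested
instead. Flags:

- **non-informative** — two or more candidates attain the overall minimum;
- **multiple mutations** — the overall minimum exceeds one;
- **homoplasy** — multiple mutations at a site with exactly two alleles;
- **polytomy-with-mutation** — an optimal placement puts a mutation under a
  node with more than two children.

One optimal placement is reported under the topmost-change convention: moving
root-to-tips, a node keeps its parent's state whenever that is optimal, so a
mutation is recorded on the edge above the highest node whose state differs
from its parent's. This mirrors the reference tree-sequence library's
parsimony mapping, with one deliberate difference: that library lets a fixed
ancestral state be overridden by an extra mutation above the root, so its
count equals min(S(c), 1 + min over s of S(s)) for candidate c. The override never
changes which candidates attain the overall minimum, so all flags agree; the
test suite cross-checks counts against that library modulo the allowance.

Three named filter policies package the use cases: `strict` (drop
non-informative, multi-mutation, and polytomy-mutation sites — the
polarisation-accuracy setting), `usfs` (drop only sites needing more than two
mutations), and `real-data` (drop non-informative sites and sites whose count
exceeds the number of observed alleles).

## uSFS estimators

For n haplotypes and biallelic sites, the posterior-average estimator assigns
each site its restricted posterior mass P_i(D_x) to category x and 1−P_i(D_x)
to n−x, so the spectrum total equals the number of contributing sites exactly
(asserted to 1e-9). With filtering, folded classes {x, n−x} are tallied as
L_x (all sites) and L_x′ (kept sites) and E[D_x] = L_x·(mean over kept sites
of P_i(D_x)). A folded class with sites but no kept representative has no
defensible estimate; it is reported as zero mass with a warning. For even n
the class x = n/2 is its own complement and is counted once. The best-call
estimators (MAX PP, MAX PP with filtering) are provided because their bias is
itself a result: filtering removes non-informative genealogies at a rate that
depends on the derived-allele frequency, inflating low-frequency classes.

QQ comparisons use the cumulative proportions of the reference spectrum as
quantile boundaries; relative errors are (estimated − true)/true on normalised
class frequencies, undefined (NaN) where the truth is empty.

## Tree construction and sanitation

UPGMA average-linkage clustering builds a rooted ultrametric tree from a
per-site symmetric pairwise-TMRCA matrix. The distance fed to the clustering
is 2·TMRCA — a monotone transform that leaves the topology unchanged — so
that node heights (half the linkage distance) are TMRCA values in generations
and branch lengths are physically meaningful; the factor is a configuration
switch (`distance_scale`, default 2). Ties are resolved by joining the pair
of clusters whose smallest member labels are lexicographically least, making
reruns deterministic; the implementation is validated against
`scipy.cluster.hierarchy.linkage(method="average")` on tie-free inputs, which
is kept as an oracle rather than the implementation because its nearest-
neighbour-chain algorithm does not guarantee that tie-break.

Inferred trees (e.g. from SMC-based TMRCAs) can carry degenerate times, so
ingestion applies two sanitation rules: internal node times below 1e-12 are
raised to 1e-12, and an internal child within 1e-14 of its parent's time is
deleted with its children re-attached, creating polytomies. The operation is
idempotent and never touches leaves. Genomic intervals are left-closed,
right-open and 0-based internally; VCF positions are converted from 1-based
at the I/O boundary only, and a VCF sample S contributes haplotypes S_0, S_1
matched to tree leaf labels by exactly that rule (mismatches are hard errors).

## Synthetic data

The generator wraps a standard coalescent-with-recombination simulator. Its
defaults are the study conditions: a constant population of 30,000 diploids,
μ = 1.25e-8 per bp per generation under JC69, uniform recombination at 1e-8
per bp (a recombination map can be supplied instead; none is bundled), and
ten replicates per condition. Variants: re-mutating the same ARGs at 1e-7 to
enrich for multi-allelic and homoplasic sites; logarithmic population-size
change between 960 and 46,000 diploids over the last 150,000 generations in
both directions, implemented as a log-linear size trajectory sampled at 50
piecewise-constant epochs (the interpolation grid is a package choice; finer
grids do not change the results measurably); K80 with κ = 5; and a GC-biased
root distribution (A,C,G,T = 0.2,0.3,0.3,0.2) with equal exchange rates. The
per-site truth is the simulator's recorded ancestral state and mutation
count, which lets analyses stratify by true single- versus multi-mutation
sites.

Problem sizes are desk scale: sequence lengths of 1–2 Mb at small sample
sizes, shrinking with sample size (down to ~80 kb at 200 diploids) so that
per-size site counts stay comparable and the full acceptance run completes in
a few minutes on one CPU. What passing tests on these data show is internal
consistency of the method given *correct* genealogies: real analyses depend
on upstream ARG inference, whose topological and branch-length errors (not
emulated here beyond the TMRCA/UPGMA ingestion path) are known to be the
dominant source of error in practice. The generator also does not emulate
selection, sequencing error, missing genotypes or unphased data.

## Numerical conventions

Impossibility is a saturating sentinel log-score of −1e18 rather than −inf,
so additions cannot produce NaNs; a site whose every root state is impossible
raises an error. Exact posterior ties are flagged and broken lexicographically
(A<C<G<T), as are parsimony placement ties. Non-segregating sites are
skipped with a count; sites with missing genotypes are dropped at VCF
ingestion with per-reason tallies. All experiment randomness flows from a
single integer seed through a generator chain, making every table
reproducible byte for byte.

## Known limitations

- No ARG inference of its own: the package consumes trees or TMRCA matrices
  produced elsewhere.
- Joint-path posteriors are not marginal posteriors (documented above).
- Only symmetric substitution models (JC69/K80); no rate heterogeneity,
  GTR or non-stationary models.
- Multi-allelic sites are polarised but excluded from the biallelic uSFS.
- Weighted-cost parsimony and placement uncertainty beyond one optimal
  solution are out of scope.
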