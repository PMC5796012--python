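# Methods

## Problem and objectives

`phylorc` searches the space of unrooted binary phylogenetic trees on a
fixed taxon set for solutions that are simultaneously good under the two
classical optimality criteria:

* **Parsimony** `f1`: the minimum number of substitutions the tree implies,
  computed by Fitch's downpass over column-compressed site patterns.
  Rooting for the downpass is arbitrary (the pendant edge of the smallest
  taxon is used); gaps, `N`/`?` and IUPAC ambiguity codes enter as state
  sets, so missing data never contributes a change on its own.
* **Likelihood** `f2 = −ln L`: the negated log-likelihood under a general
  time-reversible (GTR) substitution model with discrete-gamma rate
  variation, computed by Felsenstein's pruning recursion. Reversibility
  makes the value independent of the root used for the recursion, which is
  exercised directly by the tests. Negation turns both criteria into
  minimization problems.

No branch-length optimization happens inside the objective: branch lengths
are carried and recombined by the search operators, and the likelihood
clamps lengths below `1e−6` substitutions/site so zero-length edges from
operators stay finite. Special cases of GTR (JC69, HKY85, …) are reachable
through parameter choices, not separate code paths.

### Numerics

`P(t) = exp(Qrt)` is computed by symmetric eigendecomposition
(`diag(√π)·Q·diag(1/√π)` is symmetric for a reversible `Q`), with `Q`
normalized to one expected substitution per unit length at stationarity.
The discrete gamma uses equal-probability categories with mean-of-bin
rates (default 4 categories), renormalized to mean exactly 1; the category
count and shape are configurable because published analyses vary in this
convention.

## Normalization and reference points

Parsimony counts and log-likelihoods live on very different scales, so all
selection arithmetic uses objectives normalized against a reference box:

    f̄_i = (f_i − z*_i) / (znad_i − z*_i)

where `z*` (componentwise best) and `znad` (componentwise worst) are
**running extremes over the whole run**, updated every generation. Running
extremes rather than per-generation ranges keep the normalization from
oscillating as the population moves. A degenerate axis (`znad = z*`) maps
to 0 so it cannot influence selection; a solution at the reference point
has its objective balance defined as ½ (equally good in both directions).

## Redistribution selection

The population is decomposed over `n` weight vectors `w_i = (w_i1, 1−w_i1)`
with `w_i1` evenly spaced on `[0,1]`. After parents and offspring are
merged, each individual joins the sub-population minimizing its *relative
degree*

    R = | f̄1/(f̄1+f̄2) − w_i1 |     (ties → lowest index)

and members are ranked by the weighted sum `G = w1·f̄1 + w2·f̄2` (computed
on normalized objectives — on raw scales the weights would be
meaningless). While more than `m` individuals remain, the globally worst
member of any sub-population exceeding the capacity `m/n` is removed;
under-full sets are never trimmed, which deliberately retains outlying
search directions. `n` must divide `m` (defaults `m=100`, `n=10`).

## Consensus branches and protection

For each search direction the engine takes the best `q` trees (default 5)
from that sub-population and its two weight-space neighbours (boundary
directions use the two nearest interior sets, so three sets always
contribute) and computes their **majority-rule(+) consensus branches** —
never a consensus tree; only the split set is consumed:

* a split in strictly more than half of the elite trees is always kept
  (the majority core);
* additionally, a split is kept when it occurs in more trees than contain
  a split incompatible with it — trees that neither contain nor contradict
  it abstain. This is the abstention-style "(+)" extension from the
  consensus-tree literature. It provably contains the core and is provably
  pairwise compatible (two conflicting splits cannot both out-vote each
  other's opposition), hence always realizable on a single tree.

An earlier design admitted every observed split compatible with the
greedily accepted ones; that protects an almost fully resolved topology
within a few generations on small taxon sets and freezes the search, so
the abstention rule was adopted. A `plain_majority` switch keeps only the
core.

Protected splits constrain the operators:

* **PDG crossover** (prune a random 1…n−3-leaf subtree of one parent,
  delete its taxa from a copy of the other, graft onto a random edge —
  split edge lengths in half, handle length kept): prune/graft choices are
  resampled up to 20 times until the offspring retains every protected
  split the graft-recipient parent contained; on exhaustion the recipient
  is copied unchanged. The protection contract is therefore absolute.
* **NNI mutation** simply never selects an internal edge whose split is
  protected; if all are protected the tree is returned unchanged.

Parent selection is binary tournament: Pareto dominance first, then the
smaller normalized-objective sum, then a fair coin. Each crossover runs
PDG in both directions to yield two children (children of the no-crossover
branch are copies that keep their cached scores); each child is mutated
with the configured probability.

## Main loop and reporting

Per generation: compute consensus sets (skipped in ablation mode),
breed `N` offspring, score new trees (a per-(topology, lengths) cache
keyed by the deterministic Newick string prevents re-scoring merged
parents — one "evaluation" is one genuinely new scoring), update the
reference box, redistribute parents ∪ offspring down to `N`. The stop
condition is a generation count (default 100) or optionally an evaluation
budget. Every run records a trace: running best `f1`/`f2`, the
hypervolume of the survivor front in normalized space (reference corner
1.01², computed by the exact 2-D staircase sum), reference points,
protected-branch counts and front size. All randomness flows from one
seeded NumPy generator, and runs are bit-reproducible given (seed,
config); the deterministic Newick writer (trifurcation at the smallest
taxon's neighbour, children ordered by smallest descendant) makes outputs
diffable.

## Synthetic data

`simdata` evolves sequences along a known tree under exactly the model the
scorer assumes: root states from `π`, one gamma-category rate per site
held constant across the tree, per-edge transition sampling. It emulates
a clean, gap-free, pre-aligned DNA matrix; it does not model indels,
alignment error, rate heterotachy, or compositional drift, so passing
tests demonstrate correctness of the machinery and internal consistency
of simulator and scorer — not robustness to real-data pathologies.
`make_benchmark(n_taxa, length, seed)` fixes a uniform random topology
with exponential(mean 0.1) branch lengths and a randomized moderate GTR
parameterization (near-uniform frequencies, exchangeabilities in
[0.5, 2], gamma shape in [0.5, 2]), values chosen once as typical of
empirical nucleotide datasets.

## Problem sizes used by the test suite and acceptance script

Oracle equivalences run on exhaustive-enumeration scales (≤ 8 taxa,
≤ 10 sites; 50–200 instances). The end-to-end ablation uses the fixed
benchmark `make_benchmark(20, 500, 42)` with population 40, 4
sub-populations, 50 generations and 10 seeded runs per mode — the package's
chosen desk-scale study conditions.

## Known limitations

* On small taxon sets (around 20 taxa, i.e. only n−3 ≈ 17 internal
  branches) the per-direction protected sets saturate to the full topology
  once the sub-populations converge, after which the absolute protection
  contract reduces both operators to near no-ops and the protected search
  stalls; the unprotected ablation then reaches better fronts in the same
  number of generations. The benefit claimed for protection on datasets an
  order of magnitude larger (where the protected fraction stays partial)
  is not reproduced at this scale, and the ablation acceptance test
  records this honestly.
* The consensus frequency counter is hash-based (`O(k·n·log n)`), not the
  asymptotically optimal `O(k·n)` algorithm; at desk scale only
  performance, not correctness, would differ.
* Only DNA data; no invariant-sites mixture; no parallel execution.
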