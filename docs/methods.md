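# Methods

## Model

Each sequence belongs to exactly one of K clusters; within cluster *i*
the alleles at locus *j* are i.i.d. multinomial draws from a
cluster-specific frequency vector with a symmetric Dirichlet prior,
hyperparameter α<sub>j</sub> = 1/N<sub>A</sub>(j) per allele, where
N<sub>A</sub>(j) is the number of distinct alleles observed at the locus.
Integrating the frequencies out gives a product of Dirichlet-multinomial
terms over clusters and loci (the collapsed marginal likelihood). Because
the per-locus hyperparameters sum to one, the fast evaluation path pads
every locus to four allele slots — empty slots contribute Γ(α)/Γ(α) = 1 —
and computes everything with vectorised log-gamma; the public
`cluster_locus_log_ml` makes no such assumption and accepts arbitrary
symmetric α.

Missing cells (gaps, `n`, IUPAC ambiguity codes) contribute to no count:
the likelihood is over observed alleles only, which is also why
missingness in the generator is completely at random.

The prior over partitions is uniform over K ∈ {1..K_max} and flat over
the partitions sharing a given K, i.e. log P(S) = −log K_max −
log S₂(n, K) with S₂ the Stirling number of the second kind (computed
exactly with big integers). `log_posterior` exposes this score; the
search itself maximises the log marginal likelihood, against which its
exhaustive-enumeration guarantees are stated and tested. At fixed K the
prior cancels from every comparison.

## Input filtering

Only a/c/g/t count as alleles; everything else is missing. Columns with
fewer than two observed alleles are dropped. By default a locus is kept
only if at least two of its alleles each occur in ≥ 2 sequences, and an
allele observed exactly once at a kept locus is recoded missing, with
N<sub>A</sub>(j) recomputed afterwards — removing the noisy singleton
observation while preserving the locus's informative signal. Positions
are reported 1-based relative to the input alignment.

## Search

Greedy stochastic search with three move families cycled to convergence:

1. **Reassignment** — each sequence (rng-shuffled order) moves to the
   cluster with the best strictly positive log-ML gain, or to a new
   singleton cluster while K < K_max. Single-sequence deltas reduce to
   posterior-predictive form, log[(α_j + n_ijx)/(1 + T_ij)] summed over
   observed loci, so a full scan is O(K·M).
2. **Merge** — the best strictly improving pairwise cluster merge,
   evaluated exactly via additivity of per-cluster contributions.
3. **Split/relocate** — for clusters of ≥ 4 members, candidate subgroups
   are the nodes of the cluster's complete-linkage subtree; each subgroup
   is scored against every other cluster and against a new cluster. This
   is the move that undoes bad agglomerative starts.

A move counts as an improvement only above a 1e−10 tolerance (guards
against floating-point cycling); affected clusters' contributions are
recomputed exactly after every applied move, so the cached total never
drifts from a from-scratch evaluation. Empty clusters are removed and
labels compacted (first-appearance order) immediately. Equal best deltas
go to the lowest cluster index; complete-linkage ties are resolved by
scipy's deterministic linkage implementation.

Initialisation is a complete-linkage cut of pairwise Hamming distances
over jointly observed loci (pairs with no shared observed locus get the
maximal distance M). Restart r of `n_restarts` (default 3 — cheap
insurance against local optima) uses seed + r; restart 0 starts from the
linkage cut at K_max, later restarts randomly reassign 25% of sequences
first. Restarts are independent and may run on several joblib workers;
they are reduced in restart order, so the result is identical for any
worker count.

## Hierarchy

Level 1 clusters the full matrix with K_max = n.pops. Each level-d
cluster with ≥ 4 members is then re-clustered alone: its rows are
extracted and the locus filter re-applied (within a cluster many loci
become invariant, and allele inventories — hence N_A and α — shrink),
with K_max = min(n.pops, subset size). A cluster is inherited unsplit
when its own search prefers K = 1, when it is smaller than 4, or when no
polymorphic loci survive; no ad-hoc stopping threshold is added beyond
what the integrated likelihood itself prefers. Subset seeds derive from
(seed, depth, parent) through a SeedSequence spawn key, so results do not
depend on traversal order. Global labels at each level are assigned by
ascending parent label then sub-cluster index, making deeper levels
strict refinements of shallower ones.

The per-level log-ML log records one entry per parent (searched parents:
the search's final score; inherited parents: the single-cluster score of
their re-filtered subset, 0.0 when nothing survives), so entries at each
level sum exactly to that level's total log-ML over subset matrices.

## Synthetic data

The generator draws per-cluster allele frequencies from a symmetric
Dirichlet (`concentration`, default 0.2) at a fraction `divergence`
(default 0.5) of loci, with the remaining loci sharing one vector;
sequences are i.i.d. multinomial draws per locus. Concentration 0.2
keeps most loci near fixation within a cluster, giving a minor-allele
frequency spectrum concentrated near zero as in real within-population
SNP data; balanced within-cluster polymorphism (concentration ≳ 0.5) is
both unrealistic and adversarial to any collapsed-likelihood clustering,
which then prefers shattering clusters.

Nested specs add a second level by hierarchical drift: every
sub-cluster's frequencies are drawn from a Dirichlet centred on the
parent's frequencies with concentration `drift` (default 9), at all loci
— a genome-wide but per-locus weak signal, the signature of recently
diverged subpopulations. This default sits in the regime where
sub-structure is invisible to a flat clustering of the full data (the
Occam cost of splitting at the loci that are homogeneous within a macro
cluster outweighs the sub-signal) but resolvable once each cluster is
re-clustered with the invariant loci filtered out. The window is
intrinsically bounded: with these defaults, a depth-2 run on the
2×2×20-sequence, 200-locus condition recovers both levels exactly for
most seeds, while roughly one seed in six draws sub-divergence strong
enough that the top-level search already resolves three or four clusters.
That behaviour is a property of the model's detectability boundary, not
of the search.

What the generator does not emulate: linkage between loci, recombination,
genealogical correlation between sequences within a cluster, informative
missingness, and sequencing error. Passing tests therefore demonstrate
correct inference under the model's own assumptions, not robustness to
their violation on real data.

## Numerical and interface choices

- All likelihood arithmetic in natural-log space via `scipy.special.gammaln`;
  no raw Γ is ever evaluated.
- Incremental deltas are exact log-differences; the acceptance checks
  bound their drift from full recomputation at ≤ 1e−9 over 10,000 moves.
- Problem sizes in the test suite and acceptance script (instances of
  n ≤ 8 for exhaustive enumeration over all set partitions; 80 sequences ×
  200 loci for the planted-recovery run; 10,000-move chains at n = 30)
  keep every run comfortably within interactive time while exercising all
  code paths.
- The partition CSV mirrors the established `Isolate, level 1, level 2, …`
  table layout for drop-in downstream compatibility; the log-ML file
  echoes the run configuration except the worker count, which never
  affects results and must not affect output bytes.
- Known limitations: no admixture (each sequence belongs to exactly one
  cluster), no linked-loci model, no automatic depth selection (depth is
  user-specified), and no VCF/PLINK input in this version.
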