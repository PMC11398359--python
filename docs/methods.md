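# Methods

`seedtrace` reconstructs the migration history of a metastatic cancer: an
anatomical-site labeling of every node of a clone tree, from which each
edge whose endpoints differ is read as one seeding event. This note
documents the models, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## Observed clone proportions

For site *k* and mutation cluster *j* the read counts are modeled as
A_kj ~ Binom(A_kj + R_kj, ω_kj · F_kj) with F = U B, where B (clones ×
clusters) is implied by the clone tree (a clone carries every cluster on
its root path) and U (sites × clones) holds the clone proportions,
constrained to U ≥ 0 and row sums ≤ 1. ω converts cellular frequency to
expected VAF; its default, 0.5, is the diploid heterozygous autosomal case
and can be overridden per cell.

Two estimators are provided: the exact penalized binomial likelihood, and
the default inverse-variance weighted least squares approximation
min ‖W ⊙ (F − U B)‖² + λ‖U‖₁. Both use proximal projected gradient
descent; rows of U are independent, so each site is solved separately.
Numerical details that matter:

* W = 1/Var(F̂) with the binomial proportion stabilized by a half-count
  pseudocount; a zero-VAF cell at depth 500 gets a weight ~250× that of a
  mid-range cell, so each row's step size is set from its own curvature
  (1/λ_max of B W² Bᵀ) and the solver is an accelerated (FISTA-style)
  scheme with function-value restarts, up to 5·10⁴ iterations per row.
  A global step size does not converge on these ill-conditioned rows.
* On the feasible set the L1 penalty is linear, so the proximal step is an
  exact Euclidean projection onto the capped simplex {u ≥ 0, Σu ≤ 1}
  (sort-based).
* λ defaults to 0.1; recovery on synthetic cohorts is insensitive to λ
  over several orders of magnitude because the weighted quadratic term
  dominates.
* Zero-depth cells receive zero weight and are logged.

A clone is *present* in a site when its estimated proportion is strictly
above 5% (configurable); each presence call becomes a witness leaf with a
fixed site label. Leaf clones present nowhere are pruned iteratively.
The threshold is applied to U as estimated, without renormalizing rows.

## Parsimony metrics

For a fully labeled tree (witness edges included):

* m — migrations: edges with differing endpoint labels;
* c — comigrations: minimum number of groups of migration edges that could
  have traveled together. Same ordered-site-pair edges share a group
  unless one lies on the root path of the other (two ancestrally ordered
  migrations between the same sites cannot be one event); by Mirsky's
  theorem the minimum equals, per site pair, the longest ancestrally
  ordered chain, computed by a batched DP over the edge-ancestor relation.
  A `simple` rule (distinct ordered site pairs) is available, since the
  temporal-consistency rule is one of two reasonable formalizations.
* s — seeding sites: distinct source labels of migration edges.

Always s ≤ c ≤ m, and m = 0 ⟺ c = 0 ⟺ s = 0. The weighted score is
p = wm·m + wc·c + ws·s.

## The labeling search

The posterior over labelings is approximated by a factorized categorical
distribution with logits ψ (sites × clones); witness columns are fixed,
and by default the root is pinned to the declared primary site (every
history the method is meant to produce is primary-rooted, and the
organotropism prior scores primary-outgoing migrations; a flag relaxes
this). The ELBO — minus the weighted parsimony-plus-prior score of a
sample, plus the entropy of the unfixed columns — is ascended with the
straight-through Gumbel-softmax estimator: per column, Gumbel(0,1) noise
perturbs ψ, the hard sample is the argmax, the relaxed sample is a
tempered softmax of the same perturbed logits; the forward pass uses the
hard sample, the backward pass the relaxed one. All reported metrics come
from hard (integer) samples only.

Because the relaxed objective is a low-degree polynomial in the relaxed
labeling matrix and adjacency, its gradients are derived analytically
(softmax Jacobians chained through the matrix forms of each term) and
applied with Adam; no autodiff framework is required. Inside the relaxed
objective, c is surrogated by a soft count of distinct ordered site pairs
and s by a soft indicator of per-site out-migration mass (x/(x+h),
h = 0.5); exact integer values are always used for hard samples, so the
surrogate only steers exploration.

Defaults, and why:

* chains x = min(1024, 16·K·C) — many independently initialized chains
  capture distinct posterior modes; 1024 matches the sample size used for
  benchmark-scale problems.
* iterations 80 + 4·C per round, two rounds; temperature annealed
  exponentially 3.0 → 0.01; learning rate 0.15; ψ initialized i.i.d.
  uniform(0,1). These were validated against exhaustive enumeration
  (the oracle-equivalence property below).
* hard samples from the final quarter of iterations of every chain are
  pooled; the pool is deduplicated and only labelings whose (m, c, s) is
  not dominated within the pool are kept (dominated ones cannot reach the
  Pareto front).
* round 2 freezes *optimal subtrees* — maximal monochromatic subtrees
  (at least one edge) of each chain's round-1 sample, which are internally
  migration-free and hence unimprovable — and re-optimizes the rest.

When polytomy resolution is off, a unit-cost small-parsimony dynamic
program over the site alphabet (the Fitch–Hartigan optimum, implemented
Sankoff-style because the root may be constrained) injects one provably
minimum-migration labeling into the pool, so the front always contains a
minimum-m solution.

### Polytomy resolution

A node with more than two children receives ⌊children/2⌋ resolver nodes
(minimum 1) as zero-mutation children; every original child may stay or
reattach under a resolver, a categorical choice optimized jointly with the
labels through the same straight-through machinery. Afterwards childless
resolvers are deleted, and each remaining resolver is greedily removed
when its removal leaves the weighted parsimony score equal or better.
Resolution only adds refinement options, so the best achievable score
never worsens. The candidate pool is capped (2000) in this mode because
each candidate carries its own resolved topology.

### Deterministic post-processing

Stochastic search leaves two reproducibility gaps that are closed by
deterministic passes:

* *dominance polish* — from one representative per front metric tuple,
  all single free-node relabelings are scored in a batch and the best
  dominating move is applied greedily; this finds labelings one move away
  from the sampled front that dominate it.
* *top-solution refinement* — the reported top history is descended, by
  single-node and whole-block relabelings that keep (m, c, s) fixed, to
  the lexicographic minimum of (genetic-distance score, canonical
  labeling key). Block moves matter because an unobserved interior block
  can often sit in either of two sites at identical cost; scanning in a
  fixed order makes reruns with different seeds converge to the same
  representative. This is what makes the top-ranked history reproducible
  (the rerun-stability benchmark) without inflating sample sizes.

The per-patient driver searches under two weightings (the ranking model
and equal weights) and pools candidates, since a single weighting can
leave a corner of the front unexplored.

## Pareto front and metastasis priors

A candidate survives iff no other candidate is ≤ in all of (m, c, s) and
< in one; candidates with equal metrics but different labelings are
genuinely different hypotheses and all survive. Ranking sorts by p under
the chosen weights; exact ties are broken by the genetic-distance score,
then the organotropism score, then the canonical labeling key, so output
order is independent of input order.

Genetic distance: per clone-clone edge, (mutation count + 1) / (max
mutation count + 1) within the tree — bounded in (0, 1], scale-free
across patients; the score is Σ −log D over clone-clone migration edges
(witness and resolver edges carry no mutations and are excluded). Lower
is better: migrations preferentially sit on long edges. Natural log
throughout; the base only rescales fitted weights, not any ranking.

Organotropism: given per-site seeding frequencies o for the patient's
cancer type, the score is Σ_i −log(o_i) · (number of primary→i migration
edges); only primary-outgoing migrations are scored because frequency
data describe seeding from the primary. Occurrence tables are
row-normalized with a floor of 1e-4 of the row mass so −log stays finite.
Site names are mapped by an explicit user dictionary; no fuzzy matching.

## Calibration

Cohort weights (wm, wc, ws) are fitted by minimizing, over patients with
multi-solution fronts, the cross-entropy from the metastasis-prior softmin
distribution to the parsimony softmin distribution on each front,
starting from equal weights (projected gradient descent with backtracking,
so the loss is non-increasing). Two functional choices:

* the prior score is the within-front z-score of the genetic-distance
  score plus, when site labels permit, that of the organotropism score —
  z-scoring only mixes the two heterogeneous scales;
* the parsimony distribution uses the *raw* weighted scores with the
  weights normalized onto the simplex. Z-scoring them instead maps every
  two-solution front to the pair (+1, −1) regardless of the weights,
  making the loss piecewise constant — and two-solution fronts are the
  most common case. Normalizing the weights inside the loss plays the
  role of a temperature constraint.

Fitted weights are reported normalized to sum 1. Stability is assessed by
refitting on bootstrap resamples of the informative patients (default
B = 100) and recording how often each patient's top-ranked solution is
unchanged.

The shipped default ("pan-cancer") weights (0.55, 0.27, 0.18) are the
repository's own calibration on packaged synthetic cohorts — they are not
values derived from any published patient cohort.

## Classification

Per migration edge the *colonizing clone* is the target node, except that
a witness or resolver target (which carries no mutations of its own)
stands in for its parent. Seeding pattern: reseeding if any migration
targets the primary; else multi-source if ≥ 2 seeding sites; else
single-source primary/other. Genetic clonality is monoclonal iff one
colonizing clone seeds everything; site clonality iff every seeded site
receives exactly one. Phyleticity is monophyletic iff all colonizing
clones descend from a colonizing clone closest to the root (ties: mono if
any closest candidate works; "tree rooted at s" is read as s plus its
descendants); the alternative path-based definition asks for a simple
tree path visiting every colonizing clone, decided via the set-diameter
endpoints. If the root clone itself is observed in a metastatic site, the
witness exception makes the root a colonizing clone and the history is
monophyletic by construction.

## Synthetic cohorts

The generator draws a random rooted clone tree and a labeling jointly, so
a requested seeding pattern (primary-only, metastasis-to-metastasis,
reseeding) is satisfiable by construction; defaults mirror benchmark
scale: 80 patients, 5–11 sites, clones = sites + 1..5, depth-500 reads,
ω = 0.5, polyclonal rate 0.2. Migration edges draw mutation counts from
Poisson(15)+1 versus Poisson(5)+1 elsewhere, so the genetic-distance
prior is informative, mirroring the empirical excess of mutations on
migration edges. Within a site, present clones mix as
0.95 · (0.35·Dirichlet(1.5) + 0.65·uniform), which floors every present
clone safely above the 5% presence threshold (at most 6 clones per site).

Two deliberate idealizations, and their consequences:

* each clone occupies exactly the site of its label — real tumors carry
  ancestral clones alongside descendants, which makes deconvolution
  harder than in these fixtures;
* met-sourced migrations are drawn only from "deep" metastatic clones
  (parent in the same site). A shallow met-sourced migration can always
  be relabeled as primary-sourced at equal or better parsimony, so truths
  built on them would be strictly dominated and unrecoverable *in
  principle*; depth-2 chains protect metastasis-to-metastasis truths.
  Reseeding truths would need depth-3 chains for the same protection and
  are left at depth 2: a reseeding ground truth is therefore often
  legitimately dominated by a primary-only reinterpretation — exactly the
  ambiguity this class of methods exists to surface — so recovery-style
  claims are made only for the primary-only and met-to-met regimes.

Passing these benchmarks shows the optimizer and estimators recover
truths generated by the package's own forward model; it does not speak to
copy-number-driven VAF distortion, multi-region sample merging, or
clustering/tree-inference errors upstream of the labeling problem.

## Benchmark sizes and configurations

The packaged acceptance analyses use: 100 exhaustive-enumeration
instances (K ≤ 3, C ≤ 8); 20-patient depth-500 cohorts for proportion
recovery and end-to-end migration-graph F1 (per-run search capped at 512
chains); 12-patient cohorts per regime for calibration recovery; and an
80-patient mixed cohort with 5 reruns for top-solution stability (both
search weightings at 128 chains each — a *smaller* sample size makes rerun
stability strictly harder, so the configuration is conservative). Classification
logic is checked exhaustively on 120 random trees with ≤ 10 colonizing
clones.

## Known limitations

* No subclonal copy-number correction of VAFs; externally computed
  cell-fraction inputs or a presence matrix sidestep this.
* The comigration rule's exact published form is not fixed; both the
  temporal-consistency and the simple variant are implemented.
* Calibration's softmin temperature (via weight normalization) is a
  modeling choice; only rank orders, not the absolute weight values,
  should be interpreted.
* Stochastic search carries no optimality certificate beyond the
  minimum-m guarantee; on hard instances more restarts and a larger
  sample size are the remedy, and an unchanged Pareto front across
  restarts is the practical convergence criterion.
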