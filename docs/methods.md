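# Methods

This note records the models implemented in `synterec`, the conventions
and tunable parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical and design choices made
where the literature leaves the details open. Every number quoted here
is computed by the test suite or by `scripts/acceptance.py`.

## Dated DTL parsimony

**Model.** The species tree is a rooted binary chronogram; leaves sit at
age 0 and every internal node carries an age (time before present,
arbitrary units — the generator normalizes root age to 1). The tree is
cut into *time slices*, the intervals between consecutive distinct
internal-node ages; within a slice the set of contemporaneous species
edges is constant. A reconciliation assigns each gene-tree node one
event:

- **speciation** (cost 0) at the species node closing an edge — the two
  gene children continue into the two descendant edges;
- **duplication** (cost Δ) on an edge within a slice — both children
  continue on that edge;
- **transfer** (cost θ) — one child stays on the donor edge, the other
  regrafts onto a *different edge alive in the same slice*. The slice
  restriction is what makes the model "dated": regrafts between
  non-contemporaneous lineages are impossible by construction, and a
  transfer surviving high θ therefore reflects genuine topological and
  temporal signal;
- gene leaves must descend to their own species' terminal edge.

A **loss** (cost L each) accrues whenever a lineage crosses a speciation
boundary and continues on one side only. Event chains within one slice
are always time-consistent because gene-tree descendants can be ordered
after their ancestors inside the slice.

**Stem.** A zero-cost stem cell above the species root hosts events
ancestral to the first speciation. Without it, duplications predating
the root (which the classical LCA duplication–loss mapping produces
whenever the gene-tree root maps to the species root) would be
unrepresentable and the transfer-free limit of the model would disagree
with the closed form. The gene root itself may start at any
(edge, slice) cell or the stem with no penalty and no losses charged
above its event.

**Exact counting and uniform sampling.** The dynamic program fills, per
gene node and cell, the pair (minimum cost, number of optimal
sub-scenarios) with arbitrary-precision integers; two scenarios are
distinct iff they differ in any node's (event, location, recipient)
assignment — loss placements are then determined, so no double counting
occurs (verified by an enumeration oracle that asserts scenario
uniqueness). Sampling backtracks through the DP choosing options with
probability proportional to their exact counts, using integer
arithmetic throughout, so each optimum has probability exactly
1/N. The test suite confirms agreement of cost and count with full
scenario enumeration on 200 random instances and chi-square uniformity
of 10,000 samples over an enumerated optimum set.

**Transfer calls.** Event support is tabulated per gene node over a
grid with Δ fixed at 4, θ swept (full scale 5…40; the pipeline default
is {5,10,15,20} at desktop scale) and L ∈ {1,2,3}, with PRNG
sub-streams keyed by (tree, Δ, θ, L) so enlarging the grid never
perturbs existing cells. A node is called a transfer when its transfer
fraction exceeds 1/2 in some cell; the *top cost* is the largest θ
with majority support at the reporting L (default 1). "Consistent"
is operationalized as majority support at ≥ 2 consecutive θ values for
every L in the grid, and, when several gene-tree topologies are
supplied, on every topology containing the node's bipartition
(topologies are reconciled independently; amalgamated-likelihood
machinery is out of scope). Majority is strict (> 0.5); the threshold,
reporting L and run length are configurable.

**Branch summaries.** Per species branch the reports give
duplications / losses / resident genes; per family the sampled optima
are condensed by the modal per-sample tally per branch (ties toward the
smaller count), and gene counts are lineages entering the branch at its
top (speciation children and surviving sides of loss crossings;
transfer regrafts enter mid-slice and are not counted as crossings).

**Limitations.** Single-lineage regrafts (a transfer whose donor copy
dies immediately, leaving no branching in the gene tree) are not part of
the event alphabet, so costs can exceed those of tools that model
transfer-loss composites; trees must be rooted and strictly binary; the
DP is exact but O(nodes × edges² × slices) in the worst case, sized for
tens of taxa rather than hundreds.

## Homolog clustering

Graph edges require hits in both directions, each with E < 1e-10
(strict) and coverage of the longer sequence > 0.5 (strict); the weight
is the mean over directions of −log10(E), capped at 200 to keep E = 0
finite. MCL uses self-loops set to each node's maximum incident weight
(a standard regularization; isolated nodes get 1), column-stochastic
normalization, expansion by squaring and inflation 1.4 by default,
iterated until the maximum elementwise change falls below 1e-8;
clusters are the connected components of the converged matrix's support
and the whole procedure is deterministic. Clusters with ≥ 10 members
become CHGs (`ch1…`, ordered by size then smallest member). Average
silhouette width over the graph metric d = 1 − w/w_max (non-edges at
distance 1, singletons contributing 0) is reported across an inflation
sweep {1.2, 1.4, 1.6, 2.0} as a granularity diagnostic; no particular
peak is asserted on arbitrary data.

## Clade × context association scan

Neighborhoods are the ≤ w genes on each side of a focal gene on its
scaffold (w = 20 by default, strand ignored, truncated at ends), and a
CHG is "present" when ≥ 1 member falls in the window. Every subtree
with ≥ 5 leaves — excluding the root, whose complement is empty and
admits no contrast — is tested against every CHG with a two-sided
Fisher exact test computed by hypergeometric enumeration (the two-sided
choice lets the scan flag depletion as well as enrichment; direction is
carried by the odds ratio, Haldane-corrected when a cell is zero).
Bonferroni correction multiplies by the total number of
subtree × CHG tests — the stricter of the two readings of "total number
of tests", and configurable. A result is a *local minimum* when its
corrected P beats the same CHG's parent subtree (ties resolved toward
the smaller subtree) and strictly beats every eligible child subtree;
the reported set is built greedily by ascending corrected P among local
minima at corrected P ≤ 1e-4, skipping subtrees that share a leaf with
an already-reported subtree for that CHG.

## Neighborhood retention by event

For each internal node, retention is the mean over cross pairs (one
leaf from each child subtree) of |shared CHGs| / denominator, with the
smaller set size as the default denominator (modes: `min`, `mean`,
`jaccard`; recorded in output). Node depth is the topological edge
count from the root, with branch-length depth available. Event labels
come from the reconciliation's modal calls when run inside the
pipeline. Classes are contrasted with the two-sample Wilcoxon rank-sum
test (speciation vs duplication, transfer vs duplication) and retention
is correlated with depth by Pearson's ρ; degenerate inputs (constant
values, classes below 2 records) are reported as notices rather than
numbers.

## Exon junctions

An intron at cumulative CDS offset n lands on residue ⌊n/3⌋ with phase
n mod 3; phase-0 junctions belong to the first residue of the
downstream exon (a deterministic convention the data do not fix).
Minus-strand models are processed in transcription orientation, and a
model and its mirrored-strand counterpart yield identical junction
lists. Junctions are lifted through the gene's alignment row to
columns, and to *consensus* columns — occupancy ≥ 0.7, the same trimal
`-gt 0.7` rule used for alignment curation (gap characters `-` and `.`;
`X` counts as occupied) — with junctions in sub-threshold columns
reported as non-consensus. Binary per-gene features ("junction within
± tolerance of consensus position c", default tolerance 0) feed the
same clade scan as CHG presence. Highly divergent regions (in the
motivating family, the C-terminal domains) should be excluded upstream
by supplying per-domain sub-alignments.

## Synthetic data: what it emulates, and what it does not

The generator is the package's study-conditions bench: every emitted
file re-parses through the package readers, every stream is seeded, and
sub-streams are keyed per purpose and replicate so adding families
never perturbs earlier ones.

- **Chronogram** — forward birth–death simulation (defaults: birth 1.0,
  death 0.2 per lineage per unit time) conditioned on the extant taxon
  count, pruned of extinct lineages, root age normalized to 1. The
  pure-birth special case is checked against an independent
  interval-sequence simulation (two-sample KS).
- **Gene families** — lineages evolve down the chronogram with
  duplication 0.20, transfer 0.055 and loss 0.30 per lineage per unit
  time; these defaults yield on the order of 2 duplications, 0.5
  transfers and 3 losses per family on a 30-taxon tree, a regime where
  histories are informative but not saturated. Transfer recipients are
  uniform among coexisting branches, matching the reconciler's model
  class (a distance-biased mode would be a one-line change but is off
  by default). Truth records every event plus the *visible* labels of
  surviving internal nodes, which is what a reconciler can recover.
- **Neighborhoods** — each gene carries 2w CHGs from a pool of 400
  (window 20); along the gene tree the *derived* copy (new duplicate or
  regrafted copy; a random side at speciations) retains each parental
  CHG with the event-specific probability — defaults 0.40 speciation /
  0.11 duplication / 0.21 transfer — and refills with novel pool
  members, while the other child keeps the parental context. The
  one-sided scheme makes the expected shared fraction across a single
  event equal the planted probability; refills never re-draw dropped
  CHGs, so residual background sharing is only pool collision
  (≈ m/(P−m) ≈ 0.11 at defaults), which the tests account for.
- **Retention identifiability.** The retention statistic at a node
  convolves retention over *every* branch between the two leaves of a
  pair, so event-specific probabilities are identifiable only across
  single events; the retention-study generator therefore emits
  two-member families (one labeled event per family) for the recovery
  check, and a separate caterpillar mode with planted monotone decay
  for the depth-correlation check. Passing these tests shows the
  statistic is unbiased and the contrasts detectable under the planted
  model — not that real genomes decay context one event at a time.
- **Gene structures** — a fully occupied alignment core (120 positions)
  interleaved with low-occupancy insert columns; ancestral junctions
  evolve by per-branch loss (0.05) and per-position gain (0.01), with
  optional clade-private gains; emitted exon models invert exactly
  through the junction arithmetic.
- **Hit tables** — within-family reciprocal hits with E ~ log-uniform
  [1e-180, 1e-30] and coverage ~ U(0.6, 1), between-family noise at
  E ≥ 1e-8, plus a dropout knob for the bidirectional filter.

What the generator does **not** emulate: sequence evolution (hits are
drawn, not aligned), rate heterogeneity across lineages, gene
conversion, incomplete lineage sorting, assembly artifacts, and the
orthology-versus-CHG distinction (context counterparts are matched by
CHG membership, which errs generous). Recovery results on synthetic
data bound what the methods can do when their assumptions hold; they do
not certify performance on real genomes.

## Numerical choices

Costs are compared with tolerance 1e-9 (grids are integer-valued, so
ties are exact); optimum counts and sampling weights are Python
integers (counts beyond 10^100 are routine on larger instances);
E-values are floored at 1e-200 before log-transform; MCL converges at
max elementwise change < 1e-8 with entries below 1e-10 pruned and
support read at > 1e-7; Fisher P-values sum hypergeometric pmf terms
≤ p_obs·(1+1e-7) to absorb floating-point ties; ultrametricity is
checked at relative tolerance 1e-6 and equal node ages merge slice
boundaries at 1e-9. Duplicate ages, zero-length terminal slices and
single-gene families are handled explicitly; empty alignments,
all-zero contingency tables, single-cluster silhouettes and unmapped
leaves raise informative errors.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen
so the full suite completes in minutes on one CPU: oracle comparisons
on instances with ≤ 6 gene leaves and ≤ 5 species; event recovery on 50
families over 30 taxa (30 in the script) with 100 sampled optima per
family; the transfer false-positive screen on a 10-taxon tree with the
reduced θ grid; scan power and null calibration on 64- and 32-leaf
trees with 100–200 replicates (50–100 in the script); clustering on six
10-member families. Full-scale settings (θ ∈ {5,…,40}, 1,000 samples
per combination) are the library defaults for `event_support` and are
exercised on small instances in the tests.
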