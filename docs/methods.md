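# Methods

## Explanation semantics

The unit of evaluation is a (network, profile, assignment) triple: a signed
TF→target edge set, per-gene log2 fold changes, and a map TF → {A+, A−, A0}
(TFs absent from the map are A0). A gene is scored iff it has at least one
regulator in the network **and** a measured fold change; network targets
without a measurement are dropped with a logged warning and reported as
`unscored_genes` (counting them as unexplained would penalize assignments
for data that was never observed).

Regulatory effects follow the sign × state table (see the `scoring` module
docstring). Unsigned edges are resolved optimistically *per gene*: each
differential gene may independently assume the sign that explains it. This
keeps the explanation check local and linear-time and reflects the fact
that an unannotated sign is unknown, not absent. An unchanged gene is
explained only by an A0 regulator; the theoretically possible cancellation
of two opposing active regulators is deliberately ignored (it requires
exact compensation, which we treat as rare), so reported UTG counts are
lower bounds in that respect.

Duplicate edges with conflicting signs merge to unsigned — the
information-preserving choice given the optimistic resolution. Gene
identifiers are whitespace-trimmed and compared case-sensitively; no
aliasing is attempted. Self-loops are scored like any edge.

## Score and parameters

i-score = Σ over UTGs of |min(|fc|, m_fc) − c|, with

- **c** (default 1.0, log2 units): differential cutoff; genes with |fc| > c
  are called UP/DOWN (strict inequality — boundary genes have weight 0, so
  the convention cannot change any score).
- **m_fc** (default 3.0, log2 units): trim ceiling so extreme genes cannot
  dominate; requires 0 < c < m_fc.
- **alpha** (optional): when a p-value column is present, differential
  calls additionally require p < alpha (conjunctive rule); weights are
  unchanged. Default is fold-change-only calling, since reliable p-values
  need replication that many datasets lack.

Weights are computed in double precision; score equalities in tests use an
absolute tolerance of 1e−9.

## Act-SAT

The encoding uses 3 variables and 4 hard exactly-one clauses per TF and one
soft clause per scored gene (weight = UTG weight; zero-weight clauses are
dropped — they cannot move the optimum). Variable numbering is fixed (TFs
sorted lexicographically, A+/A−/A0 = 3i+1..3i+3) so exported WCNF files are
reproducible.

The internal solver is a depth-first branch-and-bound over TF states rather
than a clause-level SAT procedure: branching directly on the three states
makes the hard constraints implicit, and the lower bound (total weight of
clauses all of whose literals are already falsified) is exact and O(1) to
maintain per assignment step. TFs are branched in order of decreasing
touched soft weight. Among co-optima the solver returns the assignment with
the fewest active TFs, then the lexicographically smallest state tuple
(A0 < A+ < A−) — a deterministic canonical representative; the full
co-optimal set is available from Act-A*.

WCNF export multiplies real weights by an integer `scale` (default 10^6)
and rounds; a clause whose weight rounds to 0 is dropped with a warning
(exporting it would misdeclare it hard in solvers that treat weight-top
specially). Hard clauses get weight Σ(scaled soft) + 1. A sidecar JSON maps
variables back to (TF, state) and records the scale, so any external
solver's model can be decoded without this package.

## Act-A*

A partial solution fixes ≤ N TFs to active states; unset TFs are A0, so
every node is also a complete, scoreable assignment. The heuristic h
subtracts from g the N − x largest per-TF improvements, where each unset TF
contributes max(improvement at A+, improvement at A−), floored at 0. Using
the per-TF max (rather than entering both states into the sorted list)
gives a tighter yet still admissible bound: single-TF improvements computed
on the current partial always upper-bound their marginal contribution in
any joint completion, because a gene explained once needs no second
explainer. Setting a TF active can *increase* g (an unchanged gene losing
its last A0 regulator); the floor keeps h admissible while the true,
possibly negative, delta is used when a node is actually extended.

The frontier is a priority queue ordered by (h, number of active TFs,
lexicographic assignment) — a fixed tie-break that makes solution order
deterministic. Assignments are deduplicated as unordered state maps
(visited set); the addition order of the first creation is kept for the
variability report. Pruning: in BEST_ONE mode a node with h ≥ best known
complete score is discarded; in ALL_OPTIMAL mode only h > best, so every
co-optimal assignment is expanded. Because the queue is h-ordered, the
search terminates the first time the frontier minimum crosses the bound.

The solution pool contains every *completed* solution scored during the
run (pruned partials are not separately counted — every generated partial
is itself a completed assignment, so the distinction collapses to: nodes
popped from the queue). The pool report retains the best `fraction`
(default 10%), computes per-position relative improvements
(g_before − g_after)/g_empty along each solution's addition path, tabulates
each TF's first position, and can emit a DOT sketch in which repeat
occurrences collapse into meta nodes.

`constrained_search` seeds the root with prior knowledge: TFs fixed to
A+/A− are active in every solution; TFs fixed to A0 are barred from
activation.

## Randomization nulls

`zscore_evaluation` compares the real Act-A* optimum (same N throughout)
with n_shuffles (default 100) randomizations: gene-label permutation of the
profile, uniform edge resampling (same TFs, targets and edge count; random
edges are unsigned, the maximally permissive choice, making the null
conservative), or degree-preserving double-edge swaps (signs travel with
the TF endpoint, conserving each TF's sign composition; `n_swaps` counts
accepted swaps, default 10× the edge count, with an attempt cap for
networks with no legal swap). Per-shuffle seeds derive from the master seed
via a fixed counter scheme (`SeedSequence([master, i])`), so runs are
reproducible. z = (real − mean(null)) / sd(null) with the sample sd; a
zero-spread null is reported as undefined (NaN) rather than ±∞. No
multiplicity correction is applied across conditions — distributions are
reported raw.

## Synthetic fixtures

The generator plants a set of active TFs and derives each gene's status
from its regulators under the same exists-an-explaining-TF semantics the
scoring uses: differential iff some planted regulator pushes it, direction
by majority of signed pushes (ties → UP, an arbitrary documented
convention; unsigned pushes make a gene differential but vote for neither
side). Fold changes are the effect size ± Gaussian noise (defaults: effect
2.5, noise sd 0.3, well separated from c = 1); a `background_flip_rate`
fraction of genes (default 5%) has its status flipped to a different one,
modelling regulation the network cannot express. Default sizes are 12 TFs,
120 genes, 3 regulators per gene, sign mix 50/25/25 act/inh/unknown, 2
planted TFs.

Because the generative rule mirrors the explanation semantics, the planted
assignment has i-score exactly 0 in the noiseless, flip-free limit and is
recoverable by the optimizers — the correct positive control for this
scoring framework. It is **not** an expression-dynamics model: it has no
additive effects, no cooperativity, no time, and its noise is independent
per gene. Passing recovery tests therefore demonstrates correctness of the
scoring and optimization machinery, not performance on real compendia,
where incomplete and condition-specific networks dominate the error budget.

## Problem sizes in tests and the acceptance script

Exhaustive oracles bound the sizes: instances up to 8 TFs (3^8 = 6561
assignments) and 60 genes for optimizer equivalence, up to 6 TFs for
heuristic admissibility audits (brute-force best completions at every
expanded node), 100+ instances per property. Randomization ensembles use
6-TF/40-gene planted fixtures with 15 shuffles × 20 replicates. These
sizes make the full suite run in well under a minute while keeping every
check exact rather than sampled.

## Known limitations

- The i-score assumes the network is true and complete; missing edges
  inflate it and spurious edges deflate it (extra edges can only lower the
  optimum — a property the tests verify).
- Complementary cancelling configurations for unchanged genes are not
  modelled (see above).
- Act-SAT's branch-and-bound targets desk-scale instances (hundreds of
  TFs with sparse structure); for very large dense networks, export the
  WCNF and use a dedicated external max-SAT solver.
- The degree-preserving shuffle is a Markov chain; `n_swaps` controls
  mixing and is the user's responsibility (default 10×|E|).
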