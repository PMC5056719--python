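# iscore

Inconsistency scoring of transcription-factor activity predictions against
a gene regulatory network.

## The problem

Many methods infer which transcription factors (TFs) changed their activity
between two conditions from a regulatory network and expression data. There
is no gold standard to validate such predictions. `iscore` evaluates them by
asking a minimal question: **for how many target genes can the predicted TF
activity changes not explain the observed expression change at all?**

Each TF carries one of three differential activity states: more active
(A+), less active (A−) or unchanged (A0). Through a signed regulatory edge
(activating, inhibiting, or unsigned) a TF state implies a regulatory
effect on its target: for example an activating edge from an A+ TF pushes
the target up; an inhibiting edge from an A+ TF pushes it down; an unsigned
edge from an active TF may push either way; an A0 TF has no effect. A
differential target gene is *explained* if at least one regulator pushes it
in the observed direction (the activation function combining several
regulators is unknown, so one matching regulator suffices); an unchanged
gene is explained if at least one regulator is itself unchanged. Genes
failing these tests are **unexplained target genes (UTGs)**.

The **i-score** of an activity assignment weighs each UTG by how far its
fold change sits from the differential cutoff *c* (default 1), trimmed at
*m*<sub>fc</sub> (default 3):

```
i-score = Σ_{t ∈ UTG} | min(|fc_t|, m_fc) − c |
```

Lower is better; 0 means every scored gene is explainable.

## Exact optimizers

Besides scoring a given prediction, the package computes the theoretical
minimum of the i-score for a network and dataset:

- **Act-SAT** — the unrestricted optimum. Each TF gets three boolean
  variables (A+, A−, A0) with four hard exactly-one clauses; each scored
  gene one soft clause weighted by its UTG weight. The weighted max-SAT
  instance is solved exactly by an internal branch-and-bound over TF
  states, and can be exported as a standard DIMACS-style WCNF file for any
  external weighted max-SAT solver.
- **Act-A\*** — the optimum with at most *N* active TFs (default 10),
  found by best-first search with an admissible heuristic: from a partial
  solution's score, subtract the *N − x* largest single-TF score
  improvements. With `--all-optimal` every co-optimal assignment is
  enumerated, and the pool of scored solutions supports a variability
  report (per-position score improvements, first occurrence of each TF).

Network assessment compares the real optimal i-score against randomized
nulls (gene-label shuffles, uniformly random edge sets, degree-preserving
rewiring) as a z-score; negative z means the real data is explained better
than random.

## Worked example

The repository's built-in example has 3 TFs and 6 genes (see
`iscore.fixtures.worked_example`). T1 activates G1, G2 and G6; T2 inhibits
G2 and activates G3; T3 regulates G4 (unsigned), G5 (inhibiting) and G6
(activating). Fold changes: G1 = 2.5, G2 = −1.5, G3 = 0, G4 = 1.8,
G5 = −4, G6 = 0.5.

```sh
python -c "from iscore import *; net, prof = worked_example(); \
write_network(net, 'net.tsv'); write_profile(prof, 'prof.tsv')"
iscore optimize-sat --network net.tsv --profile prof.tsv
```

On the worked example the optimizer prints:

```
iscore  1
n_utg   2
active  T1  +
active  T3  +
```

meaning: with T1 and T3 more active and T2 unchanged, only G2 (weight 0.5)
and G6 (weight 0.5) remain unexplained — T1=A+ explains the up-regulated
G1, T3=A+ explains G4 via its unsigned edge and the repressed G5 via the
inhibiting edge, and G3 stays explained because T2 is unchanged. All 27
possible assignments confirm this is the unique optimum (i-score 1.0).

Scoring a prediction file and the randomization assessment work the same
way:

```sh
iscore score --network net.tsv --profile prof.tsv --activities pred.tsv --top-k 10
iscore optimize-astar --network net.tsv --profile prof.tsv -N 10 --all-optimal
iscore evaluate-random --network net.tsv --profile prof.tsv --null labels --n 100
```

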