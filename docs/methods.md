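# Methods

## The placement problem

Given a rooted, edge-weighted reference tree *T* whose leaves are labelled
with reference nucleotide sequences, and a set of query reads, phylogenetic
placement attaches each read to an edge of *T* rather than re-inferring the
tree. `spamplace` does this alignment-free: no reference MSA is needed and
reads are never aligned.

## Spaced-word matching

A binary pattern *P* of length ℓ marks *match* positions ('1', forced
identity) and *don't-care* positions ('0', mismatches allowed); the number
of match positions is the *weight* w. A spaced-word occurrence is a window
of ℓ consecutive bases read through *P*; two windows in different sequences
that agree at all match positions form a *spaced-word match* (SpaM) — a
gap-free local alignment of length ℓ.

For each pattern, all occurrences of the references and of a batch of
queries go into two lists sorted lexicographically by the match-position
nucleotides only; equal-key blocks of the two lists are crossed so that one
query occurrence may pair with many reference occurrences and vice versa.
Each candidate SpaM is scored by summing HOXD70 substitution scores over its
don't-care columns; SpaMs scoring ≤ t (default t = 0) are discarded as
background. For each (query Q, reference S) the surviving count s(Q,S), the
total number of don't-care columns and the number of mismatching ones are
accumulated; the pooled mismatch proportion p feeds the Jukes–Cantor
estimator

    d(Q,S) = -(3/4) ln(1 - (4/3) p).

The default pattern has weight 12 and 32 don't-care positions (length 44).
Its arrangement is a fixed, committed literal; placement accuracy is known
to be insensitive to the arrangement, so no pattern optimisation is
performed — additional patterns are drawn by seeded uniform sampling of
interior match positions, with match positions forced at both ends
(canonical form). Statistics are pooled (not averaged) across patterns.

Implementation notes: keys are packed two bits per base into int64 (numeric
order = lexicographic order), so weight is capped at 31; equal-key block
crossing is fully vectorised with the expanded candidate set chunked at
5·10⁶ pairs to bound memory. Windows containing non-ACGT characters yield
no occurrence (skipped, counted); sorting ties inside a key block are broken
by (strand, sequence, position) so runs are reproducible.

### Strand handling

References are enumerated on the forward strand only; queries on both
strands. Per (Q, S) pair the statistics are kept separately per strand and
the stronger strand is retained, maximising the tuple
(s, dc_columns, −dc_mismatches) with ties going to forward. This key is
symmetric under reverse-complementing the query, which makes the per-pair
statistics exactly invariant to query orientation; pooling both strands
instead would contaminate p with background matches from the wrong
orientation.

### Degenerate cases

* p ≥ 3/4 (outside the estimator's domain): the sentinel distance 5.0 is
  reported; such pairs still participate in ranking but never win in
  realistic data.
* s(Q,S) = 0: p and d are undefined; the pair is excluded from ranking.
* Patterns without don't-care positions score every SpaM 0, which the
  strict score > t filter removes at the default t = 0 — a deliberate
  consequence of keeping the threshold semantics strict on both sides.

## Placement heuristics

All heuristics first rank references with s > 0 (ties broken by a seeded
uniform draw keyed on (seed, query id), so results are independent of query
processing order):

* **min-dist** — pendant edge of the leaf minimising d(Q,S).
* **spam-count** — pendant edge of the leaf maximising s(Q,S).
* **lca-dist / lca-count** — parent edge of the lowest common ancestor of
  the two best references (by distance or count). If the LCA is the root,
  which has no parent edge, the root's child edge on the path toward the
  best reference is used. With exactly one usable reference these degrade
  to the corresponding leaf heuristic.
* **spam-x** (default, X = 4) — with top counts s1 ≥ s2: if
  |s1 − s2| > (s1 + s2)/X the query goes above the best leaf (spam-count
  branch), otherwise to the LCA edge (lca-count branch). X = 1 can never
  route to a leaf because |s1 − s2| ≤ s1 + s2.

Queries with no filtered SpaM at all are recorded at the root: first child
edge of the root, pendant 0, flagged `fallback_root`.

### Branch lengths

The attachment edge e is split at its midpoint, preserving
l(e1) + l(e2) = l(e) exactly. The pendant edge gets length
max(0, d(Q,S1) − path(attachment point → leaf S1)) where S1 is the
best-ranked reference; if no finite distance exists the pendant is 0. This
midpoint-plus-clamped-residual rule is this package's own design: it is the
simplest assignment satisfying length conservation and giving a pendant
that shrinks to zero for reads sampled from a reference itself.

## Synthetic data

`evalsim.simulate_sequences` evolves a uniform-random root sequence of
length L down the tree under Jukes–Cantor: on a branch of length b
(expected substitutions per site) each site independently mutates with
probability p(b) = (3/4)(1 − e^{−4b/3}) to a uniformly chosen different
base. Reads are made either by `fragment_reads` (consecutive
non-overlapping segments of fixed length; a shorter final remainder is
kept only if it can still contain a pattern window) or `sample_read_bag`
(⌈coverage·L/read_len⌉ reads at uniform positions on both strands —
the bag-of-reads reference mode, where record statistics are pooled to the
leaf level before placement).

What the simulator does *not* emulate: insertions/deletions, sequencing
error, rate heterogeneity across sites, base-composition bias and
low-complexity repeats. Passing tests therefore demonstrate correctness of
the matching/placement machinery and the estimator under its own model, not
robustness to real-data artefacts such as indels (which bias d upward) or
repeats (which inflate s).

## Pruning-based accuracy (PAC)

One leaf is pruned at a time (single-leaf prunings only, at this scale);
its former parent becomes degree-2 and is suppressed, merging the two
incident edges into the *true attachment edge*. The pruned taxon's sequence
is fragmented into reads, the reads are placed on the pruned tree, and each
placement is scored by the *node distance*: the number of nodes on the path
between the chosen edge and the true edge (0 = same edge, 1 = adjacent
edges — this endpoint convention is fixed here and used consistently). The
mean over reads summarises one pruning; the grand mean over prunings
summarises a run. When the pruned leaf hung off the root or a
multifurcation there is no single merged edge; the harness then accepts any
of the edges formerly adjacent to the attachment node as distance 0.
Control baselines place every read on the root's first child edge or on the
edge containing the tree midpoint (half of the longest leaf-to-leaf path;
ties resolve to the lowest edge number).

## Problem sizes and defaults

The self-contained evaluation runs on a balanced 8-leaf tree with all
branches at 0.05 substitutions/site, 10 kb leaf sequences and 150-nt reads
— small enough to verify in seconds yet deep enough that the five
heuristics differ. Distance-recovery checks use 100 kb pairs at true
distances 0.05–0.3, where the binomial standard error of p̂ is far below
the ±0.01 acceptance band. Defaults throughout: one pattern of weight 12
with 32 don't-care positions, t = 0, X = 4, seed 42, batch size 2000.
Batching and threading (thread pool over query batches, merged in batch
order) never change the output.

## Output

jplace version 3 with fields
`[edge_num, likelihood, like_weight_ratio, distal_length, pendant_length]`;
the tool reports a single placement per query, so likelihood is written as
0 and the weight ratio as 1. Edge numbers are assigned in preorder over the
parsed tree (children in input order) and appear as `{n}` after each branch
length in the tree string. A TSV summary (query, edge, best distance, best
count, heuristic, fallback flag) is written alongside.

## Known limitations

* Gap-free matching: indels create partially homologous SpaMs that inflate
  distance estimates.
* Single placement per query; no placement uncertainty is expressed.
* The branch-length rule is heuristic; reference branch lengths are never
  re-estimated.
* Low-complexity sequence should be masked upstream; the engine guards its
  memory via chunking but repeats still cost time and bias s.
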