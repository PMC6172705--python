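# Methods

## Problem setting

Complex-disease risk is spread over many loci of small effect, with rarer
variants of larger effect hitting partially overlapping genes. The working
hypothesis behind this package is *network convergence*: if a disease is
driven by a functional module, then genes carrying nominally significant
common-variant association, genes hit by de novo mutations (DNMs) and genes
disrupted by CNVs should interact with each other more than chance allows.
All analyses run on an undirected protein–protein interaction (PPI) graph.

Inputs are deliberately generic: a two-column interaction table with
publication identifiers, a gene-level p-value table (as produced by
gene-based association tests such as VEGAS — computing those p-values is out
of scope here), a genes × samples expression matrix, plain gene lists, and
GMT gene-set files.

## High-confidence network

Interaction records are merged per unordered gene pair, unioning their
publication identifiers; an edge survives only if supported by at least
`min_support` (default 2) *distinct* publications. Counting distinct PMIDs
rather than records means two database rows citing the same study count
once — "independent literature support" is about independent publications.
Self-loops are removed and the node set is exactly the union of surviving
edge endpoints. The filter is monotone in `min_support` and idempotent under
re-import of its own edge dump; both properties are tested.

## Gene scores

Gene-level p-values live in (0, 1]; a reported p of exactly 0 is clamped to
1e-6 (the resolution of a 10^6-replicate Monte-Carlo gene test) with a
warning, and duplicate gene rows keep the smallest p. Genes overlapping the
MHC region (chr6:25–34 Mb, closed intervals, any overlap) are excluded by
default because extended LD in that region inflates clustered associations;
genes without coordinates cannot be filtered and are retained with a
warning. Significance cuts use strict inequality (p < α), with α = 0.01 and
0.05 the conventional working thresholds.

## Connectivity tests

**LCC permutation test.** The observed statistic is the node and edge count
of the largest connected component (LCC) of the subgraph induced by
significant genes. The null keeps the graph fixed and permutes the gene→p
assignment over nodes; since the permuted significant set is then a
uniformly random node subset of the same size, each replicate draws such a
subset directly. Nodes without a score are assigned p = 1 first, so the
significant count is invariant. Ties in LCC selection break by node count,
then edge count, then lexicographically smallest member set, making results
deterministic.

**Augmentation test.** Observed: LCC of the subgraph induced by
`base ∪ added`. Null: the same number of added genes (|added ∖ base|) drawn
uniformly from graph nodes outside the base set. This asks whether the
candidate list (e.g. DNM carriers) is better connected to the significant
backbone than random genes are.

Empirical p-values use the pseudo-counted upper tail (r + 1)/(n + 1), where
r counts null replicates with a statistic ≥ observed; p is never 0 and lies
in [1/(n+1), 1]. The ≥ convention is the conservative reading of "more
extreme than". Default n = 10,000 replicates; on the synthetic scales used
in the tests the Monte-Carlo error at p ≈ 0.05 is about ±0.007 (3 SD).

## Edge-based module search (Gens)

Each edge (i, j) is weighted by

    W_ij = |C_ij| · P_i · P_j,     Z_ij = Φ⁻¹(1 − W_ij),

with C_ij the Pearson correlation of the two genes' expression over
pairwise-complete samples. Notes on the conventions:

* **|C| rather than C.** A negative correlation would make W negative and
  Φ⁻¹(1 − W) undefined; the magnitude measures co-expression strength and
  the sign is kept as edge metadata for display (solid/dashed rendering).
* **Missing C defaults to 1**, so the weight degenerates to P_i · P_j — no
  co-expression boost or penalty. An exactly-zero correlation is floored at
  1e-16, and W is clamped to (1e-16, 1 − 1e-16) to keep the quantile finite.
  Note the formula's quirk: because C multiplies a p-value-like product,
  *weaker* co-expression makes an edge *more* extreme; with noisy expression
  data this uniformly shifts edge Z upward, which the empirical null absorbs.
* **p-values for unscored nodes default to 1** (consistent with the
  permutation test).

A module is a connected induced subgraph with k ≥ 1 edges, scored by the
mean edge Z, `Z_m = Σ Z_ij / k`. The mean normalization is the printed
definition; `norm="sqrt"` switches to `Σ Z_ij / √k`, the normalization used
by the node-based predecessor family of methods. The difference matters: the
mean of a set of edges can never exceed its largest element, so under the
mean score the globally optimal module is always a single edge and greedy
growth from a top-scoring seed cannot absorb a near-homogeneous strong
clique (it stops at the seed, since any addition dilutes the mean). Under
√k, strong cliques are absorbed exactly. Both are available; the mean is the
default.

**Greedy growth** starts from a seed edge. At each step every node adjacent
to the module is evaluated with *all* of its edges into the module counted
(induced-subgraph scoring); the best candidate is admitted iff the new score
exceeds the old by more than `Z_m · r` (r = 0.05) *and* improves strictly —
the extra strict-improvement guard closes the pathological case Z_m ≤ 0
where `Z_m · r ≤ 0` would admit arbitrarily small increments. Ties break
toward the higher new score, then the lexicographically smaller symbol.
`search_all` grows one module per seed edge (optionally only the top
fraction of edges by Z) and deduplicates identical gene sets.

**Null calibration.** For each observed module size k, `module_null` scores
random connected modules of k genes, generated by uniform frontier
expansion from a uniformly chosen start node (restarting if a component is
exhausted). The empirical p is the pseudo-counted fraction of null scores
≥ Z_m, and `Z_n = (Z_m − mean)/sd` of the null scores; sd = 0 (possible on
degenerate graphs) flags the null and leaves Z_n unset. Nulls are cached per
module size, with a per-size seed offset so caching is order-independent.
The reference null size is 100,000; the test suite and the acceptance
script use 2,000–5,000, which puts ±3 SD Monte-Carlo error at p ≈ 0.05
around ±0.01 — adequate for the comparisons made there.

A calibration property ties these pieces together: on a signal-free graph
(uniform p, no co-expression), random modules scored against the
random-module null have uniform empirical p-values. The test asserts this as
a two-sample KS test between module scores and null scores — the one-sample
uniformity test is the same hypothesis but treats the 500 p-values as
independent when they in fact share one finite estimated null, which
inflates its statistic.

**Top-gene consensus.** Modules with empirical p < 0.05 are selected, gene
occurrences across them counted, and genes with a count strictly above the
75th percentile (linear interpolation) of the counts become "top genes";
when no count is strictly above the quartile (e.g. all counts equal), the
rule degenerates and genes at or above the quartile are kept. The result is
the induced subgraph on the top genes plus the full frequency table.

The consensus should be read as a *superset* summary of where significant
modules concentrate, not as an exact module detector: greedy growth from
every seed edge tends to flow into the strongest region of the graph, so
each significant module also carries the genes along its entry path, and
the quartile cut (by construction the top ~25% of genes appearing in
significant modules) retains the strongest of those path genes alongside
the core. On planted-module simulations the consensus reliably *covers* the
planted gene set (coverage 1.0 in the shipped acceptance run) while also
including path/hub genes, so its Jaccard similarity to the planted truth is
well below 1; the acceptance suite records this behavior explicitly.

## Enrichment

One-sided hypergeometric over-representation: with universe size N, gene-set
size K and query size n (after restriction to the universe), p = P(X ≥
overlap) for X ~ Hypergeom(N, K, n), with Benjamini–Hochberg (default) or
Bonferroni correction across sets. The universe defaults to the union of
GMT members and can be restricted (e.g. to network genes); the choice of
background materially changes p-values and is left explicit.

## Synthetic data

The generator emulates the statistical structure the pipeline's tests
assume, not real genomes:

* **Topology**: scale-free (Barabási–Albert, m = 2, mean degree ≈ 4,
  comparable to literature-curated interactomes), Erdős–Rényi (mean degree
  4) or Watts–Strogatz small-world.
* **Planted modules** are realized as cliques over randomly chosen disjoint
  gene sets — the simplest connected subgraph with unambiguous membership —
  with p ~ U(p_low, p_high) and expression rows sharing a latent factor:
  `x = √ρ·f + √(1−ρ)·ε` gives pairwise correlation ≈ ρ (corr_within).
* **Background** genes draw p from U(0, 1) (configurable) and independent
  N(0, 1) expression over n_samples (default 50) samples.
* **DNM lists** (default 50 genes) place a configurable fraction
  (default 0.5) on network neighbours of planted genes — emulating the
  common/rare convergence the augmentation test detects — and the rest on
  genes away from the planted neighbourhood; CNV lists (default 30) are
  uniform draws.
* **Coordinates** are assigned sequentially, one gene per Mb across 22
  synthetic chromosomes, so region-exclusion paths are exercisable with a
  custom window.
* Interaction files carry two distinct synthetic PMIDs per edge, so the
  default support filter reproduces the graph on round-trip; all files are
  byte-reproducible from the spec seed.

What the generator does **not** emulate: LD structure along chromosomes
(gene-level p-values are independent draws), realistic degree distributions
beyond the topology families, probe-level expression noise, or identifier
aliasing. Passing tests therefore demonstrate the correctness and
calibration of the statistics, not performance on real interactome data.

## Determinism

Every stochastic routine takes an explicit seed and uses an isolated
`numpy.random.Generator`; the CLI derives per-stage substreams from one
run-level seed, and run directories carry a manifest (parameters, input
checksums, seed, version). Fixed seeds reproduce all artifacts byte for
byte; all tie-breaks are lexicographic.

## Problem sizes used in tests and the acceptance script

Permutation tests run at their reference 10,000 replicates. Module nulls run
at 5,000 (calibration, acceptance script) or 2,000 (recovery replicates)
instead of the reference 100,000; at these sizes the quantities under test
are orders of magnitude away from their thresholds or are compared with
Monte-Carlo error bands, so the reduction does not affect any conclusion.
Synthetic graphs are 200–300 genes, the scale at which exhaustive oracles
(enumeration of placements, of connected subgraphs, of hypergeometric sums)
remain feasible next to the Monte-Carlo implementations they check.
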