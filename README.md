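# gensnet

Network-convergence analysis of common and rare genetic risk factors on
protein–protein interaction (PPI) networks.

Genome-wide association studies yield gene-level association p-values; exome
and CNV studies yield lists of genes hit by de novo mutations (DNMs) or copy
number variants. `gensnet` asks whether these signals converge on connected
regions of the interactome, and extracts the gene modules that carry the
combined signal. It provides, as a library and as a `gensnet` command line:

* **High-confidence PPI graph construction** — interaction tables (simple TSV
  or MITAB-style exports) filtered to interactions supported by at least two
  *distinct* publications.
* **LCC permutation test** — the largest connected component (LCC) of the
  subnetwork induced by significant genes (gene-level *P* < α, MHC region
  chr6:25–34 Mb excluded), compared against a null that keeps the topology
  fixed and permutes the gene→p assignment (default 10,000 replicates).
* **Augmentation test** — does adding a candidate gene list (e.g. DNM
  carriers) grow the significant-gene LCC more than adding equally many
  random genes?
* **Gens, an edge-based greedy module search.** Each edge *(i, j)* gets a
  weight and a Z score from the gene-level p-values *P_i*, *P_j* and the
  co-expression coefficient *C_ij* (Pearson, over an expression matrix):

  ```
  W_ij = |C_ij| · P_i · P_j          Z_ij = Φ⁻¹(1 − W_ij)
  ```

  A module is a connected induced subgraph scored by the mean of its k edge
  Z scores, `Z_m = Σ Z_ij / k`. Greedy growth starts from a seed edge and
  admits the best adjacent gene while the score improves by more than
  `Z_m · r` (r = 0.05). Significance comes from an empirical null of random
  connected modules of the same gene count (default 100,000), giving an
  empirical p-value and a size-normalized score
  `Z_n = (Z_m − mean(Z_m(π))) / sd(Z_m(π))`.
* **Top-gene consensus** — genes whose occurrence count across significant
  modules (empirical *P* < 0.05) exceeds the upper quartile form a consensus
  network for visualization and enrichment.
* **Hypergeometric over-representation** of any result gene set against GMT
  gene-set collections, with Benjamini–Hochberg correction.
* **Synthetic data** — a generator for all five input kinds (interactions,
  gene scores, expression, DNM/CNV lists, GMT) with planted modules whose
  association strength and within-module co-expression are controlled, so
  the whole pipeline is testable without external downloads.

## Worked example

Generate a 200-gene scale-free synthetic study with one planted 8-gene
module (gene-level p ∈ [1e−6, 1e−4], within-module co-expression 0.8) and a
DNM list half of which is network-adjacent to the planted genes, then run
the full pipeline:

```bash
gensnet simulate --spec spec.yaml --out sim
gensnet build-graph --interactions sim/interactions.tsv --out graph
gensnet lcc-test     --graph graph/graph.graphml --scores sim/scores.tsv \
                     --alpha 0.05 --n-perm 10000 --seed 1 --out lcc
gensnet augment-test --graph graph/graph.graphml --scores sim/scores.tsv \
                     --base-alpha 0.05 --add sim/dnm_genes.txt \
                     --n-perm 10000 --seed 1 --out aug
gensnet search    --graph graph/graph.graphml --scores sim/scores.tsv \
                  --expr sim/expression.tsv --n-sim 5000 --seed 1 --out search
gensnet top-genes --modules search/modules.json --graph graph/graph.graphml --out top
gensnet enrich    --genes top/top_genes.txt --gmt sim/gene_sets.gmt --out enr
```

which prints (seed 7 spec, exactly as above):

```
wrote 7 files to sim (200 genes, 424 interactions)
graph: 200 nodes, 424 edges
observed LCC: 10 nodes / 30 edges; P_node=0.029 P_edge=9.999e-05
augmented LCC: 43 nodes / 80 edges; P_node=0.07409 P_edge=0.005599
424 modules (209 with empirical P < 0.05)
top-gene network: 33 nodes, 75 edges
tested 11 gene sets
```

Reading the numbers: the ten significant genes that interact form an LCC
with far more edges than random p-value assignments produce
(P_edge ≈ 1/10001, the pseudo-count floor), because the planted module is
both associated and densely wired. Adding the DNM list grows the LCC to 43
nodes; the edge count, not the node count, is what separates it from random
additions here (P_edge ≈ 0.006). The module search seeds one greedy growth
per edge; the consensus network over significant modules contains all eight
planted genes, and the enrichment table ranks the planted gene set first
(`planted_module_1: overlap 8/8, P = 5.8e-07, BH-adjusted 6.4e-06`).

Every run directory carries a `manifest.json` with input checksums, the
resolved parameters and the RNG seed; rerunning any subcommand with the same
seed reproduces its artifacts byte for byte.

## Library layout

| module                 | contents                                              |
|------------------------|-------------------------------------------------------|
| `gensnet.ppi`          | interaction readers, support filter, GraphML/TSV IO   |
| `gensnet.scores`       | gene-score table, MHC exclusion, significance cuts    |
| `gensnet.coexpression` | expression matrix, per-edge Pearson correlations      |
| `gensnet.connectivity` | subnetworks, LCC, permutation and augmentation tests  |
| `gensnet.gens`         | edge scoring, greedy search, null calibration, top genes |
| `gensnet.enrichment`   | GMT parsing, hypergeometric over-representation       |
| `gensnet.simulate`     | synthetic-data generator and writers                  |
| `gensnet.cli`          | the `gensnet` command line                            |

See `docs/methods.md` for the statistical model, parameter defaults and the
design decisions behind the implementation.
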